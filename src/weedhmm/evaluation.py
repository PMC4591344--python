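"""One-step-ahead prediction, cross-validation and survey filters.

Prediction quality is scored the way semi-quantitative weed surveys are
read in practice: how often absence (class 1) is predicted when absence is
observed, how often presence (class > 1) is predicted when presence is
observed, and — for the misses — how far the predicted class sits from the
observed one (signed, predicted minus observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SpeciesParameters, SurveyDataset
from .inference import FitResult, SearchConfig, fit_ml
from .kernels import KernelCache, TransitionKernel

__all__ = [
    "MetricCells",
    "CVReport",
    "predictive_distribution",
    "predict_next_class",
    "compute_metrics",
    "cross_validate",
    "select_species",
    "cv_table",
]


# ---------------------------------------------------------------------------
# one-step-ahead prediction
# ---------------------------------------------------------------------------

def predictive_distribution(
    actions: Sequence[str],
    observations: Sequence[int],
    params: SpeciesParameters,
    kernels: Dict[str, TransitionKernel],
    strict_single_step: bool = False,
) -> np.ndarray:
    """Distribution of the next emerged class given an observed prefix.

    ``actions`` must contain one more entry than ``observations``: the
    trailing action governs the transition into the predicted survey.  The
    seed-bank distribution is filtered through the full prefix by default;
    in ``strict_single_step`` mode it is re-initialised from ``p0`` and
    conditioned on the latest observation only.
    """
    if len(actions) != len(observations) + 1:
        raise ValueError("need exactly one more action than observations")
    if strict_single_step and len(observations) > 1:
        observations = observations[-1:]
        actions = actions[-2:]
    alpha = params.p0.copy()
    for t, obs in enumerate(observations):
        kern = kernels[actions[t]]
        post = alpha * kern.emergence[:, obs - 1]
        c = post.sum()
        if c <= 0.0:
            warnings.warn(
                "observed prefix has probability 0 under the model; "
                "falling back to prior propagation",
                RuntimeWarning,
                stacklevel=2,
            )
            alpha = alpha @ kern.marginal_bank_transition()
        else:
            alpha = (post / c) @ kern.bank_update[:, obs - 1, :]
    return alpha @ kernels[actions[-1]].emergence


def predict_next_class(
    actions: Sequence[str],
    observations: Sequence[int],
    params: SpeciesParameters,
    kernels: Dict[str, TransitionKernel],
    strict_single_step: bool = False,
) -> int:
    """Mode of the one-step-ahead class distribution; ties go to the
    smallest class."""
    dist = predictive_distribution(
        actions, observations, params, kernels, strict_single_step
    )
    return int(np.argmax(dist)) + 1  # argmax takes the first (smallest) mode


# ---------------------------------------------------------------------------
# Table-style metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricCells:
    """Efficiencies and signed class errors; ``None`` marks an empty stratum
    (printed as "n.a."), never silently zero."""

    absence_efficiency: float | None
    presence_efficiency: float | None
    class_error_absence: Tuple[float, float] | None  # (mean, sd) over misses
    class_error_presence: Tuple[float, float] | None
    n_absence: int
    n_presence: int

    @staticmethod
    def _fmt(cell: Tuple[float, float] | None) -> str:
        if cell is None:
            return "n.a."
        return f"{cell[0]:.2f} ({cell[1]:.2f})"

    def as_row(self) -> Dict[str, object]:
        return {
            "absence_efficiency": (
                "n.a." if self.absence_efficiency is None
                else round(self.absence_efficiency, 4)
            ),
            "presence_efficiency": (
                "n.a." if self.presence_efficiency is None
                else round(self.presence_efficiency, 4)
            ),
            "class_error_absence": self._fmt(self.class_error_absence),
            "class_error_presence": self._fmt(self.class_error_presence),
            "n_absence": self.n_absence,
            "n_presence": self.n_presence,
        }


def _error_cell(errors: np.ndarray) -> Tuple[float, float] | None:
    if errors.size == 0:
        return None
    return float(errors.mean()), float(errors.std())


def compute_metrics(
    predicted: Sequence[int], observed: Sequence[int]
) -> MetricCells:
    """Efficiencies over the absence/presence strata and signed class errors
    over the incorrect predictions only."""
    pred = np.asarray(predicted, dtype=np.int64)
    obs = np.asarray(observed, dtype=np.int64)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    absent = obs == 1
    present = obs > 1
    abs_eff = float((pred[absent] == 1).mean()) if absent.any() else None
    pres_eff = float((pred[present] > 1).mean()) if present.any() else None
    miss_abs = absent & (pred != obs)
    miss_pres = present & (pred != obs)
    return MetricCells(
        absence_efficiency=abs_eff,
        presence_efficiency=pres_eff,
        class_error_absence=_error_cell((pred - obs)[miss_abs]),
        class_error_presence=_error_cell((pred - obs)[miss_pres]),
        n_absence=int(absent.sum()),
        n_presence=int(present.sum()),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    species_id: str
    metrics: MetricCells
    fold_sizes: List[int]
    fold_assignment: Dict[str, int]  # field_id -> fold
    predictions: pd.DataFrame  # field_id, fold, t, observed, predicted
    fits: List[FitResult] = field(default_factory=list)

    def as_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {"species": self.species_id}
        row.update(self.metrics.as_row())
        return row


def partition_folds(n: int, n_folds: int, seed: int) -> List[np.ndarray]:
    """Seeded random partition into near-equal folds; the remainder goes to
    the first folds (329 fields over 4 folds gives sizes 83/82/82/82)."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} fields into {n_folds} folds")
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, n_folds)
    folds, start = [], 0
    for i in range(n_folds):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


def cross_validate(
    dataset: SurveyDataset,
    n_folds: int = 4,
    search: SearchConfig | None = None,
    seed: int = 0,
    strict_single_step: bool = False,
    **fit_kwargs,
) -> CVReport:
    """K-fold cross-validated one-step-ahead prediction.

    Fields are partitioned at random into ``n_folds`` folds; for each fold
    the model is refitted on the remaining fields and every held-out
    observation is predicted one step ahead from its own prefix.
    """
    if "space" not in fit_kwargs:
        from .inference import ParameterSpace

        # pin the action set to the whole dataset: a training fold may be
        # missing an action that still occurs in its held-out series
        fit_kwargs = dict(fit_kwargs)
        fit_kwargs["space"] = ParameterSpace(
            actions=tuple(dict.fromkeys(dataset.actions_used))
        )
    folds = partition_folds(dataset.n, n_folds, seed)
    assignment = {
        dataset.series[i].field_id: k for k, fold in enumerate(folds) for i in fold
    }
    rows = []
    fits: List[FitResult] = []
    for k, fold in enumerate(folds):
        held = set(fold.tolist())
        train = SurveyDataset(
            species_id=dataset.species_id,
            series=[s for i, s in enumerate(dataset.series) if i not in held],
        )
        fit = fit_ml(train, search=search, **fit_kwargs)
        fits.append(fit)
        cache = KernelCache(
            scheme=fit_kwargs.get("scheme"),
            backend=fit_kwargs.get("kernel_backend", "exact"),
            K=fit_kwargs.get("K", 30_000),
            production_mode=fit_kwargs.get("production_mode", "poisson"),
            cap=fit_kwargs.get("cap"),
            base_seed=seed,
        )
        kernels = {
            a: cache.get(fit.params.lht[a], i)
            for i, a in enumerate(fit.params.lht)
        }
        for i in fold:
            s = dataset.series[i]
            for t in range(len(s)):
                pred = predict_next_class(
                    s.actions[: t + 1],
                    s.observations[:t],
                    fit.params,
                    kernels,
                    strict_single_step=strict_single_step,
                )
                rows.append(
                    {
                        "field_id": s.field_id,
                        "fold": k,
                        "t": t + 1,
                        "observed": s.observations[t],
                        "predicted": pred,
                    }
                )
    pred_df = pd.DataFrame(rows)
    metrics = compute_metrics(pred_df["predicted"], pred_df["observed"])
    return CVReport(
        species_id=dataset.species_id,
        metrics=metrics,
        fold_sizes=[len(f) for f in folds],
        fold_assignment=assignment,
        predictions=pred_df,
        fits=fits,
    )


def cv_table(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Survey-style summary table, one row per species."""
    return pd.DataFrame([r.as_row() for r in reports])


# ---------------------------------------------------------------------------
# survey filters
# ---------------------------------------------------------------------------

def select_species(
    records: pd.DataFrame,
    min_surveys: int = 120,
    min_pair_fraction: float = 0.10,
) -> List[str]:
    """Species retained for estimation.

    A species must occur (class > 1) in at least ``min_surveys`` survey
    records, and each of its (species, action) pairs must occur in at least
    ``min_pair_fraction`` of all recorded crop sequences (fields); a species
    failing the pair rule for any action in the table is dropped.
    """
    if records.empty:
        return []
    occ = records[records["abundance_class"] > 1]
    counts = occ.groupby("species_id").size()
    candidates = counts[counts >= min_surveys].index
    n_fields = records["field_id"].nunique()
    actions = records["action"].unique()
    kept = []
    for sp in candidates:
        sp_occ = occ[occ["species_id"] == sp]
        per_action = sp_occ.groupby("action")["field_id"].nunique()
        fractions = np.array([per_action.get(a, 0) / n_fields for a in actions])
        if np.all(fractions >= min_pair_fraction):
            kept.append(sp)
    return sorted(kept)
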