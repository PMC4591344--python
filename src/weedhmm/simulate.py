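"""Synthetic survey generator with the structure of the field campaign.

Emulates a national botanical monitoring design: a few hundred fields, each
followed for a handful of consecutive years under one of four crop-based
management actions, with emerged-plant counts censored to the four-class
Barralis-derived abundance scale.  Ground-truth life-history parameters and
the hidden count trajectories are returned alongside the observable data so
every pipeline stage can be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import optimize

from .core import (
    DEFAULT_ACTIONS,
    AbundanceClassScheme,
    FieldSeries,
    SpeciesParameters,
    SurveyDataset,
    classify_count,
    sample_count_in_class,
    step_counts_vec,
)

__all__ = ["StudyDesign", "HiddenTrajectory", "default_design", "generate_dataset"]

#: Observed action shares in the survey: winter cereals, oilseed rape,
#: maize, sunflower.  As printed they total 99.9%; renormalised here.
_ACTION_SHARES = {"WC": 0.496, "OR": 0.102, "M": 0.293, "SF": 0.108}

#: Survey scale: number of fields, and mean/sd of series duration in years.
_N_FIELDS = 329
_MEAN_LENGTH = 3.62
_SD_LENGTH = 1.19


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a synthetic survey campaign."""

    n_fields: int
    series_length_pmf: Dict[int, float]  # support {2..8} years
    action_frequencies: Dict[str, float]
    rotation_model: str = "iid"  # or "markov"
    action_transition: np.ndarray | None = None  # row-stochastic, markov only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        for name, pmf in (
            ("series_length_pmf", self.series_length_pmf),
            ("action_frequencies", self.action_frequencies),
        ):
            vals = np.array(list(pmf.values()), dtype=float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability mass function")
        if self.rotation_model not in ("iid", "markov"):
            raise ValueError("rotation_model must be 'iid' or 'markov'")
        if self.rotation_model == "markov":
            P = self.action_transition
            na = len(self.action_frequencies)
            if P is None or P.shape != (na, na) or not np.allclose(P.sum(1), 1.0):
                raise ValueError("markov rotation needs a row-stochastic action matrix")

    @property
    def actions(self) -> Tuple[str, ...]:
        return tuple(self.action_frequencies)

    def length_moments(self) -> Tuple[float, float]:
        ks = np.array(list(self.series_length_pmf))
        ps = np.array(list(self.series_length_pmf.values()))
        m = float(ks @ ps)
        return m, float(np.sqrt((ks - m) ** 2 @ ps))


def _maxent_pmf(support: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Maximum-entropy pmf on ``support`` matching the first two moments.

    Member of the exponential family p_k proportional to exp(a k + b k^2);
    the two natural parameters are solved for deterministically.
    """

    def residual(lam: np.ndarray) -> np.ndarray:
        w = np.exp(lam[0] * support + lam[1] * support**2)
        p = w / w.sum()
        m = p @ support
        v = p @ (support - m) ** 2
        return np.array([m - mean, v - sd**2])

    sol = optimize.root(residual, x0=np.array([0.0, 0.0]), tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"moment matching failed: {sol.message}")
    w = np.exp(sol.x[0] * support + sol.x[1] * support**2)
    return w / w.sum()


def default_design() -> StudyDesign:
    """The survey-calibrated design: 329 fields, series of 2--8 years with
    mean 3.62 and sd 1.19 (maximum-entropy pmf), iid crop draws at the
    observed action shares."""
    support = np.arange(2, 9)
    pmf = _maxent_pmf(support, _MEAN_LENGTH, _SD_LENGTH)
    shares = np.array(list(_ACTION_SHARES.values()))
    shares = shares / shares.sum()
    return StudyDesign(
        n_fields=_N_FIELDS,
        series_length_pmf={int(k): float(p) for k, p in zip(support, pmf)},
        action_frequencies={a: float(p) for a, p in zip(_ACTION_SHARES, shares)},
    )


@dataclass
class HiddenTrajectory:
    """Ground-truth count trajectory behind one observed series.

    ``seeds[t]`` is the bank count entering year ``t`` (length T+1, the last
    entry being the bank left after the final survey); ``plants[t]`` is the
    emerged count censored into ``observations[t]``.
    """

    field_id: str
    bank_class0: int
    seeds: np.ndarray  # (T+1,)
    plants: np.ndarray  # (T,)


def generate_dataset(
    truth: SpeciesParameters,
    design: StudyDesign | None = None,
    production_mode: str = "poisson",
    rng: np.random.Generator | None = None,
    scheme: AbundanceClassScheme | None = None,
    species_id: str = "SYNTH",
) -> Tuple[SurveyDataset, List[HiddenTrajectory]]:
    """Simulate one species' survey dataset plus its hidden truth record.

    Per field: a series length and action sequence are drawn from the
    design, the initial bank class from ``truth.p0`` (count uniform within
    the class), and the count dynamics are iterated one year at a time; the
    emerged counts are censored to the four observation classes.
    """
    design = design or default_design()
    scheme = scheme or AbundanceClassScheme()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    truth.require_actions(design.actions)
    actions = design.actions
    freqs = np.array(list(design.action_frequencies.values()))
    lengths = np.array(list(design.series_length_pmf))
    length_p = np.array(list(design.series_length_pmf.values()))

    series: List[FieldSeries] = []
    hidden: List[HiddenTrajectory] = []
    for i in range(design.n_fields):
        T = int(rng.choice(lengths, p=length_p))
        if design.rotation_model == "iid":
            a_idx = rng.choice(len(actions), size=T, p=freqs)
        else:
            a_idx = np.empty(T, dtype=np.int64)
            a_idx[0] = rng.choice(len(actions), p=freqs)
            for t in range(1, T):
                a_idx[t] = rng.choice(len(actions), p=design.action_transition[a_idx[t - 1]])
        acts = tuple(actions[j] for j in a_idx)

        c0 = int(rng.choice(np.arange(1, 7), p=truth.p0))
        y = sample_count_in_class(c0, scheme, "seedbank", rng)
        seeds = np.empty(T + 1, dtype=np.int64)
        plants = np.empty(T, dtype=np.int64)
        seeds[0] = y
        for t, a in enumerate(acts):
            x_t, y = (
                int(v[0])
                for v in step_counts_vec(
                    np.array([y]), truth.lht[a], production_mode, rng
                )
            )
            plants[t] = x_t
            seeds[t + 1] = y
        obs = tuple(int(c) for c in classify_count(plants, scheme, "emerged"))
        fid = f"F{i + 1:04d}"
        series.append(FieldSeries(field_id=fid, actions=acts, observations=obs))
        hidden.append(
            HiddenTrajectory(field_id=fid, bank_class0=c0, seeds=seeds, plants=plants)
        )
    return SurveyDataset(species_id=species_id, series=series), hidden
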