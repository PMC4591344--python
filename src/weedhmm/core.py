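"""Domain types and count-level population dynamics.

The model describes an annual weed species whose persistent soil seed bank
is never observed directly.  Each year a field under management action ``a``
(a crop type plus its associated practices) turns ``Y`` seeds into ``X'``
emerged plants by germination/establishment (probability ``sigma``), kills a
fraction ``1 - s`` of the seeds that stayed in the bank, and receives
``phi`` new seeds per emerged plant.  Field surveys record only the emerged
plants, censored to a semi-quantitative Barralis abundance class (1--4);
the seed bank is described on a finer six-class grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "DEFAULT_ACTIONS",
    "AbundanceClassScheme",
    "LHTriplet",
    "SpeciesParameters",
    "PopulationState",
    "FieldSeries",
    "SurveyDataset",
    "step_counts",
    "step_counts_vec",
    "classify_count",
    "sample_count_in_class",
]

#: Default management-action set: winter cereals, oilseed rape, maize, sunflower.
DEFAULT_ACTIONS: Tuple[str, ...] = ("WC", "OR", "M", "SF")

Grid = Literal["emerged", "seedbank"]


def _validate_bounds(bounds: Sequence[Tuple[int, int | None]], name: str) -> None:
    if not bounds:
        raise ValueError(f"{name}: empty class grid")
    expected_lo = 0
    for i, (lo, hi) in enumerate(bounds):
        if lo != expected_lo:
            raise ValueError(
                f"{name}: class {i + 1} starts at {lo}, expected {expected_lo} "
                "(intervals must be contiguous from 0)"
            )
        if hi is None:
            if i != len(bounds) - 1:
                raise ValueError(f"{name}: only the top class may be open-ended")
        else:
            if hi < lo:
                raise ValueError(f"{name}: class {i + 1} has upper bound below lower bound")
            expected_lo = hi + 1
    if bounds[-1][1] is not None:
        raise ValueError(f"{name}: top class must be open-ended (upper bound None)")


@dataclass(frozen=True)
class AbundanceClassScheme:
    """The two censoring grids mapping counts per m^2 to ordinal classes.

    Emerged plants use the four-class Barralis-derived scale; the seed bank
    uses a finer six-class grid.  The top class of each grid is open-ended;
    when a count must be *drawn* from it, the interval is truncated at
    ``emerged_top_cap`` / ``seedbank_top_cap``.
    """

    emerged_bounds: Tuple[Tuple[int, int | None], ...] = (
        (0, 0),
        (1, 2),
        (3, 20),
        (21, None),
    )
    seedbank_bounds: Tuple[Tuple[int, int | None], ...] = (
        (0, 0),
        (1, 2),
        (3, 20),
        (21, 60),
        (61, 100),
        (101, None),
    )
    emerged_top_cap: int = 100
    seedbank_top_cap: int = 300

    def __post_init__(self) -> None:
        _validate_bounds(self.emerged_bounds, "emerged_bounds")
        _validate_bounds(self.seedbank_bounds, "seedbank_bounds")
        if self.emerged_top_cap <= self.emerged_bounds[-1][0]:
            raise ValueError("emerged_top_cap must exceed the top class lower bound")
        if self.seedbank_top_cap <= self.seedbank_bounds[-1][0]:
            raise ValueError("seedbank_top_cap must exceed the top class lower bound")

    # -- helpers -----------------------------------------------------------
    def bounds(self, which: Grid) -> Tuple[Tuple[int, int | None], ...]:
        return self.emerged_bounds if which == "emerged" else self.seedbank_bounds

    def top_cap(self, which: Grid) -> int:
        return self.emerged_top_cap if which == "emerged" else self.seedbank_top_cap

    def n_classes(self, which: Grid) -> int:
        return len(self.bounds(which))

    def lowers(self, which: Grid) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds(which)], dtype=np.int64)

    def interval(self, cls: int, which: Grid, capped: bool = False) -> Tuple[int, int]:
        """Integer interval ``[lo, hi]`` of a 1-based class.

        With ``capped=True`` the open top class is truncated at the grid's cap.
        """
        bounds = self.bounds(which)
        if not 1 <= cls <= len(bounds):
            raise ValueError(f"class {cls} out of range for {which} grid")
        lo, hi = bounds[cls - 1]
        if hi is None:
            if not capped:
                raise ValueError(f"class {cls} is open-ended; pass capped=True")
            hi = self.top_cap(which)
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "emerged_bounds": [list(b) for b in self.emerged_bounds],
            "seedbank_bounds": [list(b) for b in self.seedbank_bounds],
            "emerged_top_cap": self.emerged_top_cap,
            "seedbank_top_cap": self.seedbank_top_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbundanceClassScheme":
        return cls(
            emerged_bounds=tuple(tuple(b) for b in d["emerged_bounds"]),
            seedbank_bounds=tuple(tuple(b) for b in d["seedbank_bounds"]),
            emerged_top_cap=int(d["emerged_top_cap"]),
            seedbank_top_cap=int(d["seedbank_top_cap"]),
        )


@dataclass(frozen=True)
class LHTriplet:
    """Life-history triplet under one management action.

    sigma : germination/establishment probability per seed and year.
    s     : annual survival probability of a seed that stays in the bank.
    phi   : expected number of seeds returned to the bank per emerged plant.
    """

    sigma: float
    s: float
    phi: float
    phi_max: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma={self.sigma} outside [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s={self.s} outside [0, 1]")
        if not 0.0 <= self.phi <= self.phi_max:
            raise ValueError(f"phi={self.phi} outside [0, {self.phi_max}]")


class PopulationState(NamedTuple):
    """Count state of one field: seeds in the bank, emerged plants."""

    seeds: int
    plants: int


@dataclass(frozen=True)
class SpeciesParameters:
    """Per-action life-history triplets plus the initial seed-bank class law.

    ``p0`` is the probability vector over the six seed-bank classes at the
    first survey; it is a free parameter of the model, estimated jointly
    with the triplets.
    """

    lht: Dict[str, LHTriplet]
    p0: np.ndarray

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, dtype=float)
        object.__setattr__(self, "p0", p0)
        if p0.ndim != 1 or p0.shape[0] != 6:
            raise ValueError("p0 must be a length-6 probability vector")
        if np.any(p0 < 0):
            raise ValueError("p0 entries must be non-negative")
        if abs(p0.sum() - 1.0) > 1e-12:
            raise ValueError(f"p0 must sum to 1 (got {p0.sum()!r})")
        if not self.lht:
            raise ValueError("lht must cover a non-empty action set")

    @property
    def actions(self) -> Tuple[str, ...]:
        return tuple(self.lht)

    def require_actions(self, actions: Iterable[str]) -> None:
        missing = sorted(set(actions) - set(self.lht))
        if missing:
            raise KeyError(f"no life-history triplet for action(s): {missing}")


@dataclass(frozen=True)
class FieldSeries:
    """One field's annual action sequence and observed emerged classes.

    ``actions[t]`` is the action governing the transition into the survey
    that produced ``observations[t]`` (the trailing season's action, if
    recorded, is not part of the likelihood and is not stored).
    """

    field_id: str
    actions: Tuple[str, ...]
    observations: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))
        object.__setattr__(self, "observations", tuple(int(o) for o in self.observations))
        if len(self.actions) != len(self.observations):
            raise ValueError(
                f"field {self.field_id}: {len(self.actions)} actions but "
                f"{len(self.observations)} observations"
            )
        if len(self.observations) < 1:
            raise ValueError(f"field {self.field_id}: empty series")
        if any(o not in (1, 2, 3, 4) for o in self.observations):
            raise ValueError(f"field {self.field_id}: observed classes must be in 1..4")

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class SurveyDataset:
    """A species' collection of independent field series."""

    species_id: str
    series: List[FieldSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.series) < 1:
            raise ValueError("a dataset needs at least one series")

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def actions_used(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for s in self.series:
            for a in s.actions:
                if a not in seen:
                    seen.append(a)
        return tuple(seen)

    @property
    def n_observations(self) -> int:
        return sum(len(s) for s in self.series)


# ---------------------------------------------------------------------------
# Count-level dynamics
# ---------------------------------------------------------------------------

def step_counts_vec(
    seeds: np.ndarray,
    lht: LHTriplet,
    production_mode: str = "poisson",
    rng: np.random.Generator | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Advance an array of seed-bank counts one year; returns ``(plants, seeds')``.

    Germination first (``X' ~ Binomial(Y, sigma)``), then mortality among the
    seeds that stayed (``Dead ~ Binomial(Y - X', 1 - s)``), then the seed rain
    of the emerged plants is added (``Poisson(phi * X')`` or, in deterministic
    mode, ``round(phi * X')``).  Standing plants never carry over (annuals).
    """
    if rng is None:
        rng = np.random.default_rng()
    seeds = np.asarray(seeds, dtype=np.int64)
    if np.any(seeds < 0):
        raise ValueError("seed counts must be non-negative")
    plants = rng.binomial(seeds, lht.sigma)
    survivors = rng.binomial(seeds - plants, lht.s)
    if production_mode == "poisson":
        new_seeds = rng.poisson(lht.phi * plants)
    elif production_mode == "deterministic":
        new_seeds = np.rint(lht.phi * plants).astype(np.int64)
    else:
        raise ValueError(f"unknown production_mode {production_mode!r}")
    return plants, survivors + new_seeds


def step_counts(
    state: PopulationState,
    lht: LHTriplet,
    production_mode: str = "poisson",
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """One-year update of a single field's count state."""
    plants, seeds = step_counts_vec(
        np.array([state.seeds]), lht, production_mode=production_mode, rng=rng
    )
    return PopulationState(seeds=int(seeds[0]), plants=int(plants[0]))


def classify_count(
    count: int | np.ndarray, scheme: AbundanceClassScheme, which: Grid
) -> int | np.ndarray:
    """Map a count (or array of counts) to its 1-based abundance class."""
    lowers = scheme.lowers(which)
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    cls = np.searchsorted(lowers, arr, side="right")
    if np.isscalar(count) or arr.ndim == 0:
        return int(cls)
    return cls.astype(np.int64)


def sample_count_in_class(
    cls: int,
    scheme: AbundanceClassScheme,
    which: Grid,
    rng: np.random.Generator,
    size: int | None = None,
) -> int | np.ndarray:
    """Draw count(s) uniformly from a class interval (top class capped)."""
    lo, hi = scheme.interval(int(cls), which, capped=True)
    out = rng.integers(lo, hi + 1, size=size)
    if size is None:
        return int(out)
    return out
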