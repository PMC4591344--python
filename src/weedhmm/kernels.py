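"""Class-level transition kernels of the seed-bank HMM.

The hidden chain lives on six seed-bank abundance classes; each annual
transition under action ``a`` is summarised by two conditional tables,

* ``emergence[c_y, c_x']``   = P_a(emerged class c_x' | bank class c_y)
* ``bank_update[c_y, c_x', c_y']`` = P_a(bank class c_y' | c_x', c_y)

obtained by integrating the count-level binomial/Poisson dynamics over the
class intervals (counts uniform within a class, open top classes truncated).
Two estimators are provided: a Monte-Carlo one (the survey-scale procedure,
``K`` simulated fields per bank class) and an exact enumeration used both as
a deterministic inference backend and as the oracle the Monte-Carlo
estimator is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .core import AbundanceClassScheme, LHTriplet, classify_count, step_counts_vec

__all__ = [
    "TransitionKernel",
    "estimate_kernel_mc",
    "exact_kernel_enumeration",
    "KernelCache",
    "kernel_to_frame",
]

_PAIR_PMF_FLOOR = 1e-15  # germination outcomes below this weight are dropped

# sub-table memos: survivor pmf depends on s only, seed-rain CDF on phi only,
# so component-wise samplers that move one trait at a time reuse the rest
_SURV_CACHE: Dict[Tuple, np.ndarray] = {}
_RAIN_CACHE: Dict[Tuple, Tuple[int, np.ndarray]] = {}


@dataclass(frozen=True)
class TransitionKernel:
    """Emergence matrix, bank-update tensor and their support mask.

    ``support_mask[c_y, c_x']`` is False where the pair has (numerically)
    zero emergence probability; the corresponding ``bank_update`` slice is
    filled with the uniform distribution.  Such slices can only be reached
    by the likelihood with factor 0 and never influence it.
    """

    emergence: np.ndarray  # (n_bank, n_emerged)
    bank_update: np.ndarray  # (n_bank, n_emerged, n_bank)
    support_mask: np.ndarray  # (n_bank, n_emerged) bool

    def __post_init__(self) -> None:
        e, b, m = self.emergence, self.bank_update, self.support_mask
        if e.ndim != 2 or b.shape != (*e.shape, e.shape[0]) or m.shape != e.shape:
            raise ValueError("inconsistent kernel table shapes")

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.emergence < -atol) or np.any(self.emergence > 1 + atol):
            raise ValueError("emergence entries outside [0, 1]")
        if np.any(self.bank_update < -atol) or np.any(self.bank_update > 1 + atol):
            raise ValueError("bank_update entries outside [0, 1]")
        if not np.allclose(self.emergence.sum(axis=1), 1.0, atol=atol):
            raise ValueError("emergence rows must sum to 1")
        if not np.allclose(self.bank_update.sum(axis=2), 1.0, atol=atol):
            raise ValueError("bank_update slices must sum to 1")

    def marginal_bank_transition(self) -> np.ndarray:
        """One-step bank-class transition matrix, emergence marginalised out."""
        return np.einsum("yx,yxz->yz", self.emergence, self.bank_update)


# ---------------------------------------------------------------------------
# shared tables
# ---------------------------------------------------------------------------

_LOGCOMB_CACHE: Dict[int, np.ndarray] = {}


def _log_comb_table(nmax: int) -> np.ndarray:
    """log C(n, k) for 0 <= k <= n <= nmax (lower triangle; junk above)."""
    tab = _LOGCOMB_CACHE.get(nmax)
    if tab is None:
        n = np.arange(nmax + 1)
        lg = special.gammaln(n + 1.0)
        nk = n[:, None] - n[None, :]
        tab = lg[:, None] - lg[None, :] - np.where(nk >= 0, special.gammaln(nk + 1.0), 0.0)
        _LOGCOMB_CACHE[nmax] = tab
    return tab


def _binom_pmf_rows(ns: np.ndarray, p: float, kmax: int) -> np.ndarray:
    """Matrix B[i, k] = Binomial(ns[i], p) pmf at k, k = 0..kmax (0 for k > n)."""
    ns = np.asarray(ns, dtype=np.int64)
    kk = np.arange(kmax + 1)
    valid = kk[None, :] <= ns[:, None]
    if p <= 0.0:
        return (kk[None, :] == 0).astype(float) * np.ones((ns.size, 1))
    if p >= 1.0:
        return (kk[None, :] == ns[:, None]).astype(float)
    tab = _log_comb_table(int(max(ns.max(), kmax)))
    logc = tab[ns[:, None], np.minimum(kk[None, :], ns[:, None])]
    logpmf = logc + kk[None, :] * np.log(p) + (ns[:, None] - kk[None, :]) * np.log1p(-p)
    out = np.where(valid, np.exp(np.where(valid, logpmf, -np.inf)), 0.0)
    return out


def _seedbank_boundaries(scheme: AbundanceClassScheme) -> np.ndarray:
    """Finite upper bounds of all but the top seed-bank class."""
    return np.array([hi for _, hi in scheme.seedbank_bounds[:-1]], dtype=np.int64)


def _class_intervals(scheme: AbundanceClassScheme, cap: int) -> list[tuple[int, int]]:
    out = []
    for lo, hi in scheme.seedbank_bounds:
        out.append((lo, cap if hi is None else hi))
    return out


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def exact_kernel_enumeration(
    lht: LHTriplet,
    scheme: AbundanceClassScheme | None = None,
    production_mode: str = "poisson",
    cap: int | None = None,
) -> TransitionKernel:
    """Exact class-censored transition kernel by full enumeration.

    Sums binomial (germination, survival) and Poisson (seed rain)
    probabilities over every count combination, with the initial seed count
    uniform over each class interval and the open top class truncated at
    ``cap``.  Deterministic: same inputs, bit-identical output.
    """
    scheme = scheme or AbundanceClassScheme()
    cap = int(scheme.seedbank_top_cap if cap is None else cap)
    lowers = scheme.lowers("seedbank")
    if cap < lowers.max():
        raise ValueError(f"cap={cap} is below the top seed-bank class lower bound")

    n_bank = scheme.n_classes("seedbank")
    n_em = scheme.n_classes("emerged")
    bnd = _seedbank_boundaries(scheme)  # (n_bank-1,) finite uppers
    bmax = int(bnd.max())
    em_lowers = scheme.lowers("emerged")
    intervals = _class_intervals(scheme, cap)

    # survivor table S[n, k] = Binom(n, s) pmf at k, k <= bmax
    skey = (round(lht.s, 12), cap, bmax)
    surv = _SURV_CACHE.get(skey)
    if surv is None:
        surv = _binom_pmf_rows(np.arange(cap + 1), lht.s, bmax)
        if len(_SURV_CACHE) > 64:
            _SURV_CACHE.clear()
        _SURV_CACHE[skey] = surv

    # Seed-rain CDF table PC[x, j, k] = P(New <= bnd[j] - k | x emerged plants).
    # All arguments bnd[j] - k lie in [-bmax, bmax]; plants beyond `x_lim`
    # overshoot the top boundary almost surely and land in the top bank class.
    kk = np.arange(bmax + 1)
    q = bnd[None, :, None] - kk[None, None, :]  # (1, J, K)
    xs_all = np.arange(cap + 1)
    rkey = (round(lht.phi, 12), cap, bmax, production_mode, tuple(bnd))
    hit = _RAIN_CACHE.get(rkey)
    if hit is not None:
        x_lim, pc = hit
    else:
        if production_mode == "poisson":
            mu = lht.phi * xs_all.astype(float)
            # cdf_q[x, m] = P(Pois(phi*x) <= m) by pmf recurrence; exp underflow
            # for huge means correctly yields 0 (the rain overshoots bmax a.s.)
            cdf_q = np.empty((cap + 1, bmax + 1))
            pmf = np.exp(-mu)
            acc = pmf.copy()
            cdf_q[:, 0] = acc
            for m in range(1, bmax + 1):
                pmf = pmf * (mu / m)
                acc = acc + pmf
                cdf_q[:, m] = acc
            x_lim = int(np.max(np.nonzero(cdf_q[:, bmax] > 1e-16)[0]))
            pc = np.ascontiguousarray(
                np.where(q >= 0, cdf_q[: x_lim + 1, np.maximum(q, 0)[0]], 0.0)
            )
        elif production_mode == "deterministic":
            new = np.rint(lht.phi * xs_all).astype(np.int64)
            x_lim = int(np.max(np.nonzero(new <= bmax)[0]))
            pc = (new[: x_lim + 1, None, None] <= q).astype(float)
        else:
            raise ValueError(f"unknown production_mode {production_mode!r}")
        if len(_RAIN_CACHE) > 64:
            _RAIN_CACHE.clear()
        _RAIN_CACHE[rkey] = (x_lim, pc)

    emergence = np.zeros((n_bank, n_em))
    bank_update = np.full((n_bank, n_em, n_bank), 1.0 / n_bank)
    support = np.zeros((n_bank, n_em), dtype=bool)

    for ci, (lo, hi) in enumerate(intervals):
        ys = np.arange(lo, hi + 1)
        w_y = 1.0 / ys.size
        px = _binom_pmf_rows(ys, lht.sigma, hi)  # (nY, hi+1) germination pmf

        xs = np.arange(hi + 1)
        x_class = np.searchsorted(em_lowers, xs, side="right") - 1  # 0-based
        for cx in range(n_em):
            emergence[ci, cx] = w_y * px[:, x_class == cx].sum()

        iy, ix = np.nonzero(px > _PAIR_PMF_FLOOR)
        if iy.size == 0:
            continue
        wp = w_y * px[iy, ix]
        n_surv = ys[iy] - xs[ix]
        probs = np.zeros((wp.size, n_bank))
        low = np.nonzero(xs[ix] <= x_lim)[0]
        probs[:, -1] = 1.0  # seed rain overshoots the top boundary a.s. ...
        if low.size:
            # ... except below x_lim, where Binom(n, s) * Pois(phi x) is summed
            # exactly; pairs are grouped by plant count so each group is one
            # small matmul against that count's seed-rain CDF slice.
            xv, nv = xs[ix][low], n_surv[low]
            order = np.argsort(xv, kind="stable")
            ux, starts = np.unique(xv[order], return_index=True)
            cdf = np.empty((low.size, bnd.size))
            ends = np.append(starts[1:], low.size)
            for x, s0, s1 in zip(ux, starts, ends):
                sel = order[s0:s1]
                cdf[sel] = surv[nv[sel]] @ pc[x].T
            pl = np.empty((low.size, n_bank))
            pl[:, 0] = cdf[:, 0]
            pl[:, 1:-1] = np.diff(cdf, axis=1)
            pl[:, -1] = 1.0 - cdf[:, -1]
            np.clip(pl, 0.0, 1.0, out=pl)
            probs[low] = pl

        pair_class = x_class[ix]
        for cx in range(n_em):
            m = pair_class == cx
            wsum = wp[m].sum()
            if wsum > 0.0:
                row = wp[m] @ probs[m]
                bank_update[ci, cx] = row / row.sum()
                support[ci, cx] = True

    emergence /= emergence.sum(axis=1, keepdims=True)
    return TransitionKernel(emergence, bank_update, support)


# ---------------------------------------------------------------------------
# Monte-Carlo estimation
# ---------------------------------------------------------------------------

def estimate_kernel_mc(
    lht: LHTriplet,
    scheme: AbundanceClassScheme | None = None,
    K: int = 30_000,
    production_mode: str = "poisson",
    rng: np.random.Generator | None = None,
) -> TransitionKernel:
    """Monte-Carlo transition kernel: ``K`` simulated one-year trajectories
    per seed-bank class, counts drawn uniformly within each class interval.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    scheme = scheme or AbundanceClassScheme()
    rng = rng or np.random.default_rng()
    n_bank = scheme.n_classes("seedbank")
    n_em = scheme.n_classes("emerged")
    em_lowers = scheme.lowers("emerged")
    sb_lowers = scheme.lowers("seedbank")

    emergence = np.zeros((n_bank, n_em))
    bank_update = np.full((n_bank, n_em, n_bank), 1.0 / n_bank)
    support = np.zeros((n_bank, n_em), dtype=bool)

    for ci in range(n_bank):
        lo, hi = scheme.interval(ci + 1, "seedbank", capped=True)
        ys = rng.integers(lo, hi + 1, size=K)
        plants, seeds_next = step_counts_vec(ys, lht, production_mode, rng)
        cx = np.searchsorted(em_lowers, plants, side="right") - 1
        cy2 = np.searchsorted(sb_lowers, seeds_next, side="right") - 1
        counts = np.zeros((n_em, n_bank), dtype=np.int64)
        np.add.at(counts, (cx, cy2), 1)
        row_tot = counts.sum(axis=1)
        emergence[ci] = row_tot / K
        for cxi in range(n_em):
            if row_tot[cxi] > 0:
                bank_update[ci, cxi] = counts[cxi] / row_tot[cxi]
                support[ci, cxi] = True
    return TransitionKernel(emergence, bank_update, support)


# ---------------------------------------------------------------------------
# caching / common random numbers
# ---------------------------------------------------------------------------

class KernelCache:
    """Memoises kernels on (rounded triplet, backend settings).

    With the ``mc`` backend every kernel is generated from a stream seeded by
    ``(base_seed, action index)`` only, so repeated likelihood evaluations at
    the same parameters reuse common random numbers and the Monte-Carlo
    likelihood is a deterministic function of the parameters.
    """

    def __init__(
        self,
        scheme: AbundanceClassScheme | None = None,
        backend: str = "exact",
        K: int = 30_000,
        production_mode: str = "poisson",
        cap: int | None = None,
        base_seed: int = 0,
    ) -> None:
        if backend not in ("exact", "mc"):
            raise ValueError(f"unknown kernel backend {backend!r}")
        self.scheme = scheme or AbundanceClassScheme()
        self.backend = backend
        self.K = int(K)
        self.production_mode = production_mode
        self.cap = cap
        self.base_seed = int(base_seed)
        self._store: Dict[Tuple, TransitionKernel] = {}

    def get(self, lht: LHTriplet, action_index: int = 0) -> TransitionKernel:
        key = (
            round(lht.sigma, 12),
            round(lht.s, 12),
            round(lht.phi, 12),
            action_index if self.backend == "mc" else 0,
        )
        kern = self._store.get(key)
        if kern is None:
            if self.backend == "exact":
                kern = exact_kernel_enumeration(
                    lht, self.scheme, self.production_mode, self.cap
                )
            else:
                rng = np.random.default_rng((self.base_seed, action_index))
                kern = estimate_kernel_mc(
                    lht, self.scheme, self.K, self.production_mode, rng
                )
            if len(self._store) > 4096:
                self._store.clear()
            self._store[key] = kern
        return kern


def kernel_to_frame(kernel: TransitionKernel, action: str) -> pd.DataFrame:
    """Long-format table of all kernel entries for inspection/export.

    Emergence entries carry an empty ``c_y_next``; bank-update entries carry
    all three class indices (1-based).
    """
    rows = []
    n_bank, n_em = kernel.emergence.shape
    for cy in range(n_bank):
        for cx in range(n_em):
            rows.append(
                {
                    "action": action,
                    "table": "emergence",
                    "c_y": cy + 1,
                    "c_x_next": cx + 1,
                    "c_y_next": pd.NA,
                    "probability": kernel.emergence[cy, cx],
                }
            )
            for cy2 in range(n_bank):
                rows.append(
                    {
                        "action": action,
                        "table": "bank_update",
                        "c_y": cy + 1,
                        "c_x_next": cx + 1,
                        "c_y_next": cy2 + 1,
                        "probability": kernel.bank_update[cy, cx, cy2],
                    }
                )
    return pd.DataFrame(rows)
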