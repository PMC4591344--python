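"""Likelihood computation and parameter estimation for the seed-bank HMM.

The likelihood of one field's series (c_x^1, ..., c_x^T) under actions
(a^0, ..., a^{T-1}) marginalises the hidden seed-bank classes:

    L = sum_{c_y^0..c_y^{T-1}} p0(c_y^0) P_{a^0}(c_x^1 | c_y^0)
        prod_{t=2}^{T} P_{a^{t-2}}(c_y^{t-1} | c_x^{t-1}, c_y^{t-2})
                       P_{a^{t-1}}(c_x^t | c_y^{t-1})

computed by the scaled forward recursion (`forward_loglik`), with a literal
nested-sum evaluator (`brute_force_loglik`) kept as an independent oracle.
Fields are independent, so a species' log-likelihood is the sum over its
series.  Maximum-likelihood estimation uses a Price-type controlled random
search inside the bounded parameter box; Bayesian estimation uses
component-wise random-walk Metropolis within a Gibbs sweep under uniform
priors, on transformed coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    DEFAULT_ACTIONS,
    AbundanceClassScheme,
    FieldSeries,
    LHTriplet,
    SpeciesParameters,
    SurveyDataset,
)
from .kernels import KernelCache, TransitionKernel

__all__ = [
    "LOGLIK_FLOOR",
    "FitResult",
    "PosteriorChain",
    "SearchConfig",
    "McmcConfig",
    "ParameterSpace",
    "forward_loglik",
    "brute_force_loglik",
    "total_loglik",
    "fit_ml",
    "sample_posterior",
]

#: Finite stand-in for log(0): lets the optimiser rank impossible candidates.
LOGLIK_FLOOR = -1e10


# ---------------------------------------------------------------------------
# forward / brute-force likelihood
# ---------------------------------------------------------------------------

def forward_loglik(
    series: FieldSeries,
    params: SpeciesParameters,
    kernels: Dict[str, TransitionKernel],
    floor: float = LOGLIK_FLOOR,
) -> float:
    """Log-likelihood of one series by the scaled forward recursion."""
    missing = set(series.actions) - set(kernels)
    if missing:
        raise KeyError(f"no kernel for action(s): {sorted(missing)}")
    obs = [o - 1 for o in series.observations]
    alpha = params.p0 * kernels[series.actions[0]].emergence[:, obs[0]]
    logl = 0.0
    c = alpha.sum()
    if c <= 0.0:
        return floor
    logl += math.log(c)
    alpha = alpha / c
    for t in range(1, len(obs)):
        k_prev = kernels[series.actions[t - 1]]
        k_cur = kernels[series.actions[t]]
        alpha = (alpha @ k_prev.bank_update[:, obs[t - 1], :]) * k_cur.emergence[:, obs[t]]
        c = alpha.sum()
        if c <= 0.0:
            return floor
        logl += math.log(c)
        alpha = alpha / c
    return logl


def brute_force_loglik(
    series: FieldSeries,
    params: SpeciesParameters,
    kernels: Dict[str, TransitionKernel],
    floor: float = LOGLIK_FLOOR,
    max_T: int = 7,
) -> float:
    """Literal nested sum over all hidden class sequences (test oracle).

    Enumerates the 6^T hidden sequences explicitly; guarded to short series.
    """
    T = len(series)
    if T > max_T:
        raise ValueError(f"brute force enumeration guarded to T <= {max_T}")
    n_bank = params.p0.shape[0]
    obs = [o - 1 for o in series.observations]
    total = 0.0
    for hidden in itertools.product(range(n_bank), repeat=T):
        p = params.p0[hidden[0]] * kernels[series.actions[0]].emergence[hidden[0], obs[0]]
        for t in range(2, T + 1):
            p *= kernels[series.actions[t - 2]].bank_update[
                hidden[t - 2], obs[t - 2], hidden[t - 1]
            ]
            p *= kernels[series.actions[t - 1]].emergence[hidden[t - 1], obs[t - 1]]
        total += p
    if total <= 0.0:
        return floor
    return math.log(total)


class PackedDataset:
    """Dataset flattened to integer arrays for batched forward passes."""

    def __init__(self, dataset: SurveyDataset, actions: Sequence[str]):
        self.actions = tuple(actions)
        index = {a: i for i, a in enumerate(self.actions)}
        unknown = set(dataset.actions_used) - set(index)
        if unknown:
            raise KeyError(f"dataset uses action(s) outside the action set: {sorted(unknown)}")
        n = dataset.n
        self.lengths = np.array([len(s) for s in dataset.series], dtype=np.int64)
        max_t = int(self.lengths.max())
        self.obs = np.zeros((n, max_t), dtype=np.int64)
        self.act = np.zeros((n, max_t), dtype=np.int64)
        for i, s in enumerate(dataset.series):
            self.obs[i, : len(s)] = np.array(s.observations) - 1
            self.act[i, : len(s)] = [index[a] for a in s.actions]

    def loglik(
        self,
        p0: np.ndarray,
        emergence: np.ndarray,  # (A, n_bank, n_emerged)
        bank_update: np.ndarray,  # (A, n_bank, n_emerged, n_bank)
        floor: float = LOGLIK_FLOOR,
    ) -> float:
        n, max_t = self.obs.shape
        logl = np.zeros(n)
        dead = np.zeros(n, dtype=bool)
        alpha = p0[None, :] * emergence[self.act[:, 0], :, self.obs[:, 0]]
        c = alpha.sum(axis=1)
        zero = c <= 0.0
        dead |= zero
        c_safe = np.where(zero, 1.0, c)
        logl += np.where(zero, 0.0, np.log(c_safe))
        alpha /= c_safe[:, None]
        for t in range(1, max_t):
            live = np.nonzero((self.lengths > t) & ~dead)[0]
            if live.size == 0:
                continue
            a_prev = self.act[live, t - 1]
            o_prev = self.obs[live, t - 1]
            trans = bank_update[a_prev, :, o_prev, :]  # (m, n_bank, n_bank)
            em = emergence[self.act[live, t], :, self.obs[live, t]]  # (m, n_bank)
            a_new = np.einsum("ni,nij->nj", alpha[live], trans) * em
            c = a_new.sum(axis=1)
            zero = c <= 0.0
            dead[live[zero]] = True
            c_safe = np.where(zero, 1.0, c)
            logl[live] += np.where(zero, 0.0, np.log(c_safe))
            alpha[live] = a_new / c_safe[:, None]
        logl[dead] = floor
        return float(logl.sum())


def _stack_kernels(
    actions: Sequence[str], params: SpeciesParameters, cache: KernelCache
) -> Tuple[np.ndarray, np.ndarray]:
    emergence, bank = [], []
    for i, a in enumerate(actions):
        k = cache.get(params.lht[a], action_index=i)
        emergence.append(k.emergence)
        bank.append(k.bank_update)
    return np.stack(emergence), np.stack(bank)


def total_loglik(
    dataset: SurveyDataset,
    params: SpeciesParameters,
    kernel_backend: str = "exact",
    scheme: AbundanceClassScheme | None = None,
    K: int = 30_000,
    cap: int | None = None,
    production_mode: str = "poisson",
    base_seed: int = 0,
    cache: KernelCache | None = None,
    packed: PackedDataset | None = None,
) -> float:
    """Species log-likelihood: sum of forward log-likelihoods over all series.

    Kernels (one per action appearing in the data) are built from ``params``
    and memoised; with ``kernel_backend='mc'`` they use common random numbers
    seeded from ``base_seed`` so the value is a deterministic function of the
    parameters.
    """
    actions = tuple(params.lht)
    params.require_actions(dataset.actions_used)
    if cache is None:
        cache = KernelCache(
            scheme=scheme,
            backend=kernel_backend,
            K=K,
            production_mode=production_mode,
            cap=cap,
            base_seed=base_seed,
        )
    if packed is None:
        packed = PackedDataset(dataset, actions)
    emergence, bank = _stack_kernels(actions, params, cache)
    return packed.loglik(params.p0, emergence, bank)


# ---------------------------------------------------------------------------
# parameter vector <-> SpeciesParameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpace:
    """Bounded box for the free parameters of one species.

    Layout: (sigma_a, s_a, phi_a) per action, then 5 additive-log-ratio
    coordinates of the initial bank-class law ``p0`` (last class is the
    reference).  The ALR coordinates are boxed to ``[-alr_bound, alr_bound]``
    for the random search; the transform to the simplex is smooth and
    tie-free.
    """

    actions: Tuple[str, ...] = DEFAULT_ACTIONS
    phi_max: float = 200.0
    alr_bound: float = 8.0
    n_bank: int = 6

    @property
    def dim(self) -> int:
        return 3 * len(self.actions) + self.n_bank - 1

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for _ in self.actions:
            lo += [0.0, 0.0, 0.0]
            hi += [1.0, 1.0, self.phi_max]
        lo += [-self.alr_bound] * (self.n_bank - 1)
        hi += [self.alr_bound] * (self.n_bank - 1)
        return np.array(lo), np.array(hi)

    def to_params(self, v: np.ndarray) -> SpeciesParameters:
        v = np.asarray(v, dtype=float)
        lht = {}
        for i, a in enumerate(self.actions):
            sig, s, phi = v[3 * i : 3 * i + 3]
            lht[a] = LHTriplet(float(sig), float(s), float(phi), phi_max=self.phi_max)
        return SpeciesParameters(lht=lht, p0=alr_inverse(v[3 * len(self.actions) :]))

    def to_vector(self, params: SpeciesParameters) -> np.ndarray:
        v = []
        for a in self.actions:
            t = params.lht[a]
            v += [t.sigma, t.s, t.phi]
        return np.concatenate([v, alr_forward(params.p0)])


def alr_inverse(z: np.ndarray) -> np.ndarray:
    """Additive-log-ratio coordinates -> probability vector (last = reference)."""
    e = np.exp(np.concatenate([z, [0.0]]))
    p = e / e.sum()
    return p / p.sum()


def alr_forward(p: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), eps, None)
    return np.log(p[:-1] / p[-1])


# ---------------------------------------------------------------------------
# maximum likelihood: controlled random search
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Settings of the Price-type controlled random search.

    The reflection simplex always contains the current best member, which
    sharply accelerates convergence in this 17-dimensional box; a bounded
    derivative-free (Powell) polish from the incumbent runs afterwards
    unless ``polish`` is disabled.
    """

    population_size: int | None = None  # default 10 * (dim + 1)
    max_iterations: int = 50_000
    tol: float = 1e-6
    seed: int = 0
    polish: bool = True
    polish_maxfev: int = 4_000


@dataclass
class FitResult:
    params: SpeciesParameters
    loglik: float
    n_evaluations: int
    converged: bool
    trace: np.ndarray  # best log-likelihood after each iteration


def fit_ml(
    dataset: SurveyDataset,
    space: ParameterSpace | None = None,
    search: SearchConfig | None = None,
    kernel_backend: str = "exact",
    scheme: AbundanceClassScheme | None = None,
    K: int = 30_000,
    cap: int | None = None,
    production_mode: str = "poisson",
) -> FitResult:
    """Maximum-likelihood fit by controlled random search (Price-type).

    A population of parameter vectors sampled uniformly in the box is
    refined iteratively: a trial point reflects a random member through the
    centroid of ``dim`` other random members and replaces the current worst
    member when it improves on it.  The search stops when the population's
    log-likelihood spread drops below ``tol`` or at ``max_iterations``.
    """
    space = space or ParameterSpace(actions=tuple(dict.fromkeys(dataset.actions_used)))
    search = search or SearchConfig()
    lo, hi = space.bounds()
    if np.any(hi <= lo):
        raise ValueError("infeasible parameter bounds")
    d = space.dim
    npop = search.population_size or 10 * (d + 1)
    if npop < d + 2:
        raise ValueError(f"population_size must be at least dim + 2 = {d + 2}")
    rng = np.random.default_rng(search.seed)
    cache = KernelCache(
        scheme=scheme,
        backend=kernel_backend,
        K=K,
        production_mode=production_mode,
        cap=cap,
        base_seed=search.seed,
    )
    packed = PackedDataset(dataset, space.actions)

    def objective(v: np.ndarray) -> float:
        params = space.to_params(v)
        emergence, bank = _stack_kernels(space.actions, params, cache)
        return packed.loglik(params.p0, emergence, bank)

    pop = lo + (hi - lo) * rng.random((npop, d))
    f = np.array([objective(p) for p in pop])
    n_eval = npop
    trace: List[float] = [float(f.max())]
    converged = False
    for _ in range(search.max_iterations):
        if f.max() - f.min() < search.tol:
            converged = True
            break
        best = int(np.argmax(f))
        idx = rng.choice(npop, size=d + 1, replace=False)
        simplex = np.vstack([pop[best], pop[idx[: d - 1]]])
        trial = np.clip(2.0 * simplex.mean(axis=0) - pop[idx[-1]], lo, hi)
        ft = objective(trial)
        n_eval += 1
        worst = int(np.argmin(f))
        if ft > f[worst]:
            pop[worst] = trial
            f[worst] = ft
        trace.append(float(f.max()))
    best = int(np.argmax(f))
    v_best, f_best = pop[best], float(f[best])
    if search.polish and search.polish_maxfev > 0:
        from scipy import optimize as _opt

        def neg(v: np.ndarray) -> float:
            return -objective(np.clip(v, lo, hi))

        res = _opt.minimize(
            neg,
            v_best,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"maxfev": search.polish_maxfev, "xtol": 1e-4, "ftol": 1e-8},
        )
        n_eval += int(res.nfev)
        if -res.fun > f_best:
            v_best, f_best = np.clip(res.x, lo, hi), float(-res.fun)
        trace.append(f_best)
    return FitResult(
        params=space.to_params(v_best),
        loglik=f_best,
        n_evaluations=n_eval,
        converged=converged,
        trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Bayesian estimation: Metropolis within Gibbs
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Random-walk Metropolis-within-Gibbs settings (transformed scale)."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    proposal_scale: float | np.ndarray = 0.15
    seed: int = 0
    thin: int = 1


@dataclass
class PosteriorChain:
    """Posterior draws stored column-wise on the natural scale."""

    actions: Tuple[str, ...]
    sigma: np.ndarray  # (n_draws, A)
    s: np.ndarray
    phi: np.ndarray
    p0: np.ndarray  # (n_draws, n_bank)
    logpost: np.ndarray
    acceptance_rates: Dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.logpost.shape[0]

    def draw(self, i: int, phi_max: float = 200.0) -> SpeciesParameters:
        lht = {
            a: LHTriplet(
                float(self.sigma[i, j]),
                float(self.s[i, j]),
                float(self.phi[i, j]),
                phi_max=phi_max,
            )
            for j, a in enumerate(self.actions)
        }
        return SpeciesParameters(lht=lht, p0=self.p0[i])

    def credible_interval(
        self, trait: str, action: str, level: float = 0.9
    ) -> Tuple[float, float]:
        arr = getattr(self, trait)[:, self.actions.index(action)]
        a = (1.0 - level) / 2.0
        return float(np.quantile(arr, a)), float(np.quantile(arr, 1.0 - a))


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def sample_posterior(
    dataset: SurveyDataset | None,
    init: SpeciesParameters,
    mcmc: McmcConfig | None = None,
    space: ParameterSpace | None = None,
    kernel_backend: str = "exact",
    scheme: AbundanceClassScheme | None = None,
    K: int = 30_000,
    cap: int | None = None,
    production_mode: str = "poisson",
) -> PosteriorChain:
    """Posterior sampling under uniform priors over the parameter box.

    One Gibbs sweep updates each coordinate in turn with a random-walk
    Metropolis step on a transformed scale (logit for rates, log for seed
    production, additive log-ratio for ``p0``); uniform priors on the
    natural scale enter through the Jacobian of the transform.  ``dataset``
    may be ``None`` (zero-length data), in which case the chain samples the
    prior.  Only the kernel of the action whose triplet changed is rebuilt.
    """
    mcmc = mcmc or McmcConfig()
    space = space or ParameterSpace(actions=tuple(init.lht))
    actions = space.actions
    A = len(actions)
    init.require_actions(actions)

    eps = 1e-9
    theta = np.empty(space.dim)
    for j, a in enumerate(actions):
        t = init.lht[a]
        if not (0.0 < t.sigma < 1.0 and 0.0 < t.s < 1.0 and 0.0 < t.phi <= space.phi_max):
            raise ValueError(
                f"initial triplet for action {a} must lie strictly inside the prior box"
            )
        theta[3 * j : 3 * j + 3] = [_logit(t.sigma), _logit(t.s), math.log(t.phi)]
    if np.any(init.p0 <= 0.0):
        raise ValueError("initial p0 must be strictly positive in every class")
    theta[3 * A :] = alr_forward(init.p0)

    cache = KernelCache(
        scheme=scheme,
        backend=kernel_backend,
        K=K,
        production_mode=production_mode,
        cap=cap,
        base_seed=mcmc.seed,
    )
    packed = PackedDataset(dataset, actions) if dataset is not None else None

    def unpack(th: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        sig = 1.0 / (1.0 + np.exp(-th[0 : 3 * A : 3]))
        s = 1.0 / (1.0 + np.exp(-th[1 : 3 * A : 3]))
        phi = np.exp(th[2 : 3 * A : 3])
        p0 = alr_inverse(th[3 * A :])
        return sig, s, phi, p0

    def log_target(th: np.ndarray) -> float:
        sig, s, phi, p0 = unpack(th)
        if np.any(phi > space.phi_max):
            return -np.inf
        # Jacobian of (logit, logit, log, ALR) under uniform priors
        logj = float(
            np.sum(np.log(sig) + np.log1p(-sig))
            + np.sum(np.log(s) + np.log1p(-s))
            + np.sum(np.log(phi))
            + np.sum(np.log(p0))
        )
        if packed is None:
            return logj
        lht = {
            a: LHTriplet(float(sig[j]), float(s[j]), float(phi[j]), phi_max=space.phi_max)
            for j, a in enumerate(actions)
        }
        params = SpeciesParameters(lht=lht, p0=p0)
        emergence, bank = _stack_kernels(actions, params, cache)
        return packed.loglik(p0, emergence, bank) + logj

    rng = np.random.default_rng(mcmc.seed)
    scale = np.broadcast_to(np.asarray(mcmc.proposal_scale, dtype=float), (space.dim,)).copy()
    coord_names = []
    for a in actions:
        coord_names += [f"sigma_{a}", f"s_{a}", f"phi_{a}"]
    coord_names += [f"alr_{i + 1}" for i in range(space.dim - 3 * A)]

    cur_lp = log_target(theta)
    n_keep = (mcmc.n_iter - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    if n_keep <= 0:
        raise ValueError("n_iter must exceed burn_in")
    sig_d = np.empty((n_keep, A))
    s_d = np.empty((n_keep, A))
    phi_d = np.empty((n_keep, A))
    p0_d = np.empty((n_keep, space.n_bank))
    lp_d = np.empty(n_keep)
    accepted = np.zeros(space.dim)
    proposed = np.zeros(space.dim)
    kept = 0
    for it in range(mcmc.n_iter):
        for j in range(space.dim):
            prop = theta.copy()
            prop[j] += scale[j] * rng.standard_normal()
            lp = log_target(prop)
            proposed[j] += 1
            if math.log(rng.random()) < lp - cur_lp:
                theta = prop
                cur_lp = lp
                accepted[j] += 1
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            sig, s, phi, p0 = unpack(theta)
            sig_d[kept], s_d[kept], phi_d[kept], p0_d[kept] = sig, s, phi, p0
            lp_d[kept] = cur_lp
            kept += 1
    rates = {
        name: float(accepted[j] / max(proposed[j], 1)) for j, name in enumerate(coord_names)
    }
    return PosteriorChain(
        actions=actions,
        sigma=sig_d[:kept],
        s=s_d[:kept],
        phi=phi_d[:kept],
        p0=p0_d[:kept],
        logpost=lp_d[:kept],
        acceptance_rates=rates,
    )
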