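"""Forward likelihood, ML search and posterior sampler."""

import math

import numpy as np
import pytest

from weedhmm.core import FieldSeries, LHTriplet, SpeciesParameters, SurveyDataset
from weedhmm.inference import (
    LOGLIK_FLOOR,
    McmcConfig,
    ParameterSpace,
    SearchConfig,
    alr_forward,
    alr_inverse,
    brute_force_loglik,
    fit_ml,
    forward_loglik,
    sample_posterior,
    total_loglik,
)
from weedhmm.kernels import KernelCache, TransitionKernel, exact_kernel_enumeration
from weedhmm.simulate import StudyDesign, generate_dataset

from conftest import ACTIONS, make_dataset, random_instance, random_kernel


class TestForwardRecursion:
    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_matches_explicit_hidden_state_enumeration(self, T):
        rng = np.random.default_rng(40 + T)
        for _ in range(10):
            series, params, kernels = random_instance(rng, T)
            assert forward_loglik(series, params, kernels) == pytest.approx(
                brute_force_loglik(series, params, kernels), abs=1e-10
            )

    def test_empty_bank_emits_absence_surely(self):
        p0 = np.zeros(6)
        p0[0] = 1.0
        params = SpeciesParameters(lht={"WC": LHTriplet(0.7, 0.5, 9.0)}, p0=p0)
        kernels = {"WC": exact_kernel_enumeration(params.lht["WC"])}
        series = FieldSeries("f", ("WC",), (1,))
        assert forward_loglik(series, params, kernels) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_emission_gives_minus_T_log4(self):
        rng = np.random.default_rng(0)
        kern = TransitionKernel(
            np.full((6, 4), 0.25),
            np.full((6, 4, 6), 1.0 / 6.0),
            np.ones((6, 4), dtype=bool),
        )
        kernels = {a: kern for a in ACTIONS}
        for T in (1, 3, 5):
            series, params, _ = random_instance(rng, T)
            ll = forward_loglik(series, params, kernels)
            assert ll == pytest.approx(-T * math.log(4.0), abs=1e-12)
            if T <= 4:
                assert brute_force_loglik(series, params, kernels) == pytest.approx(
                    ll, abs=1e-10
                )

    def test_impossible_sequences_hit_the_floor_in_both_implementations(self):
        p0 = np.zeros(6)
        p0[0] = 1.0
        params = SpeciesParameters(lht={"WC": LHTriplet(0.5, 0.5, 5.0)}, p0=p0)
        kernels = {"WC": exact_kernel_enumeration(params.lht["WC"])}
        series = FieldSeries("f", ("WC", "WC"), (3, 1))  # plants from an empty bank
        assert forward_loglik(series, params, kernels) == LOGLIK_FLOOR
        assert brute_force_loglik(series, params, kernels) == LOGLIK_FLOOR

    def test_brute_force_guard(self):
        rng = np.random.default_rng(1)
        series, params, kernels = random_instance(rng, 8)
        with pytest.raises(ValueError):
            brute_force_loglik(series, params, kernels)

    def test_missing_kernel_is_a_configuration_error(self):
        rng = np.random.default_rng(2)
        series, params, kernels = random_instance(rng, 2)
        kernels.pop(series.actions[0])
        with pytest.raises(KeyError):
            forward_loglik(series, params, kernels)


class TestTotalLoglik:
    def test_single_series_dataset_reduces_to_forward(self, truth):
        ds, _ = generate_dataset(
            truth,
            StudyDesign(
                n_fields=1,
                series_length_pmf={3: 1.0},
                action_frequencies={a: 0.25 for a in ACTIONS},
            ),
            rng=np.random.default_rng(5),
        )
        kernels = {a: exact_kernel_enumeration(t) for a, t in truth.lht.items()}
        assert total_loglik(ds, truth) == pytest.approx(
            forward_loglik(ds.series[0], truth, kernels), abs=1e-10
        )

    def test_independence_doubling_and_per_series_sum(self, truth, small_dataset):
        kernels = {a: exact_kernel_enumeration(t) for a, t in truth.lht.items()}
        per_series = sum(
            forward_loglik(s, truth, kernels) for s in small_dataset.series
        )
        ll = total_loglik(small_dataset, truth)
        assert ll == pytest.approx(per_series, abs=1e-9)
        doubled = make_dataset(small_dataset.series * 2)
        assert total_loglik(doubled, truth) == pytest.approx(2 * ll, abs=1e-9)

    def test_invariant_to_series_order_and_field_relabelling(self, truth, small_dataset):
        ll = total_loglik(small_dataset, truth)
        rev = make_dataset(
            [
                FieldSeries(f"renamed{i}", s.actions, s.observations)
                for i, s in enumerate(reversed(small_dataset.series))
            ]
        )
        assert total_loglik(rev, truth) == pytest.approx(ll, abs=1e-9)

    def test_exact_backend_is_bit_reproducible(self, truth, small_dataset):
        assert total_loglik(small_dataset, truth) == total_loglik(small_dataset, truth)

    def test_mc_backend_reproducible_under_fixed_seed(self, truth, small_dataset):
        a = total_loglik(small_dataset, truth, kernel_backend="mc", K=3000, base_seed=9)
        b = total_loglik(small_dataset, truth, kernel_backend="mc", K=3000, base_seed=9)
        assert a == b

    def test_profile_in_sigma_peaks_near_the_generating_value(self, truth):
        """With all other parameters at truth, the exact-backend profile in
        the dominant action's germination rate peaks within +/-0.05 of the
        generating value on a dense grid (500 series)."""
        design = StudyDesign(
            n_fields=500,
            series_length_pmf={3: 0.4, 4: 0.4, 5: 0.2},
            action_frequencies={"WC": 0.5, "OR": 0.1, "M": 0.3, "SF": 0.1},
        )
        ds, _ = generate_dataset(truth, design, rng=np.random.default_rng(77))
        cache = KernelCache()
        grid = np.arange(0.23, 0.48, 0.0125)
        lls = []
        for sig in grid:
            lht = dict(truth.lht)
            lht["WC"] = LHTriplet(float(sig), truth.lht["WC"].s, truth.lht["WC"].phi)
            p = SpeciesParameters(lht=lht, p0=truth.p0)
            lls.append(total_loglik(ds, p, cache=cache))
        peak = grid[int(np.argmax(lls))]
        assert abs(peak - truth.lht["WC"].sigma) <= 0.05


class TestSimplexTransform:
    def test_alr_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            assert np.allclose(alr_inverse(alr_forward(p)), p, atol=1e-10)

    def test_space_round_trip(self, truth):
        space = ParameterSpace(actions=ACTIONS)
        v = space.to_vector(truth)
        back = space.to_params(v)
        assert np.allclose(back.p0, truth.p0, atol=1e-10)
        for a in ACTIONS:
            assert back.lht[a].sigma == pytest.approx(truth.lht[a].sigma)


class TestMLSearch:
    def test_search_only_improves_on_the_initial_population(self, small_dataset):
        res = fit_ml(
            small_dataset,
            search=SearchConfig(
                population_size=30, max_iterations=60, seed=1, polish=False
            ),
        )
        assert np.all(np.diff(res.trace) >= 0)
        assert res.loglik >= res.trace[0]
        assert res.n_evaluations == 30 + 60

    def test_all_absent_data_drives_emergence_to_zero(self):
        series = [
            FieldSeries(f"f{i}", ("WC", "WC", "WC"), (1, 1, 1)) for i in range(15)
        ]
        ds = make_dataset(series)
        space = ParameterSpace(actions=("WC",))
        res = fit_ml(
            ds,
            space=space,
            search=SearchConfig(
                population_size=30, max_iterations=150, seed=0, polish_maxfev=400
            ),
        )
        cache = KernelCache()
        ref = SpeciesParameters(
            lht={"WC": LHTriplet(0.5, 0.5, 1.0)}, p0=np.full(6, 1.0 / 6.0)
        )
        assert res.loglik >= total_loglik(ds, ref, cache=cache)
        # absence forever: either nothing germinates or nothing is banked
        assert res.params.lht["WC"].sigma < 0.1 or res.params.p0[0] > 0.9

    def test_infeasible_population_is_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit_ml(small_dataset, search=SearchConfig(population_size=3))


class TestPosterior:
    def test_prior_sampling_with_zero_length_data(self):
        space = ParameterSpace(actions=("WC",))
        init = SpeciesParameters(
            lht={"WC": LHTriplet(0.4, 0.6, 5.0)}, p0=np.full(6, 1.0 / 6.0)
        )
        chain = sample_posterior(
            None,
            init,
            mcmc=McmcConfig(n_iter=4000, burn_in=500, proposal_scale=1.2, seed=0),
            space=space,
        )
        draws = chain.sigma[:, 0]
        # batch-means Monte-Carlo standard error
        batches = draws[: 20 * (len(draws) // 20)].reshape(20, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(draws.mean() - 0.5) < 3 * se
        assert np.all((chain.phi > 0) & (chain.phi <= 200.0))
        assert np.all(chain.p0 > 0) and np.allclose(chain.p0.sum(axis=1), 1.0)

    def test_draws_stay_inside_the_prior_box(self, truth, small_dataset):
        chain = sample_posterior(
            small_dataset,
            truth,
            mcmc=McmcConfig(n_iter=30, burn_in=10, seed=1),
        )
        assert np.all((chain.sigma >= 0) & (chain.sigma <= 1))
        assert np.all((chain.s >= 0) & (chain.s <= 1))
        assert np.all((chain.phi >= 0) & (chain.phi <= 200.0))
        for r in chain.acceptance_rates.values():
            assert 0.0 <= r <= 1.0

    def test_initialisation_outside_the_box_is_rejected(self, small_dataset):
        bad = SpeciesParameters(
            lht={a: LHTriplet(0.0, 0.5, 5.0) for a in ACTIONS},
            p0=np.full(6, 1.0 / 6.0),
        )
        with pytest.raises(ValueError):
            sample_posterior(small_dataset, bad, mcmc=McmcConfig(n_iter=2, burn_in=0))
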