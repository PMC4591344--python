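import numpy as np
import pytest

from weedhmm.core import (
    AbundanceClassScheme,
    FieldSeries,
    LHTriplet,
    SpeciesParameters,
    SurveyDataset,
)
from weedhmm.kernels import TransitionKernel
from weedhmm.simulate import StudyDesign, generate_dataset

ACTIONS = ("WC", "OR", "M", "SF")

#: Canonical simulation truth used across recovery experiments: two
#: contrasted life-history strategies spread over the four actions,
#: growth rates straddling 1.
CANONICAL_LHT = {
    "WC": (0.35, 0.50, 3.0),
    "OR": (0.20, 0.45, 1.5),
    "M": (0.10, 0.75, 5.0),
    "SF": (0.25, 0.60, 0.8),
}
CANONICAL_P0 = np.array([0.30, 0.25, 0.20, 0.15, 0.07, 0.03])


@pytest.fixture(scope="session")
def scheme():
    return AbundanceClassScheme()


@pytest.fixture(scope="session")
def truth():
    return SpeciesParameters(
        lht={a: LHTriplet(*v) for a, v in CANONICAL_LHT.items()},
        p0=CANONICAL_P0,
    )


@pytest.fixture(scope="session")
def tiny_design():
    return StudyDesign(
        n_fields=20,
        series_length_pmf={2: 0.3, 3: 0.4, 4: 0.3},
        action_frequencies={"WC": 0.5, "OR": 0.1, "M": 0.3, "SF": 0.1},
    )


@pytest.fixture(scope="session")
def small_dataset(truth, tiny_design):
    ds, _ = generate_dataset(truth, tiny_design, rng=np.random.default_rng(202))
    return ds


def random_kernel(rng, n_bank=6, n_em=4):
    """Row-stochastic kernel with Dirichlet rows (independent of any
    population model; used as a neutral HMM instance)."""
    emergence = rng.dirichlet(np.ones(n_em), size=n_bank)
    bank = rng.dirichlet(np.ones(n_bank), size=(n_bank, n_em))
    return TransitionKernel(emergence, bank, np.ones((n_bank, n_em), dtype=bool))


def random_instance(rng, T, actions=ACTIONS):
    """A random series + parameters + kernels triple for likelihood tests."""
    kernels = {a: random_kernel(rng) for a in actions}
    p0 = rng.dirichlet(np.ones(6))
    params = SpeciesParameters(
        lht={a: LHTriplet(0.5, 0.5, 1.0) for a in actions}, p0=p0
    )
    acts = tuple(actions[i] for i in rng.integers(0, len(actions), size=T))
    obs = tuple(int(o) for o in rng.integers(1, 5, size=T))
    series = FieldSeries(field_id="X", actions=acts, observations=obs)
    return series, params, kernels


def make_dataset(series_list, species_id="SP"):
    return SurveyDataset(species_id=species_id, series=list(series_list))
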