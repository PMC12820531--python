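import dataclasses

import numpy as np
import pytest

from repstates import burst_core as bc
from repstates import photon_sim
from repstates.fixtures import (DistortionParams, Fixture, StateModel,
                                get_fixture)


@pytest.fixture(scope="session")
def distorted_low_salt() -> Fixture:
    """Low-salt fixture with realistic signal distortions switched on."""
    return dataclasses.replace(
        get_fixture("low_salt"),
        distortions=DistortionParams(leakage_l=0.07, direct_excitation_d=0.05,
                                     gamma=1.2, beta=1.1),
    )


@pytest.fixture(scope="session")
def mixed_species_stream(distorted_low_salt):
    """A mixed doubly/donor-only/acceptor-only acquisition (shared: slow)."""
    return photon_sim.simulate_burst_stream(
        distorted_low_salt, 4000, seed=7, species_fractions=(0.7, 0.2, 0.1))


@pytest.fixture(scope="session")
def mixed_species_bursts(mixed_species_stream):
    bg = bc.estimate_background(mixed_species_stream)
    bursts = bc.all_photon_burst_search(mixed_species_stream, bg)
    return bg, bursts


@pytest.fixture(scope="session")
def two_state_model() -> StateModel:
    """Symmetric two-state switcher, E 0.2/0.8, k = 500/s each way."""
    Q = np.array([[-500.0, 500.0], [500.0, -500.0]])
    return StateModel(e_values=(0.2, 0.8), brightness=(5e4, 5e4), rate_matrix=Q)


@pytest.fixture(scope="session")
def two_state_fixture(two_state_model) -> Fixture:
    return Fixture("two_state", two_state_model, DistortionParams(),
                   (0.05, 0.05), (0.5, 0.5))


def static_fixture(e_values, weights, sigmas=None, brightness=5e4) -> Fixture:
    """A fixture whose states never interconvert (one state per burst)."""
    n = len(e_values)
    states = StateModel(e_values=tuple(e_values), brightness=(brightness,) * n,
                        rate_matrix=np.zeros((n, n)),
                        initial_distribution=np.asarray(weights, float))
    return Fixture("static", states, DistortionParams(),
                   tuple(sigmas) if sigmas is not None else (0.05,) * n,
                   tuple(weights))
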