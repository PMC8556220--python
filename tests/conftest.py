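import numpy as np
import pytest

import meglda as m
from meglda.spectral import (band_power_matrices, draw_bootstrap_windows,
                             periodogram_stack)

#: Bootstrap sample count used by the shared fixtures; enough for stable
#: LDA estimates while keeping the suite fast.
P_FIXTURE = 500
WINDOW = 2000


@pytest.fixture(scope="session")
def desk_scenario():
    return m.default_scenario()


@pytest.fixture(scope="session")
def atlas165():
    return m.make_atlas()


@pytest.fixture(scope="session")
def state_series(desk_scenario):
    """One 60 s session per state (the desk-scale study conditions)."""
    return {
        state: m.simulate_brali(desk_scenario, state, 60.0, seed=11 + i)
        for i, state in enumerate(desk_scenario.states)
    }


@pytest.fixture(scope="session")
def band_powers(state_series, desk_scenario):
    """Band-power matrices per state at the default window length."""
    out = {}
    for i, (state, series) in enumerate(state_series.items()):
        rng = np.random.default_rng(300 + i)
        cut = draw_bootstrap_windows(series, WINDOW, P_FIXTURE, rng)
        stack = periodogram_stack(cut, series.dt, state=state)
        out[state] = band_power_matrices(stack, m.SUBJECT1_BANDS)
    return out


@pytest.fixture(scope="session")
def alpha_clusters(band_powers, desk_scenario):
    states = list(desk_scenario.states)
    return m.ClusterSet([band_powers[s]["alpha"].values for s in states],
                        states)
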