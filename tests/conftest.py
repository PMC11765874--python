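import numpy as np
import pytest

import mrt_irt as m


@pytest.fixture(scope="session")
def instrument():
    """Packaged 15-item instrument: (QMatrix, eta, item ids)."""
    return m.mrt_fixture()


@pytest.fixture(scope="session")
def sim2000(instrument):
    """One large simulated dataset from the instrument fixture (n = 2000)."""
    q, eta, _ = instrument
    return m.simulate_responses(m.SimulationDesign(q=q, eta=eta, n_persons=2000, seed=0))


@pytest.fixture(scope="session")
def rasch2000(sim2000):
    return m.fit_rasch_cml(sim2000)


@pytest.fixture(scope="session")
def lltm2000(sim2000, instrument):
    q, _, _ = instrument
    return m.fit_lltm_cml(sim2000, q)


@pytest.fixture()
def tiny_matrix():
    """4 persons x 3 items, complete, non-degenerate."""
    values = np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 1],
            [1, 0, 1],
        ],
        dtype=float,
    )
    return m.ResponseMatrix(values, ["a", "b", "c", "d"], ["i1", "i2", "i3"])
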