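import numpy as np
import pytest

from oaecalc import SeawaterConditions, read_species_table


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged 27-species summary table."""
    return read_species_table()


@pytest.fixture(scope="session")
def default_conditions():
    return SeawaterConditions()


def hypercube(n, seed=7):
    """Deterministic sample of (TA, DIC, T, S) over the open-ocean box
    TA [2000, 2500], DIC [1700, 2400], T [0, 30], S [30, 38], restricted
    to TA > DIC (supersaturated surface water)."""
    from scipy.stats import qmc

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n)
    pts = qmc.scale(u, [2000, 1700, 0, 30], [2500, 2400, 30, 38])
    pts[:, 1] = np.minimum(pts[:, 1], pts[:, 0] * 0.97)
    return pts
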