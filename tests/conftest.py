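import numpy as np
import pandas as pd
import pytest

import zicoex as zx
from zicoex.design import build_design


@pytest.fixture(scope="session")
def droplet_small():
    """Small droplet-regime dataset shared across fitting tests."""
    return zx.simulate(
        zx.droplet_preset(n_patients=5, cells_per_patient=100), seed=11)


@pytest.fixture(scope="session")
def droplet_small_fit(droplet_small):
    return zx.fit(droplet_small.to_pair_data(), control=zx.FitControl())


@pytest.fixture()
def toy_pair():
    """Deterministic 3-patient toy dataset for design/starting-value tests."""
    rng = np.random.default_rng(7)
    n = 120
    patient = np.repeat(["a", "b", "c"], n // 3)
    group = np.tile([0, 1], n // 2)
    depth = np.full(n, 3e4)
    y1 = rng.poisson(5.0, n) + (group * rng.poisson(2.0, n))
    y2 = rng.poisson(4.0, n)
    return zx.GenePairData(y1=y1, y2=y2, patient=patient,
                           covariates=pd.DataFrame({"group": group}),
                           depth=depth)


@pytest.fixture()
def toy_blocks(toy_pair):
    return build_design(toy_pair, zx.ModelSpec.two_group())
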