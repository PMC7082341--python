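import numpy as np
import pandas as pd
import pytest

from elevbreak import SimulationParams, simulate_mountain


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic mountain (fault planted at 2400 m), shared read-only."""
    return simulate_mountain(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def site_spacing(default_bundle):
    return float(np.diff(default_bundle.truth["site_elevations"]).mean())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def coenocline():
    """Noiseless Gaussian-niche community: 30 species, 20 sites on a gradient."""
    from elevbreak import gaussian_niche

    grad = np.linspace(0.0, 100.0, 20)
    optima = np.linspace(5.0, 95.0, 30)
    abund = gaussian_niche(grad[:, None], optima[None, :], 12.0, 50.0)
    return pd.DataFrame(abund, index=[f"s{i}" for i in range(20)],
                        columns=[f"sp{j}" for j in range(30)]), grad
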