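import numpy as np
import pytest

from gemscan import simulate
from gemscan.data_io import FeatureMatrix


@pytest.fixture(scope="session")
def small_study():
    """Complete-data study with one planted effect per scan type."""
    spec = simulate.SimulationSpec(
        n_samples=120,
        n_cpgs=25,
        n_snps=40,
        n_envs=2,
        seed=42,
        g_effects={(0, 3): 0.8},
        e_effects={(1, 0): 0.7},
        gxe_effects={(2, 5, 1): 0.8},
        noise_sd=0.2,
    )
    return simulate.simulate_study(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, kind="environment", feature_prefix="f", sample_prefix="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return FeatureMatrix(
        feature_ids=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values=values,
        kind=kind,
    )
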