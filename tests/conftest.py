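import numpy as np
import pandas as pd
import pytest

from spec2gwas.spectra_preprocess import SpectraSet
from spec2gwas.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cfg():
    """Fast simulation settings for unit tests (coarse but complete)."""
    return SimulationConfig(
        n_samples=40,
        n_snps=240,
        k_subpops=4,
        grid_low=1050.0,
        grid_high=1400.0,
        seed=11,
    )


def make_spectra(values, wavelengths, samples=None, role="calibrated", replicates=None):
    """Build a SpectraSet from a plain array for toy tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    samples = samples or [f"S{i + 1}" for i in range(n)]
    if replicates is not None:
        index = pd.MultiIndex.from_arrays(
            [samples, replicates], names=["sample_id", "replicate"]
        )
    else:
        index = pd.Index(samples, name="sample_id")
    return SpectraSet(pd.DataFrame(values, index=index, columns=wavelengths), role=role)


@pytest.fixture
def toy_spectra():
    return make_spectra
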