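import numpy as np
import pytest

from massshiftnet import (
    KendrickConfig,
    averagine_component,
    chca_component,
    synthesize_spectrum,
)
from massshiftnet.models import sparse_peptide_alpha


@pytest.fixture(scope="session")
def small_range():
    """Narrow mass window used by the fast unit tests."""
    return (600.0, 750.0)


@pytest.fixture(scope="session")
def small_components(small_range):
    """Monoisotopic peptide + matrix models on the narrow window."""
    return [
        averagine_component(small_range, isotopes=1),
        chca_component(small_range, isotopes=1),
    ]


@pytest.fixture(scope="session")
def small_grid(small_range):
    return np.arange(small_range[0], small_range[1] + 0.005, 0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sparse_spectrum(small_components, small_grid):
    """Noiseless sparse peptide+matrix spectrum with known ground truth."""
    pep, mat = small_components
    gen = np.random.default_rng(42)
    pep_alpha = sparse_peptide_alpha(pep, occupancy=0.3, log_sigma=1.0, rng=gen)
    mat_alpha = mat.peak_weight * 0.5 * pep_alpha.max()
    alpha = np.concatenate([pep_alpha, mat_alpha])
    spec, truth = synthesize_spectrum(
        small_components, alpha, grid=small_grid, noise_sd=0.0
    )
    return spec, truth


@pytest.fixture(scope="session")
def small_kendrick_cfg(small_range):
    return KendrickConfig(n_mz_bins=8, n_defect_bins=32, mass_range=small_range)
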