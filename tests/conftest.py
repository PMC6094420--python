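import numpy as np
import pytest

from eemcalib.eem_data import EEMCube, EEMSample, WavelengthGrid
from eemcalib.synthetic import reference_design, simulate_cube


@pytest.fixture(scope="session")
def small_grid() -> WavelengthGrid:
    """Coarse acquisition grid (15 excitation x 40 emission) covering the
    same wavelength windows as the full instrument grid."""
    return WavelengthGrid(
        excitation=np.arange(236.0, 266.0, 2.0),
        emission=np.arange(300.0, 500.0, 5.0),
    )


@pytest.fixture(scope="session")
def small_serum_cube(small_grid) -> EEMCube:
    """61 serum-like standards + 5 blanks on the coarse grid."""
    return simulate_cube(reference_design(seed=11, n_blanks=5, grid=small_grid))


@pytest.fixture()
def tiny_cube() -> EEMCube:
    """3 samples x 4 excitation x 5 emission of deterministic random values."""
    rng = np.random.default_rng(3)
    grid = WavelengthGrid(excitation=np.arange(4.0), emission=np.arange(5.0))
    samples = [
        EEMSample(f"s{i}", rng.normal(size=(5, 4)), role="unknown", concentration=float(i))
        for i in range(3)
    ]
    return EEMCube(grid, samples)
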