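"""Synthetic EEM cubes with the bilinear structure the calibration assumes.

Each fluorophore contributes a rank-one landscape: the outer product of a
Gaussian excitation band and a Gaussian emission band, scaled by its
concentration (analyte) or a per-sample random level (interferents).
Additive Gaussian detector noise sits on top.  This reproduces the smooth,
unimodal landscapes typical of a single drug extracted into an organic
phase with residual serum background, and makes every downstream stage
testable without laboratory spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eem_data import EEMCube, EEMSample, WavelengthGrid, default_grid
from .reference_table import nominal_concentrations_molar


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian excitation/emission band pair for one fluorescent species.

    ``quantum_scale`` converts molar concentration (or an interferent level,
    which is already in intensity units with quantum_scale 1) to peak
    fluorescence intensity.
    """

    ex_center: float
    ex_width: float
    em_center: float
    em_width: float
    quantum_scale: float = 1.0

    def __post_init__(self):
        if not (self.ex_width > 0 and self.em_width > 0):
            raise ValueError("band widths must be positive")
        if not (np.isfinite(self.ex_center) and np.isfinite(self.em_center)):
            raise ValueError("band centers must be finite")
        if not self.quantum_scale > 0:
            raise ValueError("quantum_scale must be positive")

    def landscape(self, grid: WavelengthGrid) -> np.ndarray:
        """Unit-peak emission x excitation landscape on the grid."""
        g_ex = np.exp(-0.5 * ((grid.excitation - self.ex_center) / self.ex_width) ** 2)
        g_em = np.exp(-0.5 * ((grid.emission - self.em_center) / self.em_width) ** 2)
        return np.outer(g_em, g_ex)


@dataclass
class SimulationDesign:
    """Full description of one simulated acquisition run.

    ``interferents`` pairs each background fluorophore with the (low, high)
    range its per-sample level is drawn from, in intensity units.
    ``scatter_level`` > 0 adds a diagonal Rayleigh-like ridge where emission
    equals excitation wavelength, for stress testing.
    """

    grid: WavelengthGrid
    analyte: FluorophoreSpec
    concentrations: np.ndarray
    interferents: list[tuple[FluorophoreSpec, tuple[float, float]]] = field(default_factory=list)
    noise_sd: float = 0.0
    heteroscedastic: float = 0.0  # extra noise sd as a fraction of local signal
    scatter_level: float = 0.0
    n_blanks: int = 0
    seed: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size == 0:
            raise ValueError("concentration list must be non-empty")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _scatter_ridge(grid: WavelengthGrid, width: float = 5.0) -> np.ndarray:
    em = grid.emission[:, None]
    ex = grid.excitation[None, :]
    return np.exp(-0.5 * ((em - ex) / width) ** 2)


def simulate_cube(design: SimulationDesign) -> EEMCube:
    """Generate an EEM cube from a design; identical seed gives an identical cube.

    Sample i's landscape is
    ``c_i * quantum_scale * analyte_band + sum_j level_ij * interferent_band_j
    + N(0, noise_sd)``, with blanks (concentration 0) appended last when
    ``n_blanks`` > 0.
    """
    rng = np.random.default_rng(design.seed)
    grid = design.grid
    analyte_land = design.analyte.landscape(grid)
    inter_lands = [spec.landscape(grid) for spec, _ in design.interferents]
    scatter = _scatter_ridge(grid) if design.scatter_level > 0 else None

    concs = list(design.concentrations) + [0.0] * design.n_blanks
    roles = ["unknown"] * design.concentrations.size + ["blank"] * design.n_blanks

    samples = []
    for i, (c, role) in enumerate(zip(concs, roles)):
        signal = c * design.analyte.quantum_scale * analyte_land
        for land, (_, (lo, hi)) in zip(inter_lands, design.interferents):
            level = rng.uniform(lo, hi)
            signal = signal + level * land
        if scatter is not None:
            signal = signal + design.scatter_level * scatter
        if design.noise_sd > 0:
            signal = signal + rng.normal(0.0, design.noise_sd, size=signal.shape)
        if design.heteroscedastic > 0:
            signal = signal + rng.normal(0.0, 1.0, size=signal.shape) * (
                design.heteroscedastic * np.abs(signal)
            )
        sid = f"blank{i - design.concentrations.size + 1:02d}" if role == "blank" else f"s{i + 1:02d}"
        samples.append(EEMSample(sample_id=sid, intensities=signal, role=role, concentration=c))
    return EEMCube(grid=grid, samples=samples)


def reference_design(
    seed: int = 0,
    n_blanks: int = 0,
    noise_sd: float = 2.0,
    grid: WavelengthGrid | None = None,
) -> SimulationDesign:
    """Design emulating the published ibuprofen-in-serum study conditions.

    61 standards spanning 0.1-47 x 1e-7 M (the published concentration
    ladder), analyte band peaking at excitation 251 nm / emission 362.5 nm,
    and two broad serum-like interferent bands whose per-sample levels vary
    randomly, on the default acquisition grid (30 excitation x 401 emission
    points).

    The analyte's ``quantum_scale`` (1e8 intensity units per molar) puts the
    top standard near 470 intensity units, so the default ``noise_sd`` of
    2.0 is roughly 0.4% of the maximum signal.  Interferent levels (10-50
    and 5-30 units) give a background comparable to the low-concentration
    standards, which is what forces the PCA to spend more than one component
    on the data.  Blank solutions for detection-limit work are requested via
    ``n_blanks``.
    """
    if grid is None:
        grid = default_grid()
    analyte = FluorophoreSpec(
        ex_center=251.0, ex_width=6.0, em_center=362.5, em_width=22.0, quantum_scale=1e8
    )
    serum_a = FluorophoreSpec(ex_center=244.0, ex_width=12.0, em_center=335.0, em_width=35.0)
    serum_b = FluorophoreSpec(ex_center=262.0, ex_width=10.0, em_center=420.0, em_width=55.0)
    return SimulationDesign(
        grid=grid,
        analyte=analyte,
        concentrations=nominal_concentrations_molar(),
        interferents=[(serum_a, (10.0, 50.0)), (serum_b, (5.0, 30.0))],
        noise_sd=noise_sd,
        n_blanks=n_blanks,
        seed=seed,
    )
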