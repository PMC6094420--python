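"""Data model and file I/O for excitation-emission matrix (EEM) samples.

An EEM records fluorescence intensity over a grid of excitation x emission
wavelengths for one sample.  A set of samples sharing one wavelength grid
forms a three-way cube (samples x excitation x emission).  On disk a cube is
a manifest (``sample_id,grid_file,role,concentration_molar``) plus one
delimited-text grid per sample with emission wavelengths as row labels and
excitation wavelengths as column labels.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = frozenset({"calibration", "validation", "test", "blank", "unknown"})


class EEMError(Exception):
    """Base class for EEM data-model failures."""


class ManifestError(EEMError):
    """Malformed or inconsistent manifest."""


class GridMismatchError(EEMError):
    """A sample's intensity grid does not match the cube's wavelength axes."""


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise EEMError(f"{name} axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise EEMError(f"{name} axis contains non-finite wavelengths")
    if not np.all(np.diff(values) > 0):
        raise EEMError(f"{name} axis must be strictly increasing")
    return values


@dataclass(frozen=True)
class WavelengthGrid:
    """Shared excitation/emission wavelength axes of a cube (nm)."""

    excitation: np.ndarray
    emission: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "excitation", _check_axis("excitation", self.excitation))
        object.__setattr__(self, "emission", _check_axis("emission", self.emission))

    @property
    def n_ex(self) -> int:
        return self.excitation.size

    @property
    def n_em(self) -> int:
        return self.emission.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.excitation.shape == other.excitation.shape
            and self.emission.shape == other.emission.shape
            and np.array_equal(self.excitation, other.excitation)
            and np.array_equal(self.emission, other.emission)
        )


@dataclass
class EEMSample:
    """One sample's fluorescence landscape.

    ``intensities`` is an emission x excitation matrix (rows follow the
    emission axis, the long/fast axis).  Negative intensities are allowed —
    detector noise can dip below zero — but non-finite values are rejected.
    ``concentration`` is molar; ``None`` marks an unknown, 0.0 a blank.
    """

    sample_id: str
    intensities: np.ndarray
    role: str = "unknown"
    concentration: float | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise EEMError(f"sample {self.sample_id!r}: intensities must be 2-D")
        if not np.all(np.isfinite(self.intensities)):
            raise EEMError(f"sample {self.sample_id!r}: non-finite intensity values")
        if self.role not in VALID_ROLES:
            raise EEMError(
                f"sample {self.sample_id!r}: role {self.role!r} not in {sorted(VALID_ROLES)}"
            )
        if self.concentration is not None:
            c = float(self.concentration)
            if not np.isfinite(c) or c < 0:
                raise EEMError(
                    f"sample {self.sample_id!r}: concentration must be finite and >= 0"
                )
            self.concentration = c


@dataclass
class EEMCube:
    """Ordered collection of EEM samples on one wavelength grid."""

    grid: WavelengthGrid
    samples: list[EEMSample] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            raise EEMError("a cube needs at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EEMError(f"duplicate sample_id(s): {dupes}")
        expect = (self.grid.n_em, self.grid.n_ex)
        for s in self.samples:
            if s.intensities.shape != expect:
                raise GridMismatchError(
                    f"sample {s.sample_id!r}: intensity shape {s.intensities.shape} "
                    f"does not match grid (n_em={expect[0]}, n_ex={expect[1]})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(samples, n_excitation, n_emission)."""
        return (len(self.samples), self.grid.n_ex, self.grid.n_em)

    def to_array(self) -> np.ndarray:
        """Stack samples into a (m, n_ex, n_em) array."""
        return np.stack([s.intensities.T for s in self.samples])

    def concentrations(self, roles: set[str] | None = None) -> np.ndarray:
        vals = [
            np.nan if s.concentration is None else s.concentration
            for s in self.samples
            if roles is None or s.role in roles
        ]
        return np.asarray(vals, dtype=float)

    def subset(self, sample_ids: list[str]) -> "EEMCube":
        by_id = {s.sample_id: s for s in self.samples}
        return EEMCube(self.grid, [by_id[i] for i in sample_ids])


def default_grid() -> WavelengthGrid:
    """Standard acquisition grid: emission 300–500 nm step 0.5 (401 points),
    excitation 236–265 nm step 1 (30 points).

    The excitation range 235–265 at 1 nm would give 31 points; recorded cubes
    in this workflow carry 30 excitation columns, so the default drops the
    first point.  A warning documents the asymmetry.
    """
    logger.warning(
        "default excitation axis uses 30 points (236-265 nm step 1); "
        "a full 235-265 nm / 1 nm axis would have 31"
    )
    emission = np.arange(300.0, 500.0 + 0.25, 0.5)
    excitation = np.arange(236.0, 265.0 + 0.5, 1.0)
    return WavelengthGrid(excitation=excitation, emission=emission)


# ---------------------------------------------------------------------------
# File I/O

_MANIFEST_COLUMNS = ["sample_id", "grid_file", "role", "concentration_molar"]


def _sniff_delimiter(path: str) -> str:
    with open(path, "r") as fh:
        head = fh.readline()
    for delim in ("\t", ",", ";"):
        if delim in head:
            return delim
    return ","


def _read_grid_file(path: str, sample_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read one grid file -> (emission axis, excitation axis, intensities)."""
    if not os.path.exists(path):
        raise ManifestError(f"grid file for sample {sample_id!r} not found: {path}")
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
        em = df.index.to_numpy(dtype=float)
        ex = df.columns.to_numpy(dtype=float)
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise EEMError(f"sample {sample_id!r}: non-numeric cell in {path}: {exc}") from exc
    return em, ex, values


def read_cube(manifest_path: str) -> EEMCube:
    """Load a cube from a manifest of per-sample grid files.

    Sample order follows manifest order.  All grid files must share exactly
    the same wavelength axes; any mismatch, missing file, duplicate id, or
    non-numeric cell raises a descriptive error.
    """
    if not os.path.exists(manifest_path):
        raise ManifestError(f"manifest not found: {manifest_path}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _MANIFEST_COLUMNS:
            raise ManifestError(
                f"manifest header must be {','.join(_MANIFEST_COLUMNS)}; "
                f"got {reader.fieldnames}"
            )
        rows = list(reader)
    if not rows:
        raise ManifestError("manifest lists no samples")

    grid: WavelengthGrid | None = None
    samples: list[EEMSample] = []
    for row in rows:
        sid = row["sample_id"].strip()
        gpath = row["grid_file"].strip()
        if not os.path.isabs(gpath):
            gpath = os.path.join(base, gpath)
        em, ex, values = _read_grid_file(gpath, sid)
        this_grid = WavelengthGrid(excitation=ex, emission=em)
        if grid is None:
            grid = this_grid
        elif grid != this_grid:
            raise GridMismatchError(
                f"sample {sid!r}: wavelength axes ({em.size} em x {ex.size} ex) "
                f"differ from the first sample's ({grid.n_em} em x {grid.n_ex} ex)"
            )
        conc_field = (row.get("concentration_molar") or "").strip()
        conc = None if conc_field == "" else float(conc_field)
        samples.append(
            EEMSample(sample_id=sid, intensities=values, role=row["role"].strip(), concentration=conc)
        )
    return EEMCube(grid=grid, samples=samples)


def write_cube(cube: EEMCube, out_dir: str) -> str:
    """Write a cube as a manifest plus per-sample grid files; returns the
    manifest path.  ``read_cube(write_cube(cube))`` round-trips exactly
    (Python float repr is used, which is lossless)."""
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for s in cube.samples:
            fname = f"{s.sample_id}.csv"
            df = pd.DataFrame(
                s.intensities,
                index=[repr(float(v)) for v in cube.grid.emission],
                columns=[repr(float(v)) for v in cube.grid.excitation],
            )
            df.to_csv(os.path.join(out_dir, fname), float_format="%.17g")
            conc = "" if s.concentration is None else repr(float(s.concentration))
            writer.writerow([s.sample_id, fname, s.role, conc])
    return manifest_path


def write_long_table(cube: EEMCube, path: str) -> None:
    """Export a cube as one long-format table (sample_id, ex_nm, em_nm, intensity)."""
    frames = []
    for s in cube.samples:
        ex, em = np.meshgrid(cube.grid.excitation, cube.grid.emission)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "ex_nm": ex.ravel(),
                    "em_nm": em.ravel(),
                    "intensity": s.intensities.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
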