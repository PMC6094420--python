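"""Unfolding (matricization) of EEM cubes and PCA on the unfolded matrix.

Unfolding flattens each sample's emission x excitation grid into one long
row — emission varying fastest within each excitation block — so the
three-way cube becomes an ordinary samples x variables matrix, A.  PCA then
decomposes the column-mean-centered A as T P^T + E: scores T locate samples
in component space, orthonormal loadings P carry the spectral directions,
and eigenvalues (sample-covariance convention, s^2/(m-1)) account for the
variance each component explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eem_data import EEMCube, EEMSample, WavelengthGrid


@dataclass
class UnfoldedMatrix:
    """Samples x (excitation * emission) matrix with a map back to wavelengths.

    ``column_map[j]`` is the (excitation nm, emission nm) pair variable j
    measures; the map is a bijection onto the grid.
    """

    values: np.ndarray
    column_map: list[tuple[float, float]]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("unfolded values must be 2-D")
        if self.values.shape[1] != len(self.column_map):
            raise ValueError("column_map length must equal the number of variables")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id per row required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass
class PCAModel:
    """Fitted PCA of an unfolded matrix: A_centered = T P^T + E."""

    column_means: np.ndarray
    loadings: np.ndarray  # l x k, orthonormal columns
    scores: np.ndarray  # m x k
    eigenvalues: np.ndarray  # length k, s^2/(m-1), non-increasing
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def unfold(cube: EEMCube) -> UnfoldedMatrix:
    """Row i = sample i's grid flattened with emission fastest within each
    excitation block; a 61 x 30 x 401 cube yields a 61 x 12030 matrix."""
    arr = cube.to_array()  # (m, n_ex, n_em)
    m = arr.shape[0]
    values = arr.reshape(m, -1)
    column_map = [
        (float(ex), float(em))
        for ex in cube.grid.excitation
        for em in cube.grid.emission
    ]
    return UnfoldedMatrix(values=values, column_map=column_map,
                          sample_ids=[s.sample_id for s in cube.samples])


def refold(matrix: UnfoldedMatrix, grid: WavelengthGrid,
           roles: list[str] | None = None,
           concentrations: list[float | None] | None = None) -> EEMCube:
    """Exact inverse of :func:`unfold` for a matching grid."""
    l_expected = grid.n_ex * grid.n_em
    if matrix.n_variables != l_expected:
        raise ValueError(
            f"unfolded matrix has {matrix.n_variables} variables but the grid "
            f"implies {l_expected} ({grid.n_ex} ex x {grid.n_em} em)"
        )
    samples = []
    for i, sid in enumerate(matrix.sample_ids):
        block = matrix.values[i].reshape(grid.n_ex, grid.n_em)
        samples.append(
            EEMSample(
                sample_id=sid,
                intensities=block.T,
                role=roles[i] if roles else "unknown",
                concentration=concentrations[i] if concentrations else None,
            )
        )
    return EEMCube(grid=grid, samples=samples)


def fit_pca(matrix: UnfoldedMatrix, k: int) -> PCAModel:
    """Column-mean-centered SVD; retains the k leading components.

    ``variance_pct`` is relative to the total variance of the centered
    matrix (all components), so a truncated model's percentages still sum
    to less than 100.
    """
    X = matrix.values
    m, l = X.shape
    if m < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not (1 <= k <= min(m - 1, l)):
        raise ValueError(f"k must be in [1, {min(m - 1, l)}]; got {k}")
    means = X.mean(axis=0)
    Xc = X - means
    # economy SVD: U (m x r), s (r), Vt (r x l)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    all_eigs = s**2 / (m - 1)
    total = all_eigs.sum()
    if total <= 0:
        raise ValueError("constant matrix: zero total variance")
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    eigenvalues = all_eigs[:k]
    variance_pct = 100.0 * eigenvalues / total
    return PCAModel(
        column_means=means,
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
    )


def variance_table(model: PCAModel) -> pd.DataFrame:
    """Eigenvalue / variance-explained / cumulative-variance table, one row
    per retained component.  Cumulative values are exact prefix sums;
    rounding happens only at display time."""
    return pd.DataFrame(
        {
            "pc": np.arange(1, model.k + 1),
            "eigenvalue": model.eigenvalues,
            "variance_pct": model.variance_pct,
            "cumulative_pct": model.cumulative_pct,
        }
    )


def project(model: PCAModel, matrix: UnfoldedMatrix, n_pc: int | None = None) -> np.ndarray:
    """Scores of (possibly new) samples: (rows - training column means) @ P[:, :n_pc]."""
    if n_pc is None:
        n_pc = model.k
    if n_pc > model.k:
        raise ValueError(f"n_pc={n_pc} exceeds the fitted k={model.k}")
    if matrix.n_variables != model.column_means.size:
        raise ValueError(
            f"matrix has {matrix.n_variables} variables; model expects {model.column_means.size}"
        )
    return (matrix.values - model.column_means) @ model.loadings[:, :n_pc]


def flag_outliers(model: PCAModel, threshold: float = 3.0) -> list[int]:
    """Screen the PC1-PC2 score plot for atypical samples.

    A sample is flagged when its Euclidean distance from the robust score
    centroid (coordinate-wise median) exceeds ``threshold`` times the robust
    scale of those distances (1.4826 * median absolute deviation, the
    normal-consistent MAD).  Deterministic replacement for visual
    score-plot inspection; flagged samples are reported, never removed.
    """
    if model.k < 2:
        raise ValueError("outlier screening needs at least 2 components")
    pts = model.scores[:, :2]
    center = np.median(pts, axis=0)
    dist = np.linalg.norm(pts - center, axis=1)
    scale = 1.4826 * np.median(np.abs(dist - np.median(dist)))
    cutoff = np.median(dist) + threshold * scale
    return [int(i) for i in np.nonzero(dist > cutoff)[0]]
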