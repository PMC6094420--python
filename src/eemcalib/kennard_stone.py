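"""Kennard-Stone representative sample splitting.

The Kennard-Stone algorithm orders samples by design-space coverage: start
from the two mutually most-distant points, then repeatedly add the point
whose minimum distance to the already-selected set is largest (maximin).
The ordering is fully deterministic — ties break to the lowest index — so a
calibration/validation/test split derived from it is reproducible with no
randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration/validation/test id lists covering all samples."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.calibration_ids), len(self.validation_ids), len(self.test_ids))


def ks_rank(points: np.ndarray) -> list[int]:
    """Classic maximin ordering of row vectors.

    The first two indices are the pair at maximum Euclidean distance (tie:
    lexicographically smallest index pair); each subsequent index maximizes
    the minimum distance to all points already selected (tie: lowest index).
    Returns a permutation of range(m).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    m = pts.shape[0]
    if m < 2:
        raise ValueError("Kennard-Stone needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    sq = np.sum(pts**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * pts @ pts.T
    np.maximum(d2, 0.0, out=d2)

    # seed pair: max distance, ties to the smallest (i, j) in row-major scan
    iu = np.triu_indices(m, k=1)
    flat = d2[iu]
    best = int(np.argmax(flat))  # argmax returns the first maximum -> lowest (i, j)
    i0, j0 = int(iu[0][best]), int(iu[1][best])

    order = [i0, j0]
    selected = np.zeros(m, dtype=bool)
    selected[[i0, j0]] = True
    min_d2 = np.minimum(d2[i0], d2[j0])
    for _ in range(m - 2):
        min_d2[selected] = -np.inf
        nxt = int(np.argmax(min_d2))  # first maximum -> lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        min_d2 = np.minimum(min_d2, d2[nxt])
    return order


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def three_way_split(
    points: np.ndarray,
    sample_ids: list[str] | None = None,
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
) -> SplitAssignment:
    """Split samples calibration/validation/test down the Kennard-Stone ranking.

    Validation and test sizes are round(fraction * m) (half-up); the
    remainder goes to calibration, so 61 samples at (0.65, 0.15, 0.20)
    yield (40, 9, 12).  Calibration takes the head of the ranking — the
    most design-covering samples, including the maximin seed pair — then
    validation, then test.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    m = pts.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(m)]
    if len(sample_ids) != m:
        raise ValueError("one sample_id per point required")
    f_cal, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(f_cal + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")

    n_val = _round_half_up(f_val * m)
    n_test = _round_half_up(f_test * m)
    n_cal = m - n_val - n_test
    if min(n_cal, n_val, n_test) < 1:
        raise ValueError(f"split of {m} samples at {fractions} leaves an empty set")

    order = ks_rank(pts)
    ids = [sample_ids[i] for i in order]
    return SplitAssignment(
        calibration_ids=tuple(ids[:n_cal]),
        validation_ids=tuple(ids[n_cal:n_cal + n_val]),
        test_ids=tuple(ids[n_cal + n_val:]),
    )
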