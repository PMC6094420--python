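"""Published reference results for ibuprofen quantified in spiked human serum.

A published EEM-fluorescence calibration study of ibuprofen extracted from
serum reports, for each of its 61 standard solutions, the nominal spiked
concentration, the concentration predicted by the trained unfolded-PCA /
neural-network model, and the signed per-sample relative error of prediction
(REP%).  It also tabulates the per-component explained variance of the PCA
on the unfolded cube.  These printed numbers serve as arithmetic fixtures:
the per-sample REP% column should be recoverable from the nominal/predicted
pairs, its mean is the study's average relative error of prediction, and the
cumulative-variance column is the running sum of the per-PC variances.

Concentrations are in units of 1e-7 M; variances in percent.
"""

from __future__ import annotations

import numpy as np

# (sample number, nominal conc, predicted conc, printed REP%), conc in 1e-7 M
CALIBRATION_RESULTS: list[tuple[int, float, float, float]] = [
    (1, 11, 11.13, 1.20),
    (2, 12, 11.57, -3.58),
    (3, 13, 12.95, -0.39),
    (4, 1.5, 1.51, 0.46),
    (5, 16, 16.41, 2.58),
    (6, 17, 17.10, 0.61),
    (7, 18, 17.78, -1.22),
    (8, 19, 19.29, 1.52),
    (9, 21, 20.79, -1.00),
    (10, 22, 21.74, -1.17),
    (11, 23, 22.99, -0.04),
    (12, 24, 23.72, -1.17),
    (13, 25, 25.27, 1.06),
    (14, 2.5, 2.55, 1.91),
    (15, 26, 26.03, 0.12),
    (16, 27, 27.06, 0.24),
    (17, 28, 27.50, -1.79),
    (18, 29, 28.68, -1.09),
    (19, 31, 30.92, -0.25),
    (20, 32, 30.78, -3.81),
    (21, 33, 33.18, 0.55),
    (22, 34, 34.12, 0.35),
    (23, 35, 35.25, 0.73),
    (24, 3.5, 3.59, 2.59),
    (25, 36, 36.72, 1.99),
    (26, 37, 37.00, 0.01),
    (27, 38, 38.05, 0.14),
    (28, 39, 40.43, 3.66),
    (29, 41, 41.08, 0.20),
    (30, 42, 42.17, 0.41),
    (31, 43, 43.15, 0.35),
    (32, 44, 44.73, 1.66),
    (33, 45, 44.60, -0.89),
    (34, 4.5, 4.52, 0.42),
    (35, 46, 46.80, 1.74),
    (36, 47, 47.35, 0.74),
    (37, 5.5, 5.68, 3.31),
    (38, 7.5, 7.68, 2.35),
    (39, 8.5, 8.15, -4.07),
    (40, 9.5, 9.76, 2.77),
    (41, 10, 9.79, -2.13),
    (42, 1, 1.04, 3.82),
    (43, 0.1, 0.10, 3.87),
    (44, 20, 20.22, 1.11),
    (45, 2, 2.00, 0.13),
    (46, 0.2, 0.20, 0.10),
    (47, 30, 30.78, 2.61),
    (48, 3, 3.01, 0.24),
    (49, 0.3, 0.30, 0.59),
    (50, 40, 39.17, -2.07),
    (51, 4, 4.01, 0.14),
    (52, 0.4, 0.39, -2.58),
    (53, 5, 5.03, 0.66),
    (54, 0.5, 0.49, -1.34),
    (55, 6, 6.08, 1.38),
    (56, 7, 6.86, -2.00),
    (57, 0.7, 0.69, -2.02),
    (58, 8, 7.90, -1.23),
    (59, 0.8, 0.80, -0.54),
    (60, 9, 8.74, -2.91),
    (61, 0.9, 0.90, 0.15),
]

# Per-PC explained variance (%) of the PCA on the unfolded cube, PCs 1-20.
EXPLAINED_VARIANCE_PCT: list[float] = [
    39.79, 20.21, 8.24, 6.89, 5.02, 4.30, 2.79, 2.47, 1.90, 1.48,
    1.13, 0.75, 0.61, 0.54, 0.40, 0.37, 0.35, 0.24, 0.23, 0.19,
]


def nominal_concentrations_molar() -> np.ndarray:
    """The 61-level concentration ladder of the study, in molar (1e-8 to 4.7e-6)."""
    return np.array([row[1] for row in CALIBRATION_RESULTS]) * 1e-7


def predicted_concentrations_molar() -> np.ndarray:
    return np.array([row[2] for row in CALIBRATION_RESULTS]) * 1e-7


def printed_rep_pct() -> np.ndarray:
    return np.array([row[3] for row in CALIBRATION_RESULTS])
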