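# Methods

## The calibration problem

Excitation–emission matrix (EEM) fluorescence records, for one sample, the
emitted intensity over a grid of excitation × emission wavelengths.  For a
drug such as ibuprofen extracted from serum into an organic phase, the
analyte contributes a smooth, essentially rank-one landscape (an outer
product of an excitation band and an emission band) whose amplitude is
proportional to concentration, sitting on a variable serum background plus
detector noise.  Stacking the EEMs of a sample set gives a three-way cube
(samples × λ_ex × λ_em).

`eemcalib` implements the *unfolded-PCA / neural-network* (UPCA-ANN)
approach to second-order calibration:

1. **Unfold** the cube into a samples × variables matrix A, flattening each
   EEM with emission varying fastest within each excitation block.  The
   order is arbitrary but fixed; PCA is invariant to column permutations,
   and the column map retains the (λ_ex, λ_em) identity of every variable.
2. **Compress** by PCA on the column-mean-centered A: A_c = T Pᵀ + E.
   Eigenvalues use the sample-covariance convention s²/(m−1); explained
   variance is quoted relative to the total variance of the centered
   matrix.  Mean-centering only — no unit-variance scaling — is the usual
   choice for spectral data, where the variables share units and the
   variance pattern is informative.
3. **Split** samples into calibration / validation / test sets with the
   Kennard–Stone maximin algorithm on the PC scores.  Set sizes are
   round-half-up of the requested fractions for validation and test, with
   the remainder to calibration (61 samples at 0.65/0.15/0.20 → 40/9/12).
   Calibration takes the head of the ranking, so it contains the
   most-distant seed pair and spans the design; validation and test follow.
   The default fits PCA on all non-blank samples before splitting, which is
   how this workflow is normally run; a `leak_free_split` option instead
   fits PCA on the calibration rows only and projects the rest, for users
   who want strict separation at the cost of comparability.
4. **Calibrate** concentration from the leading n PC scores with a
   one-hidden-layer feed-forward network (n − n_h − 1), logistic-sigmoid
   hidden units and a linear output.  Training is full-batch gradient
   descent on the mean squared error with classical momentum,
   Δw_n = −μ ∂E/∂w + α Δw_{n−1}, plus validation-based early stopping with
   best-state restoration.
5. **Report** figures of merit: RMSE per set, per-sample and aggregate
   REP%, R², RMSEcv, and LOD/LOQ from blank predictions.

## Network details and defaults

| parameter | default | rationale |
|---|---|---|
| hidden activation | logistic sigmoid | classic regression MLP; keeps the forward pass in the standard Σ W_J f(Σ W_JI x_I + b_J) form |
| output activation | identity | unconstrained regression output |
| weight init | U(−0.3, 0.3), seeded | small symmetric start for sigmoid units; fully reproducible |
| learning rate μ | 0.7 | the operating point reported for this workflow |
| momentum α | 0.2 | same |
| epochs | 300 | same; one epoch = one full-batch update |
| early-stopping patience | 50 epochs | qualitative "stop when validation error stops improving", made concrete |
| input scaling | standardize on calibration set | PC scores have wildly different variances by construction |
| target scaling | min–max to [0.1, 0.9] on calibration set | keeps targets inside the sigmoid-era working range and away from saturation |

Plain momentum gradient descent converges slowly on near-linear problems:
the historical operating point (μ = 0.7, α = 0.2, 300 epochs) gives a
usable but visibly unconverged fit on our synthetic data, and the recovery
tests therefore budget 10⁴–6×10⁴ epochs (seconds of CPU at these problem
sizes) or raise the momentum.  This is a property of the optimizer, not of
the calibration model.

The momentum update follows the conventional form above.  (A literal
reading of one printed variant of the rule — new weight = old weight +
α·Δw with no gradient term — cannot descend the error surface; the prose
description of momentum matches the conventional form, which is what is
implemented.)

Two REP% conventions circulate: the signed per-sample relative error
100·(ŷ−y)/y, used in per-sample result tables, and the aggregate
100·RMSE/ȳ quoted next to RMSEP.  Both are implemented and labeled;
`rep_per_sample` requires strictly positive nominal concentrations.

LOD follows the univariate blank-based definition: S_b is the sample
standard deviation of the concentrations predicted for blank solutions,
LOD = 3·S_b.  No LOQ definition is standard in this setting; LOQ = 10·S_b
is adopted, consistent with reported LOQ/LOD ratios near 10/3.

## Model selection

The number of components is chosen by leave-one-out cross-validation over
the leading-n score sets: for each candidate n, each calibration sample is
left out in turn, a network is trained on the remainder for a fixed epoch
budget, and the left-out concentration is predicted.  Early stopping during
LOO monitors the *training fold*, never the left-out sample — using the
held-out point as the stopping probe would leak it into the selection.
RMSEcv curves are returned for all candidates; ties go to the smaller n.

Hyperparameter response surfaces (hidden nodes × epochs, learning rate ×
momentum) train one model per grid cell with a per-cell seed derived from
the base seed, record test-set MSE, and return the argmin with ties broken
toward the earlier (smaller) cell.

Outlier screening on the PC1–PC2 score plot replaces visual inspection
with a deterministic rule: flag samples whose distance from the
coordinate-wise median centroid exceeds the median distance plus 3× the
normal-consistent MAD of the distances.  Flagged samples are reported,
never removed — in this workflow removing them changes results only
marginally, and silent deletion would hide information.

## The synthetic generator

`synthetic.simulate_cube` produces cubes that are *bilinear by
construction*: each fluorophore is a Gaussian excitation band ⊗ Gaussian
emission band, the analyte scaled by concentration, interferents by
per-sample uniform random levels, plus additive homoscedastic Gaussian
noise (heteroscedastic and Rayleigh-scatter-ridge options exist for stress
tests).  `reference_design` reproduces the study conditions this package
targets: 61 standards on the published 0.1–47 ×10⁻⁷ M ladder, analyte
bands at λ_ex 251 nm / λ_em 362.5 nm, two broad serum-like background
bands (λ_ex 244/λ_em 335 and λ_ex 262/λ_em 420 nm) with levels comparable
to the low standards — this is what makes more than one PC necessary — and
a 30 × 401 acquisition grid.  The default noise (sd 2.0 intensity units,
≈0.4% of the top standard's peak) represents a well-behaved
fluorospectrometer.

What the generator does **not** emulate: inner-filter effects, quenching,
Rayleigh/Raman scatter (unless enabled), wavelength-dependent detector
response, or non-Gaussian band shapes.  Passing tests therefore demonstrate
that the pipeline recovers concentrations when the bilinear low-rank model
holds and backgrounds vary smoothly; they do not certify performance on
real serum extracts, where scatter handling and band distortions matter.

The default wavelength grid mirrors the acquisition ranges of the target
instrument setup: emission 300–500 nm every 0.5 nm (401 points) and a
30-point excitation axis at 236–265 nm step 1 nm.  (The nominal excitation
range 235–265 at 1 nm would give 31 points; recorded cubes in this workflow
carry 30 columns, so the default drops the first point and logs a warning.)

## Numerical choices and degenerate inputs

- PCA is computed by economy SVD of the centered matrix; eigenvalues match
  a covariance eigendecomposition to 1e-8 (verified against both a
  brute-force oracle and scikit-learn in the tests, neither of which is on
  the implementation path).
- Constant (zero-variance) matrices are rejected by `fit_pca`; `k` must be
  ≤ min(m−1, l).
- Kennard–Stone is exact maximin with ties broken to the lowest index at
  every step, including the seed pair; the output is a permutation even for
  duplicated points.
- Sigmoid inputs are clipped at ±500 before exponentiation; beyond that the
  function is flat to double precision.
- Zero input standard deviations are replaced by 1 in the scaler (a
  constant input then contributes nothing rather than NaNs).
- Grid files round-trip bit-for-bit: written with `%.17g`, parsed with
  pandas' round-trip float parser.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the design/config objects; reruns are bitwise identical.

## Problem sizes used in the tests

Unit and property tests run on reduced grids (15 × 40) and small nets,
chosen so the full suite exercises every stage — including LOO factor
selection, a response-surface scan, and Monte-Carlo LOD scaling — in about
a minute of CPU.  The end-to-end recovery checks use the full 61-standard
design; the acceptance script additionally runs the study-sized
61 × 30 × 401 cube.

## Known limitations

- Unfolding destroys the trilinear structure, so the method has no
  second-order advantage (no quantification in the presence of
  uncalibrated interferents); PARAFAC-style decompositions are out of
  scope by design.
- LOD on synthetic serum cubes is dominated by background variability, not
  detector noise, and lands above the noise-only limit; the blank-based
  definition measures exactly this combined variability.
- The per-sample REP% convention is undefined for true blanks (division by
  the nominal value); the aggregate form or RMSE should be used there.
- Intra/inter-day precision (RSD%) requires replicate acquisition runs and
  is only computed when such replicates are supplied.
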