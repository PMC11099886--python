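# Methods

This note documents the models, algorithms and design choices behind
`massshiftnet`, a self-supervised mass-recalibration framework for MALDI
mass spectrometry imaging (MSI), and states precisely what the synthetic
validation suite does and does not demonstrate.

## Problem

MALDI-TOF imaging acquires one spectrum per pixel. Surface topography and
space-charge effects displace the observed m/z axis by a smooth,
pixel-dependent error Δ(t) of typically tens of ppm — too large for
reliable annotation against theoretical masses, and variable enough across
a slide to blur dataset-level peak statistics. The goal is to estimate
Δ(t) per spectrum and correct each axis by t → t − Δ(t), without internal
calibrant spray and without labeled training data.

## Kendrick mass-defect encoding

For a mass m and base λ the centered Kendrick defect is

    δ_λ(m) = m/λ − ⌊m/λ + 1/2⌋  ∈ [−0.5, 0.5).

With the averagine base λ_av = 1 + 4.95·10⁻⁴, peptide masses cluster near
integer multiples of λ_av, so the peptide population forms a band near
δ = 0 whose displacement in a measured spectrum *is* the local mass shift
(in defect units, i.e. fractions of one ~1.0005 Da period). A spectrum is
encoded as an L×K histogram over (defect, m/z): intensities are
accumulated into K equal-width m/z columns (default 24 over the
acquisition window) and L equal-width defect rows (default 256; 64 in the
scaled-down suite). The defect axis is circular — a shift past +0.5 wraps
to −0.5 — which the network architecture respects via circular padding.

Numerical conventions: the nearest nominal mass uses floor(x + 1/2), so a
half-integer maps to the upper integer and δ = −0.5 at the tie; histogram
bins are left-closed/right-open with the top m/z edge inclusive; samples
outside the declared window are excluded (and counted). The raw histogram
conserves total in-range intensity exactly; for network input each nonzero
column is divided by its sum as a separate step (per-column normalization
removes the arbitrary per-spectrum intensity scale; all-zero columns stay
zero). Log-intensity accumulation is available behind a config flag but
off by default.

## Component models

*Averagine peptides.* Monoisotopic locations at λ_av·n for every integer n
in the window, each with an isotope envelope at +k·1.00336 Da and binomial
weights from the mass-dependent carbon count (4.9384 C per 111.1254 Da);
heavier species get flatter envelopes. Exact isotope fine structure is
irrelevant at the 0.05 Da peak width used throughout.

*CHCA matrix clusters.* Exact masses of singly charged cluster ions
[nM − pH + qNa + rK + sH]⁺ of the matrix monomer M = C₁₀H₇NO₃
(monoisotopic 189.0426 Da), computed from monoisotopic elemental masses.
The default adduct table enumerates all cation-exchange combinations with
q, r ≤ 3 and q + r ≤ 4 plus the water-loss ion [nM+H−H₂O]⁺, for cluster
sizes n up to 12; it reproduces the prominent matrix peaks observed in
peptide MALDI data (e.g. 644.05, 650.06, 682.00, 855.07 Da theoretical for
the ions near the observed 644.08, 650.10, 682.09, 855.10) within 0.1 Da.
The table is a documented stand-in for a full published cluster inventory
and is user-overridable through a plain-text config (element counts per
row).

## Synthetic data generator

Spectra are rendered as

    X(t) = b(t) + Σ_j α_j · exp(−(t − p_j − Δ(t))² / 2σ²) + ε(t)

with unit-height Gaussian peaks of width σ = 0.05 Da on a uniform 0.01 Da
grid over 600–3200 Da (the acquisition window and a sampling that resolves
σ with five points). Abundances: a log-normal template (σ_log = 1) on a
random ~30% subset of averagine positions, shared across the spots of a
dataset with per-spot log-normal jitter (σ_log = 0.25) — shared positions
make dataset-level peak statistics meaningful; a per-spot uniform matrix
level; a smooth exponentially decaying baseline (5% of the maximum peak
amplitude, 500 Da decay constant); additive Gaussian noise with SD 1% of
the template's maximum amplitude. All randomness flows from one seeded
generator.

The distortion enters in the evaluation coordinate, G(t − p − Δ(t)),
matching the fitted model's convention, so t → t − Δ(t) restores peaks to
theoretical positions exactly.

What the generator does **not** emulate: detector peak-shape asymmetry and
mass-dependent resolution, Poisson/heteroscedastic noise, spatially
correlated shift fields across neighbouring pixels, chemical noise beyond
the matrix-cluster model, and real abundance correlations. Passing tests
therefore demonstrate correctness of the algorithms under the stated
signal model, not instrument-grade performance on tissue data.

## Mass-shift functions

Three families: linear Δ(t) = β₁t + β₂ and square-root Δ(t) = β₁√t + β₂
(the shapes typical of TOF distortions), and tabulated functions
(piecewise linear through knots, constant beyond the ends) representing
shifts extracted from observed spectra. Every shift must satisfy
|Δ| < λ/2 over its domain — beyond half a defect period the shift is not
identifiable from the defect map. Random banks draw 60% linear, 10%
square-root and 30% perturbations (scale ~ U(0.5, 1.5), offset ~
U(−0.05, 0.05) Da) of the extracted functions. Default parameter ranges —
β₂ ~ U(−0.15, 0.15) Da and β₁ ~ U(−5·10⁻⁵, 5·10⁻⁵) for linear, β₁ ~
U(−2.5·10⁻³, 2.5·10⁻³) and β₂ ~ U(−0.10, 0.10) Da for square-root — keep
the maximum |Δ| near 0.3 Da over 600–3200 Da, well inside the
identifiable range; draws violating the bound are rejected and redrawn.

## Model-based auxiliary recalibration

One spectrum is approximated by

    X(t) ≈ b_φ(t) + Σ_{i,j} α_j^i · G(t − p_j^i − Δ_ψ(t); σ),  σ = 0.05 Da,

minimizing the mean squared residual jointly over peak intensities α ≥ 0
and the parameter vectors ψ, φ of two one-hidden-layer feed-forward
networks (32 ReLU units, scalar m/z input scaled to [0, 1]): Δ_ψ(t) with
no output activation (a soft L2 penalty on Δ, weight 10⁻³ on the mean
squared shift, discourages period-wrapping; an optional hard tanh cap is
available but off by default) and b_φ(t) with a softplus output clamp for
non-negativity. Because the model renders *all* candidate peaks, peaks
absent from the spectrum simply receive α → 0; no peak matching is
performed, which removes the outlier sensitivity of match-based
calibration.

Optimization: plain least squares on the native grid; α reparametrized as
softplus(u) for non-negativity, initialized from the spectrum intensity at
each theoretical location; joint Adam (step 0.02 on the max-normalized
spectrum) for at most 2000 iterations, stopping when the best objective
improves by less than 10⁻⁵ (relative) over a 100-iteration window; the
best-seen parameters are returned, so the reported objective sequence is
non-increasing. Gaussian terms are evaluated sparsely on fixed per-peak
windows (±(5σ + 0.35 Da)) — the 0.35 Da margin bounds the shift excursion
that stays inside a peak's window. Because Δ_ψ and b_φ vary on the Da
scale, far more slowly than the 0.01 Da grid, both networks are evaluated
on 1 Da knots and interpolated linearly onto the grid (the backward pass
uses the exact interpolation adjoint); this changes the fitted functions
by less than their own curvature over 1 Da and cuts the per-iteration
cost by an order of magnitude. Warm starts copy all parameters from
the previous spectrum's fit and shrink the Adam step by 5×, since a
scale-normalized optimizer would otherwise kick a converged solution away;
on similar consecutive spectra this cuts iterations substantially.

A caveat on identifiability: at σ = 0.05 Da the k-th isotopologue of one
averagine species lies 0.0029·k Da from the (k+1)-th species' envelope, so
neighbouring species' amplitudes are nearly collinear. Shift recovery is
unaffected, but per-peak amplitude recovery (the "absent peaks get zero"
property) is only well-posed for monoisotopic component models, which is
how the validation suite tests it.

*Matrix score.* The fitted decomposition splits the signal into analyte
and matrix components; the matrix score is Σ matrix α / Σ all α (peak
areas are proportional to α at common width). The baseline is excluded
from both sums; a flag switches the denominator to the raw total spectrum
intensity. Scores are clipped to [0, 1]; an all-zero fit scores 0 with a
warning.

## The shift estimator

Input: the column-normalized L×K histogram. Architecture: six 1D
convolutional layers along the defect axis with an *independent filter
bank per m/z column* (no weight sharing across columns) and circular
padding, each followed by per-(column, channel) batch normalization and
leaky rectification (slope 0.01); then four 2D convolutional layers
(3×3; zero padding on the m/z axis, circular on the defect axis) with
batch normalization and leaky rectification, which let columns exchange
information; a 1×1 per-column convolution reduces channels to one; finally
an independent two-layer perceptron per column with a tanh output scaled
by 0.5. The output is a length-K vector of shifts *in defect units*, one
per m/z bin, bounded to [−0.5, 0.5] by construction — the bound forces
defect units as the target scale; conversion to Da multiplies by λ.
Defaults (channel widths 8→16×5 with kernel 9 in the 1D block, 32→32→32→16
in the 2D block, 64 hidden MLP units) are this package's choices; a
half-width preset (4→8×5, kernel 5; 8×4; 32 hidden) serves the CPU-scale
experiments.

Training minimizes the mean squared error between predicted and simulated
shift vectors (Adam, batch 64; learning rate 10⁻⁴ by default, 10⁻³ in the
scaled-down runs where the small network and short schedule need the
larger step). The validation split (10%) is held out by sample; since
every simulated shift function appears in exactly one sample, the split
separates shift functions and measures generalization to unseen
distortions. Early stopping (patience 4–5) restores the best validation
parameters. An optional per-epoch augmentation hook regenerates the
training samples with fresh matrix fractions; the default pipeline fixes
one uniform matrix fraction per sample at assembly time, which keeps runs
bit-reproducible. A loss mask down-weighting empty histogram columns is
available and off by default.

The training set follows the self-supervised recipe: calibrate a small
subset of spots with the model-based method (150 per dataset at full
scale), simulate a bank of shift functions per calibrated spot (2500 at
full scale; 60/10/30 mixture), add u ~ U(0, 1) times the spot's fitted
matrix spectrum, distort, histogram, normalize. Recalibrating a dataset is
then one forward pass per spectrum: predict the K-vector, smooth it with
a 5-column moving average (physical shift functions vary smoothly on the
~100 Da column scale while the per-column prediction errors are nearly
uncorrelated, so the average cuts the error roughly in half without
biasing smooth shifts; disableable), interpolate it into a tabulated
shift function (piecewise linear between bin centers, constant at the
edges), and subtract.

The network is implemented in a small numpy engine with explicit backprop
(`nn.py`): every convolution is expressed as one batched BLAS matrix
product, internal data layouts are chosen to avoid per-layer transposes,
and float32 is used throughout the estimator. All layers pass central-
difference gradient checks in float64 (tests/test_nn.py); training is
bit-reproducible for a fixed seed on single-threaded execution.

## Evaluation statistics

*Matched filter.* A peak near a target is located by maximizing the inner
product with a unit-norm Gaussian template (fwhm 0.15 Da, σ ≈ 0.0637 Da)
within ±0.5 Da of the target; ties go to the lower m/z; the correlation
maximum is refined by parabolic interpolation for sub-grid precision. The
amplitude is the inner product; the detection threshold is 2.5× the local
background (median of per-1.1-Da-window maxima over a 200 Da neighbourhood,
truncated at the spectrum edges), converted to template-amplitude units.

*Relative mass dispersion.* The 50 most intense local maxima of the mean
spectrum (greedy selection with 3 Da suppression) are matched in every
spectrum; targets with coverage < 10% are dropped; the dispersion is the
(n−1)-denominator standard deviation of matched locations in ppm of the
target; the summary is the median over retained targets.

*Absolute mass error.* The same matching machinery against the
theoretically known CHCA cluster masses; per target the median ppm offset
over spectra, summarized as the mean of the retained per-target medians.
The multi-dataset retention rule ("10% coverage in 10% of datasets")
degenerates to per-dataset 10% coverage for a single dataset.

*Low-matrix flag.* Per spot, the summed matched-filter amplitude at four
prominent matrix masses (644.08, 650.10, 682.09, 855.10); a spot is
low-matrix if its sum is strictly below 60% of the 99% quantile of the
sums. Filter amplitudes are used rather than nearest-sample intensities
for robustness to sub-bin misalignment.

## Scaled-down validation conditions

The full-scale recipe (150 calibrated spots × 2500 shifts, 256-row
histograms, 30+ epochs) is sized for GPU hardware. The validation suite
runs the same pipeline at desk scale, as this package's own study
conditions: 30 synthetic calibrated spectra × 200 shifts (6000 training
samples), 64 defect bins × 24 m/z columns, the half-width network, 12
epochs (early stopping, patience 4), learning rate 10⁻³; held-out
evaluation on 50 fresh spectra with fresh shifts. The dispersion study
uses 300 spots with proportional per-spot shifts of SD 20 ppm; the
metric-oracle checks use 500 spots on a 600–1100 Da window. In the
self-supervised experiment the "extracted" shift bank is a set of
tabulated smooth functions standing in for model-based fits (the
generator's truth makes the expensive per-spot decomposition redundant
there; the decomposition itself is validated separately).

## Known limitations

- Per-peak amplitude recovery is ill-posed between near-degenerate
  isotopologue/species pairs at σ = 0.05 Da (see above); reported α should
  be interpreted per cluster, not per isotopologue, when envelopes are on.
- The estimator's accuracy is bounded by the defect binning (λ/L Da per
  row — 0.016 Da at L = 64, 0.004 Da at the default L = 256); shifts well
  below one bin are attenuated toward zero.
- Batch-norm statistics make single-spectrum training batches degenerate;
  batch size must exceed 1.
- The model-based fit assumes the component lists cover the signal;
  strong un-modelled analytes bias both the baseline and the shift near
  their masses.
- imzML round-trips store intensities as float32 (m/z as float64), so
  intensity equality holds only to single precision.
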