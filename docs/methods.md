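# Methods

`nirband` implements a three-stage wavelength-selection strategy for
near-infrared (NIR) quantitative calibration — predicting an analyte content
(wt.%) from an absorbance spectrum — together with the preprocessing,
partitioning, regression and simulation machinery needed to run and test it
end to end.

## Pipeline

**Step 0 — partitioning.** A testing set is drawn uniformly at random and
set aside.  The remaining (modeling) samples are divided into calibration
and validation parts by SPXY selection: a Kennard–Stone-style greedy
max–min procedure on the joint distance

d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y,

with d_x the Euclidean distance between SNV-pretreated spectra and
d_y = |y_i − y_j|.  Normalizers are taken over the pool being split.  The
first two picks are the pair at maximal joint distance; each later pick
maximizes its minimum distance to the selected set; ties resolve to the
lowest sample index so the procedure is fully deterministic.  Default sizes
mirror the study design the package emulates: 90 calibration, 50
validation, 54 testing out of 194.

**Step 1 — SNV.** Each spectrum is independently centered and scaled to
unit sample standard deviation (ddof = 1), removing per-sample additive
offsets and multiplicative scatter.  A constant spectrum is an error (the
offending sample is named), not a silent NaN.

**Step 2 — grid-search moving window (GSMW).** A window is a contiguous
waveband of N channels starting at 1-based channel S (admissible when
S + N − 1 ≤ P).  For every window on a width grid — the full-resolution
default is N ∈ [1:1:100] ∪ [110:10:300] ∪ [320:20:700] with all admissible
S, i.e. 78,790 windows on a 700-channel axis — a PLS1 model is fitted on
the calibration part and the latent-variable (LV) count minimizing
validation RMSE is kept.  One NIPALS fit at the LV ceiling yields
regression vectors at every truncation level, so the LV scan costs a single
fit per window.  The LV ceiling is min(15, N, n_cal − 1); 15 is a standard
chemometric cap that keeps the exhaustive scan tractable.  The top-k
(default 5) windows are chosen greedily by ascending validation RMSE,
skipping windows that overlap an already-chosen one (ties: smaller N, then
smaller S); the printed study outcome this mirrors consists of five
mutually disjoint wavebands, which motivates the greedy-disjoint rule.

**Step 3 — latent principal components (LPC).** Each kept waveband's
calibration submatrix is compressed by PCA (SVD of the mean-centered
matrix; loadings' signs fixed so each column's largest-magnitude entry is
positive).  All components above rank tolerance (singular value
> 1e-10 × largest) are retained by default — so a 36-channel band with 90
calibration samples gives 36 LPCs — with an optional truncation parameter.
Validation and testing spectra are projected with the calibration means and
loadings, never refitted, to avoid information leakage.

**Step 4 — genetic refinement.** A binary GA searches over subsets of a
band's LPCs.  Fitness is the validation RMSE of an ordinary least-squares
model with intercept on the flagged score columns (calibration scores are
orthogonal, so OLS is stable and equivalent to a full-rank latent-variable
fit).  Operators: tournament selection of size 2; single-point crossover
applied per parent pair with probability p_c; independent per-bit mutation
with probability p_m; elitism (the incumbent best replaces one child), so
the best-so-far trace is non-increasing; all-zero chromosomes are repaired
by setting one random bit.  Population size defaults to
max(20, 2 × n_candidates), rounded to even.  Two stopping rules: a hard
ceiling of 500 iterations, and a stall rule that stops when the best RMSE
has not changed by more than 1e-6 for 20 consecutive iterations.  The
parametric scan reruns the evolution for every cell of the
{40, 50, 60}% × {0.8, 1.2, 1.5}% crossover/mutation grid with a seed
derived per cell (`SeedSequence([base_seed, cell_index])`), keeping the
cell with minimum best RMSE.  The waveband whose refined model has the
lowest validation RMSE wins; its model is refitted on the calibration
scores and scored on the untouched testing set.

**Baseline.** For comparison, a conventional GA-PLS runs over the raw
wavelength flags of the full spectrum (chromosome length P): fitness is the
validation RMSE of a PLS model restricted to the flagged channels, LV count
chosen by validation RMSE under the same ceiling.  The search space for
this baseline (wavelengths rather than components) is a deliberate choice
and is labelled in the report.

## Evaluation metrics

RMSE uses denominator n (not n − 1).  R is the Pearson product-moment
correlation between reference and predicted values; when either vector has
zero variance, R is reported as undefined via an explicit flag rather than
NaN.  RMSEC/RMSEV/RMSET (and R_C/R_V/R_T) denote the calibration,
validation and testing variants.

## Conventions

- Channels use 1-based indices: channel S sits at start + (S − 1) × step.
  On the default axis (start 1100 nm, step 2 nm, P = 700) channel 441 is
  1980 nm and channel 174 is 1446 nm; the last channel is 2498 nm.  The
  channel count is authoritative — an axis is (start, step, count), never
  reconstructed from a nominal end wavelength, which avoids the classic
  off-by-one of "700 wavelengths over 1100–2500 nm".
- Wavebands are closed intervals; both endpoints count, so 1446–1520 nm at
  2 nm spacing holds 38 variables.
- PLS1 uses NIPALS with X-only deflation (exact per component for a
  univariate response).  Only mean-centering is applied; SNV already
  normalizes rows, and column autoscaling is deliberately not performed.
- Model/validation choices are made on the held-out validation part
  throughout (window ranking, LV count, GA fitness, scan cell); k-fold
  cross-validation is not implemented.

## Synthetic data

The generator emulates a feed-analysis NIR dataset at full study scale
(defaults: 700 channels from 1100 nm at 2 nm, 194 samples) with known
ground truth:

A_i(λ) = g_i · Σ_comp c_{i,comp} · Σ_bands a · exp(−(λ − μ)² / 2σ²)
         + offset_i + slope_i · (λ − λ_mid) + ε_{i,λ}

- **Analyte** (protein-like): one Gaussian band centered at 2015 nm
  (σ = 18 nm, amplitude 0.010 per wt.%), spanning roughly 1980–2050 nm.
  Concentrations follow a scaled beta on [53, 67] wt.% moment-matched to
  mean 60.7 / SD 4.36.  A beta is used because no normal truncated to
  [53, 67] can reach an SD of 4.36 (the limit is the uniform SD
  14/√12 ≈ 4.04); the matched beta (≈ Beta(0.85, 0.70)) is mildly
  U-shaped, which also resembles feed data pooled from two provenances.
- **Matrix**: broad fixed bands (no concentration variance) giving each
  spectrum a stable bulk absorbance of ~0.3–0.6.  Without it, the analyte
  band would dominate each row's mean/SD and SNV would divide the analyte's
  own variation out of its band (closure artifact).
- **Interferents** ("moisture", "ash"): smaller bands elsewhere, with
  concentrations correlated 0.3 with the analyte via mixing of the
  standardized analyte deviate.
- **Scatter**: per-sample lognormal gain g_i (σ = 0.1), plus a random
  offset (SD 0.05) and slope (SD 5e-5 per nm).  The multiplicative gain is
  essential: it is the effect SNV exists to remove, and without it the SNV
  row statistics themselves become a spurious, physically meaningless
  carrier of concentration information that rewards featureless windows.
- **Noise**: i.i.d. Gaussian, SD 0.00436, giving a signal-to-noise ratio
  (analyte peak amplitude × concentration SD) / noise SD of 10.

`standard_fixtures()` provides the full-scale planted-band set, a
20-channel × 30-sample "tiny" set for brute-force oracles, and a
noise-free rank-1 set where a single latent variable is exact.

**What the generator does not model** — and hence what passing tests do not
show about real data: instrument line shapes, wavelength-dependent detector
noise, water-vapor artifacts, nonlinear detector response, and
concentration closure among real constituents.  One measured consequence:
because the synthetic mixture is globally linear, a full-spectrum GA-PLS
baseline can exploit every channel and outperforms the windowed pipeline on
this data, whereas on real NIR data waveband selection typically wins.  The
pipeline's structure-recovery claims (the scan finds the planted band; the
GA refines the window model) hold here, but the framework-vs-baseline
ordering is data-dependent and is reported, not asserted.

## Problem sizes used in tests and reproduction runs

Exact combinatorial quantities (window counts, axis arithmetic, LPC counts)
are computed at full scale.  Scans that repeat over many seeds use a
reduced width grid (N ∈ {12, 24, 36, 48}, all S — 2,684 windows per scan)
that brackets the 36-channel planted band, and GA budgets of 100–150
iterations; the GA-optimality rate uses the full 500-iteration budget with
the stall rule lifted, since that property is about the full-budget
optimizer.  The brute-force window-scan equivalence runs on the tiny
20-channel fixture (210 windows), and the exhaustive GA oracle enumerates
all 2^10 − 1 subsets of a 10-candidate problem.

## Numerical choices

- SNV and PCA variances use ddof = 1; RMSE uses denominator n.
- NIPALS components stop early if the residual covariance with y falls
  below 1e-14 (rank exhaustion); PCA rank tolerance is 1e-10 relative.
- GA stall tolerance: |ΔRMSEV| ≤ 1e-6 wt.% counts as "no change".
- Ties: SPXY and top-window selection break ties toward the lowest
  index / smallest (N, S); the parametric scan breaks ties toward the
  earlier grid cell.
- All randomness flows through `numpy.random.default_rng` seeds recorded in
  the run manifest; reruns with the same config are byte-identical.

## Known limitations

- PLS2 (multi-response), SIMPLS, kernel PLS, and cross-validated fitness
  are out of scope.
- The GA's exploration at small chromosome lengths is limited by the
  percent-scale mutation rates it inherits (0.8–1.5% per bit flips almost
  nothing on a 20-bit string); the stall rule then ends runs early.  This
  is faithful to the method, but it means short-chromosome problems rely on
  the initial population and crossover more than on mutation.
- The baseline GA-PLS at full scale is computationally dominated by
  per-fitness PLS fits; its default population/iteration budget is kept
  modest and configurable.
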