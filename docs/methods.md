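# Methods

`oscillome` implements a source-space resting-EEG analysis chain —
band-limited oscillatory power, orthogonalized power-envelope
connectivity (PEC), cohort statistics with permutation/FDR/robustness
screening, and connectome-based predictive modeling (CPM) — together
with a synthetic cohort simulator that provides ground truth for
validating every stage.

## Signal chain

**Preprocessing.** Recordings are average-referenced and filtered with
three linear-phase FIR stages in order: high-pass (1651 taps at
500 Hz, −6 dB at 0.5 Hz), 50 Hz notch (1651 taps, −6 dB at
49.5/50.5 Hz) and low-pass (75 taps, −6 dB at 101.25 Hz). Kernels are
Hamming-designed (`scipy.signal.firwin`); the stated tap counts refer
to 500 Hz and rescale proportionally (kept odd) at other rates. Each
stage is applied once with the group delay compensated by centering,
so the composite response is zero-phase and the −6 dB points sit at
the designed cutoffs; a forward–backward pass would square the
response and move them. Signals are then cut into non-overlapping 2-s
epochs (a trailing partial epoch is dropped — the deterministic
choice), and an epoch is rejected when its absolute amplitude exceeds
100 µV anywhere (strict inequality; absolute rather than peak-to-peak
amplitude, configurable). Subject-level QC drops a subject with >15%
bad channels or >50% rejected epochs (strict inequalities); bad-channel
detection itself is interactive tooling outside this package and QC
consumes its counts.

**Source model.** A lead field `G` (sensors × 3·vertices, unconstrained
orientations) is inverted with the regularized minimum-norm operator
`x = Gᵀ (G Gᵀ + λ² s C)⁻¹ y`, where `C` is the sensor noise covariance
(identity by default) and `s = trace(G Gᵀ)/trace(C)` makes λ²
dimensionless, so the default λ² = 1/9 carries its usual SNR = 3
meaning for any lead-field scaling. The three orientation series at a
vertex are collapsed to the first principal-component score series
(no mean removal — sources are zero-mean by construction; an all-zero
vertex maps to the zero series). Vertex series are averaged within
parcellation regions after flipping each vertex to correlate
positively with the region's first principal component, making the
region series invariant to the inverse solution's arbitrary per-vertex
signs. Region averaging by sign-aligned mean (rather than a per-region
PCA) was chosen for interpretability and is configurable.

The bundled parcellation table is *synthetic configuration*: 149
AAL3-style region rows with nine-network membership (DMN, DAN, SMN,
VAN, FPN, VN, LN, SC, CB) and toy vertex allocations arranged so that
merging the thalamic subregions into one region and excluding regions
with fewer than five vertices preserves exactly 113 regions. Region
identities are not anatomy and are meant to be replaced by a user
table. No boundary-element head modeling is attempted; the
`build_toy_leadfield` sphere model (dipole-kernel gains, Fibonacci
sensor lattice) exists to exercise the inverse, not to be realistic.

**Spectra and band power.** Welch PSD uses a 2-s Hann window with 1-s
overlap (0.5 Hz resolution), computed per epoch and averaged when
epoched input is given. Each region's PSD is z-transformed across the
2–90 Hz bins (sample SD; per-region rather than pooled — flagged
configurable), and band power is the trapezoidal area under the
normalized PSD within each band: delta 2–4, theta 5–7, alpha 8–12,
beta 13–29, low-gamma 30–59, high-gamma 60–90 Hz. The z-transform
makes band power invariant to any multiplicative rescaling of the
recording — that is its purpose (inter-subject gain removal), and the
simulator's validation leans on it (below).

**Morlet transform.** Complex Morlet coefficients with center
frequency fc = 1 Hz and temporal resolution FWHM_tc = 3 s, scaled so
the temporal FWHM at analysis frequency f is `FWHM_tc·fc/f` and the
coefficient magnitude of a unit tone is 1 (the magnitude is directly
the envelope). Implemented in the frequency domain: the analytic
response `2·exp(−2π²σ_t²(f′−f)²)` multiplies the zero-padded FFT,
which equals convolution with the untruncated time kernel; the
response at negative frequencies is numerically zero for all supported
bands (≥2 Hz). The per-band envelope for connectivity is the
coefficient at the band's geometric-center frequency (averaging over
several in-band centers is available).

**PEC.** For coefficients x, y the component of y instantaneously in
phase with x is removed, `y⊥x = imag(y·conj(x)/|x|)`, and the Pearson
correlation of `log(|y⊥x|² + ε)` against `log(|x|² + ε)` is averaged
over the two directions. Log power envelopes (rather than linear) are
used, with a *relative* ε floor (10⁻¹² of mean power) so PEC is
exactly invariant to rescaling either input. If an orthogonalized
residual is numerically zero (collinear inputs — the volume-conduction
limit), that direction contributes 0 by convention. Envelope samples
may be decimated two ways: subsampling complex coefficients before
orthogonalization (exact, since orthogonalization is pointwise) and
block-averaging the log-power envelopes; cohort runs use both
(subsample 10, block 4 at 500 Hz → 12.5 effective envelope samples per
second). The feature vector over n regions is the row-major upper
triangle including the diagonal — n(n+1)/2 entries, 6441 at n = 113 —
with self-pairs fixed at 0 and excluded from inference; the diagonal
is retained in the vector only to honor that dimension convention.
Features are z-transformed across subjects (sample SD; zero-variance
columns map to 0 with a warning). The per-subject discrepancy score
for a band sums subject-minus-reference PEC over the unique
off-diagonal pairs, the reference being the healthy-control mean
matrix; it is linear and additive over disjoint pair sets.

## Statistics

Per feature family (one band's region powers, or one band's PEC
pairs): two-sample pooled-variance t-tests; label-permutation
p-values `(1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1)` with 1000
permutations shared across features (preserving their correlation);
Benjamini–Hochberg FDR at q = 0.05 applied to the permutation
p-values within the family (the correction scope is a configuration
knob); and a robustness screen drawing 95% of each group without
replacement 100 times, re-running t + FDR per replicate — a feature is
robust when selected in a configurable fraction of replicates (all of
them by default) and the per-feature mean p across replicates ranks
CPM candidates. Network summaries average a region × region t-matrix
over network blocks (within-network blocks use unique off-diagonal
pairs; single-region blocks are undefined/NaN). Cohort demographics
use Pearson chi-square on count tables (expected-zero cells are
refused with a pointer to exact tests) and one-way ANOVA reconstructed
from per-group summaries (SSB from group means about the grand mean,
SSW = Σ(nᵢ−1)sᵢ²).

## CPM

Features with two-sample t-test p below a lenient threshold (default
0.3) split into a positive set (mean higher in class 1) and a negative
set; a subject's score is Σpos − Σneg (both effect directions then
push the score the same way; Σpos + Σneg is available since the
combination convention is genuinely ambiguous), and the decision
threshold is the accuracy-maximizing midpoint between sorted unique
scores, ties broken toward the widest score gap. The "dependent
t-test" sometimes named for this selection step contradicts the
independent-groups design; an independent test is used. Evaluation
reports accuracy/sensitivity/specificity at the threshold and the
rank-based (Mann–Whitney) AUC with ties counting ½. The fitted model —
feature sets, threshold, and a feature-space fingerprint — is applied
verbatim to an external cohort (no refitting; a fingerprint mismatch
refuses to score). Each cohort is feature-z-transformed with its own
statistics before scoring. There is no cross-validation by design:
the protocol is train-once, test-external. One caveat worth stating:
the *in-sample* training AUC after feature selection is optimistically
biased — with hundreds of features at n = 50, selection at p < 0.3
separates even permuted labels almost perfectly — so permutation nulls
are meaningful only out-of-sample (fit on permuted training labels,
evaluate on the intact external cohort; that AUC centers at 0.5).
`CPMClassifier` follows the scikit-learn estimator contract and
composes with sklearn model selection.

## The simulator

Each subject's region × time signal is a sum over the six bands of
`amplitude × envelope × carrier` plus 1/f background noise, scaled by
a subject/region gain:

- **Envelopes** are correlated Gaussian processes: white noise
  low-passed below the envelope bandwidth (1 Hz; zero-phase
  fourth-order-Butterworth magnitude applied spectrally, generated on
  a 16×bandwidth grid and linearly upsampled), standardized, mixed
  through an eigenvalue square root of the target correlation matrix,
  and mapped through exp with log-SD 0.4. Log-envelope correlations
  therefore equal the target by construction — the quantity PEC
  estimates. Coupling effects add a delta to target pairs' entries;
  the matrix is re-projected to the nearest valid correlation matrix
  (eigenvalue clipping), so realized targets can shift slightly when a
  perturbation breaks positive semidefiniteness.
- **Carriers** are exactly band-limited unit-RMS noise, synthesized as
  complex Gaussian spectra on the in-band FFT bins (distributionally
  identical to FFT-masking white noise).
- **Background** is 1/f^α noise (α = 1 by default), unit RMS, at
  noise_scale 1.0 relative to a unit-amplitude band.
- **Between-subject variability** of log band amplitude decomposes
  into a global gain (SD 0.25, multiplying the whole recording), a
  per-region broadband gain (SD 0.20, multiplying the region), and a
  band-specific residual (SD 0.12). The shared-gain dominance mirrors
  real EEG, where inter-subject power differences are mostly
  skull/conductivity scaling — exactly what the PSD z-transform
  removes. An earlier fully-independent-per-band structure was
  rejected: it is unrealistic and floods the z-normalizer with
  cross-band nuisance. Planted band-power effects shift the target
  regions' log amplitude by d × (total between-subject SD), so the
  realized raw-scale Cohen's d on log band power equals the configured
  d.
- Baseline band amplitudes are resting-EEG-flavoured (alpha-dominant:
  1.2; delta 1.0; theta 0.8; beta 0.5; low-gamma 0.25; high-gamma
  0.15); the default inter-region envelope correlation is a uniform
  0.4. Defaults mirror a 5-min recording at 500 Hz over 113 regions.
  All generators are pure functions of (config, seed); heavy internals
  run in single precision.

What the simulator does **not** emulate: ocular/muscle/cardiac
artifacts, non-stationarity, realistic head geometry or channel
covariance, phase coupling, or cross-frequency structure. Passing
recovery tests therefore demonstrate the correctness and calibration
of the estimators under the generative model's assumptions, not
performance on real recordings.

## Validation experiments and problem sizes

The standing experiments (`oscillome.benchmarks`) use 60-s recordings
for cohort runs and 300-s signals for the volume-conduction check —
sizes chosen so a full run completes on one desktop CPU:

- *Volume-conduction suppression*: two instantaneous mixtures of one
  source; |PEC| stays ≤ 0.1 while the plain log-envelope correlation
  exceeds 0.9 (20 seeds).
- *Planted power recovery*: theta d = 1.2 in 10 of 113 regions,
  n = 30/group; the full stack (t, 1000 permutations, BH-FDR, 100×95%
  subsampling) recovers the target set with sensitivity ≥ 0.8 and
  false-discovery proportion ≤ 0.1 (10-seed average).
- *CPM coupling recovery*: high-gamma coupling delta −0.4 on 20 pairs,
  n = 25/group over 30 regions; training AUC ≥ 0.9, external-cohort
  AUC ≥ 0.75, out-of-sample label-permutation AUC 0.5 ± 0.1.

## Numerical and degenerate-input choices

Strict inequalities at every published threshold (100 µV, 15%, 50%);
epoch rejection is idempotent; zero-variance features map to t = 0,
p = 1 (tests) or 0 (z-transform) with warnings; a rank-deficient
lead-field gram at λ² = 0 raises with advice to regularize; non-PSD
envelope targets are rejected naming the smallest eigenvalue;
permutation p-values are floored at 1/(n_perm+1); constant CPM scores
yield the majority-rate threshold with a warning. FFT lengths use
`scipy.fft` fast lengths; the Morlet pad covers 8σ_t of the widest
kernel.

## Known limitations

The printed-table ANOVA/chi-square helpers reconstruct statistics from
rounded summaries and inherit that rounding. The toy lead field is not
a head model. The robustness default (a feature must survive every
replicate) is deliberately conservative and configurable. CPM provides
no uncertainty on its external metrics beyond the seed-to-seed spread
reported by the benchmark functions.
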