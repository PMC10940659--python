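# Methods

`dpfair` implements a complete privacy–utility / privacy–fairness analysis
pipeline for medical-imaging-style classification: differentially private
training of small group-normalized residual CNNs with Rényi-DP accounting and
noise calibration, the associated image preprocessing and label binarization,
utility metrics with bootstrap uncertainty, and subgroup fairness auditing via
the statistical parity difference — exercised end to end on synthetic
radiograph-like and CT-like cohorts whose statistical structure (prevalence
imbalance, subgroup size imbalance, subgroup-dependent image difficulty) is
controllable and known.

## Privacy model and accounting

One DP-SGD step Poisson-samples each of the N training records with
probability q, computes the per-record gradient, clips it to ℓ2-norm C,
sums, adds Gaussian noise with standard deviation σC per coordinate, and
divides by the *expected* batch size qN.  Privacy-wise each step is a sampled
Gaussian mechanism (SGM); its Rényi divergence at order α is bounded by the
standard integer-order expression

    ε_α = 1/(α−1) · ln Σ_{k=0}^{α} C(α,k) (1−q)^{α−k} q^k e^{k(k−1)/(2σ²)},

which is the exact binomial expansion of the Gaussian mixture moment
E_{z∼N(0,σ²)}[((1−q) + q·e^{(2z−1)/(2σ²)})^α].  The bound is evaluated in
log-space (log-sum-exp over the binomial terms) so high orders and small σ do
not overflow.  Composition over T steps multiplies each ε_α by T, and the
final (ε, δ) statement uses the classic conversion
ε = min_α [ε_α + ln(1/δ)/(α−1)]; tighter conversions exist, so the reported
ε is a valid upper bound either way.  The order grid is the integers 2..64
plus {80, 96, 128, 256}; all grid orders are integers, so the exact binomial
form suffices and non-integer orders are rejected rather than approximated.
The test suite validates the per-step bound against an independent
numerical-quadrature evaluation of the same integral (relative agreement
better than 1e-6 across q ∈ [8·10⁻⁴, 0.9]).

**Calibration.** `calibrate_sigma` inverts the accountant by bisection on σ
(ε is continuous and monotone decreasing in σ) inside a bracket found by
doubling, so that the full budget is spent exactly on the last training step;
the returned σ never overshoots the target by more than the stated tolerance.
The admissible range is σ ∈ [10⁻², 10⁴]; targets outside the reachable band
raise an explicit error.

**Conventions.** δ defaults to 1/N (the usual "inverse database size" rule).
Steps per epoch under Poisson sampling are round(N/B) by default (the
`n_over_b` rule; `one_over_q` is available, and which one a full-scale run
means by "epoch" is genuinely ambiguous).  The guarantee is per *record*;
when patients contribute several images, all of a patient's images are
protected only at the weaker group level, which the radiograph-like cohort
makes visible by drawing a geometric number of images per patient.  Privacy
amplification by shuffling and per-individual accounting are out of scope.

## Model and training

The architecture is a compact "ResNet9"-family CNN: stem convolution, three
downsampling stages, a residual block after the first and last stage, global
average pooling and a linear head with one sigmoid output per finding.  All
normalization is group normalization (32 groups, falling back to
gcd(32, channels) for thin desk-scale widths): batch normalization couples
records within a batch and is structurally incompatible with per-sample
gradients.  An optional extra pool after the stem halves the spatial grid
early for larger inputs.  The same builder emits 2D and 3D variants (3×3 vs
3×3×3 kernels); the 3D variant is a plain small 3D CNN.

Layers, batched backpropagation and the optimizer are implemented directly on
NumPy arrays.  The backward pass keeps the batch axis on every parameter
gradient, so per-record gradients are exact by construction — verified
against central finite differences (2D and 3D) and by recomputing singleton
batches (per-sample isolation).  Convolutions are evaluated as batched GEMMs
over an offset-major im2col buffer, which keeps array copies row-contiguous
and the GEMM inner dimension large; float32 is the default compute dtype,
with float64 available for bit-level trajectory comparisons.

Training choices follow the standard DP recipe: Mish activation for private
runs and ReLU for non-private runs; binary cross-entropy with
inverse-class-frequency positive weights (computed on the training split;
an unweighted variant serves the balanced CT task); the NAdam optimizer in
its plain bias-corrected Nesterov-Adam form, applied to the noisy averaged
gradient (optimizer state is post-processing and does not affect the
guarantee).  Bias and normalization parameters are clipped jointly with
weights in a single per-record norm.  With σ = 0, C → ∞ and full-batch
sampling, the DP loop reduces exactly to plain training; this limit is
asserted to 10⁻⁶ relative over five steps.  Rotation (±10°) and mediolateral
flip augmentation exist only on the non-private path; DP mode rejects
augmentation flags.

## Synthetic cohorts

The real cohorts this pipeline is designed for are not publicly available,
so the package ships generators that emulate their *statistical* structure
rather than their anatomy:

- **Radiograph-like (2D, multi-label).**  Smooth random background
  (Gaussian-filtered noise) plus one isotropic Gaussian bump per positive
  finding.  Left/right-named findings are placed in the corresponding image
  half.  A per-record latent factor couples findings through a Gaussian
  copula (`label_correlation`).  Severity uses the clinical five-level
  vocabularies; rendered bump contrast grows monotonically with severity
  (equally spaced quantile thresholds on the positive contrast range), and
  "uncertain" renders as a faint bump that binarizes to negative.  Subgroup
  difficulty multiplies pixel-noise and clutter amplitude and divides finding
  contrast; clutter bumps (device/tube stand-ins) arrive with Poisson rate
  `clutter_rate`.  Patients draw a shifted-geometric number of images
  (mean ≈ 4.3, the emulated cohort's records-per-patient ratio).
- **CT-like (3D, binary).**  Hounsfield-valued volumes (soft-tissue
  background around 30 HU) where positives carry a hyperdense ellipsoidal
  lesion at a fixed relative position (a pancreatic-bed stand-in), with the
  same subgroup difficulty semantics.

Cohort margins default to the emulated datasets' published statistics: male
share 100 659/153 502 ≈ 0.656, age-bin shares from the same table with
difficulty increasing across bins [0,30) … [80,100) (older patients'
radiographs are harder), CT case:control 867:758 with a 975/325/325
patient-wise stratified split.  The desk-scale default (`cxr_desk_spec`) is
465 patients (~2000 records) at 64×64 with four findings, one common and
three uncommon, a deliberately low-contrast "congestion" finding as the
injected hard label, and a 2:1 difficulty gap against the minority-sex
subgroup — the disparity the fairness audit is supposed to recover.

What these generators do **not** emulate: anatomy, pathology co-location,
scanner physics, label noise, or distribution shift between sites.  Passing
tests therefore demonstrate that the pipeline's statistics behave correctly
under known ground truth — recoverable prevalences, monotone
difficulty→utility effects, correct accounting — not that any clinical
performance level would be attained on real radiographs.

## Splits

Splitting is patient-wise: fractions apply to patients, and all images of a
patient land in one split.  Overall split sizes follow a floor rule
(validation and test floored, remainder to train), which reproduces the
emulated 975/325/325 split exactly for single-image patients.  Stratified
splits fix the positive class by cumulative flooring within class and derive
the negative class by difference, keeping every split's class ratio within
one patient of exact.

## Evaluation and fairness

AUROC uses the Mann–Whitney midrank form (ties count half).  Operating
thresholds maximize Youden's J (TPR − FPR) over observed scores with a
≥-threshold decision rule, ties broken toward the smallest threshold;
thresholds are chosen once per label on the full test split and reused for
subgroup statistics, avoiding subgroup-specific calibration leakage.
Uncertainty comes from a record-level bootstrap (1000 redraws by default;
patient-level resampling available behind a flag); redraws on which a metric
is undefined are skipped and counted, and more than half undefined is an
error.  Two AUROCs are compared with the Hanley–McNeil normal approximation
in its independent-groups form (Q1 = A/(2−A), Q2 = 2A²/(1+A)); the paired
form needs rank correlations outside this package's scope.

The statistical parity difference is P(correct | minority) −
P(correct | majority) at the chosen thresholds: optimally zero, negative
when the minority is discriminated against.  Multi-label correctness is
averaged over labels per record before group means, so every record weighs
equally.  Minority/majority are designated by training-split record counts
(ties break lexicographically); multi-valued attributes (age bins) are
audited pairwise, each bin against its complement.  The underdiagnosis rate
is the per-group false-negative rate, pooled over labels, reported as
undefined (NaN) for groups without positives.  Trends across a privacy grid
correlate the disparity with ln ε, mapping ε = ∞ to ten times the largest
finite grid value; flat disparities are reported as "no trend" rather than a
spurious correlation.

## The experiment grid

`run_experiment` executes every (ε, seed) cell: calibrate σ for finite ε
(ε = ∞ is the explicit non-private mode and never touches the accountant),
train, persist the per-record prediction table as CSV, compute per-subgroup
metrics with bootstrap and the fairness report, then aggregate means and
standard deviations across seeds.  A failed cell is logged and skipped
without aborting the grid.  The manifest records seeds, calibrated σ values,
accounted spends and package versions; every reported number is recomputable
from the persisted prediction tables alone.

## Desk-scale problem sizes and defaults

The shipped study conditions are desk-scale by design: ~2000 records at
64×64 resized to 32×32 in the preprocessing resize step, a (8, 16, 32, 32)-
width model (~38k parameters), batch 128, ε grid {0.5, 2, 8, ∞} at
δ = 1/N_train, three seeds.  Training hyperparameters (DP: Mish, learning
rate 8·10⁻³, 10 epochs, C = 1.5; non-private: ReLU, 5·10⁻³, 8 epochs) were
selected by validation-split AUROC, the same procedure a full-scale study
uses.  Under these conditions the privacy–utility ladder and the
subgroup/label difficulty effects are measured by `scripts/acceptance.py`;
the methods above say how each number is computed, and the script is the
place that computes them.

## Numerical choices and edge cases

- Rounding of quantized intensities is round-half-up everywhere, pinned so
  byte-level examples are reproducible.
- A constant image min-max-normalizes to all zeros (the conservative
  "no signal" choice for a zero dynamic range).
- Histogram equalization is the classical global CDF method, computed on the
  full frame per image.
- Resizing maps output pixel centers to input pixel centers (bilinear /
  trilinear), so an exact 2× downsample averages each block.
- An empty Poisson batch is a legal DP-SGD step that releases pure noise
  scaled by the expected batch size.
- σ = 0 is the noiseless diagnostic limit; such runs carry no finite
  guarantee and their spend is reported as absent rather than a number.
- Non-finite losses abort training with a diagnostic instead of silently
  polluting the trajectory.
- Group-norm group counts fall back to gcd(32, channels); a channel group of
  size one makes the following conv bias exactly redundant, which the
  equivalence tests tolerate with an absolute floor at optimizer round-off.

## Known limitations

- The accountant's conversion is the classic RDP→DP bound; reported ε is an
  upper bound, slightly loose against amplitude-optimized conversions.
- Per-record guarantees only; a patient with k images enjoys roughly group
  privacy over k records, not an individual-level ε.
- The NumPy training loop is single-process and CPU-bound; it is sized for
  desk-scale studies, not for 512×512 cohorts of 10⁵ images.
- Bootstrap and Hanley–McNeil treat records as independent, which ignores
  within-patient correlation; patient-level bootstrap is available but not
  the default, matching the per-record privacy framing.
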