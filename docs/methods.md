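# Methods notes

## The analysis model

The package treats one hemisphere's S1 strip as K ordered segments
(default K = 49), indexed 1 at the lateral end (lip territory) to K at the
medial end (foot territory), so positive position changes mean medial
shifts. All analyses consume three inputs per participant: run-wise
voxels × conditions beta matrices (each condition modeled against rest),
matching GLM residual matrices (timepoints × voxels), and a single
voxel → segment assignment. Session-level estimates are run averages;
change scores always subtract the average of the pre-intervention sessions.

Univariate topography reduces a condition's activity to its per-segment
means and their center of gravity, COG = Σ k·β_k / Σ β_k, computed on raw
segment means. Negative means are retained: thresholding before a COG
biases it toward the peak, and the estimator is already guarded against the
degenerate case (see "Numerical choices"). COG shifts subtract the mean of
the pre-session COGs — not the COG of the averaged pre profile; the two
differ for asymmetric profiles, and the alternative is available via
`AnalysisConfig.average_pre_profiles`.

Multivoxel analyses operate inside a hand ROI (by default segments 20–35 of
the strip) on spatially pre-whitened patterns: betas are multiplied by
Σ̂^(−1/2), where Σ̂ is the run-averaged residual voxel covariance shrunk
toward its diagonal. Cross-session fold structure is shared by all MVPA
routines: the C(4,2) = 6 two-run partitions of each session crossed between
sessions (36 folds). Decoding fits a linear SVM (squared hinge, C = 1,
scikit-learn defaults otherwise, fixed random_state) per training partition
on the two runs' unaveraged patterns (2 samples per class) and scores each
test partition, in both directions: 72 accuracy cells per finger pair.
Training on partition means instead is exposed as
`average_train_runs` for sensitivity analyses. The crossnobis distance is
the fold-mean inner product of partition pattern differences,
d² = (x_y − x_z)_Aᵀ(x_y − x_z)_B on whitened patterns, with no
voxel-count normalization — values are in squared whitened units and may
legitimately be negative (the estimator is unbiased under pattern
identity). Typicality correlates (Spearman) a participant's ten finger-pair
distances, averaged over all pre × post session pairs, with the
control-mean vector; a control's own distances are excluded from the
reference mean.

Single-case inference uses Crawford & Howell's t-test with the n-inflated
standard error and df = n − 1; p values are two-tailed and uncorrected by
default (Holm adjustment is provided as an option). Control distributions
are summarized by empirical 95% percentile intervals using linear
interpolation between order statistics — the convention is fixed and
documented because interval conventions differ materially at n = 16.
A Shapiro–Wilk screen is advisory only: it logs a warning and never
switches tests silently.

## The synthetic generator

Each condition activates voxels through a Gaussian tuning curve over the
segment axis: β(v, c) = baseline + a_c · exp(−(pos_v − μ_c)²/(2σ²)). The
default layout places the five contralateral fingers at segments 22–32
(2.5-segment spacing, amplitude 1.0), the other hand's fingers at the same
centers with amplitude 0.2 (weak ipsilateral activity), lips at segment 8
(amplitude 1.2) and feet at segment 44 (amplitude 1.0); σ = 2 segments.
Rest is not generated — betas are "versus rest" by construction.

Noise has three parts, all configurable in `NoiseModel`:

- **Spatially correlated voxel noise** added to each run's betas, drawn
  from Σ_true[i,j] = sd²·exp(−|i−j|/L) over the voxel ordering (default
  sd = 0.05 beta units, L = 2 voxels). Residual matrices are
  `n_residual_timepoints` (default 120) i.i.d. draws from the same Σ_true:
  whitening uses only the spatial covariance of residuals, so no temporal
  autocorrelation is generated.
- **Run and session gains**: the activation component is multiplied by
  1 + N(0, sd) per run (default 0.05) and per session (default 0.1). Gains
  rather than additive offsets were chosen deliberately: a constant offset
  over all K segments shifts a narrow profile's COG by tens of segments per
  0.1 beta units of offset (the profile's integrated mass is only a few
  units), which would make the COG meaningless as a topography statistic;
  multiplicative gain emulates scanner/arousal amplitude drift while
  leaving the topography — and hence the stability ground truth — intact.
  COG is scale-invariant, so gains affect ROI means and correlations but
  not the map position.
- **Between-participant somatotopy jitter**: each participant's tuning
  centers are perturbed by N(0, 1 segment), redrawn (≤100 attempts) until
  the somatotopic ordering invariants (fingers strictly ordered, lips
  lateral, feet medial) still hold. This creates realistic between-subject
  COG variability for the Crawford comparisons; it is constant across a
  participant's sessions, so it cancels in within-participant shifts.

Case participants optionally receive, from a chosen onset session, a
signed displacement of the lip center (positive = medial) and/or a
finger-selectivity scaling s ∈ [0, 1] that pulls each finger's activation
toward the across-finger mean (s = 0 collapses the fingers to a common hand
pattern, driving pairwise decoding to chance; s = 1 leaves them intact).

Default magnitudes were chosen so that a control participant behaves like
the population the analyses were designed for: between-session pairwise
decoding at ceiling, split-half finger correlations near 1, and control
COG-shift distributions centered on zero with sub-segment spread (10 voxels
per segment; peak single-run beta SNR = 20). They are study conditions, not
fitted quantities. The generator emulates the *structure* of real run-wise
estimates — somatotopic ordering, session/run variability, spatially
correlated noise with a known covariance, fold geometry — but not BOLD
time-series properties (no HRF, no temporal autocorrelation, no motion),
anatomical geometry, or between-voxel tuning heterogeneity. Passing tests
therefore validate the estimators and their calibration, not preprocessing
choices upstream of the beta matrices.

## Numerical choices

- **COG degeneracy**: |Σβ| ≤ 1e-9·K·max|β| raises a degenerate-profile
  error instead of returning an arbitrary ratio.
- **Covariance shrinkage**: analytic optimal intensity toward the diagonal
  target (Schäfer–Strimmer form) computed from the pooled per-run-demeaned
  residuals, clipped to [0.01, 1]; Σ̂^(−1/2) by eigendecomposition, with a
  positive-definiteness check. λ = 1 reproduces univariate normalization.
- **Winner-takes-all ties**: resolved to the condition listed first (lowest
  index) and reported in a tie log, so labelings are deterministic.
- **Decoding degeneracies**: training patterns identical across classes are
  recorded as chance (0.5) with a warning rather than fit.
- **Map thresholding**: masks keep values ≥ fraction·max (default 0.33 of
  the maximum); a non-positive maximum yields an empty mask plus a warning.
- **Percentile intervals**: numpy linear interpolation (`method="linear"`);
  coverage 1.0 returns the range.
- **Determinism**: cohorts derive per-participant generators from a spawned
  seed sequence; exports round to 6 decimals, making same-seed exports
  byte-identical. The SVM's random_state is fixed, so the full pipeline is
  deterministic given config + seed (recorded in the run manifest along
  with a config digest and library versions).

## Problem sizes in the shipped tests

Simulation-backed checks run at sizes chosen for tight Monte-Carlo error at
desk scale: 10,000 simulated cohorts for the Crawford type-I rate
(expected 5% ± 1.5%), 1,000 replicates for crossnobis null unbiasedness
(|mean| < 3·SE), 200 label permutations for the decoder's chance
calibration (50% ± 2 points), 50 cohorts each for the COG-shift recovery
(median within ±0.5 segments of an injected +3) and for null-case coverage
of the pooled-control 95% percentile interval, and 30 cohorts × 8
leave-one-out controls for the uniformity of null Crawford p values
(Kolmogorov–Smirnov p > 0.01). The residual-covariance kernel check uses
10⁵ residual draws.

## Known limitations

- The hand sub-strip (segments 20–35) is a named configuration constant; in
  real data the hand ROI is defined anatomically and should be supplied as
  an explicit voxel set.
- Session-level fixed-effects z-statistic maps are approximated throughout
  by run-averaged betas; this is a modeling substitution, adequate for the
  statistics computed here but not identical to a GLM fixed-effects
  combination.
- The generator's ipsilateral-hand representation is a scaled copy of the
  contralateral layout; analyses comparing hands within a hemisphere should
  not lean on its fine structure.
- Crossnobis values are reported in squared whitened units without voxel
  normalization, so magnitudes are comparable within, not across, ROI
  sizes.
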