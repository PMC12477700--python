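# somastab

Longitudinal somatotopic-stability analysis for run-wise fMRI pattern
estimates: does the primary somatosensory (S1) body map of a hand — and of
its cortical neighbors, the lips — stay in place when the hand is amputated?

The package is written for researchers who track individual participants
across sessions spanning an intervention (here: planned arm amputation) and
need to decide, per single case, whether any longitudinal change exceeds
what a control cohort shows over the same time frame. It operates on
per-run GLM outputs (a voxels × conditions matrix of beta estimates plus
the run's residuals) and a fixed assignment of voxels to the K ordered
segments of the S1 strip (segment 1 lateral/lips → segment K medial/feet).
A synthetic-cohort generator with known somatotopy, noise covariance and
injectable "amputation effects" provides ground truth for every stage.

## What it computes

**Segment topography and COG.** Condition activity is averaged per segment,
and summarized by its center of gravity

```
COG = Σ_k k·β_k / Σ_k β_k ,
```

computed on raw (non-thresholded) segment means β₁…β_K. Longitudinal change
is the COG shift: COG(post-session) − mean of the pre-session COGs
(positive = medial). ROI-mean activity (e.g. lip activity inside the hand
sub-strip), fractional-max map thresholding, and winner-takes-all labeling
cover the univariate analyses.

**Cross-session MVPA in the hand ROI.** Patterns are spatially pre-whitened
with Σ̂^(−1/2), where Σ̂ is a diagonal-target shrinkage estimate of the
residual voxel covariance. Each session's four runs are split into all
unordered two-run partitions; every partition of one session is crossed
with every partition of another (36 folds). On these folds the package
computes split-half Pearson correlations per finger, pairwise linear-SVM
decoding of the 10 finger pairs (both train/test directions, 72 accuracy
cells per pair; chance = 50%), and the cross-validated squared Mahalanobis
(crossnobis) distance

```
d²(x_y, x_z) = (x_y − x_z)_Aᵀ Σ⁻¹ (x_y − x_z)_B ,
```

an unbiased estimator (zero-mean, possibly negative, when two conditions
share a pattern). Typicality is the Spearman ρ between a participant's ten
finger-pair distances and the control-average vector (leave-one-out for
controls).

**Single-case statistics.** Each case statistic is compared to the control
cohort with Crawford & Howell's t-test, t = (x* − x̄)/(s·√((n+1)/n)),
df = n − 1, two-tailed uncorrected p, alongside the controls' empirical 95%
percentile interval. One-sample t-tests and Wilcoxon signed-rank tests are
included for within-participant comparisons.

## Worked example

Simulate a cohort of 8 controls and one case whose lip tuning center is
displaced 5 segments toward the hand from the first post session, then test
every case measure against the controls:

```python
import somastab as st

spec = st.CohortSpec(n_controls=8, n_cases=1, seed=21, n_voxels=245)
effects = st.CaseEffects(onset_session="Post3m", lip_shift_segments=5.0)
cohort = st.simulate_cohort(spec, case_effects=effects, include_residuals=False)
bundle = st.run_full_analysis(
    st.AnalysisConfig(analyses=("cog", "lip_activity")), cohort=cohort
)
cols = ["measure", "case_value", "t", "df", "p_uncorr", "ci_lo", "ci_hi"]
print(bundle.tables["casestats"][cols].round(4).to_string(index=False))
```

prints

```
           measure  case_value       t  df  p_uncorr   ci_lo  ci_hi
    cog_shift_hand      0.1915  0.7040   7    0.5042 -0.2886 0.2715
   cog_shift_index      0.7818  1.1865   7    0.2741 -0.9230 0.8554
    cog_shift_lips      5.8321 14.8456   7    0.0000 -0.5650 0.4481
  cog_shift_little      0.1234 -0.4150   7    0.6905 -0.2661 0.9140
  cog_shift_middle      0.4026  0.2024   7    0.8454 -0.7073 1.5315
    cog_shift_ring     -0.3834 -0.4545   7    0.6632 -1.1885 0.9716
   cog_shift_thumb     -0.1315  0.2690   7    0.7957 -0.9910 0.6159
lip_in_hand_change      0.0108  1.5660   7    0.1613 -0.0127 0.0081
```

Only the lip COG shift is flagged (case value ≈ +5.8 segments against a
control interval of roughly ±0.5; Crawford t(7) = 14.8, p < 0.001): the
injected lip displacement is recovered while the hand and finger maps are
correctly judged stable. With no injected effects all measures stay
non-significant.

The same analyses run from the shell on a cohort directory:

```bash
somastab simulate --seed 21 --out cohort/
somastab validate cohort/
somastab topography --cohort cohort/ --condition lips --out profiles.tsv
somastab mvpa --cohort cohort/ --analysis crossnobis --roi hand --out distances.tsv
```

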