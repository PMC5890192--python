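# Methods

## The reactivation model

The package treats "preplay-like" reactivation as the spontaneous
appearance, in single resting frames, of a stimulus-specific multivoxel
pattern. The synthetic generator makes this literal: a resting session is
i.i.d. Gaussian noise (sd `noise_sd`) in every voxel and frame, and for
each sentence exactly `reactivation_events_per_sentence` distinct frames
(disjoint across sentences) receive an additive term
`amplitude × pattern`, where the pattern is a smooth, zero-mean,
unit-norm voxel map. This is the simplest generative model under which
the top-N Fisher-Z statistic is a consistent readout of reactivation
strength: an embedded frame's correlation with its template grows
monotonically with amplitude, baseline frames correlate at the
1/√V noise floor, and the top-N mean therefore orders sentences by their
planted amplitude.

The statistic itself makes no temporal assumptions — it is order-free in
the frames — so nothing in the analysis depends on whether reactivation
events are truly single frames. Extended or autocorrelated events would
change the effective number of informative frames but not the logic.

## Stages and their contracts

**Representations.** Sentence templates are first-level GLM t-maps:
sessions are concatenated, each sentence gets one shared HRF-convolved
boxcar regressor (canonical double-gamma; `'none'` selects an identity
kernel for exact construction tests), each session gets its own
intercept, and the per-voxel t is the contrast estimate over its standard
error at residual degrees of freedom. The OLS fit and contrast are
delegated to nilearn's first-level machinery; tests pin it against a
literal normal-equations oracle at 1e-10. Combining sessions by
concatenation with session intercepts is a deliberate simplification of
fixed-effects contrast averaging across per-session betas; it estimates
the same direction with a simpler contract.

**Informative-voxel filter.** Per voxel, the population variance (ddof 0)
of t across sentences is computed; voxels strictly below the 3% quantile
(`drop_fraction`) are dropped. Ties at the cutoff are kept — dropping
would be arbitrary — so a degenerate all-equal-variance input removes
nothing and warns. Prior and posterior template sets are filtered
separately. The filter is a pure function of the t-map set and invariant
to sentence order.

**Intensity.** Voxel time courses are z-scored (ddof 0); constant voxels
are flagged degenerate and excluded from correlations rather than
raising (a whole-series of constants does raise). Each frame's pattern is
correlated with the template over the shared non-degenerate voxels (≥ 3
required); zero-variance frames yield missing values that are excluded
downstream. Correlations are clamped to |r| ≤ 1 − 1e-12 before
`arctanh` so noiseless constructions stay finite. The top-N mean
requires N available values — exceeding them is an error, never a silent
truncation — and averages in descending sorted order so the result is
exactly order-independent. Because `arctanh` is strictly increasing,
transforming before or after top-selection selects the same frames; the
transform-first order is kept and the equivalence is asserted as a
property test.

**N_top selection.** For each grid value N, the variance across sentences
of the top-N intensities is computed (the default grid is 10 to 80 in
steps of 5). The variance of a mean of N noise values falls as 1/N, so an
OLS fit of the variance curve on 1/N (with intercept) absorbs the noise
component; the per-point residual is read as signal and the maximizing N
is chosen. Exact ties — e.g. a pure a/N + c curve, where the residuals
are numerically zero — resolve to the smallest grid value (less
smoothing). A relative tolerance of 1e-9 on the curve scale separates
"numerically zero residual" from a real bump. The group-level aggregate
is the mean of per-subject choices snapped to the nearest grid value,
midpoints rounding up. With 15 embedded frames per sentence the selector
concentrates on N = 15 (measured in the acceptance study), which is why
the ROI default is 15; the searchlight default is 13, reflecting the
smaller cube patterns.

**Merged correlations.** Exactly the fixed-effect meta-analytic scheme
for Fisher-transformed Pearson correlations: Z_i = arctanh(r_i), weights
w_i = (n_i − 3)/Σ(n_j − 3), ζ = Σ w_i Z_i, SE_ζ = 1/√Σ(n_i − 3),
r_merged = tanh(ζ). The weight formula forces n > 3; subjects below that
floor, or with zero variance in either variable, are dropped with a
warning, never imputed. The main hypothesis test is one-sided (positive
facilitation); merged-correlation comparisons default to two-sided; every
test takes an explicit sidedness flag. Ratings are used raw — no
per-subject standardization. Bonferroni correction is `min(1, m·p)` with
`m` allowed to exceed the number of values passed (a wider family).

**Above/below split.** Each subject's sentences are split at the
subject's own *mean* intensity (not median); the two mean ratings are
compared with a paired t-test across subjects. A subject whose split has
an empty side (constant intensities) is dropped with a warning.

**Searchlight.** The ROI statistic is repeated in Chebyshev-radius-2
cubes (5×5×5) centered on every in-mask voxel; edge cubes are truncated,
not dropped, so maps keep full coverage. Z-scoring is per voxel over
time, hence identical between the global pass and any sub-mask — a cube
that coincides with an ROI mask reproduces the ROI pipeline bit for bit
(asserted in tests). Cubes with fewer than 3 usable voxels yield missing
values. The condition contrast replaces the original two-stage GLM +
threshold-free cluster enhancement with a paired design carrying the same
null: per subject and voxel, the Fisher-Z difference between the
intensity-rating correlation over associated and over non-associated
sentences, averaged across subjects; the null permutes association labels
within subject (counts preserved); family-wise error is controlled by the
permutation distribution of the maximum statistic over the mask (default
5,000 permutations, seeded). Max-statistic FWE is not equivalent to TFCE
— it is less sensitive to spatially extended weak effects — but it is
exact under the same exchangeability assumption and has no tuning
parameters.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the emulated study design: 16 subjects; 10 prior and 20
posterior sentences; per-subject association maps with a rounded-normal
count around 11 (sd 1.5, clipped to [1, 20]), prior answers drawn with
replacement (overlap allowed); resting sessions of 197 retained frames at
TR 3 s after 3 discarded lead-in frames (200 acquired); five induced
sessions per sentence set, each trial 2 rest + 6 sentence + 1 response
scans with 3 edge scans at both ends (96 scans for the prior set, 186 for
the posterior set). Day 1 rest embeds prior-sentence patterns, Day 2 pre
embeds posterior patterns, Day 2 post embeds the same posterior patterns
scaled by `day2post_gain` (default 1.5) to emulate post-experience
stabilization. Ratings on a 0–100 scale are an affine map of a latent
standard normal (center 50, sd 15, clamped); for associated posterior
sentences the latent couples to the planted Day-2-pre amplitude with
coefficient `rating_coupling_rho` (default 0.4), all other ratings are
independent noise.

Quantities the study does not pin down were set once to values a
practitioner would call realistic, and are exposed as parameters:

- `roi_shape` (8,8,8) with an inscribed-ellipsoid mask (~280 voxels), the
  order of a medial-temporal ROI at 3 mm.
- `reactivation_events_per_sentence` = 9: with 20 posterior sentences and
  disjoint single-frame events, 197 frames admit at most 9 events per
  sentence. The N_top selector study instead uses 15 events with 10
  sentences, the configuration whose event count the selector should (and
  does) recover.
- `amplitude_mean` 8, `amplitude_sd` 2.5, `noise_sd` 1: an embedded
  frame then correlates ~0.4 with its template against a ~0.06 baseline
  noise floor — strong enough that the intensity ranks sentences by
  amplitude (Spearman > 0.8), weak enough that frames are not trivially
  classifiable.
- `induced_amplitude` 15: yields t-maps correlating > 0.9 with the true
  pattern at the default session count, comfortably above the 0.7 the
  recovery tests require.

Not modeled, by design: scanner drift, motion, physiological noise,
temporal autocorrelation (an AR extension point is noted in the
reactivation model above), spatial structure of real hippocampal /
entorhinal anatomy, and inter-subject anatomical variability (all
subjects share the mask, since individual atlas construction is outside
the pipeline). Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under its own assumptions — white
noise, single-frame additive events — not that real resting BOLD
satisfies those assumptions.

## Numerical choices

- Fisher clamp at 1 − 1e-12; `arctanh`/`tanh` round-trip to 1e-12.
- Variance conventions: ddof 0 for z-scoring and the voxel filter
  (population variance over a fixed set); ddof 1 across sentences in the
  N_top variance curve (sentences as a sample). The N_top argmax is
  scale-free, so the latter choice is cosmetic.
- Degenerate data policy: flag-and-exclude at the voxel and frame level,
  drop-with-warning at the subject level, hard error only when nothing
  usable remains.
- Determinism: every random draw flows from `numpy` `SeedSequence`
  spawning; a fixed seed reproduces the on-disk cohort byte for byte
  (uncompressed NIfTI-1 keeps file bytes free of timestamps).
- Rank-deficient designs raise with the names of the collinear columns.

## Problem sizes in the test and acceptance studies

The statistical studies run at sizes chosen to give stable empirical
rates on one CPU: 2000 null cohorts (16 subjects × 11 sentences) for the
type-I rate, 500 cohorts for sign recovery at ρ = 0.4, 100 simulations
for the N_top selector, and 10³-voxel volumes with 6 subjects and 200
permutations for the searchlight studies. The searchlight detection
criterion counts significant voxels inside the radius-2 dilation of the
planted region, since a cube centered just outside a reactivating region
legitimately carries signal — searchlight maps smear by their radius.

## Known limitations

- The 1/N noise model behind N_top selection assumes i.i.d. frame
  correlations; autocorrelated rest data would bias the variance curve.
- The fixed-effect merge has no between-subject heterogeneity term
  (random-effects meta-analysis is out of scope).
- Max-statistic FWE is a conservative stand-in for cluster-sensitive
  inference.
- With strong planted coupling and clean imaging, r_merged can exceed
  the latent ρ because the intensity is a less noisy amplitude proxy than
  a real experiment would provide; the generator's value lies in planted
  *structure* (which condition carries an effect), not in reproducing any
  particular effect size.
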