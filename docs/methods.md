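# Methods

## Scope and model

`wristmetrics` implements the quantitative measurement chain used to
describe bilateral upper-extremity (UE) activity in children with
hemiplegic cerebral palsy during seated, joystick-driven training
sessions, together with the pre/post statistical battery typical of
single-group pilot studies. Three data channels feed one wide cohort
table (one row per child × phase, phases *early* and *late*):

1. **Dual-wrist accelerometry.** Tri-axial wrist acceleration (nominal
   30 Hz, ±8 g) is reduced to per-epoch activity counts per axis; the
   vector magnitude VM = √(ax² + ay² + az²) combines the axes. At 60-s
   epochs, VM counts/min are classified with the children's cut-points
   (sedentary ≤ 149, light 150–499, moderate 500–3999, vigorous ≥ 4000
   counts/min) into a four-band percent-time breakdown. At 1-s epochs,
   two asymmetry metrics compare the arms:
   * use ratio = hours of affected-arm use / hours of unaffected-arm
     use, where a 1-s epoch counts as "use" when VM exceeds a threshold
     (default 0 counts);
   * magnitude ratio = ln(VM_affected / VM_unaffected) per epoch,
     summarized by median and IQR because the per-epoch distribution is
     heavily skewed.
2. **Coded video.** Interval annotations on three tracks (navigation;
   arm use: bimanual / unimanual-affected / unimanual-unaffected;
   affected-arm assistance: independent / assisted / no-activity) plus
   point events for affected-arm movement bouts. All video metrics are
   restricted to navigation time by half-open interval intersection.
3. **Standardized testing.** QUEST sub-domain percentage scores
   (dissociated movements, grasps, weight bearing, protective
   extension) are ingested as data; item-level scoring is out of scope.

## Key conventions and why

* **Count scale.** 1 count = 0.001664 g = 0.0163072 m/s²; the
  conversion is exact and linear.
* **Cut-point boundaries.** A 60-s epoch exactly at a band maximum
  belongs to the lower band (149 counts/min is sedentary), matching the
  closed printed ranges. Classification uses VM counts/min by default;
  a vertical-axis option exists because the original children's
  cut-points were developed on a single axis.
* **Magnitude ratio zero handling.** Epochs with zero VM on both arms
  carry no asymmetry information and are dropped; epochs with exactly
  one zero arm are clamped to ±7 (the convention in the bilateral
  UE-accelerometry literature). The log base is natural.
* **Intervals.** Half-open [onset, offset); durations tile without
  double counting, and all metrics are invariant to splitting an
  interval into abutting sub-intervals. Timestamps are session-relative
  (0 = monitor-on), since monitors are worn only while the child is
  seated in the toy.
* **Inclusion rule.** A child enters affected-arm analyses (intensity
  percentages) only with ≥ 3 affected-wrist sessions in *both* phases,
  and enters bilateral analyses (use/magnitude ratio) only with ≥ 3
  both-wrist sessions in both phases. Exclusions are logged with
  reasons, never silent.
* **Phase aggregation.** Per-child phase values are unweighted means of
  session values; per-session magnitude-ratio medians are collapsed by
  the median to stay on the robust scale.
* **Bout-rate denominator.** Bouts are defined during navigation, so
  rates use navigation minutes (not full session time).

## Raw→counts surrogate

The vendor raw-to-counts algorithm is closed-source. `raw_to_counts`
implements an open surrogate: Butterworth band-pass 0.25–2.5 Hz (order
3), rectification, a 0.05-g dead-band, quantization in 0.001664-g
steps, and per-epoch integration of the quantized rectified amplitudes
(sum divided by the sampling rate, so counts do not depend on the
sampling rate for a fixed signal). The chain is linear-then-monotone,
so doubling the input amplitude never decreases any epoch's counts, and
a 10-Hz oscillation (outside the pass-band) yields ≈ 0 counts. The
counts-level ingestion path is primary: nothing downstream depends on
the surrogate, and exported counts are accepted directly.

## Statistical battery

* **Normality screen:** a variable is routed to non-parametric analysis
  iff bias-adjusted skewness leaves (−2, 2), bias-adjusted excess
  kurtosis leaves (−4, 4), or Shapiro–Wilk rejects at α = 0.05. When
  the screen fails, the Wilcoxon signed-rank result is primary and the
  parametric result is reported alongside.
* **Paired t** on d = early − late, two-tailed, df = n − 1.
* **Wilcoxon signed-rank:** zero differences dropped, mid-ranks for
  ties; exact two-sided p by generating-function enumeration over
  doubled ranks for n ≤ 25, normal approximation with tie and
  continuity corrections above.
* **Two-way fully-within RM-ANOVA** (band × phase; assistance category
  × phase): sums of squares from the standard within-subject
  decomposition, Mauchly's test per effect on orthonormal contrast
  scores, Greenhouse–Geisser ε applied to the df when Mauchly rejects
  at α, partial η² = SS_effect/(SS_effect + SS_error).
* **Within-subject MANOVA** (QUEST sub-domain × time): difference
  scores per sub-domain; the time effect is the univariate F(1, n−1) on
  per-subject mean differences; the interaction is a one-sample
  Pillai's-trace (equivalently Hotelling T²) test on k−1 orthonormal
  contrasts with exact F(k−1, n−k+1). With a single response the time
  F equals the squared paired t.
* **Effect sizes:** planned comparisons report Cohen's d with Hedges'
  correction J = 1 − 3/(4·df − 1) computed on the difference-score SD
  (the d_z convention; the variant using the pooled score SD is larger
  by roughly √2 for typical correlations — reported values are
  convention-specific, not comparable across variants). 95% CIs invert
  the noncentral-t distribution of the paired t. Omnibus effects report
  partial η².
* **Flags:** "*" at p ≤ 0.05, "†" at p < 0.1 (trend).

Numerical details: quantiles by linear interpolation; excess-kurtosis
convention; two-tailed tests throughout; a zero-variance difference
vector with all-zero differences returns t = 0, p = 1 (no change), and
otherwise raises. The Mauchly chi-square uses the standard
Box/Bartlett correction factor; ε is the eigenvalue form
(Σλ)²/(p·Σλ²) of the contrast covariance.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not limb biomechanics. Per session, each 60-s block draws an intensity
state from a phase-specific mixture; unaffected counts/min are uniform
within the state's band (vigorous capped at 8000); 1-s counts receive
multiplicative truncated-normal noise (CV default 0.25). The affected
arm is the unaffected stream scaled by the asymmetry scale *s*
(optionally independently re-noised), and epochs on one arm are zeroed
to hit the configured active-time ratio. Per-session log-scale jitter
(SD 0.05 on *s*, 0.02 on the active ratio) gives outcomes realistic
between-session variability. Counts are continuous; vendor integer
quantization is not emulated. Raw-mode output realizes the same counts
profile as a 0.5–2-Hz oscillation whose per-second amplitude scales
with target counts (0.01 g per count/s), inside the surrogate filter's
pass-band.

Annotation streams tile a configurable navigation fraction (default
50%, in 120-s cycles) with exponential-length (mean 10 s) arm-use and
assistance intervals whose codes are i.i.d. with the configured
probabilities — so the expected duration share of each code equals its
probability — and overlay a Poisson bout process restricted to
navigation.

Defaults are the study conditions the package targets: 11 children, 5
sessions per phase, 25-min sessions; an intensity mixture dominated by
moderate activity (≈ 79%) shifting ≈ 6 points further toward moderate
from early to late; s = 0.8 (ln s ≈ −0.22, between the early and late
magnitude-ratio medians a cohort like this shows); active-time ratio 1;
bimanual share of navigation 0.50 → 0.65; independence mix
(0.70, 0.11, 0.19); 39.6 bouts/navigation-minute. QUEST scores are
normal around (60.9, 63.3, 72.0, 71.7) with SD 12 and mean gains
(4.3, 6.7, 6.6, 12.9) with SD 5.5, clipped to [0, 100]. Three children
are emitted with only 2 early sessions and one more without
unaffected-wrist files, reproducing an 8-affected/7-bilateral analysis
set out of 11.

Every stream of randomness is a named substream of the master seed
keyed by (child, phase, session, stream name), so any subset of the
cohort regenerates identically and file trees are byte-reproducible.

**What passing tests show — and don't.** Ground-truth recovery
(median magnitude ratio ≈ ln s to |bias| < 0.05; mean use ratio ≈
active-time ratio to 0.05; type-I rate of the planned-comparison path ≈
0.05 under a null generator) demonstrates that the measurement chain
and tests are internally consistent and calibrated under the generator's
assumptions. The generator omits posture/gravity components, non-wear
artifacts, autocorrelated movement dynamics, and coding disagreement
between raters, so these results do not by themselves validate the
metrics against real pediatric recordings.

## Problem sizes used in checks

Monte-Carlo checks run at sizes chosen to keep sampling error well
inside the asserted tolerances: 50 replicate sessions per asymmetry
value for recovery, 50 null cohorts (8 children × 3 sessions × 2
phases, 20-min sessions) for type-I calibration, and 100–200 sessions
for annotation-share convergence.

## Known limitations

* The raw→counts surrogate is an open reconstruction, not the vendor
  algorithm; absolute counts from raw mode are not comparable to vendor
  exports (orderings and zero/monotonicity properties are).
* Paired effect sizes use the d_z convention; published values computed
  under other variants will differ systematically.
* The example group-summary table bundled with the package carries its
  intensity labels in reverse order relative to its per-child source
  table (and one of its cells, 4.53, recomputes to 4.5237 from the
  per-child rows); `reconcile_tables` surfaces the mapping explicitly
  rather than guessing silently. Its early magnitude-ratio median/IQR
  line (0.29 with IQR −0.34 to −0.17) is internally inconsistent as
  printed and is not used as a check value.
* No multiple-testing correction is applied beyond the significance
  flags; with ~11 planned comparisons the family-wise error rate is
  substantially above 5%.
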