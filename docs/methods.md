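# Methods

This note documents the models, estimators and numerical choices behind
anemowhisk, and what the synthetic-data generator does and does not
emulate.

## Displacement statistic and whisker comparisons

Tip displacement is the Euclidean distance of each tracked frame from
the coordinate-wise median position, `d_t = sqrt((X − x_t)² + (Y − y_t)²)`.
The median (even-length series: midpoint of the two central order
statistics, per coordinate) is the natural resting reference on an
anesthetized, static head; the statistic is translation-invariant and
scales linearly with the coordinates, so a pixel→cm calibration is a
single multiplicative constant (default 1.0, i.e. unit passthrough).
Tracking-likelihood filtering is off by default; when a threshold is
given, sub-threshold frames are excluded from the median and reported as
NaN displacement.

Cross-whisker comparison pools per-frame displacement values per whisker
into a tie-corrected Kruskal–Wallis test (scipy), matching the very
large df such pooling produces; per-animal aggregation is available by
summarizing first.  Post hoc options are Tukey's HSD on the raw values
(statsmodels) or a hand-implemented Dunn test on pooled mean ranks with
tie-corrected variance and Bonferroni adjustment.

The high/low displacement ratio uses per-whisker summary centers
(means); the signed-rank test of ratios against 1 drops zero
differences (Wilcoxon convention).

## Bending angle and wind-trace rise time

Bending angle: the point at 75% (configurable) of total arc length is
located by linear interpolation along the polyline; the angle between
the base-to-point radii of the rest and deflected shapes is returned in
degrees ([0, 180]).  Both shapes must share the base point within a
small tolerance; the measure is symmetric in its arguments and invariant
under a rigid motion applied to both shapes.

Rise time: steady state is the mean over a configurable tail window
(default: the trace's final half); the crossing of
`fraction × steady-state` is refined by linear interpolation between
the bracketing samples, so results are exact to within one sample
period.  An instantaneous step therefore reports the crossing inside
the rising sample interval, within one period of the step time.  A
threshold never reached is reported as None rather than a sentinel
number.

## Arrangement shuffle test

The spatial statistic for an arrangement is the unweighted mean of
per-group sample variances (ddof = 1); singleton groups are skipped
because their sample variance is undefined.  The null permutes the
assignment of values to the valued pad positions uniformly at random.
Monte-Carlo p-values use the add-one convention
`p = (1 + #{null ≤ observed}) / (1 + n_shuffles)` so p is never 0; the
exact mode (≤ 9 valued positions) enumerates all assignments and reports
the raw proportion.  Ties between schemes' observed statistics resolve
to the declared scheme order.  The six shipped arrangements are grid
rules over a declared (row, column) pad layout (`resources/
pad_layout.yaml`): columns (arcs), rows, Chebyshev rings around A1 and
around E4 (semicircles and opposite semicircle), and the two diagonal
band families (45° from the A1 corner, 135° from the A4 corner).  Values
are shuffled among valued positions only.

The ring-wulst aperture is operationalized as the largest angular gap
between consecutive ring points seen from the hair-shaft center — a
dense closed ring gives a near-zero aperture, a C-shaped arc a large
one.  This is one defensible formalization of a manual protractor-style
measurement and is isolated behind a single function.

## Cortical response analysis

Counts use half-open 1-s bins spanning −4…+4 s around onset; a spike at
exactly the onset belongs to the first post-stimulus bin.  z-scores are
computed on trial-averaged bin counts against the mean and SD (ddof = 1)
of the four baseline bins; a zero baseline SD flags the unit degenerate
instead of producing infinite z, and degenerate units are excluded
downstream.

Response classification fits a Poisson GLM (log link) of per-epoch
per-bin counts on a five-level period factor (baseline reference,
seconds 1–4) and Wald-tests each post-second coefficient at α = 0.05
(configurable, no multiplicity correction across bins).  A completely
silent post bin with an active baseline makes the Wald statistic
degenerate (the coefficient diverges), so that coefficient is tested by
likelihood ratio instead; this classifies full suppression correctly as
inhibition.  Units whose fit fails to converge are excluded from
population percentages.

Latency is the post-onset bin (1–4) holding the z-score maximum,
provided the maximum strictly exceeds 2 SD; ties break to the earliest
bin.

Mutual information treats the stimulus as binary per condition (wind of
that speed vs no wind) and the response as the integer spike count per
1-s bin capped at 10 (tail pooled) to limit plug-in bias; the paper-form
double sum `Σ_r Σ_s P(r) P(s|r) log₂[P(s|r)/P(s)]` is evaluated on the
empirical joint table.  The "no wind" sample pools the unit's four
baseline bins.  Because baseline seconds contain only one true stimulus
class, their "information" is defined as the same estimator applied to
each baseline second against the pooled remaining baseline bins — a
deterministic leave-one-second-out split that measures the estimator's
bias floor without extra randomness.  Normalized information is the
per-second MI divided by the mean of these four floor values; the
population test compares normalized values to 1 with a two-tailed
signed-rank test at a Bonferroni-corrected α = 0.003.

## Behavior

The direction-bias test is a one-df χ² goodness of fit of toward vs
away counts against equal expectation, excluding no-reaction trials (a
three-category variant is available); no continuity correction.
Fisher's exact test uses the standard two-sided convention (sum of table
probabilities not exceeding the observed table's).  Group and paired
contrasts always use the animal as sampling unit (fraction of toward
turns across its trials).

Small-sample rank tests (signed-rank, rank-sum) compute exact,
tie-aware null distributions by dynamic programming over doubled
midranks for n ≤ 25, with two-sided p as twice the smaller tail capped
at 1, and fall back to tie-corrected normal approximations above that.

## Synthetic-data generator

The generator encodes the study conditions the analyses assume; all
randomness flows from one integer seed through a single numpy Generator.

* **Trajectories**: isotropic Gaussian jitter of each tip around a fixed
  base point at 100 fps; amplitude per whisker and wind speed (0.5 vs
  1.5 m/s), with the long supra-orbital (lSO) whisker strictly maximal
  at low wind, followed by the straddlers and A1, and 3× low-wind
  amplitude at high wind for the wind-sensitive subset (1.3× otherwise).
  It does not model active whisking, tracking noise or resonance.
* **Morphometry**: whisker-type mean (length, diameter) pairs from a
  bivariate Gaussian carrying 90% of the variance, type-level
  correlation inflated so pooled samples hit the configured r (default
  0.83); within-type noise independent; values clipped positive.  The
  lSO type is then moved to the maximum-ratio type and boosted 2× in
  ratio at constant length×diameter product — deliberately an outlier,
  as the real lSO is.  Apertures are linear in the negated standardized
  type ratio plus noise, calibrated to the configured anticorrelation
  (default −0.66).
* **Spike trains**: exact piecewise-constant inhomogeneous Poisson
  sampling on a 1-s grid (per-second Poisson counts, uniform placement).
  Excited units multiply the 5 Hz baseline by a per-second gain profile
  (default 2.5, 3.0, 1.5, 1.2 over post-onset seconds 1–4) during wind
  epochs, inhibited units divide by it, null units stay constant; low
  wind scales the gain excess by 0.6.  The epoch schedule is a balanced
  randomized sequence of low/high/no-wind 10-s blocks (default 20 per
  condition) with a 10-s gap and 6-s start offset so the 4-s pre-window
  always fits and onsets land on integer seconds, aligning the gain
  grid with the analysis bins.
* **Behavior**: multinomial toward/away/none draws per trial with
  (stimulus, treatment)-specific probabilities; defaults reflect the
  turning statistics the pipeline is designed to detect (hand-flap
  0.31/0.07/0.62; stronger cardboard bias; trimming 0.20 vs 0.29 toward;
  lidocaine 0.18 vs Ringer 0.23), 13–20 trials per session, balanced
  shuffled stimulus sides, and paired two-session designs per animal.
* **Wind trace**: first-order exponential rise toward the mean speed
  plus white noise.  The default time constant τ = 1.5/ln 5 places the
  80%-of-mean crossing at exactly 1.5 s noise-free; a single first-order
  system then crosses 95% near 2.8 s — a two-time-constant rise could
  match both published-style crossings but is not needed by any
  analysis here.

Passing tests on these data show that the estimators recover known
parameters under idealized Gaussian/Poisson/multinomial structure; they
do not establish robustness to tracking dropouts, spike-sorting errors,
rate drift, or scorer disagreement, none of which the generator
emulates.

## Problem sizes and runtime choices

The test and acceptance runs use deliberately desk-scale sizes: 6,000
frames per trajectory (1 min at 100 fps), 16–24 units per region,
12–30 epochs per speed, 500 simulated units for GLM calibration, 200
datasets × 1,000 shuffles for permutation-test calibration, and 20–50
seeds for recovery rates.  These sizes give the Monte-Carlo bands used
in the assertions (binomial 99% intervals) while keeping a full run in
the minutes range on one CPU.

## Known limitations

* The plug-in MI estimator is biased upward at small epoch counts; the
  count cap and baseline-floor normalization mitigate but do not remove
  this (no Panzeri-style corrections).
* GLM classification treats epochs as exchangeable; slow drifts within
  a session are not modeled.
* The aperture measure depends only on point angles, not on radial
  distance, and assumes ring points are sampled densely enough that the
  largest gap is the anatomical opening.
* With strongly saturating responses the per-second MI profile can
  plateau near the stimulus entropy, making the "peak second" unstable
  between seconds 1 and 2 — a property of near-perfect discriminability,
  not an estimator defect.
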