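# Methods

## Problem and pipeline

`swayrisk` classifies fall risk in community-dwelling older adults from
static posturography: trunk-displacement trajectories recorded by a
lumbar tracker while the participant stands quietly for 30 s under four
stance conditions of increasing difficulty — feet apart / feet together
("W" / "N") crossed with eyes open / closed ("EO" / "EC").  Two binary
risk labels are supported: a self-reported fall in the previous year
(fall history), and a Timed-Up-and-Go (TUG) time of 10 s or more
(slow TUG).  The pipeline is

1. zero-phase low-pass filtering of each trial,
2. extraction of 31 stabilogram parameters per trial, averaged over the
   two trials of each condition (124 posturographic features),
3. min-max normalization fitted on the training split,
4. wrapper feature selection by a binary metaheuristic (SMA, HHO, or
   ABC) or a univariate filter baseline (mutual information, ANOVA
   F-value),
5. imbalance-aware classification (Easy Ensemble, Balanced Bagging,
   Complement Naive Bayes; SVM / decision tree / MLP as comparators),
6. Shapley-value explanation of the fitted model.

Because no real cohort ships with the package, a seeded synthetic
cohort generator provides data with the statistical structure the
analysis assumes; it is first-class, tested code.

## Synthetic cohort model

A standard-normal latent *balance deficit* per participant drives
everything:

* **Sway.**  Each trial's axes are white Gaussian noise shaped by a
  2nd-order Butterworth low-pass at 1.5 Hz (power concentrated where
  quiet-stance sway lives), demeaned, and scaled to a target RMS

      RMS_axis = base_axis * condition_gain * exp(balance_effect * deficit)

  with base RMS 2.5 mm (M-L) and 3.5 mm (A-P), condition gains
  1.0 / 1.3 / 1.6 / 2.1 along W-EO < W-EC < N-EO < N-EC, and
  `balance_effect = 0.35` (log-ratio of sway amplitude per unit
  deficit).  The exponential form is used instead of the linear
  `1 + effect*deficit` so the multiplier is strictly positive for any
  deficit draw; the two agree to first order.  The M-L and A-P
  innovations are correlated (default 0.3).  Amplitudes are calibrated
  to ordering and effect-size ratios only, not to absolute values of
  any instrument.
* **TUG.**  `tug = 10 + 2.2 * (s - z)` where `s` is a unit-variance
  blend of deficit (weight 0.85) and noise, and `z` the normal quantile
  that makes P(TUG >= 10 s) equal the configured prevalence
  (default 0.307).
* **Fall history.**  With probability `label_noise_fall = 0.35` the
  label is an independent coin at the faller prevalence (default
  0.228); otherwise it thresholds a noisy copy of the deficit, with the
  threshold chosen so both branches share the same marginal rate.  The
  fall label is therefore deliberately noisier than the TUG label,
  reflecting that falls are multifactorial while TUG tracks balance —
  which is why the classifiers separate slow-TUG better than fall
  history on this data, the qualitative structure the pipeline is
  meant to exhibit.
* **Personal metrics.**  Age ~ N(72, 7) (weakly deficit-linked), ~1/3
  male, height ~ N(157, 8.7) cm, weight ~ N(61, 12.5) kg, BMI derived.

What the generator does **not** emulate: instrument noise and dropout,
non-Gaussian heavy-tailed sway, postural drift and fatigue across
trials, and any physiological control model.  Tests passing on this
cohort show the machinery is correct and that the pipeline recovers the
planted structure; they do not certify classification performance on
real cohorts.

The sampling rate defaults to 90 Hz (typical tracker hardware) and the
duration to 30 s; both are configurable.  Displacements are in
millimeters throughout.

## Filtering

A 4th-order Butterworth low-pass at 5 Hz, applied forward and backward
(`filtfilt`), so the net phase shift is zero and the effective
magnitude response is the squared single-pass response — a 15 Hz tone
is attenuated to ~1.5e-4 of its amplitude, which the tests check
against the evaluated transfer function.  Edge transients are
suppressed by odd-reflection padding of 3x the filter order.  Trials
are demeaned after filtering, since all positional measures are defined
about the mean point.

## The 31 stabilogram parameters

Distance measures (mean, max, RMS, range, mean velocity) are computed
per axis and for the resultant radius; `range` for the radius is the
maximal radial distance and its mean velocity is planar path length per
second.  The 95% confidence ellipse area is
`2*pi*F*sqrt(s_ap^2 s_ml^2 - s_apml^2)` with F fixed at 3.00 (the
large-sample F(0.05; 2, n-2)); a singular covariance yields 0.  Sway
area per second sums the triangle areas swept about the mean.  Mean
frequency is `MVELO / (2*pi*MDIST)` in all three directions — the
rotation rate of a circular path with the observed mean distance and
speed; on a pure sinusoid of frequency f the axis value converges to f.
The fractal dimension is `ln N / ln(N d / L)` with L the planar path
length and d the planar diameter, by default the maximal distance from
the mean point (consistent with the radius-based grouping of the other
measures), configurable to the farthest-pair convention (computed via
the convex hull).

Spectral measures use Welch PSDs (Hann windows of ~5 s, 50% overlap,
linear detrend) with moments integrated over 0.15–5 Hz, matching the
analysis filter.  Total power is the band-integrated PSD; f50/f95 are
the smallest frequencies accumulating 50%/95% of band power; centroid
frequency is `sqrt(mu2/mu0)` and frequency dispersion
`sqrt(1 - mu1^2/(mu0 mu2))`.

Degenerate inputs (zero motion) yield 0 for magnitude measures and NaN
for frequency ratios; rows with NaN are caught by table validation
rather than propagated silently.

Every formula is checked in the tests against closed forms on
sinusoidal/circular paths and against an independent brute-force
re-implementation at 1e-9 relative tolerance.

## Wrapper feature selection

A candidate mask is scored by

    fitness = w1*GM + w2*AUC + w3*lambda,    lambda = 1 - |selected|/|all|

with GM and AUC the mean 3-fold stratified cross-validation scores of a
Complement NB restricted to the masked columns; personal metrics bypass
selection and are always appended at scoring and classification time.
The weights default to (0.4, 0.4, 0.2): the classification terms
dominate and sparsity acts as a mild regularizer.  The inner CNB is
evaluated through a vectorized sufficient-statistics path (per-fold
per-class column sums) that reproduces sklearn's estimator exactly and
is memoized by mask, making both the population search and brute-force
enumeration over small spaces cheap.

The three metaheuristics (Slime Mould Algorithm, Harris Hawks
Optimization, Artificial Bee Colony) run on continuous positions in
[0,1]^d, binarized per evaluation by an S-shaped transfer: bit = 1 with
probability `sigmoid(slope * (position - 0.5))`.  Two binary-adaptation
choices matter and are deliberate:

* **Transfer slope = 6.**  The slope sets how deterministic the
  binarization is.  A saturated coordinate still flips with p ~ 5%,
  which sustains exploration after the populations' exploitation phases
  contract onto the incumbent; steeper transfers make masks effectively
  deterministic and cause premature convergence (observable as failures
  to reach the brute-force optimum on 8-feature problems).
* **SMA wander recentring.**  SMA's third branch contracts positions
  toward the origin, which is the domain centre in the algorithm's
  symmetric formulation but a systematic deselection bias in the [0,1]
  box; the contraction is recentred at the box midpoint.

Empty masks are repaired by switching on the strongest position before
scoring.  Each optimizer records a non-decreasing best-so-far fitness
history and the evaluation count.  ABC is implemented in its standard
bee-inspired form (employed/onlooker neighbor search with greedy
acceptance, scout reinitialization after 20 stale rounds).

A property worth knowing when interpreting selections: Complement NB
responds to *relative feature proportions*, so a mask containing only
features that all shift in the same direction with the label is nearly
invisible to it; well-scoring masks mix signal columns with contrast
columns.  The recovery experiments therefore check that the planted
features are *contained in* the best mask, not that the mask is minimal.

## Splits, normalization, classifiers

Tables are split 50/20/30 (train/validation/test), stratified on the
active label with largest-remainder rounding per class (remainder ties
favour the later split).  Min-max normalization to [0,1] is fitted on
the training split only; out-of-range values elsewhere are clipped and
constant columns map to 0.  Test-split metrics are reported; the
validation split is reserved for tuning.

Easy Ensemble trains 9 AdaBoost learners (10 boosting rounds over
Complement NB, additive smoothing 1.0) on independent balanced
undersamples of the majority class; if boosting cannot fit on a
resample (base learner worse than random there), that member falls back
to the plain base classifier.  Balanced Bagging trains 9 Complement NB
learners on balanced bootstrap resamples with feature subsets drawn
with replacement.  Hard labels use a 0.5 threshold on the averaged
class-1 probability; AUC comes from the ROC of the continuous scores.
Comparator hyperparameters (RBF SVM with C = 1, default-depth tree,
one-hidden-layer MLP of 100 units) are common defaults, fixed and
logged — they serve only as contrast.

## Shapley explanations

The value function is the interventional expectation: v(S) is the mean
model score over background rows with the coalition's features set to
the explained instance's values.  `exact_shapley` enumerates all 2^m
coalitions (refused above m = 12) and anchors the axiom tests
(efficiency, symmetry, null player).  `shap_values` uses permutation
sampling with background-row cycling: each sampled permutation
contributes a telescoping walk from a background row to the instance,
so when every background row anchors equally many walks, per-instance
local accuracy (base value + sum of attributions = model score) holds
exactly, not just in expectation.  The explained model defaults to the
best (selection, classifier) pair by test AUC per criterion; the
background is the training split, subsampled to at most 100 rows.
Summary ranking is by descending mean |attribution| with name
tie-breaks — the ordering a beeswarm plot displays.

## Problem sizes

The test suite and the acceptance script run reduced problem sizes,
chosen as the smallest scales at which the properties are stable:
optimizer-correctness uses an 8-feature space (exhaustively enumerable,
255 masks) with population 30 and 50 epochs over 10 seeds; recovery
uses 5 planted features among 119 noise columns at n = 300 with
population 30 and 30 epochs; the end-to-end cohort run uses 215
participants.  Production defaults remain population 100 and 100
epochs.

## Known limitations

* The synthetic cohort is a structural stand-in; absolute metric values
  on it say nothing about any real population.
* Metaheuristic implementations are the core update rules, not the
  published variants with every operator nuance; they are validated by
  the brute-force-optimum property rather than by matching reference
  trajectories.
* Sampling Shapley cost grows linearly in permutations x features;
  full-table explanations use few permutations by default and are
  correspondingly noisy (local accuracy still holds exactly).
* Walking-aid use is recorded by the generator but excluded from the
  feature set by default.
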