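# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices where the design was
genuinely open.

## Trial model and exclusions

A trial table is long-format CSV with one row per trial (see
`simondelta.trials` for the column contract).  Times are milliseconds
throughout; no unit autodetection is attempted.  Booleans are serialized
as 0/1 and a missing movement time as an empty cell, so the CSV round
trip is lossless.  Practice trials are assumed pre-removed from recorded
files.

Exclusion applies four absolute criteria in a fixed precedence —
kinematic error (KE), movement error (ME), RT outside (100, 2000) ms,
movement time above 1200 ms for transport movements — so every excluded
trial is counted in exactly one category and category percentages sum to
the total.  Two conventions are worth making explicit:

* The RT bounds are read as *exclusive* ("faster than 100 ms", "slower
  than 2000 ms"): boundary values are retained.
* The KE → ME → RT → MT precedence follows the order in which the
  categories are conventionally reported with disjoint percentages; which
  of RT and MT is checked first for a trial failing both is a convention,
  not an empirical claim.

Percentages are computed against all analyzed trials pooled over
subjects.  No SD-based outlier trimming is performed — only the absolute
cutoffs.

## Quantile binning and delta-plots

Within one subject × condition cell, trials are sorted stably by
`(rt_ms, trial_index)` — trial order breaks ties, making the partition
deterministic — and the trial at sorted position *i* of *n* goes to bin
`floor(i·n_bins/n) + 1`.  Bin counts therefore differ by at most one.

Delta-plots are built **per subject**, separately within each congruence
level of each cell: `delta(b)` is the exact difference of the subject's
incongruent and congruent bin means, plotted at the midpoint of the two
means (the x-coordinate definition is a convention; the midpoint is the
standard choice).  Group curves are the across-subject mean with standard
error (Vincentizing).  Per-subject binning is required for the
repeated-measures ANOVA on final-segment slopes to have subject-level
observations; a pooled-binning mode (`scope="pooled"`) is provided for
comparison with pooled constructions but produces group curves only.

Segment slopes are `(delta(j) − delta(i)) / (x(j) − x(i))`,
dimensionless (ms/ms), reported both as the mean of per-subject slopes
(primary — the only form that supports F tests) and as the slope of the
group-mean points (secondary).  Subjects with fewer trials than bins in
either congruence level, or with a degenerate `x(i) == x(j)`, are
dropped from that cell with a logged warning, never imputed.

## Conditional accuracy functions

The CAF pools **all incongruent trials including KE** — KE trials keep
their RT and are the error events of interest.  Movement errors are *not*
counted as CAF errors and ME-flagged trials are removed from the pool:
the CAF contrasts correct initiation against wrong-hand initiation, and
a transport inaccuracy is a different failure mode.  RT-range outliers
are removed as in the main exclusions.  Accuracy per bin is
`correct / (correct + KE)`, computed per subject and then averaged.  The
inferential comparison uses the two fastest bins (Q1 vs. Q2), where the
fast-error signature lives, with Bonferroni adjustment over the bin
family.

## Inference

All ANOVAs are computed on subject × cell means of a fully crossed
within-subject design (one observation per subject per cell), giving
`df2 = (n−1)·df1`.  Sums of squares use the balanced-design
decomposition: for each effect, the cell-mean array is averaged over the
uninvolved factors, mean-centered along each involved factor, and split
into its across-subject mean (effect SS) and per-subject residual (the
effect × subject error SS).  This was implemented directly rather than
delegated to a library routine because degenerate inputs (zero error
variance, as in noiseless constructed fixtures) must be *flagged*, not
returned as numerically meaningless F values; the implementation is
cross-checked against `statsmodels` `AnovaRM` on non-degenerate designs
in the test suite.  Conventions:

* zero effect SS → `F = 0, p = 1` (regardless of the error term);
* zero error SS with nonzero effect SS → `F = inf`, `degenerate=True`;
* `η²ₚ = SS_effect / (SS_effect + SS_error)`, identical to
  `F·df1/(F·df1+df2)` whenever F is finite.  The closed form is always
  emitted; published tables occasionally print effect sizes inconsistent
  with their own F and dfs (e.g. F(1,15)=5.074 printed with 0.230 where
  the closed form gives 0.253), and no attempt is made to reproduce such
  cells.
* With all factors at two levels sphericity holds trivially; no
  correction is applied, and none is implemented.

Planned contrasts are paired comparisons of weighted cell means (weights
summing to zero) tested with a per-contrast one-sample t on the subject
scores — no pooled error term, no adjustment (Bonferroni is reserved for
the CAF bin family).  KE rates are square-root transformed at the
subject-proportion level (domain [0, 1]) before ANOVA; reporting
converts back to percentages.

## The synthetic generator

The generator emulates the *statistical structure* the
activation–suppression account predicts, not the underlying process (no
conflict-diffusion machinery):

* **Base RT** per cell is ex-Gaussian `N(μ, σ) + Exp(τ)` (defaults
  μ = 350, σ = 40, τ = 80 ms with per-movement offsets; published group
  means constrain only the mean μ+τ, so the shape parameters are
  field-typical conventions, not estimates).  One between-subject jitter
  triple per subject (SDs 25/8/15 ms) is shared across cells, creating a
  subject main effect.
* **Interference** adds `A·exp(−s·max(0, t−t0))` ms to incongruent RTs.
  `s > 0` gives decaying interference (negative-going delta-plot slope),
  `s < 0` growing, `s = 0` flat.  Exponential decay in base RT is the
  simplest mechanism producing the canonical delta-plot shapes.
* **Fast errors**: incongruent KE probability is
  `min(1, p0·exp(−k·max(0, t−t0)))`, non-increasing in base RT;
  congruent trials use a small constant rate (0.02).  KE trials keep a
  valid RT, equal to the base RT minus a 60 ms fast-error advantage and
  *without* the interference cost — an impulsive direct-route response —
  so fast errors populate the early CAF bins.
* **Movement time** for transport movements is lognormal
  (median 300 ms, σ = 0.25) and movement errors are independent
  Bernoulli events (rate 0.01), both independent of congruence: the
  congruence effect acts at response selection, not transport.
* Congruence and movement type are exactly balanced (shuffled) within a
  block; stimulus side is equiprobable and the assigned hand follows
  from congruence.  A single seeded stream with subject parameters drawn
  first makes the output bit-reproducible.

Four presets encode the qualitative regimes of the study family at desk
scale (16 subjects; 144 trials per single-movement block, 288 per mixed
block): `exp1_like` (blocked movements, both with decaying interference
and equal error rates), `exp2_like` (mixed block; one movement with
elevated fast errors and decaying interference, the other with growing
interference), `exp3_like` (their union), `exp4_like` (two movements
with *identical* parameters in every cell).  In `exp2_like` the
suppressed movement's amplitude/decay pair (A = 60 ms, s = 0.004,
t0 = 350 ms) was chosen so that the final-segment slope sign is the
robust signature; a pairing matched instead to the small published mean
effect (~2 ms) makes the true Q3–Q4 slope of order −0.01,
indistinguishable from zero at realistic trial counts, so the preset
prioritizes the sign dissociation over the mean-effect magnitude.

### What the generator does and does not emulate

It reproduces: positively skewed RTs with subject heterogeneity,
decaying/growing congruence effects across the RT distribution,
fast-error-dominated first CAF bins, balanced factorial structure, and
realistic exclusion rates.  It does **not** model sequential effects
(post-error slowing, congruence-sequence modulation), RT–MT coupling,
learning/fatigue drifts, or response-conflict dynamics.  Tests passing
on synthetic data therefore validate the *pipeline arithmetic and its
statistical behavior*, not any empirical claim about human data.

## Monte-Carlo checks and problem sizes

Stochastic properties are checked at sizes chosen to separate signal
from Monte-Carlo error: the null-interference Simon effect uses 10,000
trials (expected |effect| below ~3 ms given the ex-Gaussian SD of ~89 ms);
regime sign checks scale the presets by 7–8× (≈32–37k trials); the
suppression-rate monotonicity check uses 16 subjects × 2,000 trials per
rate.  For the monotonicity check the base configuration (μ = 350,
σ = 40, τ = 50, onset 420 ms) was derived from the closed form: the
Q3–Q4 slope of `A·e^(−s·lag)` is monotone in `s` only while `s·lag < 1`
over the Q3–Q4 range, so the onset must sit close to the upper quartiles;
with a generic onset far below Q3 the decay completes early and the true
slope is non-monotone in `s`.

## Known limitations

* Only fully crossed, balanced within-subject designs with 2-level
  factors are supported by the ANOVA layer (matching the target designs);
  unbalanced or mixed designs are out of scope.
* Binning requires at least `n_bins` trials per subject × congruence
  cell; subjects below that are dropped per cell, which can unbalance a
  downstream ANOVA (then reported as an incomplete-grid error rather
  than silently reweighted).
* The delta-plot x-coordinate and the pooled-vs-per-subject binning
  question have no single published convention; both choices here are
  documented above and the alternative pooled mode is exposed.
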