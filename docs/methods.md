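# Methods

This note records the statistical model behind each stage, the defaults
and why they are set where they are, what the synthetic generator does and
does not emulate, and the numerically delicate choices.

## Data model

A post record carries an id, a UTC timestamp, a polarity label in
{F, C, U, OOC} and like/retweet counts. Ingestion deduplicates on the id
(first occurrence wins), drops out-of-context (OOC) posts from the
polarity stream, and bins the rest into calendar days (UTC midnight
boundary, shiftable by a timezone offset; likes and retweets are
attributed to the posting day). The daily series is gap-free: days with
no retained post are explicit zero rows, flagged and skipped by every
test rather than imputed. OOC posts are excluded from volume; if they are
deliberately retained upstream they count toward interactions only.

Pooled proportion confidence intervals use a nonparametric bootstrap
(default 2000 resamples, percentile interval) over posts — equivalent to
multinomial resampling of the pooled counts — with a day-blocked variant
(resampling whole days) for when day-level clustering matters. A
bootstrap was chosen because it is assumption-light and reproducible
under a seed; the percentile interval is widened to include the point
estimate in degenerate corners (e.g. all posts in one category).

## Day-level multinomial tests

The day's count vector is modelled as Multinomial(N_t, π). The p-value is
the exact conditional tail: the total null probability of all three-part
compositions x of N_t with P(x) ≤ P(observed), ties included (two
log-probabilities within 1e-9 are treated as tied). Full enumeration is
used up to N_t = 2000 (≈ 2·10⁶ compositions, vectorised with cached
per-n factorial terms); beyond the cap a seeded Monte Carlo version is
used with the add-one correction p = (1 + #{P_sim ≤ P_obs})/(1 + n_sim),
default n_sim = 10⁴, which is never exactly zero and agrees with the
exact value to Monte Carlo error (a tested contract). If the observed
vector is impossible under the null (positive count in a zero-probability
category) the p-value is 0; outcomes that are impossible under the null
carry no mass and drop out of the tail sum automatically.

*Basic test*: π = pooled whole-period proportions. *Running test*: π for
day t is the unweighted mean of the daily proportion vectors over the
non-empty days among the 15 preceding days ("average preferences
persistence"); a pooled-count (volume-weighted) null is available behind
a flag. Days with fewer than `min_history` = 5 non-empty days in their
window are skipped — a third of the default window, so sparse stretches
do not produce nulls estimated from one or two days. The tested day is
never part of its own null window.

*Running-variance test*: σ₀² is the sample variance (divisor N−1) of the
daily favourable proportion over all observed days; for each day the
sample variance s²_w of the trailing w = 15 observed values gives
T = (w−1)s²_w/σ₀², referred to χ²(w−1). The p-value is two-sided,
2·min(F(T), 1−F(T)) capped at 1, because both unusually turbulent and
unusually frozen windows are of interest; the tail is reported as a
direction (high/low). Under iid Gaussian proportions the test is exact up
to the estimation of σ₀²; with w = 15 against a year of data that
estimation shifts the rejection rate by well under one percentage point
(the calibration test allows 0.005 absolute for it).

Rejection summaries report, per significance level, the number of
rejection days against the chance expectation α × (tested days) — at
α = 0.05 over a full year, about 18 days. This excess-over-expectation
reading is the method's inferential logic, so no multiplicity adjustment
is applied; a BH-adjusted column can be added downstream if wanted. The
window-sensitivity table re-runs the two running tests over a list of
window lengths.

## Smoothing and trend

The discrete beta kernel at evaluation day x with bandwidth h places
weights proportional to the Beta(x/(Th) + 1, (T−x)/(Th) + 1) density on
the rescaled grid j/T, j = 0..T, renormalised to sum 1. Both shape
parameters are ≥ 1, the density's mode sits at x (including x on the
boundary — no boundary bias), no weight exists outside the observed
interval by construction, and h → 0 concentrates all weight on j = x
(identity limit; if the density underflows everywhere the weight is
assigned to the nearest grid point directly). Each proportion series is
smoothed independently as a weighted mean; zero-volume days are excluded
and the weights renormalised over observed days rather than imputing.
Because the same weights apply to each category, smoothed simplex vectors
still sum to 1 whenever all categories are observed on the same days; an
optional renormalisation enforces it otherwise. Smoothing is unweighted
by volume (a volume-weighted variant is a flag): the object of interest
is the day-level opinion state, not the post-level pool.

The bandwidth is selected by leave-one-out cross-validation: each
observed day is predicted with its own weight zeroed and the rest
renormalised; h* minimises the mean squared prediction error, with ties
(within 1e-10 relative) broken toward the larger, smoother bandwidth.
One behaviour worth knowing: LOO optimises *prediction*, so on a series
with genuine short-lived structure (opinion shocks) it legitimately keeps
h small and the shocks survive into the smooth; on pure noise the error
curve drops to the noise floor and plateaus, so the selected h lands
anywhere on that plateau rather than necessarily at the grid maximum.
Replicate studies that need a fixed smoothing scale therefore use a
representative fixed h (0.05) instead of per-replicate CV.

The trend fit is ordinary least squares of the (smoothed) favourable
share on a centered and scaled day index z = (t − t̄)/sd(t) for degrees
0..5 (Vandermonde design; scaling keeps the design well-conditioned).
R²(0) is 0 by definition and an exactly constant input selects degree 0
with R² = 1. The stepwise rule selects the smallest degree d ≥ 1 with
R²(d+1) − R²(d) < 0.01; the 1% threshold is the package's reading of a
"negligible" gain. Coefficients are reported in both the scaled and the
raw day-index basis, with OLS standard errors and confidence intervals in
the scaled basis; for a quadratic fit the vertex day (stationary point)
is exposed. When the smoothed series still carries shock structure the
stepwise degree can exceed 2; the degree-2 component remains the
year-scale summary, and on trend-plus-shocks scenarios its vertex
recovers the true opinion peak to within ±20 days in ≥ 90% of seeded
replicates.

## Annotation agreement

Fleiss' kappa κ = (P̄ − P̄e)/(1 − P̄e) with per-item agreement
P_i = (Σ_j n_ij² − n)/(n(n−1)) and chance agreement P̄e = Σ_j p_j² is
computed via statsmodels on the items × categories count table; the
degenerate all-one-category table (P̄e = 1) is defined as κ = 1 under
unanimity and rejected otherwise. Items must carry the same number of
raters (others are rejected, not reweighted). Pairwise accuracy is the
share of agreeing label pairs among multiply-annotated items with an
exact Clopper–Pearson binomial interval — exact because the interval is
then conservative at any n, with no normality assumption.

## Synthetic generator

The generator emulates the structure the analysis assumes: a baseline
opinion split (default (0.70, 0.164, 0.136)); daily volumes
NB(mean 200, dispersion 10) — moderate overdispersion for the background,
with the few dominant news-driven peaks modelled as explicit spike
multipliers rather than heavy NB tails; short events adding δ to the
favourable share for a few days (C and U absorb the shift in proportion;
a composition leaving the open simplex is an error naming the offending
days, not a silent clip); and a slow quadratic trend applied on
logit(p_F) over centered unit time u ∈ [−1, 1] with the C:U ratio held
fixed, which keeps trajectories inside the simplex by construction. The
demo trend (0.08, −0.16, −0.22) rises to a peak about a third of the way
into the year and ends more than 7 points of favourable share below the
peak. Engagement is heavy-tailed negative binomial (mean 2 per post);
out-of-context chatter (default 57.8% of the stream) and duplicate
injection exercise the ingestion stage. All draws flow from one integer
seed through spawned child streams: the day-level series and the
post-level stream of the same scenario share byte-identical polarity
counts, while their interaction totals are drawn at different resolutions
and differ in distribution.

What the generator does **not** emulate: tweet text and classifier
behaviour (labels arrive error-free unless an annotator confusion model
is used), network structure and echo chambers, serial correlation of
day-to-day opinion beyond the deterministic trend/events, and
interaction-driven label attribution. Passing tests therefore certify
the statistical machinery under its stated model, not robustness to
classifier noise or to dependence structures real corpora may carry.

Replicate studies use desk-scale sizes — 365-day years, volume mean 200
(500 for power runs), 200 calibration replicates, 100 trend-recovery
replicates, 10 power replicates — chosen so each study resolves its
target quantity to well within the tolerance it is checked at.

## Numerical and degenerate-input choices

* Exact-test ties: log-probability tolerance 1e-9 (relative), so float
  representations of equal-probability outcomes are counted as ties.
* Enumeration cap 2000 (≈ 2M compositions); above it the caller is
  directed to the Monte Carlo route. Composition tables and factorial
  sums are LRU-cached (64 entries) since replicate studies revisit the
  same n.
* Variance test requires w ≥ 3 and σ₀² > 0 (a constant series is an
  error, not a rejection).
* Bandwidths must be positive; beta-kernel underflow at extreme h falls
  back to the identity weight.
* Bootstrap percentile intervals are widened to include the point
  estimate when the resampling distribution degenerates.
* Record-level ingestion errors (malformed timestamp, unknown label)
  reject the record and log a count rather than aborting the run.

## Known limitations

* The exact multinomial test is conservative at small N_t (discreteness);
  the calibration benchmark absorbs this, but per-day p-values on
  low-volume days are coarse.
* The running null is estimated, not known; days immediately after a
  shock test against a contaminated null and reject at an elevated rate
  (reported separately as "contaminated" in the power experiment).
* LOO-CV bandwidth selection tracks predictive structure, so it will not
  hide real short-term shocks from the trend stage; consumers wanting a
  pure year-scale summary should read the degree-2 component.
* Proportion CIs treat posts as independent; the day-blocked bootstrap
  is the provided guard against day-level clustering.
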