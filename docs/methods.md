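# Methods

## The quantity being measured

Every analysis in this package is built on *exposure vectors* over Q income
quantiles (Q = 4 by default). For a place α in one analysis window,

    τ_qα = Σ_{i∈q} w_i · dwell_iα / Σ_i w_i · dwell_iα

is the share of (post-stratification-weighted) time at α contributed by
quantile q. For an individual i, exposure is the convolution of their own
time shares with the places' vectors, τ_iq = Σ_α τ_iα τ_qα. Diversity is the
evenness of such a vector,

    D = 1 − Q/(2(Q−1)) · Σ_q |τ_q − 1/Q|,

which is exactly 1 for the uniform vector and exactly 0 for a point mass;
at Q = 4 the normalization constant is the familiar 2/3. The generalization
Q/(2(Q−1)) is chosen so those two extremes map to {0, 1} for any Q ≥ 2. A
normalized Shannon entropy (−Σ τ ln τ / ln Q) is provided as a robustness
variant; on random Dirichlet vectors the two are rank-correlated above 0.9
(tested), so conclusions do not hinge on the choice.

Period-over-baseline change is ΔD(t) = 100% · (D̄(t) − D̄(2019, m)) /
D̄(2019, m), with m the calendar month of t. Dividing by the same-calendar-
month 2019 value is also the package's deseasonalization convention; nothing
beyond month-matched ratio normalization is applied. Means D̄ are unweighted
means over qualifying places (≥ 2 distinct users and ≥ 30 dwell-minutes by
default, both configurable) or over individuals with matched visits;
CBG-level diversity is the unweighted mean of resident D_i.

## Preprocessing contract

Stays are kept when 10 < dwell < 240 minutes (strict inequalities; the
generator emits dwell in the open interval, so the filters are transparent
for synthetic data). User-days require more than 300 observed minutes when a
ping log is available; synthetic panels are fully observed and pass through
with a warning unless strict mode is requested. Stays are attributed to the
nearest POI within a 100 m great-circle radius, ties broken toward the
smallest POI id; unmatched stays are flagged and excluded from diversity but
kept for dwell accounting. Income quantiles are equal-count groups of users
ranked by home-CBG median household income, per CBSA; tie blocks (users
sharing a CBG income) receive the quantile of their average rank, so group
sizes are equal only up to boundary-tie sizes. Analysis windows are 2-month
moving windows labelled by their last month ("2020-04" spans 2020-03-01 to
2020-04-30 inclusive); a stay belongs to every window containing it. All
distances are haversine on a spherical Earth — at 100 m and city scales the
projection choice is immaterial, and the convention is bit-reproducible.

## The synthetic city and the Social-EPR generator

The generator builds a single synthetic CBSA: CBG centroids uniform in a
20 km disc, lognormal median incomes (median ≈ $60k), PUMAs as angular
sectors (~1 per 30 CBGs), POIs scattered 0.4 km around CBG centroids with a
fixed major-category/subcategory vocabulary, and users with uniform-random
home CBGs. Each POI's *dominant quantile* is its CBG's income quantile —
the unambiguous ground truth for "majority income quantile group".

Visits follow a social exploration and preferential return process. Per
user, latent events arrive as homogeneous Poisson at 2.5/day (no weekday
structure; an optional sinusoidal month-of-year multiplier exists for
deseasonalization exercises). At an event with S distinct places already
visited, the user explores with probability ρS^(−γ) (forced at S = 0),
otherwise returns to a known place with probability proportional to its
past visit count (implemented as a uniform draw from the visit history).
An exploration is *social* with probability σ_s — the new place is drawn
from POIs whose dominant quantile differs from the user's — and otherwise
from same-quantile POIs; within a pool, POIs are weighted by
(d + 0.05 km)^(−β) of home-to-POI distance times any subcategory preference
weight. Empty pools fall back to the complementary pool with a warning.
Dwell is lognormal (median 45 min, σ = 0.75 in log-space), rejection-sampled
into (10, 240) minutes. Baseline parameters are ρ = 0.6, γ = 0.21,
σ_s = 0.40, β = 1.5. One global seed spawns per-user substreams keyed by
user index, so trajectories are reproducible independently of user order.

Two generator design choices deserve emphasis:

* **Distance-preference shifts.** A pure power-law kernel is scale-free, so
  multiplying distances by a constant would not change anything. The
  scenario's `distance_shrink_factor` s instead sharpens the kernel to
  exponent β/s (s < 1 ⇒ stronger decay ⇒ shorter trips), which produces the
  intended per-quantile shift of the travel-distance distribution.
* **Activity reduction is thinning.** A scenario's per-quantile activity
  multiplier retains each realized visit of the full-rate trajectory with
  the multiplier's probability (a thinned Poisson process is again Poisson
  at the reduced rate, so the arrival contract is unchanged). The
  alternative — running the EPR clock slower — makes a "pure activity"
  scenario also change exploration behavior (fewer events ⇒ lower S ⇒ a
  higher exploration fraction per visit), i.e., it contaminates the
  activity factor with a preference-change factor. Thinning keeps the three
  behavioral factors of the decomposition orthogonal by construction, which
  is what makes counterfactual attribution testable against ground truth.

What the generator does *not* emulate: within-day schedules, road networks,
weekday/weekend structure, household or social-network correlation between
users, panel attrition or observation gaps, and spatial autocorrelation of
CBG income. Passing tests therefore demonstrate correctness of the
estimators and the attribution machinery under a known mobility law — not
that real mobility data satisfies that law.

## Counterfactual decomposition

For pandemic month (y, m), visits are removed uniformly at random from the
(2019, m) panel until per-stratum dwell first drops to at or below the
(y, m) panel's dwell: one global stratum for scenario (i); income quantile ×
7-bin home-distance ladder [0,1), [1,3), [3,5), [5,10), [10,20), [20,40),
[40,∞) km for scenario (ii); optionally × major category for the (ii+cat)
variant. Matching is on dwell minutes, not visit counts; removal stops at
the first crossing, leaving each stratum within one visit's dwell (≤ 240
min) of its target; strata whose target exceeds the source keep everything
(visits are never added or re-timed). Ten replicates (seeds seed+0..9) give
mean and SE. Contributions telescope exactly:
(i) = D̄₂₀₁₉ − D̄_cf(i), (ii) = D̄_cf(i) − D̄_cf(ii),
(iii) = D̄_cf(ii) − D̄_actual, and shares divide by the total decrease.

In recovery tests the baseline and scenario months are simulated with a
shared trajectory seed (common random numbers), so the configured behavioral
change is the only systematic difference between panels, and the actual
value is compared against the replicate distribution with a 2-sd prediction
band (replicate sd × √(1 + 1/n_reps)): the actual panel is one more draw of
the same removal process, not the mean of many, so a band built from the SE
of the mean alone would be rejected about half the time even for a correct
implementation.

## Behavioral estimators

*Exploration law.* A visit is an exploration iff its POI is new for the user
within the estimation window (pre-window history is unobservable, making
the empirical rate an upper bound on true exploration). Empirical fractions
per S (S ≥ 1; S = 0 is forced) are fit by weighted least squares of log p on
log S with event-count weights. Count weights are not inverse-variance on
the log scale — var(log p̂_S) ≈ (1−p_S)/(p_S n_S) — so confidence intervals
use heteroskedasticity-robust (HC1) standard errors rather than the
classical WLS covariance. A 50-seed study at ~1e5 events per panel covers
the true (ρ, γ) in 46 and 45 of 50 seeds respectively (tested).

*Social exploration σ_s.* The share of explorations landing at places whose
majority quantile (argmax τ_qα on the 2019 baseline window, held fixed
across periods; ties to the lowest quantile, flagged and excluded by
default) differs from the visitor's quantile, with a Wilson binomial CI.
Because the distance kernel concentrates a POI's visitors in its spatial
neighborhood, a minority of POIs legitimately acquire an empirical majority
different from their CBG's quantile; empirical labels agree with the
generator's dominant quantile for ~94% of POIs with ≥ 10 users at the
5000-user scale, and the empirical-pipeline σ̂_s carries a small upward
bias (≈ +0.005 at that scale, larger on sparse panels). CI-coverage claims
about the estimator itself are therefore evaluated with ground-truth labels.

*Subcategory popularity.* f_r(c) is the share of individuals whose top-r
most-visited places (ties: higher dwell, then lower POI id) include
subcategory c; Δf_r compares to the same-month 2019 table.

## Heterogeneity regression and the stringency trade-off

D_CBG or ΔD_CBG is regressed on standardized covariates (population-std
z-scores) with PUMA fixed effects absorbed by within-group demeaning.
Coefficients, classical standard errors, p-values and adjusted R² are
exactly those of the dummy-variable model (degrees of freedom are corrected
for the absorbed group means; verified against the dummy model to 1e-10);
heteroskedasticity-robust errors are available behind a flag. Collinear
columns are dropped by pivoted QR at a 1e8 condition threshold, with a VIF
report. The place-visit block {P_CBG} is the share of a CBG's residents
spending more than 0.3% of their dwell in each subcategory with at least
100 venues (both thresholds configurable; the synthetic city needs smaller
venue minimums than a real one). The stringency trade-off is the per-CBSA
Pearson correlation between monthly ΔD and the stringency index, with an
OLS slope and a lag-1 autocorrelation diagnostic in lieu of ARIMA modelling.

## Problem sizes and numerical choices

The bundled study design (`urbandiv.study`) uses 800 users, 1500 POIs, 120
CBGs and an 8-month stringency ramp (SI 85 at the April-2020 peak declining
to 28), with activity multipliers 1 − (0.25 + 0.04q)·SI/100 (higher-income
quantiles cut back more), σ_s scaled by 1 − 0.6·SI/100, distance shrink
1 − 0.4·SI/100, and routine-vs-discretionary subcategory preference shifts.
Recovery tests use 1200–1500 users so that estimator noise, not runtime,
sets the resolution; the full suite simulates a few million visit events.
Exposure sums are validated to 1e-6 and diversity is clipped to [0, 1]
against float rounding; the evenness formula groups (Q·Σ)/(2(Q−1)) so the
boundary vectors evaluate to exactly 1 and 0 in floating point. Degenerate
inputs raise: fewer distinct CBG incomes than quantiles, exposure vectors
not summing to 1, zero baselines, constant stringency series, all-forced
exploration streams.

## Known limitations

Individual diversity inherits place-exposure noise: on sparse panels D̄ is
biased downward (small-support places have artificially uneven empirical
τ), which is why D̄ comparisons are made between panels of matched dwell and
why minimum-support thresholds exist. The σ_s point estimate with empirical
labels is an upper-biased proxy on sparse panels. The exploration-law fit
assumes the power-law form globally; it is not a goodness-of-fit test. The
regression layer makes no causal claims and models no spatial
autocorrelation.
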