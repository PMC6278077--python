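# Methods

## Problem and data model

The package estimates district-level coverage of three maternal/newborn
health services — skilled birth attendance (SBA), four-plus antenatal visits
(ANC 4+), and professional postnatal care within 48 hours (PNC 48 h) — from
cluster survey microdata of the DHS type: women nested in clusters, clusters
nested in districts, cluster coordinates deliberately displaced for
confidentiality.  Analyses are restricted to each woman's most recent birth
in the five years preceding the survey.  The three outcomes are modelled
independently; a record with a missing input for one outcome is excluded
from that outcome's model only.

Outcome definitions:

* `sba = 1` iff the attendant was a doctor, nurse, or auxiliary midwife;
* `anc4 = 1` iff reported antenatal visits ≥ 4;
* `pnc48 = 1` iff a check-up by one of the professional cadres above occurred
  within 48 h of delivery (boundary inclusive).  Facility deliveries are
  assumed to have received professional postnatal care **only when both
  postnatal fields are missing**; any recorded value overrides the
  assumption (a recorded 72 h check-up scores 0 even for a facility birth).
  A recorded provider with unknown timing scores 0, since the 48 h window
  cannot be established.  The indicator is missing only when the postnatal
  fields and the facility flag are all absent.

## Geography and cluster linkage

Districts form a rook-contiguity graph (neighbors share a boundary segment
of positive length, not just a corner); rook is the stable choice on the
package's grid fixtures and the common convention in disease mapping.
Components are computed by graph traversal; islands are legal.

Clusters are linked to the district containing their reported (displaced)
point.  A circular buffer of the displacement radius — 2,000 m urban,
5,000 m rural, both configurable — is intersected with the other districts;
if it reaches any of them the cluster is flagged `ambiguous` (the true
location may lie across the border), but it keeps its containing district:
each cluster is linked to exactly one unit, and downstream code may
optionally drop flagged clusters (`linkage.drop_ambiguous`).  Points outside
every polygon are assigned to the nearest district within the buffer radius,
else left unassigned (their records are dropped with a warning).  All
coordinates must be planar meters; values that look like lon/lat degrees are
rejected rather than silently projected.

## The coverage model

For woman *i* in district *j*,

    logit(p_ij) = x_ij' β + b_j ,   b_j = σ_b ( √(1−φ) v_j + √φ u_j ),

the BYM-2 parametrization of the Besag–York–Mollié convolution: `v` iid
standard normal, `u` an intrinsic CAR (ICAR) effect with precision
proportional to D − W on the contiguity graph, variance-scaled so that the
geometric mean of its marginal variances is 1 within each connected
component.  This makes σ_b the marginal standard deviation of the combined
effect and φ the structured share of its variance, comparable across graphs.
Identification of `u` is by hard sum-to-zero constraints per component;
islands have `u = 0` and rely on `v` alone.  The model is individual-level
Bernoulli (not cluster-binomial): the likelihood is identical and covariate
handling simpler.

Fixed effects are urban residence, education, wealth quintile, maternal age,
and parity.  Two codings are supported and logged: the default **ordinal**
coding (education 0/1/2, wealth as quintile steps 0–4) yields the compact
six-parameter form β₀…β₅ used throughout the synthetic studies; the
**categorical** coding uses indicator sets with *no education* and quintile 1
as references.  Age and parity are centered and scaled by the sample
mean/sd.  These codings are package choices — survey analyses rarely report
them — and are switchable in one config key.

Priors ("uninformative" made concrete, all configurable): β_k ~ N(0, 1000),
σ_b ~ half-normal(1), φ ~ uniform(0, 1).  All are proper, so the posterior
is proper even under sparse data.

## Inference

Sampling is an adaptive Metropolis-within-Gibbs kernel, chosen for
robustness and zero dependence on gradient frameworks:

* **β**: joint random-walk proposals preconditioned by the Cholesky factor of
  the IRLS (plain-logistic) covariance, scalar step adapted to 23.4%
  acceptance; initialized at the IRLS solution.  Several β proposals per
  sweep.
* **u**: single-site Metropolis grouped by a greedy graph coloring —
  districts of one color are conditionally independent given the rest, so a
  whole color class updates in one vectorized step.  Per-node step sizes
  adapt to 44% acceptance.  After each sweep `u` is recentered to sum to
  zero within each component (hard constraint, the standard CAR practice).
* **v**: simultaneous independent Metropolis across districts (valid because
  the prior is iid and the likelihood factorizes over districts).
* **σ_b, φ**: scalar random walks on log / logit scales with Jacobians.
* **Interweaving moves**: three likelihood-invariant proposals that leave the
  linear predictor fixed and move along the directions where centered and
  non-centered parametrizations disagree — translating the intercept against
  a constant shift of `v`, rescaling σ_b against (u, v), and rebalancing φ
  against (u, v).  Only prior ratios and map Jacobians enter the acceptance
  probability.  These repair the slow mixing of σ_b and φ that plain
  non-centered samplers exhibit, at O(J) cost.

The kernel runs two full sweeps per recorded iteration.  Adaptation runs
during warmup only, so the retained chain is a fixed Markov kernel.
Defaults: 4 chains × 2,500 iterations, 1,000 warmup, thin 1.  The recovery
studies in the test suite use 2 chains × 1,500 (500 warmup), which keeps a
full 20-replicate calibration study under three minutes on one CPU.

Diagnostics: split-R̂ and effective sample size per scalar parameter (via
ArviZ); a fit carries a warning whenever any fixed-effect R̂ exceeds 1.05.
A single response class raises a separation error naming the outcome.

**DIC**: D(θ) = −2 log p(y|θ); pD = mean posterior deviance minus the
deviance at the posterior **mean** of (β, b) (the original plug-in
definition); DIC = mean deviance + pD.

## District estimates and inequality indices

District prevalence for one posterior draw is the average of
inverse-logit(x'β + b_j) over the district's **observed** women — the
empirical covariate distribution, matching the survey notion of coverage as
the proportion of sampled women receiving a service — rather than a
standardized profile.  Summaries (mean, median, sd, 2.5/97.5%) are taken
across draws.  Districts with no observations are predicted at the
sample-mean covariate profile under their own spatial effect (which the
ICAR prior conditions on their neighbors) and flagged `extrapolated`.
Absolute change between two survey rounds is the last-minus-first difference
of posterior means, with an `uncertain` flag when the two 95% intervals
overlap.

The two relative indices deliberately use different inputs: the
**performance ratio** divides the largest by the smallest *modelled* district
estimate (its interval is the 2.5/97.5% of the draw-wise max/min ratio — the
ratio of interval endpoints would not be a valid interval), whereas best and
worst regions for the **odds ratio** are picked by *observed* sample
coverage, with deterministic lexicographic tie-breaks.  The OR model is a
plain fixed-effects logistic regression of the outcome on region indicators
(worst region as reference) fitted by Newton–Raphson/IRLS to a gradient norm
below 1e−8, with Wald 95% intervals; no random-effect structure is imposed
because none is identified for a univariate contrast.  Regions with all-0 or
all-1 outcomes raise a separation error pointing to exact/penalized
alternatives rather than silently returning ±∞.

## Validation

`holdout_split` removes 25% of individual records (configurable; whole-cluster
splitting available), stratified by district with largest-remainder
allocation so the overall test share is exact and each district's share is
as close to the fraction as rounding allows; single-record districts stay in
train.  The model is refitted on the training portion and district-level
posterior-mean predictions are compared with held-out observed proportions:
MAE, MSE, and pseudo-R².  The district level is used because proportions are
the reporting unit; an individual-level Brier score is reported as a clearly
secondary metric.  pseudo-R² defaults to the coefficient of determination
1 − SS_res/SS_tot, with squared Pearson correlation as a configurable
alternative; zero variance in the observed vector makes it undefined and it
is reported missing with a reason.

## The synthetic generator

The generator is the package's test bed and defines its study conditions:
a 5×5 grid of 10 km square districts, 15 clusters of 10 women per district
(3,750 women), fixed effects (−0.5, +0.6, +0.4, +0.2, +0.1, −0.1) for
intercept/urban/education/wealth/age/parity, σ_b = 0.8, φ = 0.6.  Covariates
follow simple laws: age uniform 15–49, parity zero-truncated Poisson(2.5),
wealth uniform over quintiles (optional urban tilt), education categorical
(0.25/0.50/0.25).  `u` is drawn exactly from the scaled ICAR in the spectral
basis of each component; cluster positions are uniform within districts and
displaced a uniform distance up to the urban/rural radius in a uniform
direction.  Raw fields are back-filled to invert the recode rules exactly
(nurse attendant for SBA = 1; 4 vs 2 visits; nurse check-up at 24 h vs 72 h;
facility flag mirroring PNC 48), so generator → recode is a lossless round
trip.

What the generator does **not** emulate: two-stage sampling weights (the
models are unweighted), non-stationary covariate fields, missing data,
cross-border service use, boundary changes between rounds, or outcome
dependence beyond the shared linear predictor (the three outcomes are
conditionally independent draws from the same truth).  Passing tests
therefore demonstrate correct recovery under a well-specified model, not
robustness to the messiness of real surveys.

## Numerical choices and edge cases

* Bernoulli log-likelihoods use `−logaddexp(0, ±η)`, exact and stable for
  |η| up to ~700 and at infinite η limits.
* ICAR scaling uses the eigen-decomposition of each component block; the
  null space (one zero eigenvalue per component) is detected at a relative
  tolerance of 1e−10.
* Degenerate inputs fail loudly: invalid polygons (named), lon/lat
  coordinates, rank-deficient designs, single-class outcomes, zero district
  estimates in ratios, empty regions, zero-variance validation targets.
* Tie-breaks are deterministic everywhere (lexicographic district/region
  ids), so reruns with fixed seeds are byte-identical; the pipeline manifest
  records every derived seed.
* The holdout refit re-standardizes age/parity on the training sample; with
  a random 25% holdout the shift is negligible, but exact covariate-scale
  freezing across splits is a known simplification.

## Design choices that were genuinely open

* **Ambiguous clusters** are kept with their containing district and
  flagged, not probabilistically reassigned — linkage stays deterministic
  and one-to-one, and sensitivity is available by dropping flagged clusters.
* **Covariate coding** defaults to the ordinal six-parameter form so the
  synthetic truth has one coefficient per named covariate; indicator coding
  is one config key away.
* **Prevalence** is sample-averaged, not covariate-standardized (matches the
  coverage definition above).
* **Split unit** defaults to individual records; cluster-level splitting is
  offered because survey data are cluster-sampled.
* **pD at the posterior mean** (not median), per the original DIC
  definition.

## Known limitations

Metropolis-within-Gibbs mixes more slowly than gradient-based samplers on
strongly correlated posteriors; ESS per iteration is modest and very small
surveys can trigger R̂ warnings (the warning is attached to the fit rather
than raised).  φ is weakly identified when σ_b is small — its posterior then
approaches the uniform prior, which is expected behavior, not a defect.
Districts with no data are extrapolated at a sample-mean profile, which
understates their uncertainty relative to a full covariate-imputation
approach.  The validation statistics are district-aggregated and therefore
optimistic when districts are tiny, as the held-out proportions themselves
are noisy.
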