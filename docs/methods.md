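# Methods

`hbchoice` implements a choice-based conjoint (discrete choice experiment)
analysis pipeline for treatment-preference surveys, organized around the
study design it emulates: chronic hepatitis B patients choosing between
pairs of hypothetical oral antivirals described by six attributes.

## Attribute schema and coding

The default schema has six attributes: long-term (5-year) efficacy
(71 % / 85 % / 92 %), 5-year risk of bone thinning (< 1 % / 7 % / 14 %),
5-year risk of kidney damage (< 1 % / 10 % / 20 %), patients treated
worldwide (100,000 / 200,000 / 400,000), years on the US market
(2 / 4 / 6), and monthly out-of-pocket cost ($0 / $50 / $100 / $150).

Products are effect-coded (sum-to-zero): an attribute with `L` levels
contributes `L - 1` coefficients; level `i < L - 1` maps to the unit vector
`e_i` and the last level to all `-1`. The coded dimension is
`p = 5 x 2 + 3 = 13`. Effect coding was chosen over dummy coding because the
range-method importance works directly on level part-worths, and over a
linear-in-price specification because no functional form for cost is
assumed; "< 1 %" style labels are purely categorical so no numeric
imputation is needed.

## Design construction

The default plan is 64 paired scenarios in 8 blocks of 8 (16 product slots
per block). The construction is a seeded greedy search: per block, each
attribute's levels are laid out in counts that differ by at most one
(remainders rotate across blocks), the columns are shuffled, consecutive
slots are paired into scenarios, and count-preserving swaps repair
duplicate products or duplicate unordered pairs. Among the candidate
layouts that satisfy the constraints, the one whose pairwise level
cross-tabulations deviate least from uniform (sum of squared deviations) is
kept — a cheap orthogonality proxy rather than a D-optimal search.
Scenario identity is the unordered pair of product configurations;
additionally, whole products are kept globally unique whenever the product
space is large enough (972 configurations vs 128 slots by default).
Ties in the search resolve to the first candidate under seeded iteration
order, so plans are deterministic given the seed. Left/right (A vs B)
position of levels is not separately balanced — only level occurrence is.

Block assignment deals each group's (seed-shuffled) respondents round-robin
over blocks, so Treated and Treatment-naive counts per block differ by at
most one within each group.

## Synthetic population and calibration

Individual part-worth vectors are drawn `beta_i ~ MVN(mu, Sigma)`. The
calibrated population mean is constructed so that the range-method
importances of `mu` equal the published aggregate importance profile
(kidney risk 37.9 %, cost 23.4 %, bone risk 18.0 %, efficacy 9.0 %, market
time 6.8 %, level of use 4.9 %): each attribute's level part-worths are
symmetric about zero, equally spaced from best to worst (higher efficacy,
lower risks, lower cost, more patients and market years preferred), with
range proportional to the target importance and the six ranges scaled to
sum to 8.0 utility units. Heterogeneity defaults to `Sigma = 0.25 I`
(sd 0.5 per coded coefficient) — no individual-level variance information
is published, so this value is a documented stand-in, kept configurable:
large enough to make shrinkage do real work, small enough that the
aggregate importance profile remains recoverable. The default panel is 252
respondents, 111 Treated / 141 Treatment-naive, with Chinese / Vietnamese /
Korean ethnicity labels in 90/85/77 proportions (labels are carried but do
not enter the choice-generating rule, mirroring the reported consistency
across ethnicities).

Choices follow the binary logit rule: A is chosen over B with probability
`logistic((x_A - x_B)' beta_i)`; exactly equal utilities reduce to a fair
coin through `logistic(0) = 0.5` with no special-casing.

An important property of these conditions, measured rather than assumed:
with `Sigma = 0.25 I` the *true* respondent-level mean importance of the
heterogeneous betas is far flatter than the importance of `mu` itself
(kidney risk ~28.5 % rather than 37.9 % at large n), because independent
noise inflates the part-worth ranges of weak attributes relative to strong
ones. Recovery of the published profile from fitted part-worths therefore
depends on hierarchical shrinkage of the individual posterior means; with
only 8 choices per respondent the posterior means sit much closer to `mu`
than the true betas do, and the recovered aggregate lands within a few
points of the published column (about +/-2 points seed-to-seed spread at
n = 252).

Price-response and attitude generators are latent-threshold emulations of
the survey instruments and are *not* calibrated to the observed survey
marginals. Willingness scores discretize
`a_i + b_i * price + noise` into 1..5, with group-level intercepts (5.0
Treated / 5.2 Treatment-naive, sd 0.6), negative slopes per dollar (-0.009
Treated / -0.0065 Treatment-naive, sd 0.002, truncated at 0) and noise sd
0.5, chosen once so the top-2-box curve declines through the $100-$250
range with the Treated group more price-sensitive. Attitude scores
discretize a unit-sd latent normal around per-statement baselines, with
optional group shifts (defaults give the Treatment-naive group higher
agreement with the reluctance and lifestyle-sufficiency statements).
Passing tests on these generators demonstrates correct pipeline behaviour
on data with the assumed structure, not agreement with the original
sample's proportions, which cannot be reproduced without the raw data.

## Hierarchical Bayesian estimation

The model is a binary logit on effect-coded utility differences with no
outside option (the instrument forces a choice), a multivariate-normal
population over individual part-worths, and weakly-informative conjugate
priors:

    choice_it ~ Bernoulli(logistic(d_it' beta_i)),  d = x_A - x_B
    beta_i ~ MVN(mu, Sigma)
    mu ~ MVN(0, 100 I)
    Sigma ~ Inverse-Wishart(p + 2, I)

Original priors and sampler settings are not published; these are standard
choices for hierarchical choice models and are fully configurable.

Sampling is Metropolis-within-Gibbs with three ingredients per iteration:

1. **Individual updates.** All respondents' betas receive blocked
   random-walk proposals in one vectorized step, shaped by the current
   Sigma cholesky. Per-respondent scalar step sizes adapt toward 0.23
   acceptance during burn-in (Robbins-Monro on log scale, window 50) and
   freeze afterwards, so retained draws come from a fixed kernel.
2. **Conjugate updates.** `mu | beta, Sigma` is a multivariate-normal draw;
   `Sigma | beta, mu` is an inverse-Wishart draw via the Bartlett
   decomposition.
3. **Location translation moves.** The centered parameterization mixes the
   population location pathologically slowly when each respondent
   contributes only a handful of choices: betas can only drift toward a new
   location through small accepted moves, and the Gibbs update for `mu`
   follows their mean, giving effective sample sizes in the single digits
   at desk-scale chain lengths. The sampler therefore interleaves, for each
   coordinate `j`, a Metropolis move that shifts `mu_j` and every
   `beta_ij` by the same scalar. The hierarchical prior term is invariant
   under this shift, so the acceptance ratio involves only the full-data
   likelihood and the `mu` prior; scales adapt toward 0.44 acceptance.
   These sweeps can be disabled (`shift_moves=False`) when respondents have
   many records each and the location is already data-pinned.

Chains initialize at the pooled-logit maximum-likelihood estimate (all
betas and mu), falling back to zero under separation. Defaults are 2 chains
of 20,000 iterations, 10,000 burn-in, thinning 10. A reference run at
80,000 iterations confirmed that the default settings land on the same
posterior means (split-R-hat ~1.06, ESS > 70 for all population
parameters at the reference length).

Point estimates are posterior means across retained draws of both chains;
whether the original analysis summarized importances per-draw or from
point estimates is unpublished, and posterior means were chosen as the
simplest defensible reading. Convergence reporting uses rank-normalized
split-R-hat and bulk ESS (ArviZ), flagging parameters above 1.1; constant
chains are reported as degenerate explicitly. The pooled logit
(statsmodels) doubles as an independent oracle: with `Sigma = 0` and many
records the posterior mean of `mu` must match it within combined
Monte-Carlo/asymptotic error.

## Post-estimation

* **Relative importance (range method).** Per respondent, an attribute's
  importance is `100 * range / sum(ranges)` where the range is max minus
  min over its reconstructed level part-worths. The aggregate is the
  unweighted mean of per-respondent percentages (normalize-then-average),
  renormalized against floating-point drift; averaging raw ranges first is
  available as `aggregation="pooled_ranges"`. Respondents with all-zero
  ranges are excluded with a warning.
* **Preference shares.** Within a product set, each respondent's logit
  shares `exp(x_k' beta_i) / sum_j exp(x_j' beta_i)` are averaged across
  respondents into aggregate percentage shares; a first-choice rule is
  available as an option (`rule="first_choice"`, ties split evenly).
* **Sensitivity.** From a base-case pair, one attribute of one product is
  flexed through all its levels with everything else held at base case; the
  flexed product's aggregate share is recorded per level, and the base
  level reproduces the base-case share exactly. The original base-case
  configurations are not legible from the published figure, so the package
  default is: product A at every middle level (cost $50), product B the
  same but with 92 % efficacy and $100 cost — differing on two attributes
  so that no single flex can make the pair identical — and both fully
  overridable.

All means are unweighted; no sampling weights are modeled.

## Cost-sensitivity and attitude analyses

Willingness is operationalized as top-2-box (scores 4-5) proportions per
price, by group and overall; the unmeasured $300-$450 points are filled by
linear interpolation between $250 and $500 and flagged as extrapolated.
The cost beta is an OLS slope of the raw 1-5 score on price in dollars over
a configurable price window, treating Likert scores as interval data. Group
comparisons of attitude scores use Welch's two-sample two-tailed t-test at
alpha = 0.05 (the pooled-variance variant is not assumed since the original
choice is unstated); zero-variance-in-both-groups cases report t = 0,
p = 1 for equal means rather than a division error. No multiple-testing
correction is applied by default, matching the original analysis; a
Bonferroni option exists. A helper derives an implied maximum acceptable
price per respondent (highest measured price still scored >= 4) for
mean/median summaries when stated maxima are unavailable.

## Reproducibility and problem sizes

Every generator and the sampler are pure functions of their inputs and a
seed. The `replicate` pipeline derives stage seeds as CRC-32 hashes of
(stage name, master seed), so stages can be re-run in isolation; two runs
with the same master seed are byte-identical, and reports round
percentages to one decimal in the markdown rendering. The test suite runs
the headline recovery at the study's own scale (252 respondents x 8
choices, 2 chains x 20,000 iterations, ten master seeds) and the
oracle-equivalence check at 50,000 pooled records; smaller configurations
used in unit tests (hundreds of iterations) exercise code paths, not
convergence.

## Known limitations

* The importance-recovery guarantee is specific to the calibrated
  generator; real data with heavier-tailed or correlated heterogeneity
  would shift the shrinkage balance.
* The design search optimizes balance and a cross-tab proxy, not
  statistical efficiency under a utility prior (no D-optimality).
* Subgroup importance columns in the report reuse the joint fit's
  individual part-worths subset by group rather than refitting per
  subgroup; refitting is available by running the pipeline on subsets.
* Price-response and attitude generators are structural emulations only;
  none of the published survey proportions are asserted anywhere.
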