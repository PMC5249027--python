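# Methods

## Scope

`priorcfa` covers the *measurement* model of a seven-factor
prosthesis-satisfaction questionnaire: item→factor classification from an
expert sorting study, elicitation of informed loading priors, Bayesian
estimation of loadings, intercepts, error variances and latent scores, and
an informed-versus-uninformed sensitivity comparison. The *structural*
model (regressions between the latent factors) is deliberately out of
scope: no assumption is made about factor-on-factor regression parameters,
and no priors are elicited for them. Ordinal (probit/graded-response)
measurement, cross-loadings and marginal-likelihood model selection are
likewise out of scope.

## Classification and agreement

Each of `r` experts (22 in the packaged study) assigns every item to one of
seven substantive factors or to a rejection category. An item is retained
when one substantive factor holds a *unique strict plurality* over all
eight categories; "single majority" is read as plurality, not >50%, because
a 14-of-22 item is the canonical worked example of an assignment. Ties for
the maximum are excluded as `no_single_majority`; items whose modal
category is rejection (ties included) are excluded as
`predominantly_rejected` — the weakest reading consistent with "rejected by
a majority".

Gwet's AC1 is computed with all `q = 8` offered categories in the chance
term, since raters could and did use the rejection option:

    Pa = mean_i Σ_k r_ik (r_ik − 1) / (r (r − 1))
    Pe = 1/(q−1) Σ_k π_k (1 − π_k),   π_k = mean_i r_ik / r
    AC1 = (Pa − Pe) / (1 − Pe)

Average shared ratings (ASR) for a factor is the mean, over its items, of
the percentage of votes cast for *other substantive factors*. Rejection
votes are excluded from both numerator and denominator by default (ASR
measures confusion among factors; rejection is not a factor); the
`include_reject` switch restores the all-votes denominator, since the
original definition leaves this ambiguous. Items with no countable votes
are dropped before averaging to avoid 0/0.

## Prior elicitation

A `k`-of-`r` item gets the loading prior `N(M, SD²)` with `M = k/r` and
`SD = (1 − M)/2`, stored at full floating precision. A unanimous item would
get the degenerate `N(1, 0)` — a loading of exactly 1 would make the latent
variable redundant — so it instead receives the arithmetic mean of its
factor peers' full-precision prior means, with the same SD rule applied.
Remaining parameters are uninformed: intercepts `N(0, 100²)` (a proper
vague normal keeps the Gibbs updates conjugate), error variances
`Inv-Gamma(0.01, 0.01)`, latent values `N(0, 100²)` — the printed
"(M = 0, SD = 100)" is read as an SD, not a variance. For `I` retained
items and `F` factors the ledger counts `3I + F` parameters, `I` of them
informed: 217 and 70 for the packaged 70-item, 7-factor table.

Rendering is presentation-only and never overwrites the stored values. The
published table's `M (SD)` entries follow the convention
`SD = (1 − round(M, 2))/2`, rounded half-up — visible in the worked example
where `M = 0.77` gives the printed `SD = 0.115`. Under this convention the
packaged table reproduces all printed means except the unanimity-replaced
item 47 (computed 0.71 vs printed 0.72; the published averaging inputs are
unknown and agreement is not forced) and all printed SDs except item 40
(rule gives 0.07, table prints 0.08). Both are asserted as frozen known
exceptions in the regression tests.

### The packaged vote fixture

Raw votes were never published. The packaged fixture (synthetic, and
labelled as such) reconstructs each item's majority count as
`round(M·22)` from the printed prior means and spreads the remaining votes
as evenly as possible over the six other substantive factors. The even
spread matters: placing all minority votes on a single competing factor
would defeat strict plurality for low-agreement items (9 majority vs 13
minority). Only the majority count affects elicitation, so the fixture
reproduces the published classification and prior set exactly while its
off-majority structure (and hence its AC1 ≈ 0.43 and ASR values) is
arbitrary.

## Estimation

The CFA is linear-Gaussian with simple structure; Likert responses are
treated as continuous (the model the elicited priors parameterize specifies
no ordinal link) and omitted cells are dropped from the likelihood
(missing-at-random). All full conditionals are conjugate — normal for
loadings, intercepts and latent scores, inverse-gamma for error variances —
and are updated by plain Gibbs sweeps, vectorized over items and
respondents. Chains are seeded via `numpy.random.SeedSequence(seed)`
spawning, so identical inputs and seed give bit-identical draws.

**Identification.** The likelihood is invariant under jointly flipping a
factor's loadings and scores, and with a vague latent prior the latent
scale is unidentified (only the product λ·η is). The default
`standardized_latent` mode fixes the latent variance at 1;
`vague_latent` keeps the printed SD-100 latent prior for fidelity
experiments, in which case only scale-invariant quantities (λ·η products)
should be compared across runs. In both modes the item with the highest
prior loading mean on each factor anchors the sign: when its loading draw
is negative the whole factor is reflected. Factors with a single indicator
are rejected at fit time — one item cannot identify a latent trait.

**Defaults.** 4 chains × 2000 iterations with 1000 burn-in, no thinning; a
seed is always required. Split-R̂ and effective sample size (via ArviZ) are
reported per parameter and a warning is raised when R̂ > 1.05. HDIs are
computed as the shortest contiguous interval containing ⌈mass·n⌉ sorted
draws (own implementation, cross-checked against ArviZ in tests).
Inverse-gamma draws are generated as `scale/Gamma(shape)` with the gamma
variate floored at 1e-300, so that the heavy-tailed `Inv-Gamma(0.01, 0.01)`
prior cannot produce a division by zero when a column has no observations.

**Degenerate inputs.** An all-missing data matrix is allowed and returns
the prior (every conditional reduces to it) — used as a correctness check.
A zero-row matrix, non-integer or out-of-range responses, and
model/classification mismatches raise immediately.

## Model comparison

`make_uninformed` replaces every loading prior with `N(0, 100²)` and leaves
everything else untouched; both models are fit with identical sampler
settings and seed so Monte-Carlo error is comparable. The report gives, per
parameter: posterior means under both priors, 95% HDI bounds and widths,
Jaccard overlap of the HDIs (symmetric, 1 for identical intervals),
prior→posterior mean shift, and whether the "credibly different from zero"
status (95% HDI excluding 0) differs between models, plus the global count
of such disagreements. No threshold for a "noticeable" prior effect is
imposed; the measures are reported without a verdict. Bayes factors and
WAIC/LOO are out of scope.

## Synthetic data

*Votes*: per item, category probabilities are drawn from a Dirichlet whose
true factor carries `concentration` times the weight of each competitor
(weight 50 per competing factor — a precision constant keeping the drawn
probabilities close to their mean), then `n_raters` votes are drawn
multinomially; the expected rejection share is a separate knob. The single
consensus knob maps onto AC1: `concentration → ∞` gives unanimity
(AC1 = 1), `concentration = 1` gives chance-level sorting. Because the
rejection category is offered but unused when `rejection_prob = 0`, AC1 has
a small positive floor (≈0.02) at the chance setting — a property of the
statistic, not the generator.

*Responses*: latent traits are standard normal per respondent (optionally
correlated across factors), continuous responses `ν + λη + ε` are cut into
categories 1–5 at thresholds `(−1.5, −0.5, 0.5, 1.5)` — symmetric,
unit-spaced, giving balanced middle categories under a standard-normal
response — and cells are omitted independently with a fixed probability.

What the generator does *not* emulate: ordinal response styles (acquiescence,
extreme responding), informative missingness, respondent covariates or
longitudinal structure. Passing parameter-recovery tests therefore shows
the sampler recovers the generating linear model under discretization — at
the default thresholds the step transform attenuates loadings by only a few
percent — not that real prosthesis users' data satisfy the linear CFA.

## Test and verification sizes

Sampler verification uses three complementary routes: exact prior recovery
on an all-missing dataset (2 chains × 4000); total-variation agreement
(< 0.05) with a dense-grid integration oracle on a pinned one-factor,
two-item, five-respondent model (4 chains × 12 000); and a recovery harness
fitting the full 70-item model to 20 replications of n = 300 synthetic
respondents at 2 chains × 1500 iterations, requiring ≥ 90% coverage of the
generating loadings by the 95% HDIs (observed ≈ 0.97). Prior-influence
checks fit a 6-item, 2-factor model at n ∈ {10, 100, 1000}; the mean
informed/uninformed discrepancy of loading posteriors decreases
monotonically (≈0.29 → 0.10 → 0.008). These sizes keep the whole suite
around a minute on a single CPU while leaving comfortable margins on every
tolerance.

## Known limitations

* The printed study-level AC1 (0.39) and ASR percentages cannot be
  recomputed: they depend on the unpublished raw 85-item votes. The
  statistics are instead validated against analytic anchors and simulation
  oracles.
* The published parameter ledger counts "7 parameters" for latent values;
  the sampler necessarily draws `n_respondents × 7` latent scores. The
  ledger mirrors the count of 7 (one latent prior per factor) while the
  posterior carries per-respondent scores.
* Treating Likert categories as continuous attenuates loadings slightly
  relative to an ordinal model; with informed priors centered at the
  generating values this effect is well inside posterior uncertainty at
  n = 300.
* Item 47's printed replacement prior (0.72) and item 40's printed SD
  (0.08) are not derivable from the stated rules; the package reproduces
  the rules, not the typos.
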