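# priorcfa

Expert-elicited priors for Bayesian confirmatory factor analysis (CFA) of a
prosthesis-satisfaction questionnaire.

When a new patient-reported outcome measure is designed, the item→factor
structure and plausible factor loadings are usually unknown before any
respondent data exist. `priorcfa` implements a pipeline that turns an
*expert item-sorting study* into informed prior distributions for a
seven-factor measurement model, fits that model with an in-package Gibbs
sampler, and quantifies how much the informed priors shape the posterior
relative to a fully uninformed alternative.

The seven latent factors are satisfaction (SAT), feeling of security (FoS),
body schema integration (BSI), support (SUP), socket (SOC), mobility (MOB)
and outer appearance (OUT); experts may also reject an item outright.

## The model

Each retained item *j* is assigned to exactly one factor *f(j)* by strict
plurality of expert votes. The measurement model for respondent *i* is the
linear factor model

```
y_ij = ν_j + λ_j η_{i,f(j)} + ε_ij ,   ε_ij ~ N(0, σ_j²),
```

with 5-point Likert responses treated as continuous and omitted answers
dropped from the likelihood. Priors:

* **loadings** (informed): an item sorted to its factor by *k* of *r*
  experts gets `λ_j ~ N(M, ((1−M)/2)²)` with `M = k/r`; a unanimous item
  (which would give the degenerate N(1, 0)) instead receives a prior whose
  mean is the average of its factor peers' prior means;
* **intercepts**: `ν_j ~ N(0, 100²)` (uninformed, SD 100);
* **error variances**: `σ_j² ~ Inv-Gamma(0.01, 0.01)`;
* **latent values**: `η ~ N(0, 100²)` as printed (SD 100), or variance 1
  in the default `standardized_latent` identification mode.

For the packaged 70-item classification this yields 217 parameters, 70 of
them informed. All full conditionals are conjugate, so the posterior is
sampled by Gibbs; summaries report posterior means, 95% highest density
intervals (HDI), split-R̂ and effective sample size.

Agreement in the sorting study is summarized by Gwet's AC1
(`(Pa − Pe)/(1 − Pe)` with the chance term over all 8 offered categories)
and by per-factor *average shared ratings* — the mean percentage of votes
an item's non-majority factors received.

## Worked example

The raw expert votes were never published; the package ships a synthetic
vote fixture reconstructed from the published prior table (majority counts
`round(M·22)`), which reproduces the published classification and prior set
exactly:

```python
import priorcfa as pc

votes = pc.reconstructed_study_votes()
cls = pc.classify_items(votes)
print(f"retained items: {cls.n_assigned} (of {pc.INITIAL_ITEM_POOL} in the original pool)")

priors = pc.build_prior_set(cls, votes)
led = pc.ledger(priors)
print(f"parameters: {led.n_total} total, {led.n_informed} informed, "
      f"{led.n_uninformed} uninformed")

p = pc.elicit_loading_prior(17, 22)
print(f"17-of-22 loading prior: mean={p.mean:.4f}, sd={p.sd:.4f}")

print(pc.report_priors(priors).loc[[1, 30, 47], ["factor", "label"]])
```

prints

```
retained items: 70 (of 85 in the original pool)
parameters: 217 total, 70 informed, 147 uninformed
17-of-22 loading prior: mean=0.7727, sd=0.1136
        factor        label
item_id
1          SAT  0.91 (0.05)
30         BSI  0.50 (0.25)
47         FoS  0.71 (0.15)
```

Item 1 was sorted to satisfaction by 20 of 22 experts, hence the tight
prior `0.91 (0.05)`; item 30 (11 of 22) gets the diffuse `0.50 (0.25)`;
item 47 is the unanimity-replaced feeling-of-security item.

Fitting the model to synthetic Likert data generated from those prior means
(`n = 300`, 5% omitted answers):

```python
cls = pc.load_published_classification()
model = pc.assemble_model(cls, priors)
true = {j: model.prior("loading", j).mean for j in model.item_ids}
data = pc.simulate_responses(cls, pc.ResponseSimConfig(
    n_respondents=300, true_loadings=true, omission_prob=0.05, seed=1))

est = pc.BayesianCFA(loading_pattern=model.loading_pattern,
                     priors=model.priors, chains=2, n_iter=1500,
                     burn_in=500, random_state=1, save_latent=False).fit(data)
print(est.summary_.loc[["loading[1]", "loading[30]", "loading[47]"],
                       ["mean", "sd", "hdi_low", "hdi_high", "rhat"]].round(3))
```

```
              mean     sd  hdi_low  hdi_high   rhat
parameter
loading[1]   0.869  0.038    0.790     0.939  1.001
loading[30]  0.459  0.068    0.332     0.592  1.001
loading[47]  0.604  0.062    0.483     0.726  1.000
```

Each posterior mean sits near its generating loading with the true value
inside the 95% HDI. `BayesianCFA` is a scikit-learn-style estimator;
`transform()` returns posterior-mean latent scores per respondent.

The same pipeline is available from the shell:

```
priorcfa run --seed 1 --out out/        # fixture votes -> priors -> fit -> comparison
priorcfa agree --votes votes.csv --out report.json --classification cls.csv
priorcfa sim-votes --n-items 70 --concentration 10 --seed 1 --out votes.csv
```

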