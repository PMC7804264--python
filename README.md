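# jaycaching

Bayesian multinomial model comparison for corvid caching experiments:
does a bird's allocation of caches across locations reflect planning for
future food availability, compensation for past food scarcity, or
neither?

The package is built around two experiments with Eurasian jays
(*Garrulus glandarius*). In a nine-day experience phase each bird visited
one of three compartments per day on a three-day rotation while the food
condition alternated on a two-day cycle — two food types (peanut P /
macadamia M) in the **two-food** experiment, food present/absent in the
**food-absence** experiment. On a single test trial the bird could cache
freely in all compartments; the data are per-bird counts of items cached
per compartment (× food type). Because schedules were counterbalanced,
counts are first *semantically sorted* into schedule-relative slots
(K1/K2/K3 = compartment of trials 1-4-7 / 2-5-8 / 3-6-9; f1/f2 = food of
odd/even trials) so that all birds share one frame of predictions.

## Model

Counts for bird *b* are multinomial,
`n_b ~ Multinomial(N_b; r_b)` over the 6 (two-food) or 3 (food-absence)
categories. Candidate models differ in which factors the rates `r_bfc`
depend on:

* **Dependence models** — every combination of (food, bird, compartment)
  dependence; equal-rate constraints otherwise. With a flat Dirichlet
  prior (α = 1) on the free coordinates, the marginal likelihood
  `P(n | model) = ∫ P(n | r) P(r) dr` is available in closed form
  through Dirichlet-multinomial factors on block totals. The 2³ triples
  collapse to 7 distinct models (bird dependence is vacuous when rates
  are fixed at 1/6), and to 3 models in the food-absence layout.
* **Hypothesis models** — fully category-dependent rates with the flat
  prior truncated to an order-constraint region:
  * FPH1 (plan for the next relevant trial): `r_{f1,K1}` maximal among
    all six rates; food-absence FF group: `r_{K1}` maximal.
  * FPH2 (plan for the next three trials): `r_{f1,K2}` lowest in the f1
    block and `r_{f2,K2}` highest in the f2 block; food-absence FF
    group: `r_{K2}` lowest.
  * CCH (compensate past scarcity): the reverse inequalities of FPH2;
    food-absence FF group: `r_{K2}` maximal.
  In the food-absence experiment the Empty-First group's predictions
  mirror the Food-First group's, and both FPH variants coincide there.
  Each hypothesis is tested with bird-dependent and bird-independent
  (shared; per counterbalancing group in the food-absence layout) rates,
  giving 13 models in total for the two-food and 9 for the food-absence
  experiment.

Constrained marginal likelihoods use the encompassing-prior identity

    P(n | constrained) = P(n | unconstrained) · P(R | n) / P(R),

with the prior mass `P(R)` exact by exchangeability (1/6, 1/9, or 1/3)
and the posterior mass `P(R | n)` estimated from Monte-Carlo draws of
the conjugate Dirichlet posterior. Posterior model probabilities follow
from a uniform model prior via log-sum-exp normalisation; any posterior
ratio is a Bayes factor.

## Worked example

```python
from jaycaching import CachingModelComparison

res = CachingModelComparison.from_fixture("table1").fit(
    n_samples=1_000_000, seed=7
)
print(res.summary())
```

```
Bayesian model comparison — experiment: two_food
birds: Washington, Wellington, Caracas, Lisbon, Jerusalem, Quito
MC samples per constrained mass: 1000000; seed: 7
         model hypothesis          method   log_ml mc_se_log posterior
     food+bird                closed_form -31.0873              0.9973
     FPH1-bird       FPH1 encompassing_mc -37.6000    0.0056  0.001481
          food                closed_form -38.6673           0.0005092
food+comp+bird                closed_form -38.7717           0.0004587
     FPH2-bird       FPH2 encompassing_mc -39.6592    0.0084 0.0001888
   FPH1-pooled       FPH1 encompassing_mc -41.7363    0.0011 2.366e-05
      CCH-bird        CCH encompassing_mc -42.6556     0.027 9.436e-06
     food+comp                closed_form -42.7082           8.953e-06
   FPH2-pooled       FPH2 encompassing_mc -42.9630    0.0033 6.939e-06
    CCH-pooled        CCH encompassing_mc -43.4993    0.0043 4.059e-06
         indep                closed_form -49.0981           1.503e-08
          comp                closed_form -52.1770           6.914e-10
     comp+bird                closed_form -53.8477           1.301e-10
```

The winner (`food+bird`, posterior 0.997) lets caching rates depend on
the bird and the food type but **not** on the compartment: the birds had
individual food preferences but spread caches evenly over locations.
The best future-planning variant reaches 0.0015 and the best
compensatory-caching variant 0.00001 — neither hypothesis explains the
counts. `res.hypothesis_max("FPH")`, `res.posterior("food+bird")` and
`res.to_frame()` give programmatic access;
`CachingModelComparison.from_fixture("table1").exclude("Lisbon")`
re-runs the comparison without a bird.

The same engine drives a command line:

```sh
jaycache analyze --fixture table2 --seed 0            # food-absence data
jaycache simulate --config scenario.yaml              # synthetic tables
jaycache recover --config scenario.yaml --replicates 50
jaycache fixtures --name table1                       # dump packaged CSV
```

`jaycaching.simulate` generates synthetic tables under uniform,
bird-food-preference, or hypothesis-constrained rate regimes (effect
strength set by a truncated-Dirichlet concentration) and scores model
recovery, quantifying the design's sensitivity.

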