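# Methods

## Data model and semantic sorting

Each bird contributes one vector of cache counts: six categories
(3 compartments × 2 foods) in the two-food experiment, three in the
food-absence experiment. Counts are treated as a single multinomial
draw per bird with total equal to the number of items the bird cached
on the test trial; totals vary freely between birds (0–30 in the
packaged tables, including one bird that cached nothing).

Schedules were counterbalanced, so physical compartment labels mean
different things for different birds. All inference happens in the
semantically sorted frame: the sequence code (e.g. `BCA-MP`, `ABC-EF`)
is decoded into a bijection from schedule slots K1/K2/K3 to physical
compartments, plus either a food-slot bijection f1/f2 → {P, M} or a
Food-First/Empty-First group label. Sorting is a bijective relabelling
of cells, so per-bird totals, the multiset of cell values, and every
marginal likelihood that does not pool across birds are unchanged by
it. Pooled (bird-independent) models are pooled in the sorted frame,
because that is the frame in which rates are comparable across birds.
Sorted counts are always recomputed from raw counts and the sequence
code at load time; the sorted columns printed in the source tables are
used only as test oracles.

A zero-total bird contributes a factor of one to every marginal
likelihood and is retained in the table rather than dropped: results
are identical either way, and retention keeps the fixture aligned with
the published table.

## Closed-form marginal likelihoods

For a dependence model, group the categories into K dependent blocks of
U cells each (U·K = 6 or 3). Conditional on block totals, counts split
uniformly within blocks; block totals follow a multinomial with the
free rates. With a flat Dirichlet prior on those rates the block-level
integral is Dirichlet-multinomial. Per pooling unit with block totals
`t` (sum T):

    log ml = Σ_birds [ log coeff(n_b) − N_b log U ]
           + Σ_units [ log Γ(K) + Σ_k log t_k! − log Γ(T + K) ]

Bird-dependent models use one unit per bird; bird-independent models
use one unit per table (two-food) or per counterbalancing group
(food-absence). The group pooling is a deliberate design choice: the
sorted-frame constraints of the Food-First and Empty-First groups are
mutually exclusive, so a single shared rate vector could not serve as
the encompassing base of the constrained bird-independent variants; one
shared vector per group is the maximal sharing compatible with the
design, and the unconstrained bird-independent model uses the same
pooling so that every constrained model is an exact truncation of its
base.

Multinomial coefficients are retained in every model (they cancel in
normalisation), so each `log_ml` is a true log probability comparable
to integration oracles; an `include_coefficients=False` path exists
solely so tests can assert the cancellation. All arithmetic is in
natural-log space via `scipy.special.gammaln`; no factorial is ever
evaluated directly, so arbitrarily large counts are safe.

## Constrained models and the encompassing prior

A hypothesis model is the fully category-dependent model with its flat
prior truncated to a region R defined by weak pairwise inequalities.
Truncation multiplies the marginal likelihood by the ratio of posterior
to prior mass of R, so

    log ml = log ml(base) + log P(R | n) − log P(R),

summed over pooling units. This route needs only ordinary Dirichlet
sampling and is unbiased; no MCMC over rates is required.

* Prior masses are exact by exchangeability: the constraint patterns
  decompose into disjoint blocks in which one coordinate is the extreme
  of its block, giving 1/6 (FPH1, two-food), 1/9 (FPH2 and CCH,
  two-food: two independent blocks of three), and 1/3 (every
  food-absence pattern). The detection is structural (hub-extremal star
  blocks); non-star patterns fall back to Monte Carlo with a fixed,
  documented seed.
* Posterior masses are estimated from draws of Dirichlet(1 + counts) of
  the relevant unit, 10⁶ draws per unit by default, in 5·10⁵-draw
  chunks to bound memory. The standard error of each mass propagates to
  `log_ml` by the delta method (`se/p̂`) and sums in quadrature across
  units.
* If an estimated posterior mass is exactly zero while the prior mass
  is positive, the term is replaced by the lower bound
  `log 1/(n_samples+1)` and the result is flagged (`lower_bound=True`)
  with a runtime warning, rather than returning −∞; this matters only
  at sample counts far below the default.

The two-food FPH1 constraint is implemented as "the (f1, K1) rate is
the maximum of all six" — the reading under which its prior mass is
1/6 and which reproduces the published posteriors; the narrower literal
reading (comparisons only against categories differing in both food and
compartment) was checked and rejected during development.

Posterior model probabilities use a uniform prior over the enumerated
models and a log-sum-exp reduction; reported "hypothesis" values are
the maximum posterior over that hypothesis's variants (bird-dependent /
bird-independent, and FPH1/FPH2 for the umbrella FPH), matching how the
headline numbers group the models.

## Reproducibility

A single master seed drives everything: `model_posterior` spawns one
`numpy` `SeedSequence` child per model in enumeration order, so results
are independent of chunk sizes and identical across runs. Model
enumeration order and identifiers are fixed. Fits at the default 10⁶
draws carry Monte-Carlo standard errors on `log_ml` of order 10⁻²-10⁻³
for the packaged data — far below the spacing between models.

## Synthetic data and model recovery

The generator mirrors the multinomial data model exactly: per bird it
draws a rate vector under the chosen regime, then one multinomial count
vector, then maps counts back through a counterbalanced sequence code
(cycling compartment rotations × food orders/groups) so the output is a
valid raw-frame table. Regimes: exact-uniform rates; per-bird food
preference with uniform compartments (the structure of the winning
two-food model); and hypothesis regimes drawing rates from a symmetric
Dirichlet(κ) truncated to the constraint region by rejection sampling
(expected acceptance = the region's prior mass; a capped retry count
turns pathological regions into an informative error). κ controls
effect strength — draws concentrate toward the simplex centre as κ
grows — because the hypotheses themselves predict only orderings, not
magnitudes. Default per-bird totals resample the empirical totals of
the packaged tables so that null-scenario recovery reflects the
original design's sensitivity; recovery experiments then refit the full
model space per replicate and report how often the generating family
(best variant) ranks first and exceeds a posterior threshold, with
binomial standard errors.

What the generator does not emulate: trial-by-trial behaviour during
the experience phase, sequential dependence between caches, satiety or
motivation effects, and bird-to-bird heterogeneity beyond what the rate
regimes express. Passing recovery tests therefore demonstrate the
statistical machinery's ability to identify rate structures of the
assumed multinomial form, not the behavioural realism of that form.

## Numerical and design choices

* Weak inequalities throughout; ties have zero prior mass, so
  strictness is immaterial but is fixed for reproducibility.
* Validation is strict and early: counts must be non-negative integers,
  sequence codes must be permutations with a known suffix, bird ids
  unique; errors name the offending row or token.
* Analysis-scale runs enforce ≥10³ Monte-Carlo draws (CLI); the library
  accepts any positive count for testing.
* Problem sizes in the shipped tests — 10⁶ draws for the headline
  comparisons, 10⁴-10⁵ for property checks, 20-replicate recovery runs
  (20 birds × 100 items for the strong-effect check) — were chosen so
  the full suite completes in well under a minute while keeping every
  Monte-Carlo tolerance at 4 standard errors or better.

## Known limitations

* The bird-independent pooling convention for the food-absence
  experiment (per counterbalancing group) is a modelling decision of
  this package; alternatives (e.g. fully pooled unconstrained rates)
  change the compartment-independent posterior by a few percent.
* Posterior-mass estimation degrades for constraint regions the data
  strongly contradict; the lower-bound flag marks affected fits, and
  raising `n_samples` is the remedy.
* The comparison assumes a single multinomial draw per bird; it cannot
  detect within-trial sequential strategies.
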