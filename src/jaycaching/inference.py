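"""Marginal likelihoods and posterior model probabilities.

Dependence models have closed-form marginal likelihoods.  With a flat
Dirichlet prior on the free rate coordinates, integrating the multinomial
likelihood gives Dirichlet-multinomial factors on the dependent block
totals, while each independent dimension contributes an exact uniform
splitting factor.  Writing ``U`` for the number of cells a dependent
block spreads over and ``K`` for the number of dependent blocks, a bird
with counts ``n`` (total ``N``) contributes

    log coeff(n) - N log U            (uniform within-block split)

plus, per pooling unit, ``log Gamma(K) + sum_k log t_k! - log Gamma(T + K)``
on the block totals ``t`` — evaluated per bird for bird-dependent rates
and on pooled totals otherwise.  The pooling unit for bird-independent
rates is the whole table in the two-food experiment and the FF/EF
counterbalancing group in the food-absence experiment (the semantic
frame gives the two groups opposite hypothesis predictions, so shared
rates are meaningful only within a group).

Hypothesis models are evaluated with the encompassing-prior identity:
truncating the flat prior to a constraint region ``R`` multiplies the
unconstrained marginal likelihood by ``P(R | data) / P(R)``.  The prior
mass ``P(R)`` is analytic (exchangeability); the posterior mass is
estimated by Monte Carlo draws from the conjugate Dirichlet posterior.

All arithmetic is in natural-log space via log-gamma.  Multinomial
coefficients are included everywhere — they cancel in the normalisation
but make each ``log_ml`` a true log probability, directly comparable to
integration oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import FOOD_ABSENCE, GROUPS, TWO_FOOD, ObservationTable, ValidationError
from .models import ConstraintSet, ModelSpec, prior_constraint_mass

__all__ = [
    "MarginalLikelihoodResult",
    "PosteriorTable",
    "log_multinomial_coeff",
    "log_dirichlet_multinomial",
    "log_marginal_unconstrained",
    "estimate_constraint_mass",
    "log_marginal_constrained",
    "log_marginal",
    "model_posterior",
]

DEFAULT_MC_SAMPLES = 1_000_000


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValidationError("empty count vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError(f"counts must be integers, got {counts!r}")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValidationError(f"counts must be non-negative, got {counts!r}")
    return arr


def log_multinomial_coeff(counts) -> float:
    """log of ``N! / prod_i n_i!`` via log-gamma (no overflow)."""
    arr = _check_counts(counts)
    return float(gammaln(arr.sum() + 1) - gammaln(arr + 1).sum())


def log_dirichlet_multinomial(counts, n_categories: int | None = None) -> float:
    """Exact log marginal probability of counts under flat-Dirichlet rates.

    For a flat (``alpha = 1``) symmetric Dirichlet over ``K`` categories
    this is ``log [coeff(n) * (K-1)! * prod n_i! / (N+K-1)!]`` — i.e. the
    Dirichlet-multinomial pmf, which at ``alpha = 1`` is uniform over the
    compositions of ``N`` into ``K`` parts.
    """
    arr = _check_counts(counts)
    K = len(arr) if n_categories is None else n_categories
    if K < 1:
        raise ValidationError(f"n_categories must be >= 1, got {K}")
    if K != len(arr):
        raise ValidationError(f"{len(arr)} counts for {K} categories")
    N = arr.sum()
    return float(
        log_multinomial_coeff(arr)
        + gammaln(K)
        + gammaln(arr + 1).sum()
        - gammaln(N + K)
    )


@dataclass(frozen=True)
class MarginalLikelihoodResult:
    """Log marginal likelihood of one model, with MC metadata if estimated."""

    model_id: str
    log_ml: float
    method: str  # "closed_form" | "encompassing_mc"
    mc_se_log: float | None = None
    n_samples: int | None = None
    seed: int | None = None
    lower_bound: bool = False  # True when an MC mass estimate hit zero

    def __post_init__(self) -> None:
        if self.method not in ("closed_form", "encompassing_mc"):
            raise ValidationError(f"unknown method {self.method!r}")
        if (self.method == "encompassing_mc") != (self.mc_se_log is not None):
            raise ValidationError("mc fields present iff method is encompassing_mc")
        if not math.isfinite(self.log_ml):
            raise ValidationError(f"non-finite log_ml for {self.model_id!r}")


def _block_totals(vec: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Aggregate a sorted count vector onto the model's dependent blocks."""
    if model.experiment == TWO_FOOD:
        a = np.asarray(vec).reshape(3, 2)  # [K slot, f slot]
        if model.food_dependent and model.compartment_dependent:
            return a.ravel()
        if model.food_dependent:
            return a.sum(axis=0)
        if model.compartment_dependent:
            return a.sum(axis=1)
        return np.array([a.sum()])
    if model.compartment_dependent:
        return np.asarray(vec)
    return np.array([np.sum(vec)])


def _dims(model: ModelSpec) -> tuple[int, int]:
    """(K, U): number of dependent blocks, cells per block."""
    total = 6 if model.experiment == TWO_FOOD else 3
    K = 1
    if model.experiment == TWO_FOOD and model.food_dependent:
        K *= 2
    if model.compartment_dependent:
        K *= 3
    return K, total // K


def _pool_units(model: ModelSpec, table: ObservationTable) -> list[list[int]]:
    """Indices of birds sharing one rate vector under bird-independent rates."""
    if model.experiment == FOOD_ABSENCE:
        groups = table.groups()
        return [
            [i for i, g in enumerate(groups) if g == want]
            for want in GROUPS
            if want in groups
        ]
    return [list(range(table.n_birds))]


def _dm_block_term(totals: np.ndarray, K: int) -> float:
    return float(gammaln(K) + gammaln(totals + 1).sum() - gammaln(totals.sum() + K))


def log_marginal_unconstrained(
    model: ModelSpec,
    table: ObservationTable,
    include_coefficients: bool = True,
) -> MarginalLikelihoodResult:
    """Closed-form log marginal likelihood of a dependence model.

    ``include_coefficients=False`` drops every per-bird multinomial
    coefficient; these are model-independent, so posterior probabilities
    are unchanged (exposed to let tests assert exactly that).
    """
    if model.is_constrained:
        raise ValidationError(f"model {model.model_id!r} has a constraint")
    if model.experiment != table.experiment:
        raise ValidationError(
            f"model is for {model.experiment!r}, table is {table.experiment!r}"
        )
    K, U = _dims(model)
    vecs = [np.asarray(v) for v in table.sorted_matrix()]
    total = 0.0
    for v in vecs:
        if include_coefficients:
            total += log_multinomial_coeff(v)
        total -= v.sum() * math.log(U) if U > 1 else 0.0
    if K > 1:
        blocks = [_block_totals(v, model) for v in vecs]
        if model.bird_dependent:
            for t in blocks:
                total += _dm_block_term(t, K)
        else:
            for unit in _pool_units(model, table):
                pooled = np.sum([blocks[i] for i in unit], axis=0)
                total += _dm_block_term(pooled, K)
    return MarginalLikelihoodResult(model.model_id, total, "closed_form")


def estimate_constraint_mass(
    dirichlet_parameters,
    constraint: ConstraintSet,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed=None,
) -> tuple[float, float]:
    """Monte-Carlo probability that a Dirichlet draw satisfies the constraints.

    Returns ``(estimate, binomial standard error)``.  ``seed`` may be an
    int, a ``numpy.random.Generator`` or a ``SeedSequence``.
    """
    alpha = np.asarray(dirichlet_parameters, dtype=float)
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if np.any(alpha <= 0):
        raise ValidationError("Dirichlet parameters must be positive")
    if len(alpha) != constraint.n_categories:
        raise ValidationError(
            f"{len(alpha)} parameters for {constraint.n_categories} categories"
        )
    if not constraint.inequalities:
        return 1.0, 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    remaining = n_samples
    while remaining > 0:  # chunked to bound memory at large n_samples
        chunk = min(remaining, 500_000)
        draws = rng.dirichlet(alpha, size=chunk)
        hits += int(constraint.satisfied(draws).sum())
        remaining -= chunk
    p = hits / n_samples
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return p, se


def _mass_ratio_term(
    alpha: np.ndarray,
    constraint: ConstraintSet,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[float, float, bool]:
    """(log posterior/prior mass ratio, its variance, lower-bound flag)."""
    prior = float(prior_constraint_mass(constraint))
    post, se = estimate_constraint_mass(alpha, constraint, n_samples, rng)
    if post == 0.0:
        warnings.warn(
            "posterior constraint mass estimate is 0 with a non-zero prior "
            f"mass ({prior:.4g}); reporting the lower-bound log(1/(n+1)) — "
            "increase n_samples",
            RuntimeWarning,
            stacklevel=3,
        )
        return math.log(1.0 / (n_samples + 1)) - math.log(prior), 0.0, True
    return math.log(post) - math.log(prior), (se / post) ** 2, False


def log_marginal_constrained(
    model: ModelSpec,
    table: ObservationTable,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed=None,
    include_coefficients: bool = True,
) -> MarginalLikelihoodResult:
    """Encompassing-prior log marginal likelihood of a hypothesis model.

    The constrained model is the fully category-dependent model with its
    flat prior truncated to the constraint region, so

        log_ml = log_ml(unconstrained base) + log P(R | data) - log P(R)

    applied per pooling unit (per bird when bird-dependent, else per
    group/table).  The posterior mass is estimated from Dirichlet draws
    with parameters ``1 + counts``; the standard error of ``log_ml`` is
    propagated by the delta method and summed in quadrature over units.
    """
    if not model.is_constrained:
        raise ValidationError(f"model {model.model_id!r} has no constraint")
    if model.experiment != table.experiment:
        raise ValidationError(
            f"model is for {model.experiment!r}, table is {table.experiment!r}"
        )
    seed_int = seed if isinstance(seed, int) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = ModelSpec(
        "base",
        model.experiment,
        model.food_dependent,
        model.bird_dependent,
        model.compartment_dependent,
    )
    total = log_marginal_unconstrained(base, table, include_coefficients).log_ml
    var = 0.0
    lower_bound = False
    vecs = [np.asarray(v) for v in table.sorted_matrix()]
    groups = table.groups() if model.experiment == FOOD_ABSENCE else None
    if model.bird_dependent:
        units = [([i], groups[i] if groups else None) for i in range(table.n_birds)]
    else:
        units = [
            (idx, table.groups()[idx[0]] if groups else None)
            for idx in _pool_units(model, table)
        ]
    for idx, group in units:
        constraint = model.constraint_for_group(group)
        pooled = np.sum([vecs[i] for i in idx], axis=0)
        term, term_var, lb = _mass_ratio_term(1 + pooled, constraint, n_samples, rng)
        total += term
        var += term_var
        lower_bound = lower_bound or lb
    return MarginalLikelihoodResult(
        model.model_id,
        total,
        "encompassing_mc",
        mc_se_log=math.sqrt(var),
        n_samples=n_samples,
        seed=seed_int,
        lower_bound=lower_bound,
    )


def log_marginal(
    model: ModelSpec,
    table: ObservationTable,
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed=None,
    include_coefficients: bool = True,
) -> MarginalLikelihoodResult:
    """Dispatch to the closed form or the encompassing-prior estimator."""
    if model.is_constrained:
        return log_marginal_constrained(
            model, table, n_samples, seed, include_coefficients
        )
    return log_marginal_unconstrained(model, table, include_coefficients)


@dataclass(frozen=True)
class PosteriorTable:
    """Marginal likelihoods and normalised posterior model probabilities."""

    experiment: str
    entries: tuple[tuple[ModelSpec, MarginalLikelihoodResult, float], ...]
    data_fingerprint: str = ""

    def __post_init__(self) -> None:
        post = np.array([p for _, _, p in self.entries])
        if np.any(post < 0) or abs(post.sum() - 1.0) > 1e-9:
            raise ValidationError("posteriors must be non-negative and sum to 1")

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(m.model_id for m, _, _ in self.entries)

    @property
    def posteriors(self) -> dict[str, float]:
        return {m.model_id: p for m, _, p in self.entries}

    @property
    def log_ml(self) -> dict[str, float]:
        return {m.model_id: r.log_ml for m, r, _ in self.entries}

    def posterior(self, model_id: str) -> float:
        for m, _, p in self.entries:
            if m.model_id == model_id:
                return p
        raise KeyError(model_id)

    def hypothesis_max(self, family: str) -> float:
        """Highest posterior over a hypothesis's variants.

        ``family`` may be a specific hypothesis (``FPH1``/``FPH2``/``CCH``)
        or the umbrella ``FPH`` covering both future-planning predictions.
        """
        best = [
            p
            for m, _, p in self.entries
            if m.hypothesis is not None
            and (m.hypothesis == family or m.hypothesis_family == family)
        ]
        if not best:
            raise KeyError(f"no models for hypothesis {family!r}")
        return max(best)

    def sorted_entries(self):
        return tuple(sorted(self.entries, key=lambda e: -e[2]))


def model_posterior(
    table: ObservationTable,
    models: Sequence[ModelSpec],
    n_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
    include_coefficients: bool = True,
) -> PosteriorTable:
    """Posterior model probabilities under a uniform prior over ``models``.

    Each constrained model receives an independent, reproducible random
    substream spawned from ``seed`` in enumeration order, so a fixed seed
    yields identical results regardless of chunking.
    """
    models = tuple(models)
    if not models:
        raise ValidationError("empty model collection")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(models))
    results = []
    for m, ss in zip(models, streams):
        if m.is_constrained:
            r = log_marginal_constrained(
                m,
                table,
                n_samples,
                np.random.default_rng(ss),
                include_coefficients,
            )
            if seed is not None:
                r = MarginalLikelihoodResult(
                    r.model_id,
                    r.log_ml,
                    r.method,
                    r.mc_se_log,
                    r.n_samples,
                    seed,
                    r.lower_bound,
                )
        else:
            r = log_marginal_unconstrained(m, table, include_coefficients)
        results.append(r)
    logs = np.array([r.log_ml for r in results])
    post = np.exp(logs - logsumexp(logs))
    post /= post.sum()
    return PosteriorTable(
        table.experiment,
        tuple(zip(models, results, post)),
        table.fingerprint(),
    )
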