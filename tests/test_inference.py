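"""Marginal-likelihood machinery against independent oracles.

The closed-form Dirichlet-multinomial is checked against direct numerical
integration over the simplex; unconstrained model marginals are checked
against brute-force Monte-Carlo integration of the likelihood over the
prior; constrained marginals are checked through the encompassing-prior
partition identity and degenerate cases.
"""

import math

import numpy as np
import pytest
from scipy import integrate

from jaycaching import (
    FOOD_ABSENCE,
    TWO_FOOD,
    ConstraintSet,
    ObservationTable,
    BirdRecord,
    ValidationError,
    enumerate_models,
    estimate_constraint_mass,
    log_dirichlet_multinomial,
    log_marginal,
    log_marginal_constrained,
    log_marginal_unconstrained,
    log_multinomial_coeff,
    model_posterior,
)
from jaycaching.models import ModelSpec, build_constraints


def _toy_table(vectors, experiment=TWO_FOOD, groups=None):
    """Build a table whose *sorted* counts equal ``vectors``."""
    birds = []
    for i, vec in enumerate(vectors):
        if experiment == TWO_FOOD:
            code = "ABC-PM"  # identity assignment: raw frame == sorted frame
            raw = {
                (c, f): int(v)
                for (c, f), v in zip(
                    ((c, f) for c in "ABC" for f in "PM"), vec
                )
            }
        else:
            code = f"ABC-{groups[i]}"
            raw = dict(zip("ABC", map(int, vec)))
        birds.append(BirdRecord(f"b{i}", code, experiment, raw))
    return ObservationTable(experiment, tuple(birds))


class TestLogMultinomialCoeff:
    def test_exact_values(self):
        assert log_multinomial_coeff([0, 0, 0, 0, 0, 0]) == 0.0
        assert log_multinomial_coeff([2, 1]) == pytest.approx(math.log(3))

    def test_against_integer_arithmetic(self):
        # the largest per-bird count vector in the packaged data
        counts = [8, 0, 11, 0, 9, 0]
        exact = math.factorial(28) // (
            math.factorial(8) * math.factorial(11) * math.factorial(9)
        )
        assert log_multinomial_coeff(counts) == pytest.approx(
            math.log(exact), abs=1e-10
        )

    def test_rejects_bad_counts(self):
        with pytest.raises(ValidationError):
            log_multinomial_coeff([-1, 2])
        with pytest.raises(ValidationError):
            log_multinomial_coeff([1.5, 2])


def _quadrature_log_dm(counts):
    """Numerically integrate the multinomial likelihood over a flat Dirichlet.

    Independent oracle for K in {2, 3}: the flat Dirichlet density is
    (K-1)! on the simplex; coordinates are integrated explicitly.
    """
    counts = list(counts)
    coeff = math.exp(log_multinomial_coeff(counts))
    if len(counts) == 2:
        a, b = counts
        val, _ = integrate.quad(lambda r: r**a * (1 - r) ** b, 0, 1)
        return math.log(coeff * 1.0 * val)
    a, b, c = counts
    val, _ = integrate.dblquad(
        lambda y, x: x**a * y**b * (1 - x - y) ** c,
        0,
        1,
        0,
        lambda x: 1 - x,
        epsabs=1e-13,
    )
    return math.log(coeff * 2.0 * val)


class TestDirichletMultinomial:
    def test_trivial_cases(self):
        assert log_dirichlet_multinomial([0, 0, 0]) == 0.0
        assert log_dirichlet_multinomial([0, 1, 0, 0, 0, 0]) == pytest.approx(
            math.log(1 / 6)
        )
        assert log_dirichlet_multinomial([2, 1]) == pytest.approx(math.log(1 / 4))

    @pytest.mark.parametrize("K", [2, 3])
    def test_matches_simplex_quadrature(self, K):
        rng = np.random.default_rng(5)
        for _ in range(12):
            total = rng.integers(0, 7)
            counts = rng.multinomial(total, np.ones(K) / K)
            assert log_dirichlet_multinomial(counts) == pytest.approx(
                _quadrature_log_dm(counts), abs=1e-8
            )

    def test_composition_uniformity(self):
        # at alpha=1 every composition of N into K parts is equally likely
        assert log_dirichlet_multinomial([4, 0, 0]) == pytest.approx(
            log_dirichlet_multinomial([2, 1, 1])
        )

    def test_rejects_bad_category_count(self):
        with pytest.raises(ValidationError):
            log_dirichlet_multinomial([1, 2], n_categories=0)


def _model(experiment, food_dep, bird_dep, comp_dep):
    return ModelSpec("m", experiment, food_dep, bird_dep, comp_dep)


class TestUnconstrainedMarginals:
    def test_fully_independent_model_is_forced(self, table1):
        m = _model(TWO_FOOD, False, False, False)
        expected = sum(
            log_multinomial_coeff(v) - sum(v) * math.log(6)
            for v in table1.sorted_matrix()
        )
        assert log_marginal_unconstrained(m, table1).log_ml == pytest.approx(expected)

    def test_single_item_single_bird_full_model(self):
        # one cached item: the flat prior puts 1/6 on each category
        table = _toy_table([[0, 0, 0, 0, 0, 1]])
        m = _model(TWO_FOOD, True, True, True)
        assert log_marginal_unconstrained(m, table).log_ml == pytest.approx(
            math.log(1 / 6)
        )

    def test_all_zero_table_gives_log_one(self, table1):
        table = _toy_table([[0] * 6, [0] * 6])
        for m in enumerate_models(TWO_FOOD, include_constrained=False):
            assert log_marginal_unconstrained(m, table).log_ml == 0.0

    @pytest.mark.parametrize(
        "food_dep,bird_dep,comp_dep",
        [
            (True, True, False),
            (False, True, True),
            (True, False, True),
            (True, True, True),
            (False, False, True),
            (True, False, False),
        ],
    )
    def test_against_monte_carlo_prior_integration(self, food_dep, bird_dep, comp_dep):
        """Closed form vs brute-force E_prior[likelihood] on a tiny table."""
        table = _toy_table([[2, 0, 1, 0, 0, 1], [0, 1, 0, 2, 0, 0]])
        m = _model(TWO_FOOD, food_dep, bird_dep, comp_dep)
        closed = log_marginal_unconstrained(m, table).log_ml

        rng = np.random.default_rng(17)
        n_mc = 400_000
        K = (2 if food_dep else 1) * (3 if comp_dep else 1)
        vecs = [np.array(v) for v in table.sorted_matrix()]

        def expand(block_rates):
            # block rates -> full 6-vector of per-cell rates
            full = np.empty((block_rates.shape[0], 6))
            for cell in range(6):
                k, f = divmod(cell, 2)
                bi = 0
                if food_dep and comp_dep:
                    bi = cell
                elif food_dep:
                    bi = f
                elif comp_dep:
                    bi = k
                full[:, cell] = block_rates[:, bi] / (6 // K)
            return full

        loglik = np.zeros(n_mc)
        for b, v in enumerate(vecs):
            r = rng.dirichlet(np.ones(K), size=n_mc) if (bird_dep or b == 0) else r
            cell_rates = expand(r) if K > 1 else np.full((n_mc, 6), 1 / 6)
            loglik += log_multinomial_coeff(v) + (np.log(cell_rates) * v).sum(axis=1)
        mc = np.log(np.exp(loglik - loglik.max()).mean()) + loglik.max()
        assert closed == pytest.approx(mc, abs=0.02)

    def test_rejects_constrained_model(self, table1):
        m = enumerate_models(TWO_FOOD)[-1]
        assert m.is_constrained
        with pytest.raises(ValidationError):
            log_marginal_unconstrained(m, table1)

    def test_rejects_experiment_mismatch(self, table2):
        with pytest.raises(ValidationError):
            log_marginal_unconstrained(_model(TWO_FOOD, True, True, True), table2)


class TestEstimateConstraintMass:
    def test_empty_constraint(self):
        p, se = estimate_constraint_mass(np.ones(3), ConstraintSet(3, ()), 100, seed=0)
        assert (p, se) == (1.0, 0.0)

    def test_flat_fph1_mass(self):
        cs = build_constraints("FPH1", TWO_FOOD)
        p, se = estimate_constraint_mass(np.ones(6), cs, 300_000, seed=3)
        assert abs(p - 1 / 6) < 4 * se

    def test_flat_k2_top_mass(self):
        cs = ConstraintSet(3, ((1, ">=", 0), (1, ">=", 2)))
        p, se = estimate_constraint_mass(np.ones(3), cs, 300_000, seed=4)
        assert abs(p - 1 / 3) < 4 * se

    def test_reproducible_under_seed(self):
        cs = build_constraints("FPH1", TWO_FOOD)
        a = estimate_constraint_mass(np.ones(6), cs, 10_000, seed=9)
        b = estimate_constraint_mass(np.ones(6), cs, 10_000, seed=9)
        assert a == b

    def test_rejects_bad_inputs(self):
        cs = ConstraintSet(3, ((0, ">=", 1),))
        with pytest.raises(ValidationError):
            estimate_constraint_mass(np.ones(3), cs, 0)
        with pytest.raises(ValidationError):
            estimate_constraint_mass([1.0, -1.0, 1.0], cs, 10)


class TestConstrainedMarginals:
    def test_empty_constraint_equals_unconstrained_full_model(self, table1):
        free = ModelSpec(
            "free", TWO_FOOD, True, True, True, ConstraintSet(6, ()), "FPH1"
        )
        res = log_marginal_constrained(free, table1, n_samples=10, seed=0)
        full = log_marginal_unconstrained(_model(TWO_FOOD, True, True, True), table1)
        assert res.log_ml == pytest.approx(full.log_ml)
        assert res.mc_se_log == 0.0

    def test_all_zero_birds_give_log_one(self):
        # no data: posterior mass equals prior mass, the ratio cancels
        table = _toy_table([[0] * 6, [0] * 6])
        m = [x for x in enumerate_models(TWO_FOOD) if x.model_id == "CCH-bird"][0]
        res = log_marginal_constrained(m, table, n_samples=200_000, seed=2)
        assert res.log_ml == pytest.approx(0.0, abs=6 * res.mc_se_log)

    def test_partition_identity_food_absence(self):
        """Sum over 'Kj largest' classes of mass-weighted constrained MLs
        recovers the unconstrained full model's marginal likelihood (the
        classes partition each rate simplex up to measure zero)."""
        table = _toy_table([[4, 1, 2]], experiment=FOOD_ABSENCE, groups=["FF"])
        full = log_marginal_unconstrained(
            ModelSpec("full", FOOD_ABSENCE, None, True, True), table
        ).log_ml
        parts = []
        ses = []
        for j in range(3):
            cs = ConstraintSet(3, ((j, ">=", (j + 1) % 3), (j, ">=", (j + 2) % 3)))
            m = ModelSpec(
                f"class{j}",
                FOOD_ABSENCE,
                None,
                True,
                True,
                {"FF": cs, "EF": cs},
                "CCH",
            )
            r = log_marginal_constrained(m, table, n_samples=400_000, seed=j)
            parts.append(math.log(1 / 3) + r.log_ml)
            ses.append(r.mc_se_log)
        total = np.logaddexp.reduce(parts)
        assert total == pytest.approx(full, abs=4 * max(ses))

    def test_zero_posterior_mass_flagged_not_minus_inf(self):
        # data overwhelmingly against the constraint + tiny sample count
        table = _toy_table([[0, 60, 0]], experiment=FOOD_ABSENCE, groups=["FF"])
        m = [x for x in enumerate_models(FOOD_ABSENCE) if x.model_id == "FPH1-bird"][0]
        with pytest.warns(RuntimeWarning, match="lower-bound"):
            res = log_marginal_constrained(m, table, n_samples=20, seed=1)
        assert res.lower_bound
        assert math.isfinite(res.log_ml)


class TestModelPosterior:
    def test_posteriors_sum_to_one_and_match_bayes_factors(self, table1):
        models = enumerate_models(TWO_FOOD)
        post = model_posterior(table1, models, n_samples=20_000, seed=6)
        probs = np.array(list(post.posteriors.values()))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        # posterior ratios equal marginal-likelihood ratios (uniform model prior)
        ids = post.model_ids
        for a, b in [(ids[0], ids[3]), (ids[2], ids[8])]:
            bf = math.exp(post.log_ml[a] - post.log_ml[b])
            assert post.posterior(a) / post.posterior(b) == pytest.approx(bf, rel=1e-9)

    def test_coefficients_cancel_in_normalisation(self, table2):
        models = enumerate_models(FOOD_ABSENCE)
        with_c = model_posterior(table2, models, n_samples=20_000, seed=8)
        without = model_posterior(
            table2, models, n_samples=20_000, seed=8, include_coefficients=False
        )
        for mid in with_c.model_ids:
            assert with_c.posterior(mid) == pytest.approx(
                without.posterior(mid), rel=1e-9
            )

    def test_deterministic_under_seed(self, table2):
        models = enumerate_models(FOOD_ABSENCE)
        a = model_posterior(table2, models, n_samples=5_000, seed=3)
        b = model_posterior(table2, models, n_samples=5_000, seed=3)
        assert a.log_ml == b.log_ml

    def test_single_model_collection(self, table1):
        only = enumerate_models(TWO_FOOD, include_constrained=False)[:1]
        post = model_posterior(table1, only)
        assert post.posterior(only[0].model_id) == pytest.approx(1.0)

    def test_empty_collection_rejected(self, table1):
        with pytest.raises(ValidationError):
            model_posterior(table1, [])

    def test_concentrating_caches_in_k1f1_favours_fph1(self):
        """Regression-style monotonicity: loading (f1, K1) raises FPH1."""
        models = enumerate_models(TWO_FOOD)
        base = [[3, 2, 2, 2, 2, 2]] * 3
        loaded = [[9, 2, 2, 2, 2, 2]] * 3
        p_base = model_posterior(
            _toy_table(base), models, n_samples=30_000, seed=12
        ).hypothesis_max("FPH1")
        p_loaded = model_posterior(
            _toy_table(loaded), models, n_samples=30_000, seed=12
        ).hypothesis_max("FPH1")
        assert p_loaded > p_base
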