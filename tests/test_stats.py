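"""Rank statistics against brute-force oracles; OLS and backward elimination."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sleepssm import (
    backward_stepwise,
    mann_whitney,
    ols_fit,
    shapiro_wilk_gate,
    spearman,
)
from sleepssm.errors import ValidationError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_u_and_p(x, y):
    """U of x by pair counting; exact two-sided p by full enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # tie-free by construction
    n1 = len(x)
    null = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(combo)].sum()
        null.append(r1 - n1 * (n1 + 1) / 2)
    null = np.asarray(null)
    p = 2 * min(np.mean(null <= u_obs), np.mean(null >= u_obs))
    return u_obs, min(p, 1.0)


def spearman_d2(x, y):
    """Closed-form rho = 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_stat == 0
        assert res.rank_biserial == -1.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_multisets_zero_effect(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.rank_biserial == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_enumeration_on_random_samples(self, rng):
        for _ in range(300):
            n1, n2 = rng.integers(1, 9, size=2)
            vals = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = vals[:n1], vals[n1:]
            res = mann_whitney(x, y)
            u_exp, p_exp = brute_u_and_p(x, y)
            assert res.u_stat == u_exp
            assert res.p_two_sided == pytest.approx(p_exp, abs=1e-12)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 10)))
            y = rng.normal(size=int(rng.integers(2, 10)))
            a, b = mann_whitney(x, y), mann_whitney(y, x)
            assert a.u_stat + b.u_stat == pytest.approx(a.n1 * a.n2)
            assert a.rank_biserial == pytest.approx(-b.rank_biserial)
            assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_exact_test_size_at_nominal_level(self):
        # exhaustive null for n1=n2=5: P(p <= 0.05) under H0 never exceeds 0.05
        values = np.arange(10, dtype=float)
        rejections = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            x = values[list(combo)]
            y = values[[i for i in range(10) if i not in combo]]
            if mann_whitney(x, y).p_two_sided <= 0.05:
                rejections += 1
            total += 1
        assert rejections / total <= 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_pair_is_one(self, rng):
        x = np.sort(rng.normal(size=12))
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_small_example_matches_d2_formula(self):
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)

    def test_matches_d2_formula_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.permutation(1000)[:n].astype(float)
            y = rng.permutation(1000)[:n].astype(float)
            assert spearman(x, y).rho == pytest.approx(spearman_d2(x, y), abs=1e-12)

    def test_exact_permutation_p_n5(self, rng):
        # oracle: exhaustive 5! permutation distribution of rho
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        obs = spearman(x, y)
        rhos = [spearman_d2(x, y[list(p)]) for p in itertools.permutations(range(5))]
        p_exp = np.mean(np.abs(rhos) >= abs(obs.rho) - 1e-12)
        assert obs.method == "exact-permutation"
        assert obs.p_two_sided == pytest.approx(p_exp, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7).rho == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Shapiro-Wilk gate
# ---------------------------------------------------------------------------

class TestShapiroGate:
    def test_uniform_flagged_non_normal(self, rng):
        out = shapiro_wilk_gate({"u": rng.uniform(size=2000)})
        assert out["u"] == "non-normal"

    def test_normal_level(self):
        # level check: the gate passes normal data in at least 94% of replicates
        flags = []
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            flags.append(shapiro_wilk_gate({"g": r.normal(size=200)})["g"])
        assert np.mean([f == "normal" for f in flags]) >= 0.94

    def test_degenerate_samples_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = shapiro_wilk_gate({"c": [2.0, 2.0, 2.0, 2.0], "tiny": [1.0, 2.0]})
        assert out == {"c": "skipped", "tiny": "skipped"}


# ---------------------------------------------------------------------------
# OLS and backward elimination
# ---------------------------------------------------------------------------

class TestOLS:
    def test_exact_interpolation(self, rng):
        x = rng.normal(size=30)
        fit = ols_fit(pd.DataFrame({"x": x}), 1.0 + 2.0 * x)
        assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_prediction_at_means_is_mean_response(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        fit = ols_fit(X, y)
        pred = fit.coefficients["intercept"] + sum(
            fit.coefficients[c] * X[c].mean() for c in X.columns
        )
        assert pred == pytest.approx(y.mean(), abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
            y = rng.normal(size=50)
            fit = ols_fit(X, y)
            A = np.column_stack([np.ones(50), X.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            got = [fit.coefficients["intercept"]] + [fit.coefficients[c] for c in X.columns]
            np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_rank_deficiency_names_collinear_terms(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.raises(ValidationError, match="b"):
            ols_fit(X, rng.normal(size=30))

    def test_too_few_observations_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            ols_fit(X, rng.normal(size=4))


class TestBackwardStepwise:
    def make_data(self, rng, n=200):
        X = pd.DataFrame(
            {
                "signal": rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        y = 1.0 + 3.0 * X["signal"] + rng.normal(size=n)
        return X, y

    def test_keeps_signal_drops_noise(self, rng):
        hits = 0
        for _ in range(50):
            X, y = self.make_data(rng)
            fit = backward_stepwise(X, y)
            if set(fit.coefficients) == {"intercept", "signal"}:
                hits += 1
        assert hits / 50 >= 0.95

    def test_all_noise_reduces_to_intercept(self, rng):
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
            y = rng.normal(size=150)
            fit = backward_stepwise(X, y)
            if set(fit.coefficients) == {"intercept"}:
                hits += 1
        assert hits / 50 >= 0.8

    def test_perfect_single_predictor_retained(self, rng):
        x = rng.normal(size=50)
        fit = backward_stepwise(pd.DataFrame({"x": x}), 2.0 * x - 1.0)
        assert "x" in fit.coefficients
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_adj_r2_of_submodel_never_exceeds_full_r2(self, rng):
        X, y = self.make_data(rng, n=80)
        full = ols_fit(X, y)
        final = backward_stepwise(X, y, criterion="adj_r2")
        assert final.adj_r2 <= full.r2 + 1e-12

    def test_drop_log_records_eliminations(self, rng):
        X, y = self.make_data(rng)
        fit = backward_stepwise(X, y)
        assert set(fit.drop_log) <= {"noise1", "noise2"}
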