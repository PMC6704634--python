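"""Step 2: per-gene fits, BIC marginals, posteriors, classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from bgsc import (
    ExpressionProfile,
    Priors,
    bic_log_marginal,
    classify_gene,
    classify_matrix,
    default_priors,
    fit_group,
    posteriors,
)

finite_floats = st.floats(-20, 20, allow_nan=False, allow_infinity=False)
profiles6 = st.lists(finite_floats, min_size=6, max_size=6).map(np.array)


def brute_force_classify(x, patterns, priors):
    """Independent route: estimators, densities and Bayes applied literally."""
    marginals = {}
    n = len(x)
    for p in patterns:
        g = np.asarray(p.indicator, bool)
        if not g.any():
            mu = sum(x) / n
            s2 = sum((xi - mu) ** 2 for xi in x) / (n - 1)
            means = [mu] * n
            k = 2
        else:
            mu0 = x[~g].mean()
            mu1 = x[g].mean()
            s2 = (sum((xi - mu0) ** 2 for xi in x[~g])
                  + sum((xi - mu1) ** 2 for xi in x[g])) / (n - 2)
            means = [mu1 if gi else mu0 for gi in g]
            k = 3
        lik = math.prod(
            stats.norm.pdf(xi, mi, math.sqrt(s2)) for xi, mi in zip(x, means)
        )
        marginals[p.label] = lik / math.sqrt(n) ** k
    num = {z: marginals[z] * priors[z] for z in marginals}
    total = sum(num.values())
    post = {z: v / total for z, v in num.items()}
    return max(post, key=post.get), post


class TestFitGroup:
    def test_two_class_estimates(self, pattern_by_label):
        """Class means and pooled variance for an alternating pattern."""
        fit = fit_group(
            ExpressionProfile("g", np.array([1, 3, 1, 3, 1, 5])),
            pattern_by_label["b"],
        )
        assert fit.mu0 == pytest.approx(1.0)
        assert fit.mu1 == pytest.approx(11 / 3)
        assert fit.sigma2 == pytest.approx(2 / 3)
        assert fit.n_params == 3

    def test_single_mean_estimates(self, pattern_by_label):
        fit = fit_group(
            ExpressionProfile("g", np.array([0, 1, 0, 1, 0, 1])),
            pattern_by_label["a"],
        )
        assert fit.mu0 == pytest.approx(0.5)
        assert fit.mu1 is None
        assert fit.sigma2 == pytest.approx(0.3)
        assert fit.n_params == 2

    def test_constant_profile_is_degenerate(self, pattern_by_label):
        fit = fit_group(
            ExpressionProfile("g", np.full(6, 2.0)), pattern_by_label["a"]
        )
        assert fit.mu0 == pytest.approx(2.0)
        assert fit.sigma2 == 0.0
        assert fit.degenerate
        assert np.isfinite(fit.log_likelihood)

    def test_length_mismatch_raises(self, pattern_by_label):
        with pytest.raises(ValueError, match="expects"):
            fit_group(
                ExpressionProfile("g", np.zeros(4)), pattern_by_label["b"]
            )

    @settings(deadline=None, derandomize=True)
    @given(profiles6)
    def test_means_maximize_likelihood(self, pattern_by_label, x):
        """Closed-form class means match a numeric likelihood maximizer.

        The residual sum of squares around (mu0, mu1) is minimized numerically
        (equivalent to maximizing the profile likelihood over the means).
        """
        for label in ("a", "b", "c", "d"):
            pattern = pattern_by_label[label]
            g = np.asarray(pattern.indicator, bool)
            fit = fit_group(ExpressionProfile("g", x), pattern)
            if label == "a":
                res = optimize.minimize_scalar(
                    lambda m: np.sum((x - m) ** 2), bounds=(-25, 25),
                    method="bounded", options={"xatol": 1e-10},
                )
                assert fit.mu0 == pytest.approx(res.x, abs=1e-6)
            else:
                res = optimize.minimize(
                    lambda m: np.sum((x - np.where(g, m[1], m[0])) ** 2),
                    x0=[0.0, 0.0], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
                )
                assert fit.mu0 == pytest.approx(res.x[0], abs=1e-6)
                assert fit.mu1 == pytest.approx(res.x[1], abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(profiles6)
    def test_null_fit_permutation_invariant(self, pattern_by_label, x):
        fit = fit_group(ExpressionProfile("g", x), pattern_by_label["a"])
        perm = np.random.default_rng(0).permutation(x)
        fit_p = fit_group(ExpressionProfile("g", perm), pattern_by_label["a"])
        assert fit_p.mu0 == pytest.approx(fit.mu0)
        assert fit_p.sigma2 == pytest.approx(fit.sigma2, abs=1e-12)
        assert fit_p.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-9)

    def test_within_class_permutation_invariance(self, pattern_by_label):
        """Group b only sees the two class multisets {x1,x3,x5} / {x2,x4,x6}."""
        x = np.array([0.3, 2.1, -0.4, 1.8, 0.9, 2.6])
        base = fit_group(ExpressionProfile("g", x), pattern_by_label["b"])
        for p0 in itertools.permutations([0, 2, 4]):
            for p1 in itertools.permutations([1, 3, 5]):
                order = [p0[0], p1[0], p0[1], p1[1], p0[2], p1[2]]
                fit = fit_group(
                    ExpressionProfile("g", x[order]), pattern_by_label["b"]
                )
                assert fit.log_likelihood == pytest.approx(
                    base.log_likelihood, abs=1e-9
                )

    def test_likelihood_decreases_with_scatter(self, pattern_by_label):
        """Widening within-class spread at fixed class means lowers the fit."""
        pattern = pattern_by_label["c"]  # classes {x1,x3,x5,x6} vs {x2,x4}
        lls = []
        for eps in (0.05, 0.1, 0.2, 0.4, 0.8):
            x = np.array([-eps, 2 - eps, eps, 2 + eps, -eps, eps])
            fit = fit_group(ExpressionProfile("g", x), pattern)
            assert fit.mu0 == pytest.approx(0.0)
            assert fit.mu1 == pytest.approx(2.0)
            lls.append(fit.log_likelihood)
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestBicMarginal:
    @pytest.mark.parametrize(
        "lik,k,expected",
        [(4.22, 3, 0.287), (0.035, 3, 0.002), (0.004, 2, 0.001), (0.012, 3, 0.001)],
    )
    def test_worked_example_marginals(self, lik, k, expected):
        """Printed maximized likelihoods map to the reported marginals."""
        lm = bic_log_marginal(math.log(lik), k, 6)
        assert round(math.exp(lm), 3) == expected

    def test_zero_params_is_identity(self):
        assert bic_log_marginal(-1.234, 0, 6) == -1.234

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.integers(0, 5), st.integers(1, 100))
    def test_algebraic_identity(self, ll, k, n):
        """exp(log marginal) equals likelihood times n^(-k/2) exactly."""
        lm = bic_log_marginal(ll, k, n)
        assert math.exp(lm) == pytest.approx(
            math.exp(ll) * n ** (-k / 2), rel=1e-12
        )


class TestPosteriors:
    def test_worked_example_posteriors(self, egfr_priors):
        """Full-precision marginals with (0.7,0.1,0.1,0.1) priors."""
        liks = {"a": 0.004, "b": 0.035, "c": 4.22, "d": 0.012}
        k = {"a": 2, "b": 3, "c": 3, "d": 3}
        lm = {z: bic_log_marginal(math.log(l), k[z], 6) for z, l in liks.items()}
        post = posteriors(lm, egfr_priors)
        assert {z: round(p, 3) for z, p in post.items()} == {
            "a": 0.016, "b": 0.008, "c": 0.973, "d": 0.003
        }

    def test_uniform_case(self):
        pri = Priors({z: 0.25 for z in "abcd"})
        post = posteriors({z: -1.0 for z in "abcd"}, pri)
        assert all(p == pytest.approx(0.25) for p in post.values())

    def test_degenerate_prior_dominates(self):
        pri = Priors({"a": 1.0, "b": 0.0})
        post = posteriors({"a": -100.0, "b": 50.0}, pri)
        assert post["a"] == pytest.approx(1.0)
        assert post["b"] == 0.0

    def test_mismatched_groups_rejected(self, egfr_priors):
        with pytest.raises(ValueError):
            posteriors({"a": 0.0, "b": 0.0}, egfr_priors)

    def test_all_zero_priors_rejected(self):
        with pytest.raises(ValueError):
            Priors({"a": 0.0, "b": 0.0})

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-300, 300), min_size=4, max_size=4))
    def test_normalization_and_overflow_safety(self, egfr_priors, lms):
        post = posteriors(dict(zip("abcd", lms)), egfr_priors)
        assert abs(sum(post.values()) - 1.0) < 1e-9
        assert all(0.0 <= p <= 1.0 for p in post.values())


class TestClassifyGene:
    def test_against_brute_force(self, egfr_patterns, egfr_priors):
        """Full pipeline agrees with a literal reimplementation."""
        rng = np.random.default_rng(123)
        cases = [np.array([0, 5, 0.1, 0, -0.1, 0.05])] + [
            rng.normal(7, 1, 6) + rng.choice([0, 2]) for _ in range(30)
        ]
        for x in cases:
            got = classify_gene(
                ExpressionProfile("g", x), egfr_patterns, egfr_priors
            )
            exp_group, exp_post = brute_force_classify(x, egfr_patterns, egfr_priors)
            assert got.assigned_group == exp_group
            for z in "abcd":
                assert got.fits[z].posterior == pytest.approx(exp_post[z], abs=1e-9)

    def test_strong_isoform_I_profile_goes_to_d(self, egfr_patterns, egfr_priors):
        x = np.array([0, 5, 0.1, 0, -0.1, 0.05])
        got = classify_gene(ExpressionProfile("g", x), egfr_patterns, egfr_priors)
        assert got.assigned_group == "d"

    def test_constant_profile_convention(self, egfr_patterns, egfr_priors):
        got = classify_gene(
            ExpressionProfile("flat", np.full(6, 3.0)), egfr_patterns, egfr_priors
        )
        assert got.assigned_group == "a"
        assert got.degenerate_flag
        assert got.fits["a"].posterior == 1.0
        assert all(got.fits[z].posterior == 0.0 for z in "bcd")

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="badgene"):
            ExpressionProfile("badgene", np.array([1, 2, np.nan, 4, 5, 6]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(profiles6)
    def test_posteriors_sum_to_one(self, egfr_patterns, egfr_priors, x):
        got = classify_gene(ExpressionProfile("g", x), egfr_patterns, egfr_priors)
        assert abs(sum(got.posteriors.values()) - 1.0) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(profiles6)
    def test_uniform_priors_assign_argmax_marginal(self, egfr_patterns, x):
        pri = Priors({z: 0.25 for z in "abcd"})
        got = classify_gene(ExpressionProfile("g", x), egfr_patterns, pri)
        if not got.degenerate_flag:
            best = max(got.fits.values(), key=lambda f: f.log_marginal)
            assert got.fits[got.assigned_group].log_marginal == pytest.approx(
                best.log_marginal
            )


class TestClassifyMatrix:
    def test_matches_rowwise_calls_and_order(self, egfr_patterns, egfr_priors):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.normal(7, 1, (5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"x{j+1}" for j in range(6)],
        )
        out = classify_matrix(mat, egfr_patterns, egfr_priors)
        assert [c.gene_id for c in out] == list(mat.index)
        for gid, c in zip(mat.index, out):
            single = classify_gene(
                ExpressionProfile(gid, mat.loc[gid].to_numpy()),
                egfr_patterns, egfr_priors,
            )
            assert c.assigned_group == single.assigned_group
            assert c.posteriors == pytest.approx(single.posteriors)

    def test_row_permutation_invariance(self, egfr_patterns, egfr_priors):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(
            rng.normal(7, 1, (8, 6)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"x{j+1}" for j in range(6)],
        )
        fwd = {c.gene_id: c.assigned_group
               for c in classify_matrix(mat, egfr_patterns, egfr_priors)}
        rev = {c.gene_id: c.assigned_group
               for c in classify_matrix(mat.iloc[::-1], egfr_patterns, egfr_priors)}
        assert fwd == rev

    def test_duplicate_ids_get_suffixes(self, egfr_patterns, egfr_priors):
        mat = pd.DataFrame(
            np.random.default_rng(1).normal(0, 1, (3, 6)),
            index=["dup", "dup", "other"],
            columns=[f"x{j+1}" for j in range(6)],
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out = classify_matrix(mat, egfr_patterns, egfr_priors)
        assert [c.gene_id for c in out] == ["dup", "dup.1", "other"]

    def test_empty_matrix_rejected(self, egfr_patterns, egfr_priors):
        mat = pd.DataFrame(columns=[f"x{j+1}" for j in range(6)])
        with pytest.raises(ValueError):
            classify_matrix(mat, egfr_patterns, egfr_priors)
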