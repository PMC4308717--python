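"""DNR statistic, mixture thresholding, and the companion expression analyses."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from xconstraint import expression
from xconstraint.expression import (anova_decomposition, antisense_ratio,
                                    classify_constraint, compute_dnr,
                                    cross_species_corr, expression_breadth,
                                    fit_dnr_mixture, localization_stats,
                                    match_by_expression, mixture_intersection,
                                    output_fraction)
from xconstraint.io_core import ExpressionMatrix, OrthologyMap


def em(values, species="s"):
    return ExpressionMatrix(values=pd.DataFrame(values), species=species)


def orth(ids1, ids2):
    return OrthologyMap(pairs=pd.DataFrame({"id1": ids1, "id2": ids2}))


def dnr_of(vals1, vals2):
    m1 = em({"s%d" % i: [v] for i, v in enumerate(vals1)})
    m2 = em({"t%d" % i: [v] for i, v in enumerate(vals2)})
    m1.values.index = ["g"]
    m2.values.index = ["h"]
    return compute_dnr(m1, m2, orth(["g"], ["h"]))["dnr"].iloc[0]


class TestComputeDnr:
    def test_log_ratio_across_species(self):
        assert dnr_of([10.0, 100.0], [1.0, 50.0]) == pytest.approx(2.0)

    def test_constant_expression_is_zero(self):
        assert dnr_of([5.0, 5.0], [5.0, 5.0]) == 0.0

    def test_single_detection_in_one_species_undefined(self):
        assert np.isnan(dnr_of([10.0, 0.0, 0.0], [3.0, 4.0]))

    def test_missing_orthologue_undefined(self):
        m1 = em({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        m1.values.index = ["g1", "g2"]
        m2 = em({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        m2.values.index = ["h1", "h2"]
        table = compute_dnr(m1, m2, orth(["g1", "gX"], ["h1", "h2"]))
        assert np.isnan(table["dnr"].iloc[1])
        assert not np.isnan(table["dnr"].iloc[0])

    def _brute_force(self, a1, a2):
        out = []
        for i in range(a1.shape[0]):
            v1 = [v for v in a1[i] if v > 0]
            v2 = [v for v in a2[i] if v > 0]
            if len(v1) < 2 or len(v2) < 2:
                out.append(np.nan)
            else:
                allv = v1 + v2
                out.append(np.log10(max(allv)) - np.log10(min(allv)))
        return np.array(out)

    def test_matches_bruteforce_scan_on_random_matrices(self, rng):
        for _ in range(100):
            g, s1, s2 = rng.integers(1, 12), rng.integers(2, 6), rng.integers(2, 6)
            a1 = rng.lognormal(0, 2, (g, s1)) * (rng.random((g, s1)) < 0.7)
            a2 = rng.lognormal(0, 2, (g, s2)) * (rng.random((g, s2)) < 0.7)
            m1 = ExpressionMatrix(values=pd.DataFrame(
                a1, index=[f"g{i}" for i in range(g)]))
            m2 = ExpressionMatrix(values=pd.DataFrame(
                a2, index=[f"h{i}" for i in range(g)]))
            got = compute_dnr(m1, m2, orth(list(m1.values.index),
                                           list(m2.values.index)))["dnr"].to_numpy()
            expect = self._brute_force(a1, a2)
            assert np.allclose(got, expect, equal_nan=True)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.integers(min_value=0, max_value=5))
    def test_scaling_and_species_swap_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        a1 = rng.lognormal(0, 1, (5, 4))
        a2 = rng.lognormal(0, 1, (5, 4))
        ids1, ids2 = [f"g{i}" for i in range(5)], [f"h{i}" for i in range(5)]
        m1 = ExpressionMatrix(values=pd.DataFrame(a1, index=ids1))
        m2 = ExpressionMatrix(values=pd.DataFrame(a2, index=ids2))
        base = compute_dnr(m1, m2, orth(ids1, ids2))["dnr"].to_numpy()
        ms1 = ExpressionMatrix(values=pd.DataFrame(a1 * scale, index=ids1))
        ms2 = ExpressionMatrix(values=pd.DataFrame(a2 * scale, index=ids2))
        scaled = compute_dnr(ms1, ms2, orth(ids1, ids2))["dnr"].to_numpy()
        swapped = compute_dnr(m2, m1, orth(ids2, ids1))["dnr"].to_numpy()
        assert np.allclose(base, scaled, equal_nan=True, atol=1e-9)
        assert np.allclose(base, swapped, equal_nan=True)


class TestMixture:
    def test_symmetric_intersection_is_exact_midpoint(self):
        for sigma in (0.2, 0.5, 1.3):
            thr = mixture_intersection(0.5, 1.0, sigma, 0.5, 3.0, sigma)
            assert thr == pytest.approx(2.0, abs=1e-6)

    def test_threshold_recovery_from_samples(self):
        rng = np.random.default_rng(7)
        n = 10_000
        comp = rng.random(n) < 0.45
        x = np.where(comp, rng.normal(1.0, 0.4, n), rng.normal(3.0, 0.8, n))
        fit = fit_dnr_mixture(x, seed=7)
        true_thr = mixture_intersection(0.45, 1.0, 0.4, 0.55, 3.0, 0.8)
        assert abs(fit.threshold - true_thr) <= 0.10
        assert fit.mu1 < fit.threshold < fit.mu2

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0.8, 0.3, 500), rng.normal(3.0, 0.7, 500)])
        f1 = fit_dnr_mixture(x, seed=5)
        f2 = fit_dnr_mixture(x, seed=5)
        assert f1 == f2

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_dnr_mixture(np.ones(10))

    def test_no_interior_intersection_reports_roots(self):
        # an extreme weight imbalance leaves one density dominant between the means
        with pytest.raises(ValueError, match="no density intersection"):
            mixture_intersection(1e-9, 1.0, 0.5, 1 - 1e-9, 1.4, 0.5)


class TestClassify:
    def table(self, dnrs):
        return pd.DataFrame({"id1": [f"g{i}" for i in range(len(dnrs))],
                             "dnr": dnrs})

    def test_boundary_is_constrained(self):
        calls = classify_constraint(self.table([2.0, 2.01, np.nan]), 2.0)
        assert calls.tolist() == ["constrained", "unconstrained", "undefined"]

    def test_counts_partition_defined_set(self, rng):
        dnrs = np.where(rng.random(200) < 0.3, np.nan, rng.uniform(0, 5, 200))
        calls = classify_constraint(self.table(dnrs), 2.0)
        n_def = np.sum(~np.isnan(dnrs))
        assert (calls == "constrained").sum() + (calls == "unconstrained").sum() == n_def


class TestMatching:
    def test_identical_distributions_keep_everything(self, rng):
        e = rng.normal(0, 1, 200)
        calls = pd.Series(["constrained"] * 100 + ["unconstrained"] * 100,
                          index=[f"g{i}" for i in range(200)])
        a1 = pd.Series(np.concatenate([e[:100], e[:100]]), index=calls.index)
        a2 = pd.Series(np.concatenate([e[100:], e[100:]]), index=calls.index)
        c, u = match_by_expression(calls, a1, a2, bins=5, seed=1)
        assert len(c) == len(u) == 100

    def test_disjoint_ranges_give_empty_subsets(self):
        calls = pd.Series(["constrained"] * 50 + ["unconstrained"] * 50,
                          index=[f"g{i}" for i in range(100)])
        a = pd.Series(np.concatenate([np.linspace(0, 1, 50),
                                      np.linspace(10, 11, 50)]), index=calls.index)
        c, u = match_by_expression(calls, a, a, bins=10, seed=1)
        assert c == [] and u == []

    def test_matched_sets_pass_ks(self, rng):
        """Shifted class distributions become indistinguishable after grid
        matching (two-sample KS <= 0.05 per species)."""
        n = 4000
        calls = pd.Series(["constrained"] * n + ["unconstrained"] * n,
                          index=[f"g{i}" for i in range(2 * n)])
        rng = np.random.default_rng(1)
        a1 = pd.Series(np.concatenate([rng.normal(0.5, 1, n), rng.normal(0, 1, n)]),
                       index=calls.index)
        a2 = pd.Series(np.concatenate([rng.normal(0.5, 1, n), rng.normal(0, 1, n)]),
                       index=calls.index)
        c, u = match_by_expression(calls, a1, a2, bins=10, seed=1)
        assert len(c) == len(u) > 0
        for avg in (a1, a2):
            ks = stats.ks_2samp(avg.loc[c], avg.loc[u]).statistic
            assert ks <= 0.05


class TestOutputFraction:
    def setup_method(self):
        vals = pd.DataFrame({"s1": [10.0, 20.0, 0.0], "s2": [1.0, 1.0, 1.0]},
                            index=["a", "b", "c"])
        self.m = ExpressionMatrix(values=vals)
        self.L = pd.Series([4.0, 3.0, 5.0], index=["a", "b", "c"])

    def test_fraction_formula(self):
        frac = output_fraction(self.m, self.L, ["a"])
        assert frac["s1"] == pytest.approx(40.0 / 100.0)

    def test_all_and_none(self):
        assert np.allclose(output_fraction(self.m, self.L, ["a", "b", "c"]), 1.0)
        assert np.allclose(output_fraction(self.m, self.L, []), 0.0)

    def test_additive_over_disjoint_subsets(self):
        f_ab = output_fraction(self.m, self.L, ["a", "b"])
        f_a = output_fraction(self.m, self.L, ["a"])
        f_b = output_fraction(self.m, self.L, ["b"])
        assert np.allclose(f_ab, f_a + f_b)


class TestAnova:
    def test_pure_gene_effect(self):
        frac = anova_decomposition(pd.DataFrame([[1.0, 1.0], [3.0, 3.0]]))
        assert frac["gene"] == pytest.approx(1.0)
        assert frac["sample"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_sample_effect(self):
        frac = anova_decomposition(pd.DataFrame([[1.0, 2.0], [1.0, 2.0]]))
        assert frac["sample"] == pytest.approx(1.0)
        assert frac["gene"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_sums_of_squares(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        x = rng.normal(0, 1, (50, 10))
        frac = anova_decomposition(pd.DataFrame(x))
        long = pd.DataFrame({
            "v": x.ravel(),
            "gene": np.repeat([f"g{i}" for i in range(50)], 10),
            "sample": np.tile([f"s{j}" for j in range(10)], 50),
        })
        tab = sm.stats.anova_lm(ols("v ~ C(gene) + C(sample)", data=long).fit(), typ=2)
        ss = tab["sum_sq"]
        total = ss.sum()
        assert frac["gene"] == pytest.approx(ss["C(gene)"] / total, abs=1e-10)
        assert frac["sample"] == pytest.approx(ss["C(sample)"] / total, abs=1e-10)
        assert frac["residual"] == pytest.approx(ss["Residual"] / total, abs=1e-10)
        assert abs(sum(frac.values()) - 1.0) < 1e-10

    def test_tiny_matrix_rejected(self):
        with pytest.raises(ValueError):
            anova_decomposition(pd.DataFrame([[1.0, 2.0]]))


class TestBreadthAndCorrelation:
    def test_breadth_counts_nonzero_samples(self):
        m = ExpressionMatrix(values=pd.DataFrame(
            {"s%d" % i: [float(i < 7), 0.0] for i in range(30)}, index=["a", "b"]))
        b = expression_breadth(m)
        assert b["a"] == 7 and b["b"] == 0

    def test_perfect_correlation(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert cross_species_corr(a, a, list("abcd")) == pytest.approx(1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(3)
        n = 5000
        rho = 0.8
        x = rng.normal(0, 1, n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
        ids = [f"g{i}" for i in range(n)]
        cc = cross_species_corr(pd.Series(x, index=ids), pd.Series(y, index=ids), ids)
        assert 0.78 <= cc <= 0.82


class TestAntisense:
    def test_balanced_strands(self):
        s = pd.DataFrame({"s1": [5.0], "s2": [2.0]}, index=["g"])
        res = antisense_ratio(s, s)
        assert res["mean_ratio"].iloc[0] == pytest.approx(0.5)
        assert res["sd_ratio"].iloc[0] == pytest.approx(0.0)

    def test_no_antisense(self):
        s = pd.DataFrame({"s1": [5.0]}, index=["g"])
        a = pd.DataFrame({"s1": [0.0]}, index=["g"])
        assert antisense_ratio(s, a)["mean_ratio"].iloc[0] == 0.0

    def test_cross_species_attenuation(self):
        """Correlation of mean antisense ratios across species matches the
        analytic attenuation of the true-ratio correlation by binomial noise."""
        rng = np.random.default_rng(11)
        n_genes, n_samples, depth = 2000, 10, 200
        q = rng.beta(2, 8, n_genes)  # shared true ratio
        ids = [f"g{i}" for i in range(n_genes)]
        means = {}
        for k, seed in enumerate((100, 200)):
            r = np.random.default_rng(seed)
            a_counts = r.binomial(depth, q[:, None], (n_genes, n_samples)).astype(float)
            res = antisense_ratio(pd.DataFrame(float(depth) - a_counts, index=ids),
                                  pd.DataFrame(a_counts, index=ids))
            means[k] = res["mean_ratio"]
        cc = stats.pearsonr(means[0], means[1]).statistic
        noise_var = np.mean(q * (1 - q) / depth) / n_samples
        expect = np.var(q) / (np.var(q) + noise_var)
        assert abs(cc - expect) <= 0.05


class TestLocalization:
    def test_equal_compartments(self):
        m = pd.DataFrame({"s1": [2.0], "s2": [3.0]}, index=["g"])
        res = localization_stats(ExpressionMatrix(values=m),
                                 ExpressionMatrix(values=m.copy()))
        assert res["mean_log_ratio"].iloc[0] == pytest.approx(0.0)
        assert res["sd_log_ratio"].iloc[0] == pytest.approx(0.0)
        assert not res["cytosolic"].iloc[0]

    def test_tenfold_nuclear(self):
        c = pd.DataFrame({"s1": [2.0], "s2": [3.0]}, index=["g"])
        n = c * 10
        res = localization_stats(ExpressionMatrix(values=n), ExpressionMatrix(values=c))
        assert res["mean_log_ratio"].iloc[0] == pytest.approx(1.0)

    def test_lognormal_sd_recovery(self):
        """Per-gene s.d. of the log ratio recovers the generating s.d. within
        5% on average at 50 samples."""
        rng = np.random.default_rng(5)
        n_genes, n_samples, sd = 200, 50, 0.4
        ids = [f"g{i}" for i in range(n_genes)]
        cols = [f"s{j}" for j in range(n_samples)]
        base = rng.lognormal(1, 0.5, (n_genes, 1))
        ratio = 10 ** rng.normal(0, sd, (n_genes, n_samples))
        nuc = pd.DataFrame(base * ratio, index=ids, columns=cols)
        cyt = pd.DataFrame(np.broadcast_to(base, nuc.shape).copy(),
                           index=ids, columns=cols)
        res = localization_stats(ExpressionMatrix(values=nuc),
                                 ExpressionMatrix(values=cyt))
        assert abs(res["sd_log_ratio"].mean() - sd) / sd <= 0.05
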