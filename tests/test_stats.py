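"""Statistical battery: normality gating, tests, Spearman, OLS, adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glymap import stats


def _toy_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    dx = np.r_[["NL"] * (n // 2), ["MCIAD"] * (n - n // 2)]
    age = rng.normal(70, 8, n)
    sex = rng.choice(["F", "M"], n)
    x = rng.normal(0, 1, n)
    return pd.DataFrame({"dx": dx, "age": age, "sex": sex, "x": x,
                         "y": 0.5 * x + rng.normal(0, 0.3, n)})


class TestChooseTest:
    def test_normal_samples_choose_t(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=50), rng.normal(size=50)]
        assert stats.choose_test(groups) == "t_test"

    def test_exponential_sample_chooses_wilcoxon(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=50), rng.exponential(size=50)]
        assert stats.choose_test(groups) == "wilcoxon"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            stats.choose_test([[1.0, 2.0], [1.0, 2.0, 3.0]])


class TestGroupCompare:
    def test_apoe4_counts_chi2_yates(self):
        # carriers 3/16 NL vs 9/13 MCI-AD; Yates-corrected chi-square
        rows = (["NL"] * 3 + ["MCIAD"] * 9)
        rows = [(1, d) for d in rows] + [(0, d) for d in ["NL"] * 13 + ["MCIAD"] * 4]
        table = pd.DataFrame(rows, columns=["apoe4", "dx"])
        cmp = stats.group_compare(table, "apoe4", kind="chi2")
        assert cmp.pvalue == pytest.approx(0.018, abs=5e-4)

    def test_identical_groups_wilcoxon_p_one(self):
        vals = np.arange(10.0)
        table = pd.DataFrame({"dx": ["NL"] * 10 + ["MCIAD"] * 10,
                              "v": np.r_[vals, vals]})
        cmp = stats.group_compare(table, "v", kind="wilcoxon")
        assert cmp.pvalue == pytest.approx(1.0)

    def test_huge_shift_detected(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "dx": ["NL"] * 20 + ["MCIAD"] * 20,
            "v": np.r_[rng.normal(0, 1, 20), rng.normal(10, 1, 20)],
        })
        cmp = stats.group_compare(table, "v", kind="auto")
        assert cmp.pvalue < 1e-6

    def test_constant_variable_degenerate(self):
        table = pd.DataFrame({"dx": ["NL"] * 5 + ["MCIAD"] * 5, "v": 1.0})
        with pytest.raises(ValueError, match="constant"):
            stats.group_compare(table, "v", kind="t")


class TestSpearman:
    def test_perfect_monotone(self):
        t = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 3,
                          "z": -np.arange(10.0)})
        c = stats.spearman_matrix(t, ["x", "y", "z"])
        assert c.rho[0, 1] == pytest.approx(1.0)
        assert c.rho[0, 2] == pytest.approx(-1.0)
        assert np.allclose(c.rho, c.rho.T)
        assert np.allclose(np.diag(c.rho), 1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.integers(0, 5, size=(10, 3)).astype(float),
                         columns=["a", "b", "c"])  # ties on purpose
        c = stats.spearman_matrix(t, ["a", "b", "c"])
        ranks = np.column_stack([sps.rankdata(t[v]) for v in ("a", "b", "c")])
        oracle = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(c.rho, oracle, atol=1e-12)

    def test_constant_variable_flagged(self):
        t = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        c = stats.spearman_matrix(t, ["a", "b"])
        assert c.degenerate == ("b",)
        assert np.isnan(c.rho[0, 1])


class TestLinearModel:
    def test_exact_linear_data(self):
        t = _toy_table()
        t["y_exact"] = 2.0 + 3.0 * t["x"]
        r = stats.fit_linear_model(t, "y_exact", ["x"])
        assert r.r2 == pytest.approx(1.0)
        assert np.allclose(r.residuals, 0, atol=1e-10)
        assert r.terms.loc["x", "estimate"] == pytest.approx(3.0)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.normal(size=n)
        t = pd.DataFrame({"x": x, "age": rng.normal(70, 8, n),
                          "sex": rng.choice(["F", "M"], n),
                          "y": 0.5 * x + rng.normal(0, 0.5, n)})
        r = stats.fit_linear_model(t, "y", ["x", "age", "sex"])
        est, se = r.terms.loc["x", "estimate"], r.terms.loc["x", "se"]
        assert abs(est - 0.5) <= 3 * se

    def test_treatment_coding_terms(self):
        t = _toy_table()
        r = stats.fit_linear_model(t, "y", ["age", "sex", "dx"])
        assert "sexM" in r.terms.index
        assert "dxNL" in r.terms.index
        assert r.r2_adj <= r.r2 <= 1.0

    def test_orthogonal_response_near_zero_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        y -= np.polyval(np.polyfit(x, y, 1), x)  # project out x
        t = pd.DataFrame({"x": x, "y": y})
        r = stats.fit_linear_model(t, "y", ["x"])
        assert abs(r.terms.loc["x", "t"]) < 1e-8

    def test_collinear_design_rejected(self):
        t = _toy_table()
        t["x2"] = 2.0 * t["x"]
        with pytest.raises(ValueError, match="collinear"):
            stats.fit_linear_model(t, "y", ["x", "x2"])


class TestPartialRegression:
    def test_frisch_waugh_identity(self):
        for seed in range(20):
            t = _toy_table(seed=seed)
            full = stats.fit_linear_model(t, "y", ["x", "age", "sex", "dx"])
            _, _, slope = stats.partial_regression(t, "y", ["x", "age", "sex", "dx"], "x")
            assert slope == pytest.approx(full.terms.loc["x", "estimate"], abs=1e-10)

    def test_intercept_only_adjustment_is_simple_slope(self):
        t = _toy_table()
        _, _, slope = stats.partial_regression(t, "y", ["x"], "x")
        simple = stats.fit_linear_model(t, "y", ["x"]).terms.loc["x", "estimate"]
        assert slope == pytest.approx(simple, abs=1e-12)


class TestAdjustPvalues:
    @pytest.mark.parametrize(
        "method,p,expected",
        [
            ("holm", [0.2], [0.2]),
            ("holm", [0.01, 0.04], [0.02, 0.04]),
            ("bh", [0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_hand_computed_examples(self, method, p, expected):
        assert stats.adjust_pvalues(p, method) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.adjust_pvalues([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_holm_dominates_bh_and_bounds(self, p):
        holm = stats.adjust_pvalues(p, "holm")
        bh = stats.adjust_pvalues(p, "bh")
        assert np.all(holm >= np.asarray(p) - 1e-15)
        assert np.all(holm <= 1.0) and np.all(bh <= 1.0)
        assert np.all(holm >= bh - 1e-12)
        # monotone in the raw p-values
        order = np.argsort(p)
        assert np.all(np.diff(holm[order]) >= -1e-12)
        assert np.all(np.diff(bh[order]) >= -1e-12)


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "ref,comp,expected",
        [
            (4.41, 4.83, 9.5),  # GM pCSF group sensitivity
            (1.52, 1.68, 10.5),  # PVS/WMV
            (25.15, 25.77, 2.5),  # WM FW
        ],
    )
    def test_group_sensitivity_values(self, ref, comp, expected):
        assert stats.percent_increase(ref, comp) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            stats.percent_increase(0.0, 1.0)
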