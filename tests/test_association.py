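import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneupr._stats import bh_adjust
from aneupr.association import (
    msi_stratified_corr,
    ols_fit,
    partial_spearman,
    scna_group_expression_test,
    spearman_bh,
)
from aneupr.coexpression import StratifiedCohort
from aneupr.io import ExpressionMatrix
from aneupr.simulate import simulate_ols_design

from _oracles import brute_spearman


class TestOls:
    def test_exact_fit_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = 2.0 * x + rng.normal(0, 1e-8, 200)
        idx = [f"s{i}" for i in range(200)]
        rep = ols_fit(
            pd.Series(y, index=idx), pd.DataFrame({"x": x}, index=idx)
        )
        assert rep.coefficient("x") == pytest.approx(2.0, abs=1e-6)

    def test_binary_covariate_equals_mean_difference(self):
        rng = np.random.default_rng(1)
        g = np.array(["a"] * 30 + ["b"] * 30)
        y = rng.normal(0, 1, 60) + (g == "b") * 0.7
        idx = [f"s{i}" for i in range(60)]
        rep = ols_fit(
            pd.Series(y, index=idx), pd.DataFrame({"g": g}, index=idx)
        )
        expected = y[g == "b"].mean() - y[g == "a"].mean()
        assert rep.coefficient("g[b]") == pytest.approx(expected)

    def test_planted_stage_effects_recovered(self):
        resp, cov, truth = simulate_ols_design(seed=4)
        rep = ols_fit(resp, cov, baseline_levels={"stage": "I"})
        for st_ in ("II", "III", "IV"):
            lo, hi = rep.ci(f"stage[{st_}]")
            assert lo <= truth[st_] <= hi

    def test_listwise_deletion_counted(self):
        idx = [f"s{i}" for i in range(10)]
        y = pd.Series(np.arange(10.0), index=idx)
        cov = pd.DataFrame({"x": np.arange(10.0)}, index=idx)
        cov.loc["s3", "x"] = np.nan
        rep = ols_fit(y, cov)
        assert rep.n == 9
        assert rep.n_dropped == 1

    def test_rank_deficiency_names_aliased_terms(self):
        idx = [f"s{i}" for i in range(20)]
        x = np.arange(20.0)
        cov = pd.DataFrame({"x": x, "x2": 2 * x}, index=idx)
        with pytest.raises(ValueError, match="x2"):
            ols_fit(pd.Series(x, index=idx), cov)

    def test_ci_brackets_coefficient(self):
        resp, cov, _ = simulate_ols_design(n_samples=500, seed=2)
        rep = ols_fit(resp, cov, baseline_levels={"stage": "I"})
        assert (
            (rep.terms["ci_low"] <= rep.terms["coefficient"])
            & (rep.terms["coefficient"] <= rep.terms["ci_high"])
        ).all()


class TestSpearmanBh:
    def test_monotone_extremes_and_hand_ranks(self):
        x = {"up": pd.Series([1.0, 2, 3, 4, 5, 6]),
             "down": pd.Series([1.0, 2, 3, 4, 5, 6]),
             "tied": pd.Series([1.0, 2.0, 2.0, 3.0, 5.0, 4.0, 7.0, 6.0])}
        y = {"up": pd.Series([2.0, 3, 5, 7, 8, 9]),
             "down": pd.Series([9.0, 8, 7, 5, 3, 2]),
             "tied": pd.Series([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 9.0])}
        out = spearman_bh(x, y)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)
        assert out.loc["tied", "rho"] == pytest.approx(
            brute_spearman(x["tied"], y["tied"])
        )

    def test_constant_vector_untestable(self):
        x = {"t": pd.Series([1.0] * 6)}
        y = {"t": pd.Series(np.arange(6.0))}
        out = spearman_bh(x, y)
        assert not out.loc["t", "testable"]

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        x = {f"t{i}": pd.Series(rng.normal(0, 1, 30)) for i in range(12)}
        y = {k: v * (i / 12) + pd.Series(rng.normal(0, 1, 30))
             for i, (k, v) in enumerate(x.items())}
        out = spearman_bh(x, y).dropna(subset=["p"]).sort_values("p")
        assert out["q"].is_monotonic_increasing


class TestPartialSpearman:
    def test_fully_explained_by_control(self):
        rng = np.random.default_rng(0)
        z = pd.Series(rng.normal(0, 1, 100))
        rho, p = partial_spearman(z, z * 1.0, z.to_frame("c"))
        assert abs(rho) < 0.15

    def test_independent_control_leaves_correlation(self):
        rng = np.random.default_rng(1)
        n = 400
        x = pd.Series(rng.normal(0, 1, n))
        y = 0.6 * x + pd.Series(rng.normal(0, 0.8, n))
        c = pd.Series(rng.normal(0, 1, n))
        rho_partial, _ = partial_spearman(x, y, c.to_frame("c"))
        rho_plain, _ = stats.spearmanr(x, y)
        assert rho_partial == pytest.approx(rho_plain, abs=0.05)

    def test_confounder_removed(self):
        rng = np.random.default_rng(2)
        n = 400
        z = rng.normal(0, 1, n)
        x = pd.Series(z + rng.normal(0, 0.7, n))
        y = pd.Series(z + rng.normal(0, 0.7, n))
        rho_plain, _ = stats.spearmanr(x, y)
        rho_partial, p = partial_spearman(x, y, pd.Series(z).to_frame("z"))
        assert rho_plain > 0.4
        assert abs(rho_partial) < 0.12

    def test_zero_controls_equals_plain_spearman(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(0, 1, 50))
        y = pd.Series(rng.normal(0, 1, 50))
        rho, _ = partial_spearman(x, y, pd.DataFrame(index=x.index))
        plain, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(plain, abs=1e-10)

    def test_collinear_controls_error(self):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(0, 1, 30))
        y = pd.Series(rng.normal(0, 1, 30))
        c = pd.Series(np.ones(30))
        with pytest.raises(ValueError):
            partial_spearman(x, y, c.to_frame("c"))


class TestMsiStratified:
    def test_planted_signs_recovered(self):
        rng = np.random.default_rng(7)
        n = 400
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
        burden = pd.Series(rng.normal(0, 1, n), index=idx)
        msi = pd.Series(
            np.where(np.arange(n) < 80, 0.7, 0.1), index=idx, dtype=float
        )
        muts = pd.Series(
            np.where(
                msi >= 0.4,
                100 - 20 * burden + rng.normal(0, 5, n),
                50 + 20 * burden + rng.normal(0, 5, n),
            ),
            index=idx,
        )
        out = msi_stratified_corr(muts, burden, msi)
        assert out.loc["MSS", "rho"] > 0.5
        assert out.loc["MSI-H", "rho"] < -0.5

    def test_empty_stratum_untestable(self):
        idx = pd.Index(["a", "b", "c", "d", "e", "f"], name="sample")
        muts = pd.Series(np.arange(6.0), index=idx)
        burden = pd.Series(np.arange(6.0)[::-1], index=idx)
        msi = pd.Series(0.1, index=idx)
        out = msi_stratified_corr(muts, burden, msi)
        assert not out.loc["MSI-H", "testable"]
        assert out.loc["MSS", "testable"]

    def test_zero_threshold_sends_everything_msih(self):
        idx = pd.Index([f"s{i}" for i in range(6)], name="sample")
        muts = pd.Series(np.arange(6.0), index=idx)
        burden = pd.Series(np.arange(6.0), index=idx)
        msi = pd.Series(0.2, index=idx)
        out = msi_stratified_corr(muts, burden, msi, threshold=0.0)
        assert not out.loc["MSS", "testable"]
        assert out.loc["MSI-H", "rho"] == pytest.approx(1.0)


class TestGroupExpression:
    def _setup(self, shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        low = [f"l{i}" for i in range(n)]
        high = [f"h{i}" for i in range(n)]
        x = rng.normal(5, 1, size=(3, 2 * n))
        x[0, n:] += shift
        expr = ExpressionMatrix(
            pd.DataFrame(np.clip(x, 0, None),
                         index=pd.Index(["up", "g1", "g2"], name="gene"),
                         columns=low + high)
        )
        strata = StratifiedCohort(
            groups={"TT": (low, high)}, thresholds={"TT": (0, 0)}
        )
        return expr, strata

    def test_planted_shift_flagged(self):
        expr, strata = self._setup(shift=1.0)
        out = scna_group_expression_test(expr, strata, ["up", "g1", "g2"])
        assert out.loc["up", "significant"]
        assert not out.loc["g1", "significant"]

    def test_identical_strata_near_null(self):
        expr, strata = self._setup(shift=0.0, seed=5)
        out = scna_group_expression_test(expr, strata, ["up", "g1", "g2"])
        assert (out["p"] > 0.01).all()

    def test_single_sample_stratum_errors(self):
        expr, _ = self._setup(shift=0.0)
        strata = StratifiedCohort(
            groups={"TT": (["l0"], ["h0"])}, thresholds={"TT": (0, 0)}
        )
        with pytest.raises(ValueError):
            scna_group_expression_test(expr, strata, ["up"])


class TestBh:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_propagates(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert not np.isnan(q[0])
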