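import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from aneupr import coexpression
from aneupr.coexpression import (
    StratifiedCohort,
    adjacency,
    classify_pairs,
    diff_matrix,
    empirical_fdr,
    permutation_test,
    stratify,
)
from aneupr.io import ExpressionMatrix

from _oracles import brute_spearman
from conftest import make_metadata


def _expr_from_array(x, genes=None, samples=None):
    genes = genes or [f"G{i:02d}" for i in range(x.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(x.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(np.clip(x, 0, None), index=pd.Index(genes, name="gene"),
                     columns=samples)
    )


class TestStratify:
    def test_percentile_split(self):
        samples = [f"s{i}" for i in range(1, 11)]
        scores = pd.Series(range(1, 11), index=samples, dtype=float)
        meta = make_metadata(samples)
        cohort = stratify(scores, meta)
        low, high = cohort.groups["TT"]
        assert sorted(low) == ["s1", "s10", "s2"] or set(low) == {"s1", "s2", "s3"}
        assert set(low) == {"s1", "s2", "s3"}
        assert set(high) == {"s8", "s9", "s10"}

    def test_all_identical_scores_error(self):
        samples = [f"s{i}" for i in range(10)]
        scores = pd.Series(1.0, index=samples)
        with pytest.raises(ValueError, match="degenerate"):
            stratify(scores, make_metadata(samples))

    def test_equal_percentiles_split_in_half(self):
        samples = [f"s{i}" for i in range(10)]
        scores = pd.Series(np.arange(10, dtype=float), index=samples)
        cohort = stratify(scores, make_metadata(samples), lo_pct=50, hi_pct=50)
        low, high = cohort.groups["TT"]
        assert len(low) + len(high) == 10
        assert set(low).isdisjoint(high)

    def test_small_types_skipped_with_warning(self):
        samples = [f"s{i}" for i in range(5)]
        scores = pd.Series(np.arange(5, dtype=float), index=samples)
        with pytest.warns(UserWarning, match="skipping"):
            cohort = stratify(scores, make_metadata(samples))
        assert cohort.types() == []
        assert cohort.skipped == ["TT"]


class TestAdjacency:
    def test_diagonal_and_extremes(self):
        x = np.vstack([np.arange(6.0), np.arange(6.0) * 2, 5 - np.arange(6.0)])
        expr = _expr_from_array(x, genes=["a", "b", "c"])
        c = adjacency(expr, list(expr.samples), ["a", "b", "c"])
        assert c.loc["a", "a"] == 1.0
        assert c.loc["a", "b"] == pytest.approx(1.0)
        assert c.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_hand_rank_computation_with_ties(self):
        x = np.array([[1.0, 2.0, 2.0, 3.0, 5.0, 4.0], [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]])
        expr = _expr_from_array(x, genes=["a", "b"])
        c = adjacency(expr, list(expr.samples), ["a", "b"])
        assert c.loc["a", "b"] == pytest.approx(
            brute_spearman(x[0], x[1]), abs=1e-12
        )

    def test_constant_gene_warns_and_zeroes(self):
        x = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        expr = _expr_from_array(x, genes=["a", "const"])
        with pytest.warns(UserWarning, match="constant"):
            c = adjacency(expr, list(expr.samples), ["a", "const"])
        assert c.loc["a", "const"] == 0.0

    def test_too_few_samples(self):
        expr = _expr_from_array(np.ones((2, 4)))
        with pytest.raises(ValueError):
            adjacency(expr, list(expr.samples), list(expr.genes))


class TestDiffMatrix:
    def test_identical_phenotypes_give_zero(self):
        c = pd.DataFrame(np.eye(3) * 0.5 + 0.5)
        d = diff_matrix(c, c.copy())
        assert (d.to_numpy() == 0).all()

    def test_hand_values(self):
        c_low = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        c_high = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        d = diff_matrix(c_low, c_high)
        assert d.iloc[0, 1] == pytest.approx(1.0)  # (0.5 * |1 - (-1)|)^4
        c_high0 = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        d2 = diff_matrix(c_low, c_high0)
        assert d2.iloc[0, 1] == pytest.approx(0.0625)  # 0.5^4

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            diff_matrix(pd.DataFrame(np.eye(2)), pd.DataFrame(np.eye(3)))

    @settings(max_examples=50, derandomize=True)
    @given(
        hnp.arrays(
            float, (4, 4), elements=st.floats(min_value=-1, max_value=1, width=32)
        )
    )
    def test_label_swap_invariance(self, raw):
        c1 = pd.DataFrame((raw + raw.T) / 2)
        c2 = pd.DataFrame(np.eye(4) * 0.3 + 0.1)
        d_fwd = diff_matrix(c1, c2)
        d_rev = diff_matrix(c2, c1)
        np.testing.assert_allclose(d_fwd, d_rev, atol=1e-12)
        assert (d_fwd.to_numpy() >= 0).all()
        np.testing.assert_allclose(d_fwd, d_fwd.T)


class TestPermutationTest:
    def test_planted_pair_detected_in_small_panel(self):
        # one differential pair in a 10-gene panel, n = 100/group
        rng = np.random.default_rng(42)
        n = 100
        genes = [f"G{i}" for i in range(10)]
        x = rng.normal(5, 1, size=(10, 2 * n))
        f = rng.normal(0, 1, n)
        x[0, :n] = 5 + np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(0, 1, n)
        x[1, :n] = 5 + np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(0, 1, n)
        samples = [f"S{i:03d}" for i in range(2 * n)]
        expr = _expr_from_array(x, genes=genes, samples=samples)
        cohort = StratifiedCohort(
            groups={"TT": (samples[:n], samples[n:])}, thresholds={"TT": (0, 0)}
        )
        res = permutation_test(expr, cohort, genes, n_perm=1000, seed=4)
        assert res["TT"].perm_q.loc["G0", "G1"] < 0.05

    def test_zero_statistic_gives_p_one(self):
        # perfectly identical constant-free structure both groups: D_obs == 0
        x = np.tile(np.arange(10.0), (3, 1))
        x += np.random.default_rng(0).normal(0, 1e-9, x.shape)
        samples = [f"S{i}" for i in range(10)]
        expr = _expr_from_array(x + 5, genes=["a", "b", "c"], samples=samples)
        cohort = StratifiedCohort(
            groups={"TT": (samples[:5], samples[5:])}, thresholds={"TT": (0, 0)}
        )
        res = permutation_test(expr, cohort, ["a", "b", "c"], n_perm=100, seed=1)
        # ranks are identical in every subset -> D_obs = 0 -> p = 1
        assert res["TT"].perm_p.loc["a", "b"] == pytest.approx(1.0)

    def test_small_groups_skipped(self):
        x = np.random.default_rng(0).normal(5, 1, (3, 8))
        samples = [f"S{i}" for i in range(8)]
        expr = _expr_from_array(x, genes=["a", "b", "c"], samples=samples)
        cohort = StratifiedCohort(
            groups={"TT": (samples[:4], samples[4:])}, thresholds={"TT": (0, 0)}
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = permutation_test(expr, cohort, ["a", "b", "c"], n_perm=100, seed=1)
        assert res == {}

    def test_low_n_perm_warns(self):
        x = np.random.default_rng(0).normal(5, 1, (2, 20))
        samples = [f"S{i}" for i in range(20)]
        expr = _expr_from_array(x, genes=["a", "b"], samples=samples)
        cohort = StratifiedCohort(
            groups={"TT": (samples[:10], samples[10:])}, thresholds={"TT": (0, 0)}
        )
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(expr, cohort, ["a", "b"], n_perm=50, seed=1)

    def test_seeding_is_order_independent(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 1, (3, 40))
        samples = [f"S{i}" for i in range(40)]
        expr = _expr_from_array(x, genes=["a", "b", "c"], samples=samples)
        g1 = {"T1": (samples[:10], samples[10:20]), "T2": (samples[20:30], samples[30:])}
        cohort_both = StratifiedCohort(groups=g1, thresholds={k: (0, 0) for k in g1})
        res_both = permutation_test(expr, cohort_both, ["a", "b", "c"], n_perm=200, seed=3)
        # T2 alone occupies a different type position; seeding is by sorted
        # type order so the same types in the same order reproduce exactly
        res_again = permutation_test(expr, cohort_both, ["a", "b", "c"], n_perm=200, seed=3)
        pd.testing.assert_frame_equal(res_both["T2"].perm_p, res_again["T2"].perm_p)


class TestClassification:
    def _fake_result(self, ttype, q, delta, n=50):
        genes = ["a", "b", "c"]
        mk = lambda v: pd.DataFrame(v, index=genes, columns=genes)  # noqa: E731
        ones = np.ones((3, 3))
        qm = ones.copy()
        qm[0, 1] = qm[1, 0] = q
        dm = np.zeros((3, 3))
        dm[0, 1] = dm[1, 0] = delta
        small_p = np.full((3, 3), 1e-6)
        return coexpression.DiffCoexResult(
            tumor_type=ttype, n_low=n, n_high=n,
            c_low=mk(ones * 0.9), c_high=mk(ones * 0.8),
            delta=mk(dm), d=mk(np.abs(dm)), perm_p=mk(qm), perm_q=mk(qm),
            p_low=mk(small_p), p_high=mk(small_p),
        )

    def test_recurrence_threshold_is_nine_types(self):
        sig = {f"T{i:02d}": self._fake_result(f"T{i:02d}", 0.01, 0.5) for i in range(9)}
        rest = {f"U{i:02d}": self._fake_result(f"U{i:02d}", 0.9, 0.0) for i in range(23)}
        table = classify_pairs({**sig, **rest})
        assert table.loc[("a", "b"), "status"] == "perturbed"
        assert table.loc[("a", "b"), "direction"] == "reduced"

        sig8 = dict(list(sig.items())[:8])
        table8 = classify_pairs({**sig8, **rest})
        assert table8.loc[("a", "b"), "status"] != "perturbed"

    def test_preserved_requires_both_strata_significant_everywhere(self):
        results = {f"T{i}": self._fake_result(f"T{i}", 0.9, 0.0) for i in range(10)}
        table = classify_pairs(results, min_types=9)
        # every pair correlation p is tiny in both strata and nothing is perturbed
        assert (table["status"] == "preserved").all()

    def test_majority_direction_tie_is_mixed(self):
        up = {f"T{i}": self._fake_result(f"T{i}", 0.01, 0.5) for i in range(5)}
        down = {f"U{i}": self._fake_result(f"U{i}", 0.01, -0.5) for i in range(5)}
        table = classify_pairs({**up, **down}, min_types=9)
        assert table.loc[("a", "b"), "status"] == "perturbed"
        assert table.loc[("a", "b"), "direction"] == "mixed"


class TestEmpiricalFdr:
    def _table(self, genes, perturbed_pairs):
        pairs = [
            (a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]
        ]
        idx = pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])
        status = [
            "perturbed" if (a, b) in perturbed_pairs else "neither" for a, b in pairs
        ]
        return pd.DataFrame(
            {"n_significant_types": 0, "direction": "none", "status": status},
            index=idx,
        )

    def test_zero_when_nothing_flagged(self):
        genes = [f"g{i}" for i in range(10)]
        rate = empirical_fdr({"CTRL": self._table(genes, set())})
        assert rate.gene_rate == 0.0
        assert rate.pair_rate == 0.0

    def test_ratio_arithmetic(self):
        genes = [f"g{i}" for i in range(20)]
        rate = empirical_fdr({"CTRL": self._table(genes, {("g0", "g1")})})
        assert rate.gene_rate == pytest.approx(2 / 20)

    def test_empty_controls_error(self):
        with pytest.raises(ValueError):
            empirical_fdr({})
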