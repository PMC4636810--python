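"""Tests for normalisation, DE testing and overrepresentation analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossase.datasets import de_gene_table
from crossase.design import GROUP_MAT, GROUP_PAT
from crossase.expression import (
    ExpressionMatrix,
    de_filter,
    de_test,
    fold_change,
    log_transform,
    ora_hypergeometric,
    quantile_normalize,
    rpkm,
)

GROUPS = {f"m{i}": GROUP_MAT for i in range(3)} | {f"p{i}": GROUP_PAT for i in range(3)}


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["s1"].tolist() == [2.5, 3.5, 4.5]
        assert out["s2"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_samples_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 7.0], "b": [3.0, 1.0, 7.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_columns_share_sorted_values_after(self):
        # tie-free input: with ties the mean-of-reference rule intentionally
        # departs from the shared reference distribution
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_receive_mean_of_reference_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        out = quantile_normalize(m)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_sample_identity_with_warning(self):
        m = pd.DataFrame({"only": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert out.equals(m)


class TestRpkm:
    def test_formula_example(self):
        m = pd.DataFrame({"s": [10.0, 999_990.0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 5000})
        out = rpkm(m, lengths)
        assert out.loc["g1", "s"] == pytest.approx(10.0)
        assert out.loc["g2", "s"] == pytest.approx(999_990 * 1e9 / (1e6 * 5000))

    def test_zero_count_and_scale_invariance(self):
        m = pd.DataFrame({"s": [0.0, 50.0], "t": [10.0, 40.0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        out = rpkm(m, lengths)
        assert out.loc["g1", "s"] == 0.0
        doubled = rpkm(2 * m, lengths)
        assert np.allclose(out, doubled)

    def test_invalid_inputs(self):
        m = pd.DataFrame({"s": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            rpkm(m, pd.Series({"g": 0}))
        with pytest.raises(ValueError):
            rpkm(pd.DataFrame({"s": [0.0]}, index=["g"]), pd.Series({"g": 100}))


class TestLogTransform:
    def test_values_and_monotonicity(self):
        m = pd.DataFrame({"s": [0.0, 10.0, 100.0]})
        out = log_transform(m)["s"]
        assert out.iloc[0] == 0.0
        assert out.iloc[1] == pytest.approx(math.log(11), abs=1e-4)
        assert out.is_monotonic_increasing
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-1.0]}))


class TestFoldChange:
    @pytest.mark.parametrize(
        "mat, pat, expected", [(3.98, 3.01, 1.32), (1.66, 0.93, 1.78), (2.0, 2.0, 1.00)]
    )
    def test_log_layer_ratio(self, mat, pat, expected):
        assert round(fold_change(mat, pat), 2) == expected

    def test_zero_denominator_is_undefined(self):
        assert math.isnan(fold_change(1.0, 0.0))


class TestDeTest:
    @staticmethod
    def _matrix(mat_vals, pat_vals):
        return pd.DataFrame(
            [list(mat_vals) + list(pat_vals)],
            index=["g"],
            columns=list(GROUPS),
        )

    def test_identical_groups_give_p_one_and_unit_fold(self):
        m = self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        rec = de_test(m, GROUPS)
        assert rec.loc["g", "p_value"] == pytest.approx(1.0)
        assert rec.loc["g", "fold_change"] == pytest.approx(1.0)

    def test_matches_welch_t_oracle(self):
        """p equals the closed-form Welch t CDF on random fixtures."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.normal(size=3), rng.normal(2, 1, size=3)
            m = self._matrix(a, b)
            p_pkg = de_test(m, GROUPS).loc["g", "p_value"]
            va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
            t = (a.mean() - b.mean()) / math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
            p_hand = 2 * stats.t.sf(abs(t), df)
            assert p_pkg == pytest.approx(p_hand, abs=1e-9)

    def test_degenerate_zero_variance_flagged(self):
        m = self._matrix([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        rec = de_test(m, GROUPS)
        assert rec.loc["g", "p_value"] == 0.0
        assert bool(rec.loc["g", "degenerate"])


class TestDeFilter:
    @staticmethod
    def _rec(p, fch, rpkm_max):
        return pd.DataFrame(
            {"p_value": [p], "fold_change": [fch],
             "rpkm_mat": [rpkm_max], "rpkm_pat": [0.1]}, index=["g"]
        )

    @pytest.mark.parametrize(
        "p, fch, rpkm_max, kept",
        [
            (0.04, 1.25, 0.6, True),
            (0.04, 1.10, 0.6, False),   # under the 20% rule
            (0.04, 0.75, 0.6, True),    # down-regulation passes symmetrically
            (0.06, 1.25, 0.6, False),
            (0.04, 1.25, 0.4, False),
        ],
    )
    def test_threshold_combinations(self, p, fch, rpkm_max, kept):
        assert (len(de_filter(self._rec(p, fch, rpkm_max))) == 1) is kept

    def test_every_published_de_row_passes(self):
        """The (0.05, 0.5, 20%) filter retains the full published DE table."""
        tab = de_gene_table()
        rec = pd.DataFrame(
            {
                "p_value": tab["p_value"].to_numpy(),
                "fold_change": [
                    fold_change(m, p)
                    for m, p in zip(tab["mean_log_mat"], tab["mean_log_pat"])
                ],
                "rpkm_mat": np.expm1(tab["mean_log_mat"].to_numpy()),
                "rpkm_pat": np.expm1(tab["mean_log_pat"].to_numpy()),
            },
            index=tab["gene"],
        )
        assert len(de_filter(rec)) == len(tab)


class TestOra:
    def test_micro_example_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        de = universe[:5]
        gene_set = {"s": set(universe[1:4]) | {universe[10]}}  # overlap 3
        res = ora_hypergeometric(de, universe, gene_set)
        p_pkg = res["p_value"].iloc[0]
        # oracle: enumerate all C(20,5) draws
        members = gene_set["s"]
        n_extreme = sum(
            1 for draw in itertools.combinations(universe, 5)
            if len(set(draw) & members) >= 3
        )
        assert p_pkg == pytest.approx(n_extreme / math.comb(20, 5), abs=1e-9)
        assert p_pkg == pytest.approx(0.0319918, abs=1e-6)

    def test_zero_overlap_gives_p_one(self):
        res = ora_hypergeometric(["g0"], ["g0", "g1", "g2"], {"s": {"g1"}})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_bh_adjustment_by_hand(self):
        sets = {f"s{i}": {"g0"} for i in range(3)}
        res = ora_hypergeometric(["g0"], [f"g{i}" for i in range(10)], sets)
        res["p_value"] = [0.01, 0.02, 0.03]
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(res["p_value"], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["g"], [], {})
        with pytest.raises(ValueError):
            ora_hypergeometric(["x"], ["g"], {})


class TestExpressionMatrix:
    def test_layers_are_built_in_order_and_consistent(self, design):
        from crossase.simulate import simulate_expression

        counts, lengths, _ = simulate_expression(design, 60, seed=21)
        groups = design.sample_table().set_index("sample")["group"].to_dict()
        em = ExpressionMatrix(counts, lengths, groups).normalize()
        assert set(em.layers) == {"raw", "quantile", "rpkm", "log"}
        assert np.allclose(em.layers["log"], np.log1p(em.layers["rpkm"]))
        for layer in em.layers.values():
            assert layer.shape == counts.shape

    def test_nonpositive_lengths_excluded_with_warning(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="length"):
            em = ExpressionMatrix(counts, pd.Series({"g1": 100, "g2": 0}), {})
        assert list(em.counts.index) == ["g1"]
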