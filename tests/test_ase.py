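"""Unit and property tests for the allelic-imbalance cascade."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossase.ase import (
    AseParams,
    FilterTrace,
    allele_ratio,
    classify_parental_expression,
    group_consistency_filter,
    group_difference_score,
    individual_quality_filter,
    permutation_fdr,
    population_coverage_filter,
    run_ase,
    select_informative_sites,
    signed_sqrt_chi2,
)
from crossase.design import GROUP_MAT, GROUP_PAT, CrossDesign, SimTruth
from crossase.simulate import plant_imprinting, simulate_allele_counts

from conftest import make_snp_data

F1 = ["matBFMI_1", "matBFMI_2", "matBFMI_3", "patBFMI_1", "patBFMI_2", "patBFMI_3"]
PARENTS = ["BFMI_M", "BFMI_F", "B6N_M", "B6N_F"]
ALL = PARENTS + F1
GROUPS = {s: GROUP_MAT for s in F1[:3]} | {s: GROUP_PAT for s in F1[3:]}


def _full_site(parent_bfmi=(0, 0, 10, 10), parent_b6n=(10, 10, 0, 0), f1=(5, 5, 5, 5)):
    site = {s: parent_bfmi for s in PARENTS[:2]}
    site |= {s: parent_b6n for s in PARENTS[2:]}
    site |= {s: f1 for s in F1}
    return site


class TestAlleleRatio:
    @pytest.mark.parametrize(
        "dp4, expected",
        [((3, 2, 6, 9), 0.75), ((0, 0, 7, 5), 1.0), ((10, 10, 10, 10), 0.5)],
    )
    def test_examples(self, dp4, expected):
        assert allele_ratio(dp4) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert math.isnan(allele_ratio((0, 0, 0, 0)))


class TestSignedSqrtChi2:
    @pytest.mark.parametrize(
        "dp4, expected",
        [((5, 5, 5, 5), 0.0), ((3, 2, 9, 6), 2.2360679), ((9, 6, 3, 2), -2.2360679)],
    )
    def test_examples(self, dp4, expected):
        assert signed_sqrt_chi2(dp4) == pytest.approx(expected, abs=1e-6)

    def test_matches_goodness_of_fit_oracle(self):
        """|score|² equals the textbook χ² against a balanced expectation."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            ref, alt = rng.integers(0, 200, size=2)
            if ref + alt == 0:
                continue
            s = signed_sqrt_chi2((ref, 0, alt, 0))
            chi2, _ = stats.chisquare([ref, alt])
            assert s * s == pytest.approx(chi2, abs=1e-9)
            assert math.copysign(1, s) == (1 if alt >= ref else -1)

    @given(ref=st.integers(0, 500), alt=st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_allele_swap(self, ref, alt):
        if ref + alt == 0:
            return
        fwd = signed_sqrt_chi2((ref, 0, alt, 0))
        rev = signed_sqrt_chi2((alt, 0, ref, 0))
        assert fwd == pytest.approx(-rev, abs=1e-12)
        assert (fwd == 0) == (ref == alt)

    @given(depth=st.integers(4, 400))
    @settings(max_examples=100, deadline=None)
    def test_magnitude_grows_with_depth_at_fixed_ratio(self, depth):
        # √χ² = √d · |2p − 1| at p = 3/4
        ref, alt = depth, 3 * depth
        s = signed_sqrt_chi2((ref, 0, alt, 0))
        assert s == pytest.approx(math.sqrt(4 * depth) * 0.5, rel=1e-12)


class TestInformativeSites:
    def test_keeps_divergent_homozygous_site_and_reanchors(self, sample_map):
        # site 0: BFMI alt-hom (kept as-is); site 1: BFMI ref-hom -> re-anchored
        data = make_snp_data(
            [
                _full_site(),
                _full_site(parent_bfmi=(10, 10, 0, 0), parent_b6n=(0, 0, 10, 10),
                           f1=(2, 2, 9, 9)),
            ],
            ALL,
        )
        out, trace = select_informative_sites(data, sample_map)
        assert out.n_snps == 2
        # after re-anchoring, the alt allele is the BFMI allele everywhere:
        # BFMI parentals read as pure alt at both sites
        bfmi_idx = out.sample_index(PARENTS[:2])
        assert (out.ref_depth()[:, bfmi_idx] == 0).all()
        # and the F1 dp4 of the flipped site is swapped ref<->alt
        f1_idx = out.sample_index(F1)
        assert (out.alt_depth()[1, f1_idx] == 4).all()

    def test_drops_missing_parental_and_concordant_sites(self, sample_map):
        missing_parent = _full_site()
        del missing_parent["B6N_M"]
        both_alt = _full_site(parent_b6n=(0, 0, 10, 10))
        het_bfmi = _full_site(parent_bfmi=(5, 5, 5, 5))
        data = make_snp_data([missing_parent, both_alt, het_bfmi], ALL)
        out, trace = select_informative_sites(data, sample_map)
        assert out.n_snps == 0
        reasons = trace.stages[0]["reasons"]
        assert reasons["parental_missing"] == 1
        assert reasons["no_strain_difference"] == 1
        assert reasons["not_homozygous"] == 1

    def test_missing_parental_sample_raises(self, sample_map):
        data = make_snp_data([_full_site()], ALL[1:])
        with pytest.raises(KeyError):
            select_informative_sites(data, sample_map)


class TestCoverageAndQualityFilters:
    def test_population_threshold_is_inclusive(self, sample_map):
        # 10 samples x 10 reads = 100 -> kept; 99 -> dropped
        at = _full_site(f1=(5, 0, 5, 0), parent_bfmi=(0, 0, 5, 5), parent_b6n=(5, 5, 0, 0))
        below = _full_site(f1=(5, 0, 5, 0), parent_bfmi=(0, 0, 5, 5), parent_b6n=(5, 4, 0, 0))
        data = make_snp_data([at, below], ALL)
        out, _ = population_coverage_filter(data, min_total=100)
        assert out.n_snps == 1

    def test_zero_threshold_is_identity_and_total_is_population_wide(self, sample_map):
        one_sample_all = {s: (0, 0, 0, 0) for s in ALL} | {"matBFMI_1": (25, 25, 25, 25)}
        data = make_snp_data([one_sample_all], ALL, missing=np.zeros((1, 10), bool))
        assert population_coverage_filter(data, min_total=0)[0].n_snps == 1
        assert population_coverage_filter(data, min_total=100)[0].n_snps == 1

    @pytest.mark.parametrize(
        "qual, dp4, kept",
        [
            (49.9, (5, 5, 5, 5), False),   # low confidence
            (60.0, (1, 1, 1, 1), False),   # fewer than 5 high-quality reads
            (50.0, (2, 1, 1, 1), True),    # both boundaries inclusive-complement
        ],
    )
    def test_per_sample_masking(self, sample_map, qual, dp4, kept):
        site = _full_site(f1=dp4)
        data = make_snp_data([site], ALL)
        data.qual[0, data.sample_index(["matBFMI_2"])] = qual
        data.dp4[0, data.sample_index(["matBFMI_2"])[0]] = dp4
        out, _ = individual_quality_filter(data, sample_map)
        assert (out.n_snps == 1) is kept


class TestConsistencyFilter:
    @staticmethod
    def _data_with_ratios(mat_ratios, pat_ratios=(0.5, 0.5, 0.5), depth=100):
        site = _full_site()
        for s, r in zip(F1[:3], mat_ratios):
            a = round(r * depth)
            site[s] = (depth - a, 0, a, 0)
        for s, r in zip(F1[3:], pat_ratios):
            a = round(r * depth)
            site[s] = (depth - a, 0, a, 0)
        return make_snp_data([site], ALL)

    def test_tight_ratios_kept(self, sample_map):
        data = self._data_with_ratios((0.48, 0.50, 0.52))
        assert group_consistency_filter(data, sample_map)[0].n_snps == 1

    def test_discordant_ratios_removed(self, sample_map):
        # SD of {0.10, 0.60, 0.90} ≈ 0.404 > 0.20
        data = self._data_with_ratios((0.10, 0.60, 0.90))
        out, trace = group_consistency_filter(data, sample_map)
        assert out.n_snps == 0
        assert trace.stages[0]["reasons"]["high_group_sd"] == 1

    def test_identical_ratios_kept(self, sample_map):
        data = self._data_with_ratios((0.3, 0.3, 0.3))
        assert group_consistency_filter(data, sample_map)[0].n_snps == 1

    def test_insufficient_replicates_dropped(self, sample_map):
        data = self._data_with_ratios((0.5, 0.5, 0.5))
        data.missing[0, data.sample_index(["patBFMI_1", "patBFMI_2"])] = True
        out, trace = group_consistency_filter(data, sample_map)
        assert out.n_snps == 0
        assert trace.stages[0]["reasons"]["insufficient_replicates"] == 1


class TestGroupDifference:
    def test_worked_example(self):
        scores = pd.DataFrame([[2.236, 2.0, 1.8, 0.5, -0.3, 0.1]], columns=F1)
        rec = group_difference_score(scores, GROUPS)
        assert rec["group_sum_mat"].iloc[0] == pytest.approx(6.036)
        assert rec["group_sum_pat"].iloc[0] == pytest.approx(0.3)
        assert rec["diff_score"].iloc[0] == pytest.approx(5.736)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(20, 6)), columns=F1)
        swapped = {s: (GROUP_PAT if g == GROUP_MAT else GROUP_MAT)
                   for s, g in GROUPS.items()}
        d1 = group_difference_score(scores, GROUPS)["diff_score"]
        d2 = group_difference_score(scores, swapped)["diff_score"]
        assert np.allclose(d1, -d2)

    def test_invariant_to_within_group_permutation(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.normal(size=(10, 6)), columns=F1)
        shuffled = scores[["matBFMI_3", "matBFMI_1", "matBFMI_2",
                           "patBFMI_2", "patBFMI_3", "patBFMI_1"]]
        d1 = group_difference_score(scores, GROUPS)["diff_score"]
        d2 = group_difference_score(shuffled, GROUPS)["diff_score"]
        assert np.allclose(d1, d2)

    def test_unknown_label_raises(self):
        scores = pd.DataFrame(np.zeros((1, 6)), columns=F1)
        with pytest.raises(ValueError, match="unknown group"):
            group_difference_score(scores, {s: "mystery" for s in F1})


class TestPermutationFdr:
    def test_alpha_one_flags_every_nonzero_site(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(rng.normal(size=(50, 6)), columns=F1)
        thr, rec = permutation_fdr(scores, GROUPS, alpha=1.0)
        nonzero = rec["diff_score"] != 0
        assert rec.loc[nonzero, "passes_fdr"].all()

    def test_no_signal_reports_infinite_threshold(self):
        scores = pd.DataFrame(np.zeros((30, 6)), columns=F1)
        thr, rec = permutation_fdr(scores, GROUPS, alpha=0.05)
        assert math.isinf(thr)
        assert not rec["passes_fdr"].any()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.normal(size=(40, 6)), columns=F1)
        a = permutation_fdr(scores, GROUPS, n_perm=7, seed=5)
        b = permutation_fdr(scores, GROUPS, n_perm=7, seed=5)
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_pool_null_method(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(40, 6)), columns=F1)
        thr, rec = permutation_fdr(scores, GROUPS, n_perm=50, seed=1,
                                   null_method="pool")
        assert math.isfinite(thr) or not rec["passes_fdr"].any()


class TestClassification:
    def test_monoallelic_and_partial_labels(self):
        rec = pd.DataFrame(
            {
                "gene": ["Peg3", "H13", "Abca8b", "Abca8b", "bal"],
                "passes_fdr": [True, True, True, True, False],
                "ratio_mat": [0.02, 0.97, 0.383, 0.40, 0.5],
                "ratio_pat": [0.97, 0.03, 0.620, 0.65, 0.5],
            }
        )
        out = classify_parental_expression(rec).set_index("gene")
        assert out.loc["Peg3", "label"] == "paternal-allele-expressed"
        assert out.loc["H13", "label"] == "maternal-allele-expressed"
        assert out.loc["Abca8b", "label"] == "partial imbalance"
        assert out.loc["Abca8b", "n_snps"] == 2
        assert "bal" not in out.index

    def test_abca8b_mean_difference(self):
        rec = pd.DataFrame(
            {
                "gene": ["Abca8b"] * 3,
                "passes_fdr": [True] * 3,
                "ratio_pat": [0.576, 0.608, 0.677],
                "ratio_mat": [0.309, 0.385, 0.457],
            }
        )
        out = classify_parental_expression(rec)
        assert out["pct_diff"].iloc[0] == pytest.approx(23.67, abs=0.01)


class TestCascade:
    def test_filter_trace_counts_are_monotone(self, design):
        truth = SimTruth()
        plant_imprinting(truth, [f"snp_{i:06d}" for i in range(5)])
        data, _ = simulate_allele_counts(design, 300, rho=0.15, truth=truth, seed=9)
        _, _, trace = run_ase(data, design.sample_table(), AseParams())
        counts = [s["n_in"] for s in trace.stages] + [trace.stages[-1]["n_out"]]
        assert counts == sorted(counts, reverse=True)
        for s in trace.stages:
            assert s["n_out"] <= s["n_in"]

    def test_trace_rejects_increasing_counts(self):
        trace = FilterTrace()
        with pytest.raises(ValueError):
            trace.add("bad", 5, 6)

    def test_empty_input_yields_empty_output(self, design):
        data, _ = simulate_allele_counts(design, 0, seed=1)
        scores, genes, trace = run_ase(data, design.sample_table(), AseParams())
        assert len(scores) == 0 and len(genes) == 0
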