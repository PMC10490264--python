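"""Normalization, dispersion estimation and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homeoscope.diffexpr import (
    NegativeBinomialDE,
    bh_adjust,
    call_degs,
    copy_contrast,
    estimate_dispersions,
    estimate_size_factors,
    wald_test,
)
from homeoscope.exceptions import ContractError, EstimationError, NormalizationError
from tests.conftest import nb_counts, two_group_frame


class TestSizeFactors:
    def test_identical_samples_give_equal_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_gives_factor_ratio_two(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]})
        sf = estimate_size_factors(counts)
        assert np.isclose(sf["s2"] / sf["s1"], 2.0)

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        k = rng.poisson(100, size=(50, 4))
        counts = pd.DataFrame(k, columns=list("abcd"))
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = counts["c"] * 10
        sf2 = estimate_size_factors(scaled)
        # only factor *ratios* are identifiable under median-of-ratios
        ratio = (sf2 / sf2["a"]) / (sf / sf["a"])
        assert np.allclose(ratio[["b", "d"]], 1.0)
        assert np.isclose(ratio["c"], 10.0)

    def test_no_common_nonzero_gene_raises(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(NormalizationError):
            estimate_size_factors(counts)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self, rng):
        mu = np.full(2000, 200.0)
        k1 = nb_counts(rng, mu, 50, 0.0)
        k2 = nb_counts(rng, mu, 50, 0.0)
        sf = np.ones(50)
        disp = estimate_dispersions([k1, k2], [sf, sf])
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered(self, rng):
        mu = np.full(2000, 200.0)
        k1 = nb_counts(rng, mu, 50, 0.1)
        k2 = nb_counts(rng, mu, 50, 0.1)
        sf = np.ones(50)
        disp = estimate_dispersions([k1, k2], [sf, sf])
        assert 0.05 < np.median(disp) < 0.2

    def test_constant_counts_hit_floor(self):
        k = np.full((3, 4), 7.0)
        disp = estimate_dispersions([k, k], [np.ones(4), np.ones(4)], shrink=False)
        assert np.allclose(disp, 1e-8)

    def test_single_replicates_raise(self):
        k = np.array([[5.0]])
        with pytest.raises(EstimationError):
            estimate_dispersions([k, k], [np.ones(1), np.ones(1)])


class TestBH:
    def test_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert np.allclose(bh_adjust([0.3]), [0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ContractError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ContractError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        m = len(p)
        # direct transcription of the step-up rule
        expected = np.empty(m)
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        for i in range(m):
            candidates = [
                min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
            ]
            expected[i] = min(candidates)
        assert np.allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_p(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestWald:
    def test_exactly_equal_groups_null_point(self):
        block = np.array([[100, 120, 110], [30, 20, 25]])
        counts, groups = two_group_frame(block, block)
        res = wald_test(counts, pd.DataFrame({"genotype": groups}), ("g1", "g2"))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_label_swap_negates_lfc_preserves_p(self, rng):
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 300))
        k1 = nb_counts(rng, mu, 3, 0.05)
        k2 = nb_counts(rng, mu * 2, 3, 0.05)
        counts, groups = two_group_frame(k1, k2)
        design = pd.DataFrame({"genotype": groups})
        fwd = wald_test(counts, design, ("g1", "g2"))
        rev = wald_test(counts, design, ("g2", "g1"))
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_zero_group_mean_pseudocount(self):
        k1 = np.zeros((1, 3))
        k2 = np.full((1, 3), 200.0)
        counts, groups = two_group_frame(k1, k2)
        sf = pd.Series(1.0, index=counts.columns)
        model = NegativeBinomialDE().fit(
            counts, groups, ("g1", "g2"), size_factors=sf
        )
        res = model.results_
        assert np.isfinite(res["log2FoldChange"]).all()
        assert res["log2FoldChange"].iloc[0] > 5  # ~log2(200/0.5)
        assert res["padj"].iloc[0] < 0.05

    def test_deg_call_threshold_is_strict(self):
        res = pd.DataFrame(
            {"log2FoldChange": [-1.0, 2.0], "padj": [0.049, 0.05]},
            index=["g1", "g2"],
        )
        degs = call_degs(res, alpha=0.05)
        assert list(degs.index) == ["g1"]
        assert degs.loc["g1", "direction"] == "down"

    def test_empty_group_raises(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]})
        groups = pd.Series(["g1", "g1"], index=counts.columns)
        with pytest.raises(ContractError):
            wald_test(counts, pd.DataFrame({"genotype": groups}), ("g1", "g2"))

    def test_planted_degs_recovered_against_truth(self, rng):
        """Strong planted effects among nulls: the DEG set essentially equals
        the planted set."""
        n_null, n_alt = 2000, 200
        mu = np.exp(rng.uniform(np.log(50), np.log(500), n_null + n_alt))
        mu2 = mu.copy()
        mu2[n_null:] *= 4.0
        k1 = nb_counts(rng, mu, 3, 0.05)
        k2 = nb_counts(rng, mu2, 3, 0.05)
        counts, groups = two_group_frame(k1, k2)
        res = wald_test(counts, pd.DataFrame({"genotype": groups}), ("g1", "g2"))
        degs = set(call_degs(res).index)
        planted = set(counts.index[n_null:])
        assert len(planted - degs) <= 0.05 * len(planted)
        assert len(degs - planted) <= 0.05 * len(degs)


class TestCopyContrast:
    def test_positive_lfc_means_a_over_d(self, rng):
        mu_a, mu_d = np.full(50, 400.0), np.full(50, 100.0)
        ka = nb_counts(rng, mu_a, 3, 0.05)
        kd = nb_counts(rng, mu_d, 3, 0.05)
        genes = [f"gA{i}" for i in range(50)] + [f"gD{i}" for i in range(50)]
        counts = pd.DataFrame(np.vstack([ka, kd]), index=genes,
                              columns=["s1", "s2", "s3"])
        pairs = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(50)],
            "a_gene": [f"gA{i}" for i in range(50)],
            "d_gene": [f"gD{i}" for i in range(50)],
        })
        sf = pd.Series(1.0, index=counts.columns)
        res = copy_contrast(counts, pairs, ["s1", "s2", "s3"], sf)
        assert (res["log2FoldChange"] > 0).mean() > 0.95
        assert np.isclose(res["log2FoldChange"].median(), 2.0, atol=0.3)


def test_cross_check_against_reference_glm_engine(rng):
    """Independent cross-validation of the Wald engine against a published
    NB-GLM differential-expression implementation on a small fixture."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    import logging

    logging.getLogger("pydeseq2").setLevel(logging.ERROR)
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    n = 300
    mu = np.exp(rng.uniform(np.log(50), np.log(500), n))
    fold = np.ones(n)
    fold[:60] = 4.0
    k1 = nb_counts(rng, mu, 3, 0.05)
    k2 = nb_counts(rng, mu * fold, 3, 0.05)
    counts, groups = two_group_frame(k1, k2)

    ref_counts = counts.T
    meta = pd.DataFrame({"condition": groups.to_numpy()}, index=ref_counts.index)
    dds = DeseqDataSet(counts=ref_counts, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
    stats.summary()
    ref = stats.results_df

    mine = wald_test(counts, pd.DataFrame({"genotype": groups}), ("g1", "g2"))
    corr = np.corrcoef(mine["log2FoldChange"], ref["log2FoldChange"])[0, 1]
    assert corr > 0.99
    deg_mine = set(mine.index[mine["padj"] < 0.05])
    deg_ref = set(ref.index[ref["padj"] < 0.05])
    jaccard = len(deg_mine & deg_ref) / max(1, len(deg_mine | deg_ref))
    assert jaccard > 0.8
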