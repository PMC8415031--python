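"""Regulatory-map layer: BH filtering, interaction geometry, classifications."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aidnet.regulatory import (
    CIS,
    DISEASE_SPECIFIC,
    IDENTICAL,
    SHARED,
    TRANS_INTER,
    TRANS_INTRA,
    bh_fdr,
    build_regulatory_map,
    classify_genes,
    classify_interaction,
    classify_snps,
    filter_significant,
    percent,
    regulatory_summary,
    tissue_specificity,
)
from helpers import bh_stepup_by_hand


class TestBhFdr:
    def test_hand_worked_stepup(self):
        # m=4: raw p*m/k = [.02, .02, .04, .04]; step-up minima leave them as-is
        assert bh_fdr([0.005, 0.01, 0.03, 0.04]) == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_all_null_boundary(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_textbook_recursion_and_permutation_invariance(self, pvals):
        q = bh_fdr(pvals)
        assert q == pytest.approx(bh_stepup_by_hand(pvals), abs=1e-12)
        # permutation of inputs permutes outputs identically
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pvals))
        q_perm = bh_fdr([pvals[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], abs=1e-12)
        # q-values of the sorted p list are non-decreasing
        assert np.all(np.diff(bh_fdr(sorted(pvals))) >= -1e-15)

    def test_global_null_type_i_control(self):
        """Under 200 uniform p-values, q < 0.05 rejections are rare events."""
        clean = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            q = bh_fdr(rng.uniform(size=200))
            clean += int((q < 0.05).sum() == 0)
        assert clean >= 95


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "snp_chrom,snp_pos,gene_chrom,tss,expected",
        [
            ("chr1", 1_000_000, "chr1", 1_500_000, CIS),
            ("chr1", 1, "chr1", 2_000_002, TRANS_INTRA),
            ("chr1", 5, "chr2", 5, TRANS_INTER),
            ("chr1", 1, "chr1", 1_000_001, CIS),  # distance exactly 1 Mb
            ("chr1", 1, "chr1", 1_000_002, TRANS_INTRA),  # one base beyond
        ],
    )
    def test_geometry(self, snp_chrom, snp_pos, gene_chrom, tss, expected):
        assert classify_interaction(snp_chrom, snp_pos, gene_chrom, tss) == expected

    def test_rejects_nonpositive_coordinates(self):
        with pytest.raises(ValueError):
            classify_interaction("chr1", 0, "chr1", 5)


class TestFilterSignificant:
    def test_single_p_below_alpha_kept(self):
        df = pd.DataFrame({"eqtl_p": [0.04]})
        assert len(filter_significant(df)) == 1

    def test_boundary_is_strict(self):
        df = pd.DataFrame({"eqtl_p": [0.05]})
        assert len(filter_significant(df)) == 0

    def test_ten_signals_against_ninety_nulls(self):
        # hand step-up with m=100: q = (k * 1e-4) * 100 / k = 0.01 < 0.05 for
        # each signal; the nulls at >= 0.5 stay at q >= 0.5 * 100/100
        signal = [i * 1e-4 for i in range(1, 11)]
        rng = np.random.default_rng(3)
        noise = list(0.5 + 0.5 * rng.uniform(size=90))
        df = pd.DataFrame({"eqtl_p": signal + noise, "idx": range(100)})
        kept = filter_significant(df)
        assert sorted(kept["idx"]) == list(range(10))
        # agreement with the hand step-up on the same 100 values
        q_hand = bh_stepup_by_hand(signal + noise)
        assert all(q_hand[i] < 0.05 for i in range(10))
        assert all(q_hand[i] >= 0.05 for i in range(10, 100))

    def test_empty_input_is_empty_output(self):
        out = filter_significant(pd.DataFrame({"eqtl_p": []}))
        assert len(out) == 0 and "q_value" in out.columns

    def test_groupwise_correction_is_per_group(self):
        # the same p is significant alone (q = 0.01) but washed out inside a
        # 100-test group (q = 0.01 * 100 / 1 = 1.0)
        small = pd.DataFrame({"eqtl_p": [0.01], "disease": "A"})
        big = pd.DataFrame({"eqtl_p": [0.01] + [0.9] * 99, "disease": "B"})
        both = pd.concat([small, big], ignore_index=True)
        kept = filter_significant(both, group_col="disease")
        assert set(kept["disease"]) == {"A"}


class TestClassification:
    def test_pleiotropy_flags(self):
        flags = classify_snps({"rs1": {"CRD", "ULC"}, "rs2": {"CRD"}})
        assert flags == {"rs1": True, "rs2": False}

    def test_gene_categories_partition(self):
        gene_snps = {"g_ident": ["rs1"], "g_shared": ["rs1", "rs2"], "g_spec": ["rs2", "rs3"]}
        pleio = {"rs1": True, "rs2": False, "rs3": False}
        gene_dis = {"g_ident": {"A", "B"}, "g_shared": {"A", "B", "C"}, "g_spec": {"C"}}
        cats = classify_genes(gene_snps, pleio, gene_dis)
        assert cats == {"g_ident": IDENTICAL, "g_shared": SHARED, "g_spec": DISEASE_SPECIFIC}

    def test_non_pleiotropic_snps_of_two_diseases_make_shared(self):
        cats = classify_genes(
            {"g": ["rs1", "rs2"]},
            {"rs1": False, "rs2": False},
            {"g": {"CRD", "ULC"}},
        )
        assert cats["g"] == SHARED


class TestTissueSpecificity:
    def test_counts_and_fraction(self):
        df = pd.DataFrame(
            {
                "gene": ["g1", "g1", "g2", "g3", "g3"],
                "tissue": ["T1", "T1", "T1", "T1", "T2"],
                "interaction": [TRANS_INTRA, TRANS_INTER, CIS, TRANS_INTER, TRANS_INTER],
            }
        )
        counts, frac = tissue_specificity(df)
        # g2 is cis-only, hence not trans-regulated
        assert counts.to_dict() == {"g1": 1, "g3": 2}
        assert frac == pytest.approx(0.5)

    def test_reported_single_tissue_proportion(self):
        assert percent(2100, 2498, 0) == 84


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (225, 4789, 1, 4.7),
            (186, 2065, 0, 9),
            (0, 10, 1, 0.0),
            (1879, 2065, 0, 91),
            (60, 186, 1, 32.3),
            (1, 8, 1, 12.5),  # exact half rounds away from zero
            (1, 800, 1, 0.1),
        ],
    )
    def test_half_away_rounding(self, num, den, decimals, expected):
        assert percent(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)


def _tiny_study():
    """Hand-built two-disease study: 3 SNPs, 3 genes, known classifications."""
    gwas = pd.DataFrame(
        {
            "rsid": ["rs1", "rs1", "rs2", "rs3"],
            "chrom": ["chr1"] * 4,
            "pos": [100_000, 100_000, 5_000_000, 9_000_000],
            "disease": ["CRD", "ULC", "CRD", "ULC"],
            "gwas_p": [1e-8] * 4,
        }
    )
    assoc = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3", "rs2"],
            "gene": ["gA", "gA", "gB", "gC"],
            "gene_chrom": ["chr1", "chr1", "chr2", "chr1"],
            "gene_tss": [600_000, 600_000, 9_000_000, 5_100_000],
            "tissue": ["T1", "T1", "T2", "T1"],
            "eqtl_p": [1e-6, 1e-5, 1e-4, 0.9],
            "hic_evidence": ["c1"] * 4,
        }
    )
    return gwas, assoc


class TestBuildRegulatoryMap:
    def test_tiny_study_classifications(self):
        gwas, assoc = _tiny_study()
        rmap = build_regulatory_map(gwas, assoc)
        assert rmap.snps["rs1"].pleiotropic and not rmap.snps["rs2"].pleiotropic
        # gA: pleiotropic rs1 + non-pleiotropic rs2 -> shared
        assert rmap.genes["gA"].category == SHARED
        # gB: single non-pleiotropic SNP of one disease -> disease-specific
        assert rmap.genes["gB"].category == DISEASE_SPECIFIC
        # gC only had the null association, which BH discards
        assert "gC" not in rmap.genes
        assert rmap.n_genes_dropped == 1
        interactions = {
            (r, g): i
            for r, g, i in zip(
                rmap.associations["rsid"], rmap.associations["gene"],
                rmap.associations["interaction"],
            )
        }
        # rs1 sits 500 kb from gA's TSS (cis); rs2 is 4.4 Mb away on the same
        # chromosome (trans-intra); rs3 targets gB across chromosomes
        assert interactions == {
            ("rs1", "gA"): CIS,
            ("rs2", "gA"): TRANS_INTRA,
            ("rs3", "gB"): TRANS_INTER,
        }

    def test_category_counts_partition_the_gene_set(self):
        gwas, assoc = _tiny_study()
        rmap = build_regulatory_map(gwas, assoc)
        summary = regulatory_summary(rmap)
        assert sum(summary["gene_categories"].values()) == summary["n_genes"]
        assert (
            summary["n_pleiotropic_snps"] + summary["n_non_pleiotropic_snps"]
            == summary["n_snps"]
        )
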