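"""Synthetic-data generators: boundaries, planted structure, determinism."""

import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from aidnet.regulatory import filter_significant
from aidnet.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_associations,
    simulate_drug_table,
    simulate_gene_sets,
    simulate_genes,
    simulate_gwas_snps,
    simulate_ppin,
    write_inputs,
)
from helpers import pair_counting_ari


class TestConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_snps=0).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(pleiotropy_rate=1.2).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_diseases=1, pleiotropy_rate=0.1).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_proteins=2, k_blocks=3).validate()


class TestGwasSnps:
    def test_pleiotropy_rate_zero_boundary(self):
        df = simulate_gwas_snps(SimulationConfig(pleiotropy_rate=0.0, seed=1))
        assert (df.groupby("rsid")["disease"].nunique() == 1).all()

    def test_pleiotropy_rate_one_boundary(self):
        df = simulate_gwas_snps(SimulationConfig(pleiotropy_rate=1.0, seed=1))
        assert (df.groupby("rsid")["disease"].nunique() >= 2).all()

    def test_every_snp_has_a_disease_and_suggestive_p(self):
        df = simulate_gwas_snps(SimulationConfig(seed=2))
        assert df["rsid"].nunique() == 200
        assert (df["gwas_p"] <= 5e-6).all()

    def test_planted_pleiotropy_recovered_within_binomial_ci(self):
        config = SimulationConfig(n_snps=2000, pleiotropy_rate=0.09, seed=1)
        df = simulate_gwas_snps(config)
        observed = (df.groupby("rsid")["disease"].nunique() >= 2).mean()
        half_width = 2.576 * math.sqrt(0.09 * 0.91 / 2000)  # binomial 99% CI
        assert abs(observed - 0.09) < half_width


class TestAssociations:
    def test_cis_fraction_one_boundary(self):
        config = SimulationConfig(cis_fraction=1.0, seed=4)
        snps = simulate_gwas_snps(config)
        assoc = simulate_associations(snps, config)
        true = assoc[assoc["is_true"]].merge(
            snps.drop_duplicates("rsid")[["rsid", "chrom", "pos"]], on="rsid"
        )
        same = true["gene_chrom"] == true["chrom"]
        near = (true["gene_tss"] - true["pos"]).abs() <= 1_000_000
        assert (same & near).all()

    def test_cis_fraction_zero_boundary(self):
        config = SimulationConfig(cis_fraction=0.0, seed=4)
        snps = simulate_gwas_snps(config)
        assoc = simulate_associations(snps, config)
        true = assoc[assoc["is_true"]].merge(
            snps.drop_duplicates("rsid")[["rsid", "chrom", "pos"]], on="rsid"
        )
        cis = (true["gene_chrom"] == true["chrom"]) & (
            (true["gene_tss"] - true["pos"]).abs() <= 1_000_000
        )
        assert not cis.any()

    def test_empty_snps_rejected(self):
        with pytest.raises(ValueError):
            simulate_associations(pd.DataFrame(), SimulationConfig())

    def test_each_pair_has_at_least_one_tissue(self):
        config = SimulationConfig(seed=5)
        assoc = simulate_associations(simulate_gwas_snps(config), config)
        assert (assoc.groupby(["rsid", "gene"])["tissue"].nunique() >= 1).all()

    def test_signal_beats_pure_null_through_bh(self):
        """More associations survive FDR with planted signal than under the null."""
        base = SimulationConfig(true_assoc_rate=0.2, seed=7)
        null = dataclasses.replace(base, true_assoc_rate=0.0)
        kept = {}
        for name, config in (("signal", base), ("null", null)):
            assoc = simulate_associations(simulate_gwas_snps(config), config)
            kept[name] = len(filter_significant(assoc)) / max(1, len(assoc))
        assert kept["signal"] > kept["null"]


class TestPpin:
    def test_pure_blocks_are_cliques(self):
        config = SimulationConfig(n_proteins=12, k_blocks=3, p_in=1.0, p_out=0.0, seed=1)
        edges, blocks = simulate_ppin(config)
        g = nx.from_pandas_edgelist(edges, "protein_a", "protein_b")
        components = [set(c) for c in nx.connected_components(g)]
        assert len(components) == 3
        for comp in components:
            assert {blocks[n] for n in comp} == {blocks[next(iter(comp))]}
            sub = g.subgraph(comp)
            n = len(comp)
            assert sub.number_of_edges() == n * (n - 1) // 2

    def test_p_out_zero_gives_at_least_k_components(self):
        config = SimulationConfig(n_proteins=30, k_blocks=3, p_in=0.6, p_out=0.0, seed=2)
        edges, _ = simulate_ppin(config)
        g = nx.from_pandas_edgelist(edges, "protein_a", "protein_b")
        assert nx.number_connected_components(g) >= 3

    def test_no_self_loops_and_scores_in_range(self):
        config = SimulationConfig(seed=3)
        edges, _ = simulate_ppin(config)
        assert (edges["protein_a"] != edges["protein_b"]).all()
        lo, hi = config.score_range
        assert edges["combined_score"].between(lo, hi).all()

    def test_disassortative_config_warns(self):
        config = SimulationConfig(p_in=0.05, p_out=0.3, n_proteins=20, seed=1)
        with pytest.warns(UserWarning):
            simulate_ppin(config)

    def test_louvain_recovers_planted_blocks(self):
        from aidnet.communities import louvain

        config = SimulationConfig(n_proteins=60, k_blocks=3, p_in=0.5, p_out=0.02, seed=3)
        edges, blocks = simulate_ppin(config)
        g = nx.from_pandas_edgelist(edges, "protein_a", "protein_b")
        p = louvain(g, seed=0)
        nodes = sorted(g)
        assert pair_counting_ari([blocks[n] for n in nodes],
                                 [p.assignment[n] for n in nodes]) > 0.9


class TestGeneSetsAndDrugs:
    def test_no_sets_gives_empty_collection(self):
        assert simulate_gene_sets(["A", "B", "C"], n_sets=0, set_size_range=(1, 2)) == {}

    def test_oversized_sets_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_sets(["A", "B"], n_sets=1, set_size_range=(1, 5))

    def test_sets_sample_without_replacement(self):
        collection = simulate_gene_sets([f"G{i}" for i in range(30)], n_sets=10,
                                        set_size_range=(5, 15), seed=2)
        for _, members in collection.values():
            assert len(members) == len(set(members))

    def test_druggable_fraction_one_covers_every_gene(self):
        genes = [f"G{i}" for i in range(40)]
        df = simulate_drug_table(genes, druggable_fraction=1.0, seed=1)
        assert set(df["gene"]) == set(genes)


class TestWriteInputs:
    def test_byte_identical_given_same_seed(self, tmp_path):
        config = SimulationConfig(seed=13)
        paths_a, _ = write_inputs(config, tmp_path / "a")
        paths_b, _ = write_inputs(config, tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes()

    def test_files_reparse_through_pipeline_readers(self, tmp_path):
        from aidnet.enrichment import read_gmt
        from aidnet.ppin import load_reference_ppin

        config = SimulationConfig(seed=13)
        paths, truth = write_inputs(config, tmp_path)
        gwas = pd.read_csv(paths["gwas"], sep="\t")
        assoc = pd.read_csv(paths["associations"], sep="\t")
        assert set(gwas.columns) == {"rsid", "chrom", "pos", "disease", "gwas_p"}
        assert "is_true" not in assoc.columns
        g = load_reference_ppin(paths["ppin"], score_threshold=0.0)
        assert set(g.nodes) <= set(truth.blocks)
        collection = read_gmt(paths["gene_sets"])
        assert truth.planted_set_name in collection

    def test_planted_fractions_recovered_within_three_se(self, tmp_path):
        config = SimulationConfig(n_snps=2000, seed=21)
        paths, _ = write_inputs(config, tmp_path)
        gwas = pd.read_csv(paths["gwas"], sep="\t")
        observed = (gwas.groupby("rsid")["disease"].nunique() >= 2).mean()
        se = math.sqrt(0.09 * 0.91 / 2000)
        assert abs(observed - 0.09) <= 3 * se
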