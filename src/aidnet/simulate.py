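"""Synthetic generators for the five pipeline inputs.

The real analysis starts from a GWAS-catalog SNP table, a CoDeS3D-style
SNP-gene-tissue eQTL table, a STRING-style scored PPI edge list, GMT
gene-set collections and a DGIdb-style drug-gene table.  None of these can
be shipped, so this module simulates all five with controlled ground truth:

* SNPs live on a small synthetic genome (5 chromosomes x 10 Mb) and a known
  fraction of them is pleiotropic (associated with >= 2 diseases).
* True SNP-gene associations are planted with a known cis fraction and
  p-values concentrated near zero; null pairs carry uniform p-values, so
  the downstream BH filter has a well-defined job.
* The PPI network is a planted-partition graph: `k_blocks` communities with
  within-block edge probability `p_in` and between-block probability
  `p_out`, every edge carrying a STRING-like combined score.
* Gene sets are random draws from the gene universe, optionally with one
  planted set equal to a PPI block, so enrichment has a known positive.

Every generator is deterministic given ``SimulationConfig.seed``; each
operation draws from its own substream (seed paired with a fixed offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_gwas_snps",
    "simulate_genes",
    "simulate_associations",
    "simulate_ppin",
    "simulate_gene_sets",
    "simulate_drug_table",
    "write_inputs",
]

#: Synthetic genome: small enough for desk-scale tests, large enough that
#: cis, trans-intrachromosomal and trans-interchromosomal pairs all occur.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 6))
CHROM_LENGTH: int = 10_000_000

#: Genome-wide suggestive threshold applied to the simulated GWAS p-values.
GWAS_P_CEILING: float = 5e-6

# fixed substream offsets (design: one global seed, independent stages)
_OFF_GWAS, _OFF_GENES, _OFF_ASSOC, _OFF_PPIN, _OFF_SETS, _OFF_DRUGS = 1, 2, 3, 4, 5, 6


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 200 SNPs over 6 diseases with a 9% pleiotropy rate, a 63% cis
    share among true associations, and a 100-protein PPI with 3 planted
    blocks (p_in=0.5 versus p_out=0.02).
    """

    n_diseases: int = 6
    n_snps: int = 200
    n_genes: int = 300
    n_tissues: int = 10
    pleiotropy_rate: float = 0.09
    cis_fraction: float = 0.63
    true_assoc_rate: float = 0.2
    effect_p_scale: float = 1.0
    n_proteins: int = 100
    k_blocks: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    score_range: tuple[float, float] = (0.5, 1.0)
    pairs_per_snp: int = 7
    trans_single_tissue_rate: float = 0.84
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_diseases": self.n_diseases,
            "n_snps": self.n_snps,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "n_proteins": self.n_proteins,
            "k_blocks": self.k_blocks,
            "pairs_per_snp": self.pairs_per_snp,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        probs = {
            "pleiotropy_rate": self.pleiotropy_rate,
            "cis_fraction": self.cis_fraction,
            "true_assoc_rate": self.true_assoc_rate,
            "p_in": self.p_in,
            "p_out": self.p_out,
            "trans_single_tissue_rate": self.trans_single_tissue_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.effect_p_scale <= 0:
            raise ConfigurationError("effect_p_scale must be positive")
        lo, hi = self.score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"score_range must satisfy 0 <= lo <= hi <= 1, got {self.score_range!r}")
        if self.pleiotropy_rate > 0 and self.n_diseases < 2:
            raise ConfigurationError("pleiotropy requires at least two diseases")
        if self.n_proteins < self.k_blocks:
            raise ConfigurationError("n_proteins must be >= k_blocks")

    @property
    def diseases(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_diseases)]

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


def simulate_gwas_snps(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the SNP-disease association table.

    Returns one row per (SNP, disease) pair with columns
    ``rsid, chrom, pos, disease, gwas_p``.  A fraction ``pleiotropy_rate``
    of SNPs is assigned two or more distinct diseases (mostly 2, tailing
    off to 5, mirroring the observation that most pleiotropic SNPs link
    few conditions); the rest get exactly one.  All p-values are at or
    below the suggestive threshold of 5e-6.
    """
    config.validate()
    rng = _rng(config, _OFF_GWAS)
    diseases = config.diseases
    rows = []
    n_multi_choices = np.array([2, 3, 4, 5])
    n_multi_probs = np.array([0.60, 0.25, 0.10, 0.05])
    for s in range(config.n_snps):
        rsid = f"rs{s + 1:06d}"
        chrom = CHROMOSOMES[rng.integers(0, len(CHROMOSOMES))]
        pos = int(rng.integers(1, CHROM_LENGTH + 1))
        if config.n_diseases >= 2 and rng.random() < config.pleiotropy_rate:
            k = int(min(config.n_diseases, rng.choice(n_multi_choices, p=n_multi_probs)))
        else:
            k = 1
        assigned = rng.choice(diseases, size=k, replace=False)
        for disease in sorted(assigned):
            gwas_p = float(10.0 ** rng.uniform(-12.0, np.log10(GWAS_P_CEILING)))
            rows.append((rsid, chrom, pos, disease, gwas_p))
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "disease", "gwas_p"])


def simulate_genes(config: SimulationConfig) -> pd.DataFrame:
    """Gene universe: identifiers with uniform TSS positions on the synthetic genome."""
    config.validate()
    rng = _rng(config, _OFF_GENES)
    rows = []
    for g in range(config.n_genes):
        chrom = CHROMOSOMES[rng.integers(0, len(CHROMOSOMES))]
        tss = int(rng.integers(1, CHROM_LENGTH + 1))
        rows.append((f"G{g + 1:05d}", chrom, tss))
    return pd.DataFrame(rows, columns=["gene", "gene_chrom", "gene_tss"])


def simulate_associations(
    snps: pd.DataFrame,
    config: SimulationConfig,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the CoDeS3D-style SNP-gene-tissue association table.

    For every SNP, ``pairs_per_snp`` candidate SNP-gene pairs are drawn.
    A pair is a *true* association with probability ``true_assoc_rate``;
    true pairs are cis (same chromosome, within 1 Mb of the TSS) with
    probability ``cis_fraction`` and draw their eQTL p-value from
    Beta(0.05 * effect_p_scale, 1), which piles mass near zero.  Null
    pairs target a uniformly random gene and draw p ~ Uniform(0, 1).
    Each pair is observed in >= 1 tissue; trans pairs are single-tissue
    with probability ``trans_single_tissue_rate``.

    Returns one row per (rsid, gene, tissue) with columns
    ``rsid, gene, gene_chrom, gene_tss, tissue, eqtl_p, hic_evidence``
    plus the ground-truth helper column ``is_true`` (dropped on write).
    """
    config.validate()
    if snps is None or len(snps) == 0:
        raise ValueError("snps table must be nonempty")
    if genes is None:
        genes = simulate_genes(config)
    rng = _rng(config, _OFF_ASSOC)
    tissues = np.array(config.tissues)

    gene_chrom = genes["gene_chrom"].to_numpy()
    gene_tss = genes["gene_tss"].to_numpy()
    gene_id = genes["gene"].to_numpy()

    uniq = snps.drop_duplicates("rsid")[["rsid", "chrom", "pos"]]
    rows = []
    for rsid, chrom, pos in uniq.itertuples(index=False):
        seen: set[str] = set()
        for _ in range(config.pairs_per_snp):
            is_true = rng.random() < config.true_assoc_rate
            if is_true:
                cis_mask = (gene_chrom == chrom) & (np.abs(gene_tss - pos) <= 1_000_000)
                want_cis = rng.random() < config.cis_fraction
                pool = np.flatnonzero(cis_mask if want_cis else ~cis_mask)
                if pool.size == 0:
                    continue  # no gene available in the requested class; drop the slot
                gi = int(pool[rng.integers(0, pool.size)])
                eqtl_p = float(rng.beta(0.05 * config.effect_p_scale, 1.0))
            else:
                gi = int(rng.integers(0, len(gene_id)))
                eqtl_p = float(rng.uniform())
            gene = gene_id[gi]
            if gene in seen:
                continue
            seen.add(gene)
            is_cis = gene_chrom[gi] == chrom and abs(int(gene_tss[gi]) - pos) <= 1_000_000
            single_rate = 0.5 if is_cis else config.trans_single_tissue_rate
            if rng.random() < single_rate or config.n_tissues == 1:
                n_t = 1
            else:
                n_t = int(min(config.n_tissues, 1 + rng.geometric(0.6)))
            chosen = rng.choice(tissues, size=n_t, replace=False)
            hic = f"cell_line_{int(rng.integers(1, 21)):02d}"
            for tissue in sorted(chosen):
                rows.append(
                    (rsid, gene, gene_chrom[gi], int(gene_tss[gi]), tissue, eqtl_p, hic, bool(is_true))
                )
    return pd.DataFrame(
        rows,
        columns=["rsid", "gene", "gene_chrom", "gene_tss", "tissue", "eqtl_p", "hic_evidence", "is_true"],
    )


def _block_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def simulate_ppin(
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Simulate a scored PPI edge list from a planted-partition model.

    Nodes are split into ``k_blocks`` near-equal blocks; each within-block
    pair is an edge with probability ``p_in`` and each between-block pair
    with probability ``p_out``.  Edge scores are uniform in ``score_range``.
    If ``gene_ids`` is given, node names are sampled from it (so the PPI
    overlaps the regulatory map's gene universe); otherwise synthetic
    protein names are used.

    Returns ``(edges, blocks)`` where ``edges`` has columns
    ``protein_a, protein_b, combined_score`` and ``blocks`` maps each node
    name to its planted block label (the ground truth).
    """
    config.validate()
    if config.p_in < config.p_out:
        warnings.warn("p_in < p_out: planted structure is disassortative", stacklevel=2)
    rng = _rng(config, _OFF_PPIN)
    n = config.n_proteins
    if gene_ids is not None:
        pool = sorted(gene_ids)
        if len(pool) < n:
            raise ValueError(f"need >= {n} gene ids, got {len(pool)}")
        names = list(rng.choice(pool, size=n, replace=False))
    else:
        names = [f"P{i + 1:05d}" for i in range(n)]
    sizes = _block_sizes(n, config.k_blocks)
    block_of = np.repeat(np.arange(config.k_blocks), sizes)
    lo, hi = config.score_range
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            p = config.p_in if block_of[i] == block_of[j] else config.p_out
            if p > 0 and rng.random() < p:
                rows.append((names[i], names[j], float(rng.uniform(lo, hi))))
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    blocks = {names[i]: int(block_of[i]) for i in range(n)}
    return edges, blocks


def simulate_gene_sets(
    genes: Iterable[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
    planted: Iterable[str] | None = None,
    planted_name: str = "PLANTED_SET",
) -> dict[str, tuple[str, list[str]]]:
    """Random gene-set collection (GMT-style), optionally with one planted set.

    Each random set samples genes without replacement.  ``planted`` (for
    example one PPI block) is included verbatim under ``planted_name`` so
    downstream enrichment has a known positive control.
    """
    universe = sorted(set(genes))
    if not universe:
        raise ValueError("gene universe must be nonempty")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid set_size_range {set_size_range!r}")
    if hi > len(universe):
        raise ValueError(f"set size {hi} exceeds the {len(universe)}-gene universe")
    rng = np.random.default_rng([int(seed), _OFF_SETS])
    collection: dict[str, tuple[str, list[str]]] = {}
    if planted is not None:
        members = sorted(set(planted))
        missing = set(members) - set(universe)
        if missing:
            raise ValueError(f"planted set contains genes outside the universe: {sorted(missing)[:5]}")
        collection[planted_name] = ("planted positive-control set", members)
    for i in range(int(n_sets)):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        collection[f"SET{i + 1:04d}"] = (f"random set {i + 1}", members)
    return collection


def simulate_drug_table(
    genes: Iterable[str],
    druggable_fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a drug-gene interaction table (columns ``gene, drug``).

    Each gene is druggable with probability ``druggable_fraction``;
    druggable genes get a geometric number of distinct drugs (mean ~6.7,
    occasionally exceeding 20, exercising the heavily-targeted label).
    """
    if not 0.0 <= druggable_fraction <= 1.0:
        raise ValueError("druggable_fraction must lie in [0, 1]")
    universe = sorted(set(genes))
    if not universe:
        raise ValueError("gene universe must be nonempty")
    rng = np.random.default_rng([int(seed), _OFF_DRUGS])
    rows = []
    for gene in universe:
        if rng.random() < druggable_fraction:
            n_drugs = int(rng.geometric(0.15))
            drugs = rng.choice(500, size=min(n_drugs, 500), replace=False)
            for d in sorted(drugs):
                rows.append((gene, f"DRUG{d + 1:04d}"))
    return pd.DataFrame(rows, columns=["gene", "drug"])


def write_gmt(collection: Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write a gene-set collection in standard GMT (name, description, genes)."""
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class GroundTruth:
    """Planted structure of one simulated study, for validation."""

    blocks: dict[str, int]
    association_truth: pd.DataFrame  # rsid, gene, is_true (pair level)
    planted_set_name: str
    snp_n_diseases: dict[str, int] = field(default_factory=dict)


def write_inputs(
    config: SimulationConfig,
    outdir: str | Path,
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (10, 40),
    druggable_fraction: float = 0.3,
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate and write all five inputs; return their paths and ground truth.

    Files written (TSV with headers, plus standard GMT):
    ``gwas.tsv``, ``associations.tsv``, ``ppin_edges.tsv``,
    ``gene_sets.gmt``, ``drug_gene.tsv``.  The PPI nodes are sampled from
    the simulated gene universe; the planted gene set is block 0 of the
    PPI.  Byte-identical outputs for identical config + seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gwas = simulate_gwas_snps(config)
    genes = simulate_genes(config)
    assoc = simulate_associations(gwas, config, genes=genes)
    # PPI nodes are drawn from genes with genuine regulatory support first
    # (the disease subnetwork is induced on mapped eGenes, and the reference
    # interactome covers essentially all of them), topped up with the rest
    # of the universe if the true eGene pool is short.
    true_genes = sorted(set(assoc.loc[assoc["is_true"], "gene"]))
    rest = sorted(set(genes["gene"]) - set(true_genes))
    pool = (true_genes + rest)[: config.n_proteins]
    edges, blocks = simulate_ppin(config, gene_ids=pool)
    planted = sorted(n for n, b in blocks.items() if b == 0)
    collection = simulate_gene_sets(
        genes["gene"], n_sets, set_size_range, seed=config.seed, planted=planted
    )
    drug_table = simulate_drug_table(genes["gene"], druggable_fraction, seed=config.seed)

    paths = {
        "gwas": outdir / "gwas.tsv",
        "associations": outdir / "associations.tsv",
        "ppin": outdir / "ppin_edges.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "drugs": outdir / "drug_gene.tsv",
    }
    gwas.to_csv(paths["gwas"], sep="\t", index=False)
    assoc.drop(columns=["is_true"]).to_csv(paths["associations"], sep="\t", index=False)
    edges.to_csv(paths["ppin"], sep="\t", index=False)
    write_gmt(collection, paths["gene_sets"])
    drug_table.to_csv(paths["drugs"], sep="\t", index=False)

    truth = GroundTruth(
        blocks=blocks,
        association_truth=assoc.drop_duplicates(["rsid", "gene"])[["rsid", "gene", "is_true"]],
        planted_set_name="PLANTED_SET",
        snp_n_diseases=gwas.groupby("rsid")["disease"].nunique().to_dict(),
    )
    return paths, truth
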