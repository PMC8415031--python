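"""FDR-filtered SNP-gene regulatory map and its classification layers.

The regulatory map is the association table that survives Benjamini-
Hochberg FDR < 0.05, decorated with three classification layers:

* each SNP-gene link is **cis** (same chromosome, SNP within 1 Mb of the
  gene TSS), **trans-intrachromosomal** (same chromosome, further away) or
  **trans-interchromosomal** (different chromosomes);
* each SNP is **pleiotropic** if its surviving associations span two or
  more diseases;
* each gene is **identical** (regulated by pleiotropic SNPs only),
  **disease-specific** (regulated by non-pleiotropic SNPs of a single
  disease) or **shared** (everything else: mixed regulators, or
  non-pleiotropic SNPs from more than one disease).

Multiple testing mirrors the per-disease design of the source analysis:
associations are partitioned by disease before BH correction, and a
pleiotropic SNP is tested once per disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CIS_WINDOW",
    "SnpRecord",
    "GeneRecord",
    "RegulatoryMap",
    "bh_fdr",
    "classify_interaction",
    "filter_significant",
    "classify_snps",
    "classify_genes",
    "tissue_specificity",
    "percent",
    "build_regulatory_map",
]

logger = logging.getLogger(__name__)

#: cis window: SNP within 1 Mb (inclusive) of the gene TSS on the same chromosome.
CIS_WINDOW: int = 1_000_000

CIS, TRANS_INTRA, TRANS_INTER = "cis", "trans_intra", "trans_inter"
IDENTICAL, SHARED, DISEASE_SPECIFIC = "identical", "shared", "disease_specific"


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chrom: str
    pos: int
    diseases: frozenset[str]
    pleiotropic: bool

    def __post_init__(self):
        if not self.diseases:
            raise ValueError(f"SNP {self.rsid} has an empty disease set")
        if self.pleiotropic != (len(self.diseases) >= 2):
            raise ValueError(f"SNP {self.rsid}: pleiotropic flag inconsistent with disease set")


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    protein_coding: bool = True
    category: str | None = None
    diseases: frozenset[str] = frozenset()


@dataclass
class RegulatoryMap:
    """The FDR-passing association set with SNP and gene labels attached."""

    snps: dict[str, SnpRecord]
    genes: dict[str, GeneRecord]
    associations: pd.DataFrame  # one surviving (rsid, gene, tissue) row each
    n_genes_dropped: int = 0

    def gene_ids(self, protein_coding_only: bool = False) -> set[str]:
        return {
            g for g, rec in self.genes.items()
            if not protein_coding_only or rec.protein_coding
        }


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, aligned to input order.

    q_(k) = min over ranks j >= k of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_interaction(
    snp_chrom: str, snp_pos: int, gene_chrom: str, gene_tss: int, cis_window: int = CIS_WINDOW
) -> str:
    """Classify one SNP-gene link by genomic geometry (cis / trans_intra / trans_inter)."""
    if snp_pos <= 0 or gene_tss <= 0:
        raise ValueError("coordinates must be positive (1-based)")
    if snp_chrom != gene_chrom:
        return TRANS_INTER
    return CIS if abs(int(snp_pos) - int(gene_tss)) <= cis_window else TRANS_INTRA


def filter_significant(
    associations: pd.DataFrame,
    alpha: float = 0.05,
    p_col: str = "eqtl_p",
    group_col: str | None = None,
) -> pd.DataFrame:
    """BH-correct the association table and keep rows with q strictly below alpha.

    With ``group_col`` (e.g. ``"disease"``), BH runs independently within
    each group, mirroring a per-disease analysis; otherwise once over the
    whole table.  Returns a copy with a ``q_value`` column, filtered.
    """
    if associations is None or len(associations) == 0:
        out = pd.DataFrame(associations) if associations is not None else pd.DataFrame()
        out = out.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    out = associations.copy()
    if group_col is None:
        out["q_value"] = bh_fdr(out[p_col].to_numpy())
    else:
        out["q_value"] = (
            out.groupby(group_col, group_keys=False)[p_col]
            .transform(lambda s: pd.Series(bh_fdr(s.to_numpy()), index=s.index))
        )
    return out[out["q_value"] < alpha].copy()


def classify_snps(snp_diseases: Mapping[str, Iterable[str]]) -> dict[str, bool]:
    """Pleiotropy flags: True iff a SNP's (surviving) disease set has >= 2 members."""
    return {rsid: len(set(ds)) >= 2 for rsid, ds in snp_diseases.items()}


def classify_genes(
    gene_snps: Mapping[str, Iterable[str]],
    snp_pleiotropic: Mapping[str, bool],
    gene_diseases: Mapping[str, Iterable[str]],
) -> dict[str, str]:
    """Gene categories from regulator pleiotropy and the gene's disease span.

    identical        -- every regulating SNP is pleiotropic;
    disease_specific -- only non-pleiotropic regulators and one disease overall;
    shared           -- everything else (mixed regulators, or non-pleiotropic
                        SNPs spanning more than one disease).
    The three categories partition the gene set.
    """
    categories: dict[str, str] = {}
    for gene, snps in gene_snps.items():
        snps = list(snps)
        if not snps:
            raise ValueError(f"gene {gene} has no regulating SNPs")
        n_dis = len(set(gene_diseases[gene]))
        if all(snp_pleiotropic[s] for s in snps):
            categories[gene] = IDENTICAL
        elif n_dis <= 1:
            categories[gene] = DISEASE_SPECIFIC
        else:
            categories[gene] = SHARED
    return categories


def tissue_specificity(associations: pd.DataFrame) -> tuple[pd.Series, float]:
    """Distinct-tissue counts per trans-regulated gene, and the single-tissue fraction.

    A gene is trans-regulated if it has at least one surviving trans
    (intra- or inter-chromosomal) association; its tissue count is over
    those trans associations only.
    """
    trans = associations[associations["interaction"].isin([TRANS_INTRA, TRANS_INTER])]
    counts = trans.groupby("gene")["tissue"].nunique()
    if len(counts) == 0:
        return counts, float("nan")
    return counts, float((counts == 1).mean())


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-int(decimals))
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def build_regulatory_map(
    gwas: pd.DataFrame,
    associations: pd.DataFrame,
    alpha: float = 0.05,
    cis_window: int = CIS_WINDOW,
    noncoding: Iterable[str] = (),
) -> RegulatoryMap:
    """Assemble the FDR-filtered, fully classified regulatory map.

    ``gwas`` supplies each SNP's coordinates and candidate disease set;
    ``associations`` the raw SNP-gene-tissue rows with ``eqtl_p``.  Every
    association row is tested once per disease of its SNP (per-disease
    BH); a (rsid, gene, tissue) row survives if it passes in any disease,
    and the SNP's surviving disease set drives the pleiotropy flag.
    Genes with no surviving association are dropped (count logged).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    required = {"rsid", "gene", "gene_chrom", "gene_tss", "tissue", "eqtl_p"}
    missing = required - set(associations.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")

    snp_info = gwas.drop_duplicates("rsid").set_index("rsid")[["chrom", "pos"]]
    disease_of = gwas.groupby("rsid")["disease"].agg(lambda s: sorted(set(s)))

    known = associations["rsid"].isin(disease_of.index)
    if not known.all():
        logger.warning("dropping %d association rows with unknown SNPs", int((~known).sum()))
        associations = associations[known]

    # expand: one test per (association row, disease of the SNP)
    expanded = associations.copy()
    expanded["disease"] = expanded["rsid"].map(disease_of)
    expanded = expanded.explode("disease", ignore_index=True)

    surviving = filter_significant(expanded, alpha=alpha, group_col="disease")

    n_input_genes = associations["gene"].nunique()
    if len(surviving) == 0:
        logger.warning("no associations survive FDR < %s", alpha)
        return RegulatoryMap({}, {}, surviving.head(0), n_genes_dropped=n_input_genes)

    snp_dis = surviving.groupby("rsid")["disease"].agg(lambda s: frozenset(s))
    pleio = classify_snps(snp_dis)

    # collapse back to unique (rsid, gene, tissue) rows, keeping the smallest q
    assoc = (
        surviving.sort_values(["q_value", "eqtl_p"], kind="mergesort")
        .drop_duplicates(["rsid", "gene", "tissue"])
        .drop(columns=["disease"])
        .reset_index(drop=True)
    )
    assoc["interaction"] = [
        classify_interaction(
            snp_info.loc[r, "chrom"], int(snp_info.loc[r, "pos"]), gc, int(gt), cis_window
        )
        for r, gc, gt in zip(assoc["rsid"], assoc["gene_chrom"], assoc["gene_tss"])
    ]
    assoc = assoc.sort_values(["rsid", "gene", "tissue"], kind="mergesort").reset_index(drop=True)

    snps = {
        rsid: SnpRecord(
            rsid=rsid,
            chrom=snp_info.loc[rsid, "chrom"],
            pos=int(snp_info.loc[rsid, "pos"]),
            diseases=frozenset(snp_dis[rsid]),
            pleiotropic=pleio[rsid],
        )
        for rsid in sorted(snp_dis.index)
    }

    gene_snps = assoc.groupby("gene")["rsid"].agg(lambda s: sorted(set(s)))
    gene_dis = {
        g: frozenset().union(*(snps[r].diseases for r in rsids))
        for g, rsids in gene_snps.items()
    }
    noncoding = set(noncoding)
    categories = classify_genes(gene_snps, pleio, gene_dis)
    gene_coords = assoc.drop_duplicates("gene").set_index("gene")[["gene_chrom", "gene_tss"]]
    genes = {
        g: GeneRecord(
            gene_id=g,
            chrom=gene_coords.loc[g, "gene_chrom"],
            tss=int(gene_coords.loc[g, "gene_tss"]),
            protein_coding=g not in noncoding,
            category=categories[g],
            diseases=gene_dis[g],
        )
        for g in sorted(gene_snps.index)
    }

    n_dropped = n_input_genes - len(genes)
    if n_dropped:
        logger.info("dropped %d genes with no FDR-surviving association", n_dropped)
    return RegulatoryMap(snps=snps, genes=genes, associations=assoc, n_genes_dropped=n_dropped)


def regulatory_summary(rmap: RegulatoryMap) -> dict:
    """Counts and rounded proportions of the map (SNP pleiotropy, gene
    categories, cis/trans/both regulation, trans tissue specificity)."""
    n_snps = len(rmap.snps)
    n_pleio = sum(1 for s in rmap.snps.values() if s.pleiotropic)
    n_genes = len(rmap.genes)
    cat_counts = {c: 0 for c in (IDENTICAL, SHARED, DISEASE_SPECIFIC)}
    for rec in rmap.genes.values():
        cat_counts[rec.category] += 1

    assoc = rmap.associations
    cis_genes = set(assoc.loc[assoc["interaction"] == CIS, "gene"])
    trans_genes = set(assoc.loc[assoc["interaction"].isin([TRANS_INTRA, TRANS_INTER]), "gene"])
    both = cis_genes & trans_genes
    tissue_counts, _ = tissue_specificity(assoc)

    summary = {
        "n_snps": n_snps,
        "n_pleiotropic_snps": n_pleio,
        "n_non_pleiotropic_snps": n_snps - n_pleio,
        "n_genes": n_genes,
        "n_genes_dropped": rmap.n_genes_dropped,
        "gene_categories": cat_counts,
        "n_associations": int(len(assoc)),
        "n_cis_genes": len(cis_genes),
        "n_trans_genes": len(trans_genes),
        "n_both_genes": len(both),
    }
    if n_snps:
        summary["pct_pleiotropic_snps"] = percent(n_pleio, n_snps, 1)
        summary["pct_non_pleiotropic_snps"] = percent(n_snps - n_pleio, n_snps, 1)
    if n_genes:
        summary["pct_gene_categories"] = {
            c: percent(k, n_genes, 1) for c, k in cat_counts.items()
        }
        summary["pct_cis_genes"] = percent(len(cis_genes), n_genes, 1)
        summary["pct_trans_genes"] = percent(len(trans_genes), n_genes, 1)
        summary["pct_both_genes"] = percent(len(both), n_genes, 1)
    if len(tissue_counts):
        summary["n_trans_single_tissue_genes"] = int((tissue_counts == 1).sum())
        summary["pct_trans_single_tissue"] = percent(
            int((tissue_counts == 1).sum()), int(len(tissue_counts)), 1
        )
    return summary
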