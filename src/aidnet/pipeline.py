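"""End-to-end pipeline: regulatory map -> Ai-PPIN -> modules -> centrality
-> enrichment -> druggability, with one JSON summary per run.

Every stage writes its artifact under the output directory and logs one
structured line with input/output record counts, so the shrinkage from
input SNPs to mapped genes to network nodes to module members is
auditable.  Runs are deterministic given config + seed: two identical
runs produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import centrality as centrality_mod
from . import communities, drugs, enrichment, ppin, regulatory
from .regulatory import percent
from .simulate import SimulationConfig, write_inputs

__all__ = ["PipelineConfig", "run_pipeline", "proportions_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the published thresholds.

    Either the five input paths or ``simulate`` must be provided.
    """

    gwas_path: str | None = None
    associations_path: str | None = None
    ppin_path: str | None = None
    gene_sets_path: str | None = None
    drugs_path: str | None = None
    simulate: SimulationConfig | None = None

    alpha_fdr: float = 0.05  # BH threshold on eQTL associations
    cis_window: int = 1_000_000  # cis: SNP within 1 Mb of the TSS
    ppi_score_threshold: float = 0.7  # STRING combined score, strict >
    n_rand: int = 10_000  # randomized networks for the qs-test
    alpha_modules: float = 0.05  # qs-test family level (Sidak-corrected)
    centrality_fraction: float = 0.1  # top decile per centrality measure
    enrichment_alpha: float = 0.05  # BH threshold on enrichment terms
    seed: int = 0
    outdir: str = "aidnet_results"

    def validate(self) -> None:
        for name in ("alpha_fdr", "alpha_modules", "enrichment_alpha",
                     "ppi_score_threshold", "centrality_fraction"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value!r}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if self.simulate is None:
            paths = [self.gwas_path, self.associations_path, self.ppin_path,
                     self.gene_sets_path, self.drugs_path]
            if any(p is None for p in paths):
                raise ValueError("provide either all five input paths or a simulate config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim:
            if sim is True:
                cfg.simulate = SimulationConfig(seed=cfg.seed)
            else:
                cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["score_range"] = list(self.simulate.score_range)
        return d


def proportions_report(counts: dict[str, tuple[int, int] | tuple[int, int, int]]) -> dict[str, float]:
    """Rounded percentages for a dict of named (numerator, denominator[, decimals]).

    Entries with a zero denominator are omitted with a warning.
    """
    out: dict[str, float] = {}
    for name, spec in counts.items():
        num, den, *rest = spec
        decimals = rest[0] if rest else 0
        if den <= 0:
            logger.warning("omitting proportion %r: zero denominator", name)
            continue
        out[name] = percent(num, den, decimals)
    return out


def _stage(name: str, **counts) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}
    truth = None

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=int(config.seed))
        paths, truth = write_inputs(sim, outdir / "inputs")
        summary["config"]["simulate"]["seed"] = int(config.seed)
    else:
        paths = {
            "gwas": Path(config.gwas_path),
            "associations": Path(config.associations_path),
            "ppin": Path(config.ppin_path),
            "gene_sets": Path(config.gene_sets_path),
            "drugs": Path(config.drugs_path),
        }
    gwas = pd.read_csv(paths["gwas"], sep="\t")
    assoc_raw = pd.read_csv(paths["associations"], sep="\t")
    collection = enrichment.read_gmt(paths["gene_sets"])
    drug_table = pd.read_csv(paths["drugs"], sep="\t")
    _stage("inputs", snps=gwas["rsid"].nunique(), assoc_rows=len(assoc_raw),
           gene_sets=len(collection), drug_rows=len(drug_table))

    # --- regulatory map ---------------------------------------------------
    rmap = regulatory.build_regulatory_map(
        gwas, assoc_raw, alpha=config.alpha_fdr, cis_window=config.cis_window
    )
    rmap.associations.to_csv(outdir / "regulatory_map.tsv", sep="\t", index=False)
    reg_summary = regulatory.regulatory_summary(rmap)
    summary["regulatory_map"] = reg_summary
    _stage("regulatory_map", snps=len(rmap.snps), genes=len(rmap.genes),
           associations=len(rmap.associations))

    # --- Ai-PPIN ----------------------------------------------------------
    ref = ppin.load_reference_ppin(paths["ppin"], score_threshold=config.ppi_score_threshold)
    mapped = rmap.gene_ids(protein_coding_only=True)
    appin = ppin.induce_disease_network(ref, mapped)
    ppin.write_network(appin, outdir / "appin_edges.tsv", outdir / "appin.graphml")
    summary["network"] = {
        "ref_nodes": ref.number_of_nodes(),
        "ref_edges": ref.number_of_edges(),
        "mapped_protein_coding_genes": len(mapped),
        "appin_nodes": appin.number_of_nodes(),
        "appin_edges": appin.number_of_edges(),
        "clustering_coefficient": (
            ppin.clustering_coefficient(appin) if appin.number_of_nodes() else None
        ),
    }
    _stage("network", ref_nodes=ref.number_of_nodes(), appin_nodes=appin.number_of_nodes(),
           appin_edges=appin.number_of_edges())
    if appin.number_of_edges() == 0:
        raise RuntimeError("network stage produced an empty disease network")

    # --- modules ----------------------------------------------------------
    partition = communities.louvain(appin, seed=int(config.seed))
    stats = communities.qs_test(
        appin, partition, n_rand=int(config.n_rand), alpha=config.alpha_modules,
        seed=int(config.seed) + 1,
    )
    members_rows = [
        (s.label, node)
        for s in stats
        for node in sorted(partition.communities()[s.label], key=str)
    ]
    pd.DataFrame(members_rows, columns=["module", "node"]).to_csv(
        outdir / "module_members.tsv", sep="\t", index=False
    )
    stats_df = pd.DataFrame(
        [
            (s.label, s.n_nodes, s.quality, s.size, s.p_value, s.significant, s.n_null)
            for s in stats
        ],
        columns=["module", "n_nodes", "quality", "size", "p_value", "significant", "n_null"],
    )
    stats_df.to_csv(outdir / "module_stats.tsv", sep="\t", index=False)
    significant = [s for s in stats if s.significant]
    summary["modules"] = {
        "Q": partition.q,
        "n_modules": len(stats),
        "n_significant": len(significant),
        "stats": stats_df.to_dict(orient="records"),
    }
    _stage("modules", n_modules=len(stats), n_significant=len(significant), Q=round(partition.q, 4))

    # --- centrality -------------------------------------------------------
    comms = partition.communities()
    central_by_module: dict[int, set] = {}
    centrality_frames = []
    for s in significant:
        sub = appin.subgraph(comms[s.label])
        if sub.number_of_nodes() < 2 or sub.number_of_edges() < 1:
            logger.info("module %d too small for centrality (n=%d)", s.label, sub.number_of_nodes())
            continue
        scores = centrality_mod.module_centrality(sub)
        cset = centrality_mod.central_nodes(scores, fraction=config.centrality_fraction)
        central_by_module[s.label] = cset.central
        frame = scores.to_frame()
        frame.insert(0, "module", s.label)
        frame["in_top_dc"] = frame["node"].isin(cset.top_dc)
        frame["in_top_cc"] = frame["node"].isin(cset.top_cc)
        frame["in_top_ec"] = frame["node"].isin(cset.top_ec)
        frame["central"] = frame["node"].isin(cset.central)
        centrality_frames.append(frame)
    if centrality_frames:
        pd.concat(centrality_frames, ignore_index=True).to_csv(
            outdir / "centrality.tsv", sep="\t", index=False
        )
    all_central = sorted(set().union(*central_by_module.values())) if central_by_module else []
    summary["centrality"] = {
        "central_by_module": {str(k): sorted(v) for k, v in sorted(central_by_module.items())},
        "n_central": len(all_central),
    }
    _stage("centrality", modules=len(central_by_module), central=len(all_central))

    # --- enrichment -------------------------------------------------------
    annotated = set().union(*(set(m) for _, m in collection.values())) if collection else set()
    universe = set(appin.nodes) & annotated
    shared_genes = {g for g, rec in rmap.genes.items() if rec.category == regulatory.SHARED}
    enr_frames = []
    for s in significant:
        module_genes = comms[s.label]
        if not universe:
            logger.warning("empty annotated universe; skipping enrichment")
            break
        res = enrichment.hypergeom_enrichment(
            module_genes, collection, universe, alpha=config.enrichment_alpha,
            module_label=s.label,
        )
        res = enrichment.flag_shared_central(
            res, shared_genes, central_by_module.get(s.label, set())
        )
        enr_frames.append(res)
    if enr_frames:
        enr = pd.concat(enr_frames, ignore_index=True)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        top = enrichment.top_terms(enr, 5)
        summary["enrichment"] = {
            "universe_size": len(universe),
            "n_enriched_terms": int(enr["enriched"].sum()),
            "n_flagged_terms": int((enr["enriched"] & enr["shared_central_flag"]).sum()),
            "top_terms": top[["module", "set_name", "overlap", "q_value",
                              "shared_central_flag"]].to_dict(orient="records"),
        }
    else:
        enr = pd.DataFrame(columns=enrichment.RESULT_COLUMNS)
        summary["enrichment"] = {"universe_size": len(universe), "n_enriched_terms": 0,
                                 "n_flagged_terms": 0, "top_terms": []}
    _stage("enrichment", universe=len(universe),
           enriched=summary["enrichment"]["n_enriched_terms"])

    # --- drugs ------------------------------------------------------------
    gene_universe = set(assoc_raw["gene"])
    report = drugs.druggable_report(all_central, drug_table, universe=gene_universe)
    with open(outdir / "druggability.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    summary["drugs"] = report.to_dict()
    _stage("drugs", central=report.n_central, druggable=report.n_central_druggable)

    # --- ground-truth checks in simulate mode -----------------------------
    if truth is not None:
        block_nodes = [n for n in appin.nodes if n in truth.blocks]
        ari = adjusted_rand_score(
            [truth.blocks[n] for n in block_nodes],
            [partition.assignment[n] for n in block_nodes],
        ) if block_nodes else float("nan")
        observed_pleio = [1 if d >= 2 else 0 for d in truth.snp_n_diseases.values()]
        planted_rows = enr[enr["set_name"] == truth.planted_set_name]
        summary["ground_truth"] = {
            "block_recovery_ari": float(ari),
            "input_pleiotropic_fraction": float(sum(observed_pleio) / len(observed_pleio)),
            "planted_set_min_q": (
                float(planted_rows["q_value"].min()) if len(planted_rows) else None
            ),
            "planted_set_enriched": bool(planted_rows["enriched"].any()) if len(planted_rows) else False,
            "planted_set_flagged": (
                bool(planted_rows["shared_central_flag"].any()) if len(planted_rows) else False
            ),
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
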