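"""Reference PPI network construction and disease-subnetwork induction.

The reference network (ref-PPIN) comes from a STRING-style scored edge
list: self-links are removed, reciprocal duplicates collapse to one
undirected edge, and only edges with combined score strictly above the
high-confidence threshold (default 0.7) are retained.  The disease
network (Ai-PPIN) is the subgraph induced on the protein-coding genes of
the regulatory map; genes that end up without any qualifying interaction
(degree 0 in the induced subgraph) are excluded from the Ai-PPIN and
reported separately.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "load_reference_ppin",
    "induce_disease_network",
    "clustering_coefficient",
    "write_network",
]

logger = logging.getLogger(__name__)

SCORE_THRESHOLD: float = 0.7


def load_reference_ppin(
    edges: pd.DataFrame | str | Path,
    score_threshold: float = SCORE_THRESHOLD,
    string_raw_scores: bool = False,
    id_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Build the reference PPI graph from a scored edge list.

    ``edges`` is a DataFrame or TSV path with columns
    ``protein_a, protein_b, combined_score``.  Scores must be in [0, 1];
    with ``string_raw_scores=True`` STRING's 0-1000 integers are divided
    by 1000.  Retention requires score strictly greater than
    ``score_threshold``.  Self-links are dropped, duplicate or reciprocal
    pairs collapse to a single undirected edge (the larger score wins).
    ``id_map`` optionally renames node identifiers; unmapped identifiers
    are dropped with a logged count.  Malformed rows are skipped with a
    warning; if every row is malformed, a ``ValueError`` is raised.
    """
    if isinstance(edges, (str, Path)):
        edges = pd.read_csv(edges, sep="\t")
    g = nx.Graph()
    n_bad = n_unmapped = n_valid = 0
    for row in edges.itertuples(index=False):
        try:
            a, b, score = str(row[0]), str(row[1]), float(row[2])
        except (TypeError, ValueError, IndexError):
            n_bad += 1
            continue
        if a in ("", "nan") or b in ("", "nan") or score != score:
            n_bad += 1
            continue
        if string_raw_scores:
            score /= 1000.0
        if not 0.0 <= score <= 1.0:
            n_bad += 1
            continue
        n_valid += 1
        if id_map is not None:
            if a not in id_map or b not in id_map:
                n_unmapped += 1
                continue
            a, b = id_map[a], id_map[b]
        if a == b:
            continue
        if score > score_threshold:
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
    if n_bad:
        logger.warning("skipped %d malformed edge rows", n_bad)
    if n_unmapped:
        logger.info("dropped %d edges with unmappable identifiers", n_unmapped)
    if n_valid == 0:
        raise ValueError("no valid edge rows in the input")
    return g


def induce_disease_network(ref: nx.Graph, gene_ids: Iterable[str]) -> nx.Graph:
    """Induce the disease PPI subnetwork on mapped (protein-coding) genes.

    Keeps only edges with both endpoints in ``gene_ids``; nodes isolated
    within the subgraph are excluded.  Returns a new graph.
    """
    members = set(gene_ids) & set(ref.nodes)
    if not members:
        logger.warning("mapped gene set has no overlap with the reference network")
        return nx.Graph()
    sub = ref.subgraph(members).copy()
    isolated = [n for n, d in sub.degree() if d == 0]
    if isolated:
        logger.info("excluding %d isolated mapped genes from the disease network", len(isolated))
    sub.remove_nodes_from(isolated)
    return sub


def clustering_coefficient(g: nx.Graph) -> float:
    """Average local clustering coefficient (nodes of degree < 2 contribute 0)."""
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined for an empty graph")
    return nx.average_clustering(g)


def write_network(g: nx.Graph, tsv_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Write a graph as a sorted TSV edge list and optionally as GraphML."""
    rows = sorted((min(a, b), max(a, b), d.get("score", "")) for a, b, d in g.edges(data=True))
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
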