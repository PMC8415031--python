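"""Hypergeometric over-representation analysis of modules against gene sets.

Each module is tested against every set of a GMT collection: with a
universe of N annotated genes, a set of K of them and a module testing n,
the over-representation p-value is the upper hypergeometric tail
P(X >= overlap).  BH correction runs per module across the collection;
a term is enriched when q < alpha.  The shared-central flag marks terms
whose module overlap contains at least one gene that is both in the
"shared" regulatory category and central within that module — the
asterisk annotation of the enrichment bar charts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .regulatory import bh_fdr

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeom_pvalue",
    "hypergeom_enrichment",
    "flag_shared_central",
    "top_terms",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "module",
    "set_name",
    "overlap",
    "overlap_genes",
    "set_size",
    "module_size",
    "universe_size",
    "p_value",
    "q_value",
    "enriched",
    "shared_central_flag",
]


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {name: (description, members)}.

    Standard GMT: one set per line, tab-separated name, description, then
    member genes.  Duplicate members collapse; lines with fewer than
    three fields are skipped with a warning.
    """
    collection: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: skipping line with %d field(s)", path, lineno, len(fields))
                continue
            name, desc, *members = fields
            seen: list[str] = []
            for m in members:
                if m and m not in seen:
                    seen.append(m)
            collection[name] = (desc, seen)
    return collection


def write_gmt(collection: Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def hypergeom_pvalue(universe_size: int, set_size: int, module_size: int, overlap: int) -> float:
    """Upper tail P(X >= overlap), X ~ Hypergeometric(N, K, n)."""
    if overlap < 0 or overlap > min(set_size, module_size):
        raise ValueError("overlap must lie in [0, min(K, n)]")
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, module_size))


def hypergeom_enrichment(
    module_genes: Iterable[str],
    collection: Mapping[str, tuple[str, list[str]]],
    universe: Iterable[str],
    alpha: float = 0.05,
    module_label: int | str = 0,
) -> pd.DataFrame:
    """Over-representation of one module against every set of a collection.

    Sets and the module are intersected with the universe before testing;
    BH runs across all sets tested for this module.  Returns one row per
    set with the columns of ``RESULT_COLUMNS`` (shared_central_flag left
    False; see :func:`flag_shared_central`).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    module = set(module_genes) & universe
    n = len(module)
    big_n = len(universe)
    rows = []
    for name in sorted(collection):
        _, members = collection[name]
        gene_set = set(members) & universe
        overlap_genes = sorted(module & gene_set)
        k = len(gene_set)
        p = hypergeom_pvalue(big_n, k, n, len(overlap_genes))
        rows.append((module_label, name, len(overlap_genes), ";".join(overlap_genes), k, n, big_n, p))
    result = pd.DataFrame(
        rows,
        columns=["module", "set_name", "overlap", "overlap_genes", "set_size",
                 "module_size", "universe_size", "p_value"],
    )
    if len(result):
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
        result["enriched"] = result["q_value"] < alpha
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    result["shared_central_flag"] = False
    return result[RESULT_COLUMNS]


def flag_shared_central(
    results: pd.DataFrame,
    shared_genes: Iterable[str],
    central_genes: Iterable[str],
) -> pd.DataFrame:
    """Set ``shared_central_flag`` where a term's module overlap contains a
    gene that is both shared-category and central in that module.

    ``central_genes`` is the central set of the module the results rows
    belong to (use per-module calls when flagging several modules).
    """
    mark = set(shared_genes) & set(central_genes)
    out = results.copy()
    out["shared_central_flag"] = [
        bool(set(genes.split(";")) & mark) if genes else False
        for genes in out["overlap_genes"]
    ]
    return out


def top_terms(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k most significant enriched terms per module (stable order).

    Sorted by q, then p, then set name; returns fewer than k when fewer
    terms are enriched.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    enriched = results[results["enriched"]]
    ordered = enriched.sort_values(["q_value", "p_value", "set_name"], kind="mergesort")
    return ordered.groupby("module", group_keys=False, sort=True).head(k).reset_index(drop=True)
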