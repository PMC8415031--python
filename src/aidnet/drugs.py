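"""Druggability of central proteins from a drug-gene interaction table.

A protein is druggable when it appears with at least one drug in the
table (drug identity is the raw name, case-folded; duplicate rows are
ignored).  The report gives the druggable count and rounded proportion
for the central set and, when a background universe is supplied, the
same for the background; proteins with more than 20 distinct drugs are
singled out as heavily targeted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .regulatory import percent

__all__ = ["DruggabilityReport", "druggable_report", "HEAVY_DRUG_COUNT"]

logger = logging.getLogger(__name__)

#: label proteins with strictly more than this many distinct drugs
HEAVY_DRUG_COUNT: int = 20


@dataclass
class DruggabilityReport:
    n_central: int
    n_central_druggable: int
    percent_druggable: float
    drug_counts: dict[str, int] = field(default_factory=dict)  # per central protein
    heavily_targeted: list[str] = field(default_factory=list)  # > HEAVY_DRUG_COUNT drugs
    n_universe: int | None = None
    n_universe_druggable: int | None = None
    percent_universe_druggable: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_central": self.n_central,
            "n_central_druggable": self.n_central_druggable,
            "percent_druggable": self.percent_druggable,
            "drug_counts": dict(sorted(self.drug_counts.items())),
            "heavily_targeted": self.heavily_targeted,
            "n_universe": self.n_universe,
            "n_universe_druggable": self.n_universe_druggable,
            "percent_universe_druggable": self.percent_universe_druggable,
        }


def druggable_report(
    central_proteins: Iterable[str],
    drug_table: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> DruggabilityReport:
    """Join central proteins against the drug-gene table.

    ``drug_table`` needs columns ``gene, drug``.  ``universe`` (for
    example every gene of the annotation or of the mapped set) enables
    the background proportion.
    """
    central = sorted(set(central_proteins))
    pairs = drug_table[["gene", "drug"]].copy()
    pairs["drug"] = pairs["drug"].astype(str).str.casefold()
    pairs = pairs.drop_duplicates()
    druggable_genes = set(pairs["gene"])

    if not central:
        logger.warning("empty central set: druggability report is all zeros")
        report = DruggabilityReport(0, 0, 0.0)
    else:
        counts_all = pairs.groupby("gene")["drug"].nunique()
        drug_counts = {p: int(counts_all.get(p, 0)) for p in central}
        n_druggable = sum(1 for c in drug_counts.values() if c >= 1)
        report = DruggabilityReport(
            n_central=len(central),
            n_central_druggable=n_druggable,
            percent_druggable=percent(n_druggable, len(central), 0),
            drug_counts=drug_counts,
            heavily_targeted=sorted(p for p, c in drug_counts.items() if c > HEAVY_DRUG_COUNT),
        )
    if universe is not None:
        uni = set(universe)
        if uni:
            n_u_drug = len(uni & druggable_genes)
            report.n_universe = len(uni)
            report.n_universe_druggable = n_u_drug
            report.percent_universe_druggable = percent(n_u_drug, len(uni), 0)
    return report
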