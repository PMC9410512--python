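"""Treatment-recovery metrics over a (reference, disease, treated) triple.

Each gene gets a two-letter category from its regulation calls in
disease-vs-reference and treated-vs-reference: the first letter is the
disease call, the second the treated call, with D = down, U = up, X =
neutral. {DX} and {UX} are recovered genes; {XD}/{XU} were newly
dysregulated by the treatment; {DD}/{UU} did not respond; {DU}/{UD}
switched regulation type — the worst outcome, penalized doubly:

    GER = 100 * (DX + UX - XD - XU - 2 (DU + UD))
              / (DX + DD + DU + UX + UU + UD + XD + XU)

Pathway-level restoration compares alteration scores before and after
treatment: PRE from the WPR pair, CPR from the PTD pair, both as
``(1 - treated/disease) * 100`` with outcomes ideal (= 100), positive
(0-100), null (= 0), or negative (the treatment moved the pathway farther
from reference).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import round_half_up
from .io import GeneSetCollection
from .pathways import score_pathways
from .regulation import DOWN, UP, RegulationTable

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "RecoveryReport",
    "categorize",
    "compute_ger",
    "compute_pre",
    "compute_cpr",
    "analyze_recovery",
]

CATEGORIES = ("DX", "UX", "XD", "XU", "DD", "UU", "UD", "DU", "XX")
_LETTER = {DOWN: "D", UP: "U", "NEUTRAL": "X"}


def categorize(
    reg_disease: RegulationTable,
    reg_treated: RegulationTable,
    scope: list[str] | None = None,
) -> tuple[dict[str, int], pd.Series]:
    """Two-letter category per gene and the counts over all 9 categories.

    Both tables must be against the same reference; if their gene
    universes differ the intersection is used with a warning.
    """
    if reg_disease.comparison[0] != reg_treated.comparison[0]:
        raise ValueError(
            "both comparisons must share the same reference condition "
            f"(got {reg_disease.comparison[0]!r} and {reg_treated.comparison[0]!r})"
        )
    genes = reg_disease.genes
    if not genes.equals(reg_treated.genes):
        genes = genes.intersection(reg_treated.genes)
        logger.warning("gene universes differ; categorizing %d common genes",
                       len(genes))
    if scope is not None:
        genes = genes[genes.isin(set(scope))]
    d = reg_disease.calls.loc[genes].map(_LETTER)
    t = reg_treated.calls.loc[genes].map(_LETTER)
    cats = (d + t).rename("category")
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    return counts, cats


def compute_ger(counts: dict[str, int]) -> float:
    """Gene expression recovery, percent; NaN when nothing was or became
    regulated (zero denominator)."""
    num = (
        counts.get("DX", 0)
        + counts.get("UX", 0)
        - counts.get("XD", 0)
        - counts.get("XU", 0)
        - 2 * (counts.get("DU", 0) + counts.get("UD", 0))
    )
    den = sum(counts.get(c, 0) for c in CATEGORIES if c != "XX")
    if den == 0:
        return math.nan
    return 100.0 * num / den


def compute_pre(wpr_disease: float, wpr_treated: float) -> float:
    """Pathway restoration efficiency: ``(1 - WPR_treated/WPR_disease)*100``.

    Negative when the treatment worsened the pathway's regulation; NaN
    when the disease left the pathway's WPR at 0 (nothing to restore).
    """
    if wpr_disease == 0:
        return math.nan
    return (1.0 - wpr_treated / wpr_disease) * 100.0


def compute_cpr(ptd_disease: float, ptd_treated: float) -> tuple[float, str]:
    """Comprehensive pathway restoration and its outcome class.

    ideal (treated distance 0), positive (reduced), null (unchanged),
    negative (increased); NaN/undefined when the disease distance is 0.
    """
    if ptd_disease == 0:
        return math.nan, "undefined"
    cpr = (1.0 - ptd_treated / ptd_disease) * 100.0
    if ptd_treated == 0:
        outcome = "ideal"
    elif ptd_treated == ptd_disease:
        outcome = "null"
    elif ptd_treated > ptd_disease:
        outcome = "negative"
    else:
        outcome = "positive"
    return cpr, outcome


@dataclass
class RecoveryReport:
    """Category counts, GER, and per-pathway WPR/PRE and PTD/CPR."""

    design: tuple[str, str, str]  # reference, disease, treated
    counts: dict[str, int]
    ger: float
    categories: pd.Series | None = None
    pathway_table: pd.DataFrame | None = None
    scope: str = "all"
    thresholds: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        ref, dis, tre = self.design
        lines = [
            f"# recovery report: reference={ref} disease={dis} treated={tre}",
            "scope\t" + self.scope,
        ]
        lines += [f"{c}\t{self.counts.get(c, 0)}" for c in CATEGORIES]
        ger = "NA" if math.isnan(self.ger) else f"{round_half_up(self.ger, 2):.2f}"
        lines.append(f"GER\t{ger}")
        Path(path).write_text("\n".join(lines) + "\n")
        if self.pathway_table is not None:
            self.pathway_table.to_csv(
                str(path) + ".pathways.tsv", sep="\t", index_label="set_name"
            )


def analyze_recovery(
    reg_disease: RegulationTable,
    reg_treated: RegulationTable,
    sets: GeneSetCollection | None = None,
    scope: list[str] | None = None,
) -> RecoveryReport:
    """Full recovery analysis from the two against-reference comparisons.

    When ``sets`` is given, every pathway also gets its WPR pair + PRE and
    PTD pair + CPR with outcome class.
    """
    counts, cats = categorize(reg_disease, reg_treated, scope=scope)
    ger = compute_ger(counts)
    pathway_table = None
    if sets is not None:
        dis = score_pathways(reg_disease, sets)
        tre = score_pathways(reg_treated, sets)
        rows = []
        for name in dis.index.intersection(tre.index):
            wpr_d, wpr_t = float(dis.at[name, "WPR"]), float(tre.at[name, "WPR"])
            ptd_d, ptd_t = float(dis.at[name, "PTD"]), float(tre.at[name, "PTD"])
            cpr, outcome = compute_cpr(ptd_d, ptd_t)
            rows.append(
                {
                    "set_name": name,
                    "n_quantified": int(dis.at[name, "n_quantified"]),
                    "WPR_disease": wpr_d,
                    "WPR_treated": wpr_t,
                    "PRE": compute_pre(wpr_d, wpr_t),
                    "PTD_disease": ptd_d,
                    "PTD_treated": ptd_t,
                    "CPR": cpr,
                    "outcome": outcome,
                }
            )
        pathway_table = pd.DataFrame(rows).set_index("set_name") if rows else None
    return RecoveryReport(
        design=(reg_disease.comparison[0], reg_disease.comparison[1],
                reg_treated.comparison[1]),
        counts=counts,
        ger=ger,
        categories=cats,
        pathway_table=pathway_table,
        scope="all" if scope is None else "scoped",
    )
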