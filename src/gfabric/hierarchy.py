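"""Gene commanding height (GCH) and the gene master regulator (GMR).

GCH combines how tightly a gene's expression is controlled (REC) with how
strongly it is coordinated with the rest of the transcriptome (mean
squared correlation): ``GCH = (REC + 1) * exp(4 * <COR^2> - 1)``. A gene
with median control and mean squared correlation 0.25 scores exactly 1;
the top scorer in a condition is that condition's gene master regulator.
GCH is a ranking heuristic — correlation cannot say which gene of a pair
is the master — but its top is the most influential, most protected gene.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GeneHierarchy", "compute_gch", "rank_genes", "compute_hierarchy"]


def compute_gch(rec: pd.Series, cor: pd.DataFrame) -> pd.Series:
    """``(REC + 1) * exp(4 * m - 1)`` with m the gene's mean squared
    correlation with every other gene (undefined entries excluded)."""
    c = cor.loc[rec.index, rec.index].to_numpy(dtype=float)
    sq = c**2
    np.fill_diagonal(sq, np.nan)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(sq, axis=1)
    gch = (rec.to_numpy() + 1.0) * np.exp(4.0 * m - 1.0)
    out = pd.Series(gch, index=rec.index, name="GCH")
    n_undef = int(np.isnan(m).sum())
    if n_undef:
        logger.warning(
            "%d gene(s) with all correlations undefined: GCH undefined", n_undef
        )
    return out


@dataclass
class GeneHierarchy:
    condition: str
    gch: pd.Series
    ranking: list[str]

    @property
    def gmr(self) -> str:
        """The gene master regulator: top of the ranking."""
        return self.ranking[0]

    def top(self, k: int = 20) -> list[str]:
        return self.ranking[: min(k, len(self.ranking))]

    def write(self, path: str | Path) -> None:
        ranked = self.gch.loc[self.ranking]
        df = pd.DataFrame(
            {"GCH": ranked, "rank": np.arange(1, len(ranked) + 1)}
        )
        df.to_csv(path, sep="\t", index_label="gene")


def rank_genes(gch: pd.Series, condition: str = "", top_k: int | None = None) -> GeneHierarchy:
    """Descending GCH; ties broken lexicographically by gene id.

    Genes with undefined GCH are excluded from the ranking with a warning.
    """
    finite = gch[np.isfinite(gch)]
    if len(finite) < len(gch):
        logger.warning("%d gene(s) dropped from ranking (undefined GCH)",
                       len(gch) - len(finite))
    if finite.empty:
        raise ValueError("no gene with a finite GCH to rank")
    order = sorted(finite.index, key=lambda g: (-finite[g], str(g)))
    if top_k is not None:
        order_view = order[: min(top_k, len(order))]
        logger.debug("top-%d view: %s", top_k, order_view)
    return GeneHierarchy(condition=condition, gch=gch, ranking=order)


def compute_hierarchy(fabric, cap: float = 100.0) -> GeneHierarchy:
    """Convenience: REC from the fabric's REV, then GCH and the ranking."""
    from .fabric import compute_rec

    rec = compute_rec(fabric.rev, cap=cap)
    gch = compute_gch(rec, fabric.cor)
    return rank_genes(gch, condition=fabric.condition)
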