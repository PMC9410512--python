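"""Two-condition, per-gene comparison: ratio, test, adaptive cut-off, WIR, ITD.

The fold-change significance threshold is not a uniform 1.5x or 2x band:
each gene gets its own cut-off derived from its expression variability in
the two compared conditions, so stably expressed genes are held to a
stricter standard than noisy ones. Beyond the binary call, two graded
measures quantify each gene's contribution to the transcriptomic
alteration:

* **WIR** (weighted individual regulation) — signed: reference expression
  level x (|fold change| - 1) x statistical confidence (1 - p).
* **ITD** (individual transcriptomic distance) — magnitude of the 3-vector
  of relative changes in AVE, REV, and the gene's correlations with all
  other genes; a gene can be NEUTRAL by the fold-change criterion and
  still have a large ITD through changed variability or decoupled
  correlations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fabric import FabricProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationTable",
    "expression_ratio",
    "welch_p",
    "fold_change_cut",
    "classify_regulation",
    "compute_wir",
    "compute_itd_components",
    "compare_conditions",
    "UP",
    "DOWN",
    "NEUTRAL",
]

UP, DOWN, NEUTRAL = "UP", "DOWN", "NEUTRAL"


def expression_ratio(ave_a, ave_b):
    """Signed expression ratio B vs A; negative for down-regulation.

    ``r = B/A``; returns ``r`` if r >= 1 else ``-1/r``, so |x| >= 1 always
    and x = 1 means no change.
    """
    r = np.asarray(ave_b, dtype=float) / np.asarray(ave_a, dtype=float)
    x = np.where(r >= 1.0, r, -1.0 / r)
    return float(x) if x.ndim == 0 else x


def welch_p(values_a, values_b) -> float:
    """Two-tailed heteroscedastic (Welch) t-test p-value on log2 values."""
    a = np.log2(np.asarray(values_a, dtype=float))
    b = np.log2(np.asarray(values_b, dtype=float))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fold_change_cut(rev_a, rev_b):
    """Gene-specific absolute fold-change cut-off (>= 1).

    ``1 + 2 * sqrt((REV_A/100)^2 + (REV_B/100)^2)`` — two root-sum-squared
    CVs above 1, so two conditions each at REV ~ 23% give CUT ~ 1.65 and
    perfectly reproducible genes get CUT = 1 (any significant ratio counts).
    """
    ra = np.asarray(rev_a, dtype=float) / 100.0
    rb = np.asarray(rev_b, dtype=float) / 100.0
    cut = 1.0 + 2.0 * np.sqrt(ra**2 + rb**2)
    return float(cut) if cut.ndim == 0 else cut


def classify_regulation(x, p, cut, p_threshold: float = 0.05):
    """UP if x >= CUT, DOWN if x <= -CUT, both requiring p < p_threshold."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    cut = np.asarray(cut, dtype=float)
    sig = p < p_threshold
    call = np.where(
        sig & (x >= cut), UP, np.where(sig & (x <= -cut), DOWN, NEUTRAL)
    )
    return str(call) if call.ndim == 0 else call


def compute_wir(ave_a, x, p):
    """Weighted individual regulation: ``AVE_A * sign(x) * (|x|-1) * (1-p)``."""
    x = np.asarray(x, dtype=float)
    wir = np.asarray(ave_a, dtype=float) * np.sign(x) * (np.abs(x) - 1.0) * (
        1.0 - np.asarray(p, dtype=float)
    )
    return float(wir) if wir.ndim == 0 else wir


def compute_itd_components(
    x, rev_a, rev_b, cor_a: np.ndarray, cor_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three orthogonal components of ITD for every gene (vectorized).

    * d_AVE = sign(x) (|x| - 1) — relative change of the expression level;
    * d_REV = (REV_B - REV_A)/REV_A (0 when both are 0);
    * d_COR = 1/2 * mean over the other genes of |COR_B - COR_A|,
      undefined correlations excluded from the mean.
    """
    x = np.asarray(x, dtype=float)
    d_ave = np.sign(x) * (np.abs(x) - 1.0)
    ra = np.asarray(rev_a, dtype=float)
    rb = np.asarray(rev_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_rev = np.where((ra == 0) & (rb == 0), 0.0, (rb - ra) / ra)
    diff = np.abs(cor_b - cor_a)
    np.fill_diagonal(diff, np.nan)  # exclude self-correlation from the mean
    with np.errstate(invalid="ignore"):
        d_cor = 0.5 * np.nanmean(diff, axis=1)
    d_cor = np.nan_to_num(d_cor, nan=0.0)
    return d_ave, d_rev, d_cor


@dataclass
class RegulationTable:
    """Per-gene comparison of condition B against reference A.

    ``table`` columns: x (signed fold change), p (Welch p-value), cut
    (gene-specific threshold), call (UP/DOWN/NEUTRAL), wir, itd. Genes
    quantified in only one condition never enter the numeric pipeline;
    they are listed in ``only_in_a`` / ``only_in_b`` (the presence/absence,
    "turned on/off" report).
    """

    comparison: tuple[str, str]
    table: pd.DataFrame
    p_threshold: float = 0.05
    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def counts(self) -> dict[str, int]:
        c = self.table["call"].value_counts()
        return {k: int(c.get(k, 0)) for k in (UP, DOWN, NEUTRAL)}

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path: str | Path, comparison: tuple[str, str]) -> "RegulationTable":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        table.index = table.index.rename(None)
        return cls(comparison, table)


def compare_conditions(
    fabric_a: FabricProfile,
    fabric_b: FabricProfile,
    p_threshold: float = 0.05,
) -> RegulationTable:
    """Build the full RegulationTable for B (e.g. disease) vs A (reference).

    The gene universe is the intersection of the two conditions'
    quantified genes, ordered as in the reference; genes missing from one
    side are reported separately, not scored.
    """
    common = fabric_a.genes.intersection(fabric_b.genes)
    common = fabric_a.genes[fabric_a.genes.isin(common)]  # reference order
    only_a = [g for g in fabric_a.genes if g not in set(common)]
    only_b = [g for g in fabric_b.genes if g not in set(common)]
    if only_a or only_b:
        logger.warning(
            "gene universes differ: %d only in %s, %d only in %s; restricted "
            "to %d common genes",
            len(only_a), fabric_a.condition, len(only_b), fabric_b.condition,
            len(common),
        )

    ave_a = fabric_a.ave.loc[common].to_numpy()
    ave_b = fabric_b.ave.loc[common].to_numpy()
    rev_a = fabric_a.rev.loc[common].to_numpy()
    rev_b = fabric_b.rev.loc[common].to_numpy()

    x = expression_ratio(ave_a, ave_b)

    la = np.log2(fabric_a.normalized.loc[common].to_numpy())
    lb = np.log2(fabric_b.normalized.loc[common].to_numpy())
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    both_flat = (la.std(axis=1, ddof=1) == 0) & (lb.std(axis=1, ddof=1) == 0)
    if both_flat.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[both_flat & equal] = 1.0
        p[both_flat & ~equal] = 0.0

    cut = fold_change_cut(rev_a, rev_b)
    call = classify_regulation(x, p, cut, p_threshold)
    wir = compute_wir(ave_a, x, p)
    cor_a = fabric_a.cor.loc[common, common].to_numpy()
    cor_b = fabric_b.cor.loc[common, common].to_numpy()
    d_ave, d_rev, d_cor = compute_itd_components(x, rev_a, rev_b, cor_a, cor_b)
    itd = np.sqrt(d_ave**2 + d_rev**2 + d_cor**2)

    table = pd.DataFrame(
        {"x": x, "p": p, "cut": cut, "call": call, "wir": wir, "itd": itd},
        index=common,
    )
    return RegulationTable(
        comparison=(fabric_a.condition, fabric_b.condition),
        table=table,
        p_threshold=p_threshold,
        only_in_a=only_a,
        only_in_b=only_b,
    )
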