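"""Significance classification of gene-pair coordination and its remodeling.

With n biological replicates, a Pearson correlation is significantly
non-zero at level p when |r| exceeds the critical value from the
t-distribution with n - 2 degrees of freedom — at n = 4 and p < 0.05 that
is r ~ 0.950, so only near-deterministic co-variation counts. Pairs are:

* SYNERGISTIC  — cor >=  r_critical (expressed together);
* ANTAGONISTIC — cor <= -r_critical (one up when the other is down);
* INDEPENDENT  — |cor| within a near-zero band (a positive finding:
  the two genes' transcription is decoupled);
* UNCLASSIFIED — everything in between, kept explicit, never dropped.

No multiplicity correction is applied to the pairwise tests: with ~10^7
pairs at p < 0.05 the expected false-positive count is substantial and is
logged so the consequence is visible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .fabric import FabricProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SYNERGISTIC",
    "ANTAGONISTIC",
    "INDEPENDENT",
    "UNCLASSIFIED",
    "CoordinationProfile",
    "PartnerSummary",
    "critical_r",
    "classify_pairs",
    "partner_summary",
    "remodeling_diff",
    "RemodelingTable",
]

UNCLASSIFIED = "UNCLASSIFIED"
SYNERGISTIC = "SYNERGISTIC"
ANTAGONISTIC = "ANTAGONISTIC"
INDEPENDENT = "INDEPENDENT"
_LABELS = np.array([UNCLASSIFIED, SYNERGISTIC, ANTAGONISTIC, INDEPENDENT])
_CODE = {lab: i for i, lab in enumerate(_LABELS)}


def critical_r(n: int, p_threshold: float = 0.05) -> float:
    """Two-tailed critical Pearson |r| for significance at ``p_threshold``.

    Inverts ``t = r sqrt((n-2)/(1-r^2))`` at the t(1 - p/2; n-2) quantile.
    """
    if n < 3:
        raise ValueError(f"correlation inference needs n >= 3 replicates, got {n}")
    t = stats.t.ppf(1.0 - p_threshold / 2.0, n - 2)
    return float(t / np.sqrt((n - 2) + t**2))


@dataclass
class CoordinationProfile:
    """Pair classification over a gene scope in one condition.

    ``codes`` is a symmetric int8 matrix over ``genes`` (diagonal is
    UNCLASSIFIED and ignored); ``cor`` keeps the underlying correlations
    for edge lists and diffs.
    """

    condition: str
    genes: pd.Index
    codes: np.ndarray
    cor: np.ndarray
    r_critical: float
    independence_threshold: float

    def label(self, gene_i: str, gene_j: str) -> str:
        i = self.genes.get_loc(gene_i)
        j = self.genes.get_loc(gene_j)
        return str(_LABELS[self.codes[i, j]])

    def labels_for(self, hub: str) -> pd.Series:
        """Label of every other gene's pairing with ``hub``."""
        i = self.genes.get_loc(hub)
        s = pd.Series(_LABELS[self.codes[i]], index=self.genes)
        return s.drop(hub)

    def counts(self) -> dict[str, int]:
        iu = np.triu_indices(len(self.genes), k=1)
        vals, cnt = np.unique(self.codes[iu], return_counts=True)
        out = {lab: 0 for lab in _LABELS}
        for v, c in zip(vals, cnt):
            out[str(_LABELS[v])] = int(c)
        return out

    def to_edge_list(self, include_unclassified: bool = False) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.genes), k=1)
        codes = self.codes[iu, ju]
        keep = np.ones(len(codes), dtype=bool)
        if not include_unclassified:
            keep = codes != _CODE[UNCLASSIFIED]
        return pd.DataFrame(
            {
                "gene_i": self.genes[iu[keep]],
                "gene_j": self.genes[ju[keep]],
                "cor": self.cor[iu[keep], ju[keep]],
                "label": _LABELS[codes[keep]],
            }
        )

    def write(self, path: str | Path, include_unclassified: bool = False) -> None:
        self.to_edge_list(include_unclassified).to_csv(path, sep="\t", index=False)


def classify_pairs(
    fabric: FabricProfile,
    scope: list[str] | None = None,
    independence_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> CoordinationProfile:
    """Label every in-scope pair of the fabric's correlation matrix.

    Pairs with undefined correlation stay UNCLASSIFIED. The expected
    false-positive count of the uncorrected significance calls is logged.
    """
    if scope is None:
        genes = fabric.genes
    else:
        genes = fabric.genes[fabric.genes.isin(set(scope))]
    rc = critical_r(fabric.n_replicates, p_threshold)
    c = fabric.cor.loc[genes, genes].to_numpy(dtype=float)
    codes = np.zeros(c.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[c >= rc] = _CODE[SYNERGISTIC]
        codes[c <= -rc] = _CODE[ANTAGONISTIC]
        codes[np.abs(c) <= independence_threshold] = _CODE[INDEPENDENT]
    codes[np.isnan(c)] = _CODE[UNCLASSIFIED]
    np.fill_diagonal(codes, _CODE[UNCLASSIFIED])
    n_pairs = len(genes) * (len(genes) - 1) // 2
    logger.info(
        "classified %d pairs at p < %g (r_critical = %.3f); expected false "
        "positives under the null: %.0f",
        n_pairs, p_threshold, rc, n_pairs * p_threshold,
    )
    return CoordinationProfile(
        condition=fabric.condition,
        genes=genes,
        codes=codes,
        cor=c,
        r_critical=rc,
        independence_threshold=independence_threshold,
    )


@dataclass
class PartnerSummary:
    """A hub gene's partner percentages over a scope (hub excluded).

    Percentages are of all partners in the scope; they need not sum to
    100 because UNCLASSIFIED pairs exist.
    """

    hub: str
    scope: str
    n_partners: int
    pct_synergistic: float
    pct_antagonistic: float
    pct_independent: float

    def rounded(self, ndigits: int = 1) -> "PartnerSummary":
        return PartnerSummary(
            self.hub,
            self.scope,
            self.n_partners,
            round_half_up(self.pct_synergistic, ndigits),
            round_half_up(self.pct_antagonistic, ndigits),
            round_half_up(self.pct_independent, ndigits),
        )


def partner_summary(
    profile: CoordinationProfile, hub: str, scope_name: str = "all"
) -> PartnerSummary:
    if hub not in profile.genes:
        raise KeyError(f"hub gene {hub!r} not quantified in this profile")
    labels = profile.labels_for(hub)
    n = len(labels)
    if n == 0:
        raise ValueError(f"hub {hub!r} has no partners in scope {scope_name!r}")
    return PartnerSummary(
        hub=hub,
        scope=scope_name,
        n_partners=n,
        pct_synergistic=100.0 * float((labels == SYNERGISTIC).sum()) / n,
        pct_antagonistic=100.0 * float((labels == ANTAGONISTIC).sum()) / n,
        pct_independent=100.0 * float((labels == INDEPENDENT).sum()) / n,
    )


@dataclass
class RemodelingTable:
    """How a hub's partnerships change across conditions.

    ``labels``: partner x condition label matrix. ``changes``: for each
    consecutive condition pair, the partner sets per (from-label,
    to-label) transition — switches (synergistic <-> antagonistic),
    decouplings to INDEPENDENT, and new couplings all appear here.
    """

    hub: str
    labels: pd.DataFrame
    changes: dict[tuple[str, str], dict[tuple[str, str], list[str]]]

    def switches(self, cond_a: str, cond_b: str) -> list[str]:
        tr = self.changes[(cond_a, cond_b)]
        return sorted(
            tr.get((SYNERGISTIC, ANTAGONISTIC), [])
            + tr.get((ANTAGONISTIC, SYNERGISTIC), [])
        )

    def decoupled(self, cond_a: str, cond_b: str) -> list[str]:
        tr = self.changes[(cond_a, cond_b)]
        return sorted(
            g
            for (frm, to), gs in tr.items()
            if to == INDEPENDENT and frm != INDEPENDENT
            for g in gs
        )


def remodeling_diff(
    profiles: list[CoordinationProfile], hub: str
) -> RemodelingTable:
    """Diff a hub's partner labels across >= 2 coordination profiles."""
    if len(profiles) < 2:
        raise ValueError("remodeling needs at least two conditions")
    common = profiles[0].genes
    for p in profiles[1:]:
        common = common[common.isin(set(p.genes))]
    cols = {}
    for p in profiles:
        cols[p.condition] = p.labels_for(hub).reindex(common.drop(hub))
    labels = pd.DataFrame(cols)
    changes: dict[tuple[str, str], dict[tuple[str, str], list[str]]] = {}
    conds = list(labels.columns)
    for a, b in zip(conds, conds[1:]):
        tr: dict[tuple[str, str], list[str]] = {}
        moved = labels.index[labels[a] != labels[b]]
        for g in moved:
            tr.setdefault((labels.at[g, a], labels.at[g, b]), []).append(g)
        changes[(a, b)] = tr
    return RemodelingTable(hub=hub, labels=labels, changes=changes)
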