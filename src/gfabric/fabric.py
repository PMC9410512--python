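"""Per-condition transcriptome fabric: AVE, REV, COR, and control scores.

A condition's "fabric" characterizes every gene by three independent
feature families:

* **AVE** — average expression across biological replicates, in multiples
  of the condition's *median* gene expression (the median gene has AVE = 1).
* **REV** — relative expression variability, in percent: the mid-interval
  of the chi-square confidence interval for the coefficient of variation
  (CV) of expression across biological replicates. With few replicates the
  point CV is a noisy estimate; the mid-interval of its chi-square
  confidence band is a conservative, interval-aware summary of how loosely
  a gene's expression is controlled.
* **COR** — Pearson correlation of log2 expression between every pair of
  genes across the replicates of that one condition.

From REV derive the control scores: **REC** (relative expression control,
``median REV / REV - 1``; positive = more tightly controlled than the
median gene) and its pathway version **PREC**.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .io import ExpressionDataError, ExpressionSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "FabricProfile",
    "ControlScores",
    "collapse_and_normalize",
    "compute_ave",
    "compute_rev",
    "rev_interval_factor",
    "compute_cor",
    "compute_rec",
    "compute_prec",
    "compute_fabric",
    "compute_control_scores",
    "value_count",
    "fold_increase",
]


# ---------------------------------------------------------------------------
# collapsing and normalization
# ---------------------------------------------------------------------------

def collapse_and_normalize(es: ExpressionSet) -> ExpressionSet:
    """Collapse spots to genes (mean over valid spots) and median-scale.

    After collapsing, every value is divided by the median over genes of
    the per-gene replicate mean, so the median gene's AVE is exactly 1.
    """
    if es.spot_map is not None:
        arr = es.values.to_numpy()
        rows = []
        for gene, idx in es.spot_map.items():
            rows.append(arr[idx].mean(axis=0))
        mat = pd.DataFrame(rows, index=list(es.spot_map), columns=es.values.columns)
    else:
        mat = es.values.copy()
    scale = float(np.median(mat.mean(axis=1).to_numpy()))
    return ExpressionSet(es.condition, mat / scale, None)


def compute_ave(es: ExpressionSet) -> pd.Series:
    """Per-gene mean across replicates of the normalized matrix.

    Expects ``es`` already collapsed and median-normalized, so the median
    over genes is 1 by construction.
    """
    return es.values.mean(axis=1).rename("AVE")


# ---------------------------------------------------------------------------
# REV: chi-square mid-interval coefficient of variation
# ---------------------------------------------------------------------------

def rev_interval_factor(nu, alpha: float = 0.05):
    """Mid-interval factor of the chi-square CI for a CV with ``nu`` d.o.f.

    ``0.5 * (sqrt(nu / chi2(1-alpha/2; nu)) + sqrt(nu / chi2(alpha/2; nu)))``
    — about 2.15 for nu = 3 (four replicates) at alpha = 0.05.
    """
    nu = np.asarray(nu, dtype=float)
    hi = stats.chi2.ppf(1 - alpha / 2, nu)
    lo = stats.chi2.ppf(alpha / 2, nu)
    return 0.5 * (np.sqrt(nu / hi) + np.sqrt(nu / lo))


def compute_rev(es: ExpressionSet, alpha: float = 0.05) -> pd.Series:
    """Relative expression variability, percent, per gene.

    Sample CV (s over mean, across replicates) widened by the chi-square
    mid-interval factor. When a gene is probed by several spots, per-spot
    CVs are pooled as their root mean square and the degrees of freedom
    add over spots (n - 1 each), keeping technical replication additive
    in nu.
    """
    arr = es.values.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 2:
        raise ExpressionDataError("REV needs >= 2 replicates")
    if es.spot_map is not None:
        cvs, nus, genes = [], [], []
        for gene, idx in es.spot_map.items():
            sub = arr[idx]
            cv_spots = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
            cvs.append(float(np.sqrt(np.mean(cv_spots**2))))
            nus.append(len(idx) * (n - 1))
            genes.append(gene)
        cv = np.array(cvs)
        nu = np.array(nus, dtype=float)
        index = pd.Index(genes)
    else:
        cv = arr.std(axis=1, ddof=1) / arr.mean(axis=1)
        nu = np.full(arr.shape[0], n - 1, dtype=float)
        index = es.values.index
    rev = 100.0 * cv * rev_interval_factor(nu, alpha)
    return pd.Series(rev, index=index, name="REV")


# ---------------------------------------------------------------------------
# COR: log2 Pearson correlation matrix
# ---------------------------------------------------------------------------

def compute_cor(es: ExpressionSet) -> pd.DataFrame:
    """Pearson correlation of log2 expression across replicates, all pairs.

    Genes with zero variance across replicates get undefined (NaN)
    off-diagonal correlations — they carry no co-variation information —
    and are excluded from any downstream average. The diagonal is exactly 1.
    """
    logx = np.log2(es.values.to_numpy(dtype=float))
    sd = logx.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(logx)
    c = np.clip(c, -1.0, 1.0)
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero log2 variance: correlations set undefined",
            int(degenerate.sum()),
        )
        c[degenerate, :] = np.nan
        c[:, degenerate] = np.nan
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=es.values.index, columns=es.values.index)


# ---------------------------------------------------------------------------
# control scores
# ---------------------------------------------------------------------------

def compute_rec(rev: pd.Series, cap: float = 100.0) -> pd.Series:
    """Relative expression control: ``median(REV) / REV - 1``.

    A gene at the transcriptome's median variability scores 0; tightly
    controlled genes score positive. REV = 0 (identical replicates) would
    be infinite control and is reported capped at ``cap``.
    """
    med = float(rev.median())
    with np.errstate(divide="ignore"):
        rec = med / rev - 1.0
    rec = rec.clip(upper=cap)
    return rec.rename("REC")


def compute_prec(rev: pd.Series, sets: GeneSetCollection) -> dict[str, float]:
    """Pathway relative expression control per gene set.

    ``median REV over all genes / median REV over the set's quantified
    members - 1``; sets with no quantified member are skipped with a
    warning.
    """
    med = float(rev.median())
    out: dict[str, float] = {}
    for name, members in sets.items():
        present = rev.index.intersection(members)
        if len(present) == 0:
            logger.warning("gene set %r has no quantified member; skipped", name)
            continue
        out[name] = med / float(rev.loc[present].median()) - 1.0
    return out


@dataclass
class ControlScores:
    rec: pd.Series
    prec: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the fabric object
# ---------------------------------------------------------------------------

@dataclass
class FabricProfile:
    """AVE/REV/COR of one condition, plus the normalized replicate matrix.

    ``normalized`` keeps the collapsed, median-scaled genes x replicates
    matrix so that two-condition tests (Welch t on log2 values) can be run
    without re-reading the raw data.
    """

    condition: str
    ave: pd.Series
    rev: pd.Series
    cor: pd.DataFrame
    n_replicates: int
    normalized: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.ave.index

    @property
    def rev_median(self) -> float:
        return float(self.rev.median())

    @property
    def rev_mean(self) -> float:
        return float(self.rev.mean())

    def write(self, out_dir: str | Path) -> None:
        """Serialize as <label>.genes.tsv (AVE/REV/REC) + <label>.cor.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab = pd.DataFrame(
            {"AVE": self.ave, "REV": self.rev, "REC": compute_rec(self.rev)}
        )
        tab.to_csv(out / f"{self.condition}.genes.tsv", sep="\t", index_label="gene")
        self.cor.to_csv(out / f"{self.condition}.cor.tsv", sep="\t", index_label="gene")
        self.normalized.to_csv(
            out / f"{self.condition}.normalized.tsv", sep="\t", index_label="gene"
        )

    @classmethod
    def read(cls, out_dir: str | Path, condition: str) -> "FabricProfile":
        out = Path(out_dir)
        tab = pd.read_csv(out / f"{condition}.genes.tsv", sep="\t", index_col="gene")
        cor = pd.read_csv(out / f"{condition}.cor.tsv", sep="\t", index_col="gene")
        norm = pd.read_csv(
            out / f"{condition}.normalized.tsv", sep="\t", index_col="gene"
        )
        cor.columns = cor.index
        return cls(
            condition=condition,
            ave=tab["AVE"],
            rev=tab["REV"],
            cor=cor,
            n_replicates=norm.shape[1],
            normalized=norm,
        )


def compute_fabric(es: ExpressionSet, alpha: float = 0.05) -> FabricProfile:
    """Full fabric of one condition from a (possibly spot-level) matrix."""
    rev = compute_rev(es, alpha=alpha)  # scale-invariant: raw spot-level is fine
    norm = collapse_and_normalize(es)
    ave = compute_ave(norm)
    rev = rev.reindex(ave.index)
    cor = compute_cor(norm)
    return FabricProfile(
        condition=es.condition,
        ave=ave,
        rev=rev,
        cor=cor,
        n_replicates=es.n_replicates,
        normalized=norm.values,
    )


def compute_control_scores(
    fabric: FabricProfile,
    sets: GeneSetCollection | None = None,
    cap: float = 100.0,
) -> ControlScores:
    rec = compute_rec(fabric.rev, cap=cap)
    prec = compute_prec(fabric.rev, sets) if sets is not None else {}
    return ControlScores(rec=rec, prec=prec)


# ---------------------------------------------------------------------------
# bookkeeping identities
# ---------------------------------------------------------------------------

def value_count(n_genes: int) -> dict[str, int]:
    """Number of fabric values for ``n`` genes: n AVEs + n REVs + C(n,2) CORs."""
    pairs = n_genes * (n_genes - 1) // 2
    return {"ave": n_genes, "rev": n_genes, "cor": pairs, "total": 2 * n_genes + pairs}


def fold_increase(n_genes: int) -> int:
    """Fold increase of fabric values over an AVE-only characterization."""
    return int(round_half_up(value_count(n_genes)["total"] / n_genes, 0))
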