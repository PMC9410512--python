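"""Pathway-level aggregation of per-gene alteration: WPR and PTD.

Both scores share the form ``(100 / |set|) * sqrt(sum of squares)`` over a
gene set's quantified members — WPR over the WIR values (expression
regulation), PTD over the ITD values (full transcriptomic distance). The
shared prefactor means any ratio of two scores over the same set (the
basis of the recovery metrics PRE and CPR) is independent of it. Note
that adding a member with zero alteration strictly lowers a score: these
are per-member densities, not sums.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .regulation import RegulationTable

logger = logging.getLogger(__name__)

__all__ = ["compute_wpr", "compute_ptd", "score_pathways"]


def _rss_score(values) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("pathway score needs at least one quantified member")
    return 100.0 / v.size * float(np.sqrt(np.sum(v**2)))


def compute_wpr(wir_values) -> float:
    """Weighted pathway regulation: ``(100/{G}) * sqrt(sum WIR_i^2)``."""
    return _rss_score(wir_values)


def compute_ptd(itd_values) -> float:
    """Pathway transcriptomic distance: ``(100/{G}) * sqrt(sum ITD_i^2)``."""
    return _rss_score(itd_values)


def score_pathways(reg: RegulationTable, sets: GeneSetCollection) -> pd.DataFrame:
    """WPR and PTD for every gene set, on the comparison's gene universe.

    Membership counts use quantified members only; total membership is
    reported alongside so coverage is visible. Sets with no quantified
    member are skipped with a warning.
    """
    rows = []
    universe = reg.genes
    for name, members in sets.items():
        present = universe.intersection(members)
        if len(present) == 0:
            logger.warning("gene set %r: no member quantified; skipped", name)
            continue
        sub = reg.table.loc[present]
        rows.append(
            {
                "set_name": name,
                "comparison": f"{reg.comparison[0]}->{reg.comparison[1]}",
                "n_members": len(members),
                "n_quantified": len(present),
                "WPR": compute_wpr(sub["wir"]),
                "PTD": compute_ptd(sub["itd"]),
            }
        )
    return pd.DataFrame(rows).set_index("set_name") if rows else pd.DataFrame(
        columns=["comparison", "n_members", "n_quantified", "WPR", "PTD"]
    )
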