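"""Reading, writing, and validation of expression tables, gene sets, and designs.

Expression tables are delimited text (TAB or comma, auto-detected) with a
header row of replicate labels and a first column of gene or probing-spot
identifiers. Values must be strictly positive, linear-scale intensities:
background subtraction and any flooring of values below detection are the
caller's responsibility and are validated, not performed, here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionSet",
    "GeneSetCollection",
    "StudyDesign",
    "ExpressionDataError",
    "read_expression_set",
    "write_expression_set",
    "read_gene_sets",
    "write_gene_sets",
    "read_spot_map",
]


class ExpressionDataError(ValueError):
    """Raised when an input table violates the expression-data contract."""


@dataclass
class ExpressionSet:
    """A genes x replicates matrix for one experimental condition.

    ``values`` rows are gene identifiers, or probing-spot identifiers when
    ``spot_map`` is given; columns are biological replicates (independent
    animals/samples). ``spot_map`` maps each gene id to the positional row
    indices of the spots probing it; spot collapsing happens downstream so
    that replicate variability can be pooled over spots.
    """

    condition: str
    values: pd.DataFrame
    spot_map: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 2:
            raise ExpressionDataError(
                f"condition {self.condition!r}: need >= 2 replicates, got {v.shape[1]}"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [
                (v.index[i], v.columns[j])
                for i, j in zip(*np.nonzero(~np.vectorize(_is_number)(arr)))
            ]
            raise ExpressionDataError(
                f"condition {self.condition!r}: non-numeric cells at {bad[:5]}"
            )
        mask = ~np.isfinite(arr) | (arr <= 0)
        if mask.any():
            i, j = np.nonzero(mask)
            coords = [(str(v.index[a]), str(v.columns[b])) for a, b in zip(i[:5], j[:5])]
            raise ExpressionDataError(
                f"condition {self.condition!r}: non-positive or non-finite values "
                f"at (row, replicate) {coords}"
                + (" ..." if mask.sum() > 5 else "")
            )
        if self.spot_map is None and v.index.has_duplicates:
            dupes = sorted(set(v.index[v.index.duplicated()].astype(str)))
            raise ExpressionDataError(
                f"condition {self.condition!r}: duplicate identifiers without a "
                f"spot map: {dupes[:10]}"
            )
        if self.spot_map is not None:
            n = v.shape[0]
            for g, idx in self.spot_map.items():
                if not idx or min(idx) < 0 or max(idx) >= n:
                    raise ExpressionDataError(
                        f"spot map for gene {g!r} has out-of-range row indices"
                    )

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        if self.spot_map is not None:
            return list(self.spot_map)
        return [str(g) for g in self.values.index]

    @property
    def replicate_labels(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def is_spot_level(self) -> bool:
        return self.spot_map is not None


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_set(
    path: str, condition_label: str, spot_map_path: str | None = None
) -> ExpressionSet:
    """Read a delimited expression table and validate it.

    With ``spot_map_path`` (two-column TSV: spot_id, gene_id), rows stay at
    spot level and the returned set carries a gene -> row-index map; spots
    absent from the map are treated as single-spot genes under their own id.
    """
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str).rename(None)
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.nonzero(bad.to_numpy())
        coords = [(str(raw.index[a]), str(raw.columns[b])) for a, b in zip(i[:5], j[:5])]
        raise ExpressionDataError(f"{path}: non-numeric cells at {coords}")
    spot_map = None
    if spot_map_path is not None:
        spot_to_gene = read_spot_map(spot_map_path)
        pos = {s: k for k, s in enumerate(num.index)}
        spot_map = {}
        for spot in num.index:
            gene = spot_to_gene.get(spot, spot)
            spot_map.setdefault(gene, []).append(pos[spot])
    return ExpressionSet(condition_label, num.astype(float), spot_map)


def read_spot_map(path: str) -> dict[str, str]:
    """Two-column delimited file (spot_id, gene_id) -> {spot: gene}."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionDataError(f"{path}: spot map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_expression_set(es: ExpressionSet, path: str) -> None:
    es.values.to_csv(path, sep="\t", index_label="id")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT), kept in file order.

    Members need not all be present in an ExpressionSet; coverage is
    reported when sets are scored.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ExpressionDataError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB members...``.

    Duplicate members within a set are dropped (order preserved) with a
    logged warning; a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionDataError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicated member(s); de-duplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gsc: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class StudyDesign:
    """Reference / disease / optionally treated condition labels."""

    reference: str
    disease: str
    treated: str | None = None

    def __post_init__(self) -> None:
        labels = [self.reference, self.disease] + (
            [self.treated] if self.treated is not None else []
        )
        if len(set(labels)) != len(labels):
            raise ExpressionDataError(f"design labels must be distinct: {labels}")

    def validate_against(self, conditions: dict[str, ExpressionSet]) -> None:
        for lab in (self.reference, self.disease, self.treated):
            if lab is not None and lab not in conditions:
                raise ExpressionDataError(
                    f"design label {lab!r} has no loaded expression set "
                    f"(have {sorted(conditions)})"
                )
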