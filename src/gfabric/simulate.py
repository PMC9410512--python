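"""Synthetic expression studies with known ground truth.

The generator emulates the study design the fabric machinery targets:
small groups (default 4) of biological replicates per condition, positive
right-skewed intensities, and block-structured co-expression. Log2
expression is drawn from a multivariate normal whose correlation matrix
is assembled from within-block constants, then exponentiated — i.e., a
correlated log-normal model, chosen because correlations are defined on
log2 values and microarray/sequencing intensities are positive and
right-skewed. Per-gene linear-scale means and coefficients of variation
are matched exactly by the log-normal moment relations
``sigma_ln = sqrt(ln(1 + CV^2))``, ``mu_ln = ln(mean) - sigma_ln^2 / 2``.

Optionally each gene is probed by several spots, each spot adding
independent multiplicative log-normal technical noise.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionSet, write_expression_set

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "ConditionSpec",
    "SimulationSpec",
    "simulate_study",
    "make_three_condition_fixture",
    "FixtureTruth",
    "write_study",
]


@dataclass
class Block:
    """A co-expression block: member gene indices and their common
    within-block log2 correlation."""

    members: list[int]
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"block correlation {self.rho} outside [-1, 1]")


@dataclass
class ConditionSpec:
    label: str
    mean: np.ndarray  # per-gene linear-scale mean
    cv: np.ndarray    # per-gene biological CV (linear scale)
    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if (self.mean <= 0).any():
            raise ValueError("means must be positive")
        if (self.cv < 0).any():
            raise ValueError("CVs must be non-negative")


@dataclass
class SimulationSpec:
    n_genes: int
    conditions: list[ConditionSpec]
    n_replicates: int = 4
    spots_per_gene: int = 1
    technical_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.conditions:
            if len(c.mean) != self.n_genes or len(c.cv) != self.n_genes:
                raise ValueError(
                    f"condition {c.label!r}: mean/cv length != n_genes"
                )


def _assemble_correlation(n: int, blocks: list[Block]) -> np.ndarray:
    r = np.eye(n)
    touched: set[int] = set()
    overlapping = False
    for b in blocks:
        if touched & set(b.members):
            overlapping = True
        touched |= set(b.members)
        idx = np.asarray(b.members)
        r[np.ix_(idx, idx)] = b.rho
    np.fill_diagonal(r, 1.0)
    w = np.linalg.eigvalsh(r)
    if w.min() < -1e-10:
        if not overlapping:
            raise ValueError(
                "assembled correlation matrix is not positive semi-definite; "
                "check block correlations"
            )
        # overlapping blocks can conflict; project to the nearest PSD matrix
        vals, vecs = np.linalg.eigh(r)
        adj = float(-vals[vals < 0].sum())
        vals = np.clip(vals, 0.0, None)
        r = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        logger.warning(
            "overlapping blocks forced a nearest-PSD projection "
            "(clipped eigenvalue mass %.3g)", adj,
        )
    return r


def simulate_study(spec: SimulationSpec) -> dict[str, ExpressionSet]:
    """Draw every condition's (possibly spot-level) expression matrix.

    Deterministic given ``spec.seed``; condition draws are independent
    streams spawned from the seed so adding a condition does not perturb
    the others.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.conditions))
    out: dict[str, ExpressionSet] = {}
    for cspec, ss in zip(spec.conditions, children):
        rng = np.random.default_rng(ss)
        out[cspec.label] = _simulate_condition(cspec, spec, rng)
    return out


def _simulate_condition(
    cspec: ConditionSpec, spec: SimulationSpec, rng: np.random.Generator
) -> ExpressionSet:
    n, m = spec.n_genes, spec.n_replicates
    sigma_ln = np.sqrt(np.log1p(cspec.cv**2))
    mu_ln = np.log(cspec.mean) - sigma_ln**2 / 2.0
    r = _assemble_correlation(n, cspec.blocks)
    # draw correlated standard normals via eigen decomposition (supports
    # the degenerate rho = 1 blocks used in tests)
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 0.0, None)
    z = rng.standard_normal((m, n)) @ (vecs * np.sqrt(vals)).T
    lin = np.exp(mu_ln[:, None] + sigma_ln[:, None] * z.T)  # genes x replicates
    genes = [f"g{i:04d}" for i in range(n)]
    cols = [f"{cspec.label}_r{j + 1}" for j in range(m)]
    if spec.spots_per_gene <= 1:
        df = pd.DataFrame(lin, index=genes, columns=cols)
        return ExpressionSet(cspec.label, df)
    s = spec.spots_per_gene
    tech_sigma = np.sqrt(np.log1p(spec.technical_cv**2))
    noise = np.exp(
        rng.standard_normal((n * s, m)) * tech_sigma - tech_sigma**2 / 2.0
    )
    spots = np.repeat(lin, s, axis=0) * noise
    spot_ids = [f"g{i:04d}_s{k + 1}" for i in range(n) for k in range(s)]
    df = pd.DataFrame(spots, index=spot_ids, columns=cols)
    spot_map = {g: list(range(i * s, (i + 1) * s)) for i, g in enumerate(genes)}
    return ExpressionSet(cspec.label, df, spot_map)


# ---------------------------------------------------------------------------
# the canonical three-condition fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureTruth:
    """Ground-truth sidecar of the three-condition fixture."""

    table: pd.DataFrame  # per gene: means per condition, cv, block, designed calls
    counts: dict[str, int]  # designed recovery-category counts on the pathway
    pathway: list[str]
    set_name: str = "designed_pathway"

    def write(self, path: str | Path) -> None:
        self.table.to_csv(str(path), sep="\t", index_label="gene")
        Path(str(path) + ".counts.json").write_text(json.dumps(self.counts))


def make_three_condition_fixture(
    seed: int,
    n_genes: int = 200,
    n_pathway: int = 40,
    cv: float = 0.02,
    restored: str = "partial",
) -> tuple[dict[str, ExpressionSet], FixtureTruth]:
    """A small NN/IN/IT study with designed recovery categories.

    A 40-gene "pathway" is dysregulated in the disease condition IN and,
    depending on ``restored``:

    * ``"partial"`` — restored per a fixed category design
      (DX = 7, UX = 5, XD = 2, XU = 0, DD = 1, UU/UD/DU = 0) so recovery
      metrics have exact expected counts;
    * ``"full"`` — IT is byte-identical to NN (ideal recovery, CPR = 100);
    * ``"worse"`` — IT is dysregulated farther than IN (negative CPR).

    The replicate CV is kept low (default 2%) so the designed calls are
    the deterministic outcome of the pipeline: designed 4-fold shifts sit
    far above the gene-specific cut-offs, and the per-gene Welch tests on
    4 + 4 replicates are decisively significant.
    """
    if restored not in ("partial", "full", "worse"):
        raise ValueError(f"unknown restoration mode {restored!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F]))
    base = 2.0 ** rng.normal(0.0, 1.5, size=n_genes)  # spread of expression levels
    cvs = np.full(n_genes, cv)

    up, down = 4.0, 0.25
    calls_in = np.array(["X"] * n_genes)
    calls_it = np.array(["X"] * n_genes)
    # designed categories on the first n_pathway genes, mirroring a
    # partially restored pathway: first letter = disease, second = treated
    design = ["DX"] * 7 + ["UX"] * 5 + ["XD"] * 2 + ["DD"] * 1
    design += ["XX"] * (n_pathway - len(design))
    mean_in = base.copy()
    mean_it = base.copy()
    for i, cat in enumerate(design):
        d, t = cat
        if d == "D":
            mean_in[i] = base[i] * down
        elif d == "U":
            mean_in[i] = base[i] * up
        if restored == "partial":
            if t == "D":
                mean_it[i] = base[i] * down
            elif t == "U":
                mean_it[i] = base[i] * up
        elif restored == "worse" and d != "X":
            mean_it[i] = base[i] * (down / 4 if d == "D" else up * 4)
        calls_in[i] = d
        calls_it[i] = t if restored == "partial" else (
            "X" if restored == "full" else d
        )

    # distinct co-expression blocks per condition: the pathway is tightly
    # synergistic in NN, partially rewired in IN
    blocks_nn = [Block(list(range(0, 10)), 0.95)]
    blocks_in = [Block(list(range(10, 20)), 0.95)]
    blocks_it = [Block(list(range(0, 10)), 0.95)]

    conds = [
        ConditionSpec("NN", base, cvs, blocks_nn),
        ConditionSpec("IN", mean_in, cvs, blocks_in),
        ConditionSpec("IT", mean_it, cvs, blocks_it),
    ]
    spec = SimulationSpec(n_genes=n_genes, conditions=conds, seed=seed)
    study = simulate_study(spec)
    if restored == "full":
        # ideal recovery: the treated transcriptome IS the reference one
        study["IT"] = ExpressionSet(
            "IT",
            study["NN"].values.rename(
                columns=lambda c: c.replace("NN_", "IT_")
            ),
        )
        calls_it[:] = "X"

    genes = list(study["NN"].values.index)
    counts = {
        c: int(sum(1 for i in range(n_pathway) if calls_in[i] + calls_it[i] == c))
        for c in ("DX", "UX", "XD", "XU", "DD", "UU", "UD", "DU", "XX")
    }
    block_id = np.full(n_genes, -1)
    block_id[:10] = 0
    truth = FixtureTruth(
        table=pd.DataFrame(
            {
                "mean_NN": base,
                "mean_IN": mean_in,
                "mean_IT": mean_it,
                "cv": cvs,
                "block_NN": block_id,
                "call_IN": calls_in,
                "call_IT": calls_it,
            },
            index=genes,
        ),
        counts=counts,
        pathway=genes[:n_pathway],
    )
    return study, truth


def write_study(
    study: dict[str, ExpressionSet],
    out_dir: str | Path,
    truth: FixtureTruth | None = None,
) -> None:
    """Write each condition as a TSV (plus the ground-truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, es in study.items():
        write_expression_set(es, out / f"{label}.tsv")
    if truth is not None:
        truth.write(out / "ground_truth.tsv")
        with open(out / f"{truth.set_name}.gmt", "w") as fh:
            fh.write(
                "\t".join([truth.set_name, "designed fixture pathway",
                           *truth.pathway]) + "\n"
            )
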