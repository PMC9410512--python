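"""End-to-end orchestration: fabric -> regulation -> hierarchy /
coordination / pathways -> recovery, from a single config.

Every numeric threshold used anywhere in the run is recorded in the
manifest (``manifest.json``) next to the outputs, so a report can always
be traced back to its parameters.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coordination import classify_pairs
from .fabric import compute_fabric
from .hierarchy import compute_hierarchy
from .io import StudyDesign, read_expression_set, read_gene_sets
from .pathways import score_pathways
from .recovery import analyze_recovery
from .regulation import compare_conditions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    expressions: dict[str, str]          # condition label -> table path
    reference: str
    disease: str
    out_dir: str
    treated: str | None = None
    spot_maps: dict[str, str] = field(default_factory=dict)
    gene_sets: str | None = None
    p_threshold: float = 0.05
    independence_threshold: float = 0.05
    rev_alpha: float = 0.05
    rec_cap: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("p_threshold", self.p_threshold),
            ("independence_threshold", self.independence_threshold),
            ("rev_alpha", self.rev_alpha),
        ):
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        StudyDesign(self.reference, self.disease, self.treated)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    Missing treated condition skips the recovery stage with a logged
    notice; everything else still completes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    conditions = {}
    for label, path in config.expressions.items():
        spot_map = config.spot_maps.get(label)
        conditions[label] = read_expression_set(path, label, spot_map)
    design = StudyDesign(config.reference, config.disease, config.treated)
    design.validate_against(conditions)
    sets = read_gene_sets(config.gene_sets) if config.gene_sets else None

    fabrics = {}
    for label, es in conditions.items():
        fab = compute_fabric(es, alpha=config.rev_alpha)
        fab.write(out / "fabric")
        fabrics[label] = fab
    outputs["fabric"] = out / "fabric"

    reg_disease = compare_conditions(
        fabrics[design.reference], fabrics[design.disease], config.p_threshold
    )
    reg_path = out / f"regulation_{design.reference}_vs_{design.disease}.tsv"
    reg_disease.write(reg_path)
    outputs["regulation_disease"] = reg_path

    hier = compute_hierarchy(fabrics[design.reference], cap=config.rec_cap)
    hier_path = out / f"hierarchy_{design.reference}.tsv"
    hier.write(hier_path)
    outputs["hierarchy"] = hier_path

    scope = None
    if sets is not None:
        scope = sorted({g for members in sets.sets.values() for g in members})
    coord = classify_pairs(
        fabrics[design.reference],
        scope=scope,
        independence_threshold=config.independence_threshold,
        p_threshold=config.p_threshold,
    )
    coord_path = out / f"coordination_{design.reference}.tsv"
    coord.write(coord_path)
    outputs["coordination"] = coord_path

    if sets is not None:
        scores = score_pathways(reg_disease, sets)
        scores_path = out / "pathway_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index_label="set_name")
        outputs["pathway_scores"] = scores_path

    if design.treated is not None:
        reg_treated = compare_conditions(
            fabrics[design.reference], fabrics[design.treated],
            config.p_threshold,
        )
        reg_t_path = out / f"regulation_{design.reference}_vs_{design.treated}.tsv"
        reg_treated.write(reg_t_path)
        outputs["regulation_treated"] = reg_t_path
        report = analyze_recovery(reg_disease, reg_treated, sets=sets)
        rec_path = out / "recovery.tsv"
        report.write(rec_path)
        outputs["recovery"] = rec_path
    else:
        logger.info("no treated condition in the design; recovery stage skipped")

    manifest = {
        "gfabric_version": __version__,
        "config": asdict(config),
        "thresholds": {
            "p_threshold": config.p_threshold,
            "independence_threshold": config.independence_threshold,
            "rev_alpha": config.rev_alpha,
            "rec_cap": config.rec_cap,
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs
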