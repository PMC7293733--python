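"""End-to-end orchestration: one config, fixed seeds, a run manifest.

Stages run in order diffexpr -> survival -> drugsens (if a panel is given)
-> positivity.  Each stage writes a TSV plus a JSON metadata sidecar; the
manifest records SHA-256 digests of every output, so identical config + seed
implies identical digests.  The single global seed fans out to per-stage
child seeds through a stage-name hash, so adding a stage never shifts
another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr as de
from . import drugsens as ds
from . import positivity as pos
from . import survival as surv
from .core import (
    CellLinePanel,
    ExpressionMatrix,
    ResultTable,
    SampleAnnotations,
    read_expression_matrix,
    read_sample_annotation,
)

logger = logging.getLogger("fgfr_atlas")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All inputs and stage thresholds for one pipeline run."""

    matrix_path: str
    annotation_path: str
    out_dir: str
    genes: list[str] = field(default_factory=lambda: ["FGFR1", "FGFR2", "FGFR3", "FGFR4"])
    # optional cell-line panel inputs
    panel_expression_path: str | None = None
    panel_ic50_path: str | None = None
    panel_mutations_path: str | None = None
    # stage thresholds
    min_normals: int = 1
    de_mode: str = "unpaired"
    pseudocount: float = 1.0
    min_days: float = 30.0
    min_prop: float = 0.1
    permutation_reps: int = 0
    min_lines: int = 10
    p_threshold: float = 1e-3
    fdr_threshold: float = 0.25
    gene_set: list[str] = field(default_factory=lambda: ["FGFR1", "FGFR3"])
    reference_cohort: str = "BLCA"
    target_prevalence: float = 0.42
    bootstrap_reps: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if not (0 < self.p_threshold <= 1 and 0 < self.fdr_threshold <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.min_days < 0 or not 0 <= self.min_prop < 0.5:
            raise ValueError("min_days must be >= 0 and min_prop in [0, 0.5)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_panel(config: RunConfig) -> CellLinePanel:
    expr = read_expression_matrix(config.panel_expression_path)
    ic50 = pd.read_csv(config.panel_ic50_path, sep="\t", index_col=0)
    mutations = None
    if config.panel_mutations_path:
        mutations = pd.read_csv(config.panel_mutations_path, sep="\t", index_col=0)
    return CellLinePanel(
        expression=expr,
        log_ic50=ic50["log_ic50"],
        tissue_type=ic50["tissue"] if "tissue" in ic50 else
        pd.Series("PAN", index=ic50.index),
        mutations=mutations,
    )


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are preserved and a FAILED marker file is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_expression_matrix(config.matrix_path)
    annots = read_sample_annotation(config.annotation_path)
    manifest: dict = {"stages": {}, "config": dataclasses.asdict(config)}
    common_meta = {"seed": config.seed, "matrix": config.matrix_path,
                   "annotations": config.annotation_path}

    def finish_stage(name: str, table: ResultTable) -> None:
        path = out / f"{name}.tsv"
        table.write(path)
        manifest["stages"][name] = {
            "path": str(path),
            "digest": _digest(path),
            "sidecar_digest": _digest(Path(f"{path}.meta.json")),
        }

    stage = "diffexpr"
    try:
        scan = de.de_scan(matrix, annots, config.genes,
                          min_normals=config.min_normals, mode=config.de_mode,
                          pseudocount=config.pseudocount)
        finish_stage(stage, ResultTable(
            scan.to_frame(),
            {**common_meta, "stage": stage, "mode": config.de_mode,
             "min_normals": config.min_normals,
             "skipped": [s.__dict__ for s in scan.skipped]},
        ))

        stage = "survival"
        sscan = surv.survival_scan(
            matrix, annots, config.genes, min_days=config.min_days,
            min_prop=config.min_prop, permutation_reps=config.permutation_reps,
            seed=child_seed(config.seed, stage),
        )
        finish_stage(stage, ResultTable(
            sscan.to_frame(),
            {**common_meta, "stage": stage, "min_days": config.min_days,
             "min_prop": config.min_prop,
             "failed": [f.__dict__ for f in sscan.failed]},
        ))

        stage = "drugsens"
        if config.panel_expression_path and config.panel_ic50_path:
            panel = _load_panel(config)
            corr = ds.expr_ic50_scan(panel, config.genes,
                                     min_lines=config.min_lines)
            rows = pd.DataFrame([c.__dict__ for c in corr])
            if panel.mutations is not None:
                markers = ds.mutation_scan(panel, p_threshold=config.p_threshold,
                                           fdr_threshold=config.fdr_threshold)
                rows = pd.concat(
                    [rows, pd.DataFrame([m.__dict__ for m in markers])],
                    ignore_index=True,
                )
            finish_stage(stage, ResultTable(
                rows, {**common_meta, "stage": stage,
                       "p_threshold": config.p_threshold,
                       "fdr_threshold": config.fdr_threshold}))
        else:
            logger.info("run_all: no cell-line panel configured, skipping drugsens")
            manifest["stages"][stage] = {"skipped": "no panel inputs"}

        stage = "positivity"
        result = pos.positivity_scan(
            matrix, annots,
            pos.PositivityConfig(
                gene_set=config.gene_set,
                reference_cohort=config.reference_cohort,
                target_prevalence=config.target_prevalence,
                report_genes=config.genes,
            ),
            bootstrap_reps=config.bootstrap_reps,
            seed=child_seed(config.seed, stage),
        )
        rows = pd.DataFrame(
            [
                {"cohort": c.cohort, "n_tumor": c.n_tumor, "set_ratio": c.set_ratio,
                 **{f"ratio_{g}": v for g, v in c.per_gene.items()}}
                for c in result.per_cohort.values()
            ]
        )
        finish_stage(stage, ResultTable(
            rows,
            {**common_meta, "stage": stage, "cutoff": result.cutoff,
             "achieved_reference_ratio": result.achieved_reference_ratio,
             "reference_cohort": result.reference_cohort,
             "gene_set": list(result.gene_set),
             "note": "per-gene ratios reuse the single calibrated cutoff"},
        ))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
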