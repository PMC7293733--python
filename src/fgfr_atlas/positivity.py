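"""Prevalence-calibrated biomarker positivity across cohorts.

The procedure: a clinical trial reports that a fraction p of screened patients
in one tumor type are biomarker-positive by an orthogonal assay (RNA-ISH).
Assuming positivity is monotone in RNA-Seq abundance, the expression cutoff is
set so that exactly a fraction p of the reference cohort's tumors score at or
above it, and the same cutoff is then applied to every other cohort to predict
per-gene and gene-set positive ratios.

A sample's gene-set score is the maximum linear expression over the set
("FGFR1 or FGFR3 positive" = either gene exceeds the shared cutoff).  The
cutoff is always an observed expression value: the k-th largest reference
score with k = round(p * n).  Ties at the cutoff can only raise the achieved
ratio; it is reported, never hidden.  Only tumor samples participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ExpressionMatrix, SampleAnnotations

DEFAULT_GENE_SET = ("FGFR1", "FGFR3")
DEFAULT_REPORT_GENES = ("FGFR1", "FGFR2", "FGFR3", "FGFR4")
DEFAULT_REFERENCE_COHORT = "BLCA"
DEFAULT_TARGET_PREVALENCE = 0.42


@dataclass
class PositivityConfig:
    gene_set: Sequence[str] = DEFAULT_GENE_SET
    reference_cohort: str = DEFAULT_REFERENCE_COHORT
    target_prevalence: float = DEFAULT_TARGET_PREVALENCE
    report_genes: Sequence[str] = DEFAULT_REPORT_GENES

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValueError("gene_set must be non-empty")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")


def sample_score(
    matrix: ExpressionMatrix, sample: str, gene_set: Sequence[str]
) -> float:
    """Max linear expression of *sample* over *gene_set* (singleton = that gene)."""
    return float(_scores(matrix, [sample], gene_set)[0])


def _scores(
    matrix: ExpressionMatrix, samples: Sequence[str], gene_set: Sequence[str]
) -> np.ndarray:
    for g in gene_set:
        if g not in matrix:
            raise KeyError(f"gene {g!r} not in expression matrix")
    rows = np.vstack([matrix.gene_values(g, samples) for g in gene_set])
    return rows.max(axis=0)


def calibrate_cutoff(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    config: PositivityConfig,
) -> tuple[float, float]:
    """Choose the cutoff so the reference cohort's tumor positive ratio matches
    the target prevalence as closely as ties allow.

    Returns (cutoff, achieved_reference_ratio).  With n reference tumors and
    k = round(p * n), the cutoff is the k-th largest gene-set score; exactly
    the samples scoring >= it are positive (tie blocks may raise the ratio).
    """
    if config.reference_cohort not in annots.cohorts:
        raise KeyError(
            f"reference cohort {config.reference_cohort!r} not found; "
            f"available: {', '.join(annots.cohorts)}"
        )
    tumors = annots.tumor_samples(config.reference_cohort)
    tumors = [s for s in tumors if s in set(matrix.samples)]
    n = len(tumors)
    if n == 0:
        raise ValueError("reference cohort has no tumor samples")
    scores = _scores(matrix, tumors, config.gene_set)
    k = int(np.floor(config.target_prevalence * n + 0.5))  # round half up
    if k == 0 or k == n:
        raise ValueError(
            f"target prevalence {config.target_prevalence} unattainable at "
            f"cohort size {n}"
        )
    cutoff = float(np.sort(scores)[::-1][k - 1])
    achieved = float(np.mean(scores >= cutoff))
    return cutoff, achieved


def positive_ratio(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    cohort: str,
    gene_set: Sequence[str],
    cutoff: float,
) -> float:
    """Fraction of the cohort's tumor samples scoring >= cutoff (inclusive)."""
    tumors = annots.tumor_samples(cohort)
    tumors = [s for s in tumors if s in set(matrix.samples)]
    if len(tumors) == 0:
        raise ValueError(f"cohort {cohort!r} has no tumor samples")
    scores = _scores(matrix, tumors, gene_set)
    return float(np.mean(scores >= cutoff))


@dataclass(frozen=True)
class CohortPositivity:
    cohort: str
    n_tumor: int
    set_ratio: float
    per_gene: dict[str, float]
    set_ci: tuple[float, float] | None = None


@dataclass
class PositivityResult:
    cutoff: float
    achieved_reference_ratio: float
    reference_cohort: str
    gene_set: tuple[str, ...]
    per_cohort: dict[str, CohortPositivity] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def positivity_scan(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    config: PositivityConfig | None = None,
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> PositivityResult:
    """Calibrate on the reference cohort, then predict positive ratios everywhere.

    Per cohort: the gene-set ratio over ``config.gene_set`` plus singleton
    ratios for each report gene, all at the single calibrated cutoff.  With
    ``bootstrap_reps`` > 0 a seeded percentile bootstrap over tumor samples
    yields a CI for the set ratio.
    """
    config = config or PositivityConfig()
    cutoff, achieved = calibrate_cutoff(matrix, annots, config)
    rng = np.random.default_rng(seed)
    result = PositivityResult(
        cutoff=cutoff,
        achieved_reference_ratio=achieved,
        reference_cohort=config.reference_cohort,
        gene_set=tuple(config.gene_set),
    )
    present = set(matrix.samples)
    for cohort in annots.cohorts:
        tumors = [s for s in annots.tumor_samples(cohort) if s in present]
        if not tumors:
            result.skipped[cohort] = "no tumor samples"
            continue
        set_scores = _scores(matrix, tumors, config.gene_set)
        per_gene = {
            g: float(np.mean(_scores(matrix, tumors, [g]) >= cutoff))
            for g in config.report_genes
        }
        ci = None
        if bootstrap_reps > 0:
            n = len(tumors)
            idx = rng.integers(0, n, size=(bootstrap_reps, n))
            boot = (set_scores[idx] >= cutoff).mean(axis=1)
            ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
        result.per_cohort[cohort] = CohortPositivity(
            cohort=cohort,
            n_tumor=len(tumors),
            set_ratio=float(np.mean(set_scores >= cutoff)),
            per_gene=per_gene,
            set_ci=ci,
        )
    return result
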