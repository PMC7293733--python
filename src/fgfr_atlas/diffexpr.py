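"""Tumor-vs-normal differential expression per gene and cohort.

Each (gene, cohort) cell is tested with the two-sided Wilcoxon rank-sum test
(or the matched-pair signed-rank variant) and summarized by the log2 fold
change of group means on the linear scale with a pseudocount.  Raw p-values
are tiered (P < 0.05, P < 0.001) as in heat-grid presentations of pan-cancer
screens; a BH-adjusted column is emitted alongside but does not drive tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleAnnotations
from .drugsens import bh_adjust

#: group sizes up to this use exact enumeration (when tie-free)
DEFAULT_EXACT_MAX_N = 25


class RankTestResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool = False


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = DEFAULT_EXACT_MAX_N
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= ``exact_max_n`` values and the
    pooled data is tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  The statistic is the
    Mann-Whitney U of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                              degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and x.size <= exact_max_n and y.size <= exact_max_n
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return RankTestResult(float(res.statistic), min(float(res.pvalue), 1.0))


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], exact_max_n: int = DEFAULT_EXACT_MAX_N
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on (tumor, normal) pairs.

    Zero differences are dropped before ranking; if all pairs tie, the test is
    degenerate with p = 1.  Exact null enumeration when the effective n is
    <= ``exact_max_n`` and |differences| are tie-free.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("pairs must be a non-empty sequence of (tumor, normal)")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    if d.size == 0:
        return RankTestResult(statistic=0.0, p_value=1.0, degenerate=True)
    tie_free = np.unique(np.abs(d)).size == d.size
    use_exact = tie_free and d.size <= exact_max_n
    res = stats.wilcoxon(
        d, alternative="two-sided", zero_method="wilcox",
        method="exact" if use_exact else "approx", correction=True,
    )
    return RankTestResult(float(res.statistic), min(float(res.pvalue), 1.0))


def log2_fold_change(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 1.0
) -> float:
    """log2((mean(x) + pc) / (mean(y) + pc)) of linear-scale values."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.log2((x.mean() + pseudocount) / (y.mean() + pseudocount)))


TIER_NS = "ns"
TIER_P05 = "p_lt_05"
TIER_P001 = "p_lt_001"


def _tier(p: float) -> str:
    if p < 0.001:
        return TIER_P001
    if p < 0.05:
        return TIER_P05
    return TIER_NS


@dataclass(frozen=True)
class DEResult:
    gene: str
    cohort: str
    log2fc: float
    p_value: float
    n_tumor: int
    n_normal: int
    tier: str
    mode: str
    degenerate: bool = False


@dataclass(frozen=True)
class SkippedCell:
    gene: str
    cohort: str
    reason: str


@dataclass
class DEScan:
    """Results of a gene-by-cohort differential-expression scan."""

    results: list[DEResult]
    skipped: list[SkippedCell]

    def to_frame(self) -> pd.DataFrame:
        """Flat table with a BH-adjusted q column over all tested cells."""
        df = pd.DataFrame([r.__dict__ for r in self.results])
        if len(df):
            df["q_value"] = bh_adjust(df["p_value"].tolist())
        return df


def de_scan(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    genes: Sequence[str],
    min_normals: int = 1,
    mode: str = "unpaired",
    pseudocount: float = 1.0,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> DEScan:
    """Test every requested gene in every cohort with enough normal tissue.

    Cohorts with fewer than ``min_normals`` normal samples are skipped with an
    explicit reason (mirroring the exclusion of cohorts that ship no normal
    tissue at all).  ``mode`` is ``unpaired`` (rank-sum on all samples) or
    ``paired`` (signed-rank on matched pairs only).
    """
    if mode not in ("unpaired", "paired"):
        raise ValueError(f"mode must be 'unpaired' or 'paired', got {mode!r}")
    for g in genes:
        if g not in matrix:
            raise KeyError(f"gene {g!r} not in expression matrix")

    results: list[DEResult] = []
    skipped: list[SkippedCell] = []
    for cohort in annots.cohorts:
        tumor = annots.tumor_samples(cohort)
        normal = annots.normal_samples(cohort)
        tumor = [s for s in tumor if s in set(matrix.samples)]
        normal = [s for s in normal if s in set(matrix.samples)]
        if len(normal) == 0:
            reason = "no normal tissues"
        elif len(normal) < min_normals:
            reason = f"fewer than {min_normals} normal samples"
        elif len(tumor) == 0:
            reason = "no tumor samples"
        else:
            reason = None
        if mode == "paired":
            pairs = annots.matched_pairs(cohort)
            if reason is None and len(pairs) == 0:
                reason = "no matched pairs"
        if reason is not None:
            skipped.extend(SkippedCell(g, cohort, reason) for g in genes)
            continue

        for g in genes:
            if mode == "unpaired":
                xv = matrix.gene_values(g, tumor)
                yv = matrix.gene_values(g, normal)
                test = wilcoxon_rank_sum(xv, yv, exact_max_n=exact_max_n)
            else:
                t_ids = [t for t, _ in pairs]
                n_ids = [n for _, n in pairs]
                xv = matrix.gene_values(g, t_ids)
                yv = matrix.gene_values(g, n_ids)
                test = wilcoxon_signed_rank(list(zip(xv, yv)),
                                            exact_max_n=exact_max_n)
            results.append(
                DEResult(
                    gene=g,
                    cohort=cohort,
                    log2fc=log2_fold_change(xv, yv, pseudocount),
                    p_value=test.p_value,
                    n_tumor=len(xv),
                    n_normal=len(yv),
                    tier=_tier(test.p_value),
                    mode=mode,
                    degenerate=test.degenerate,
                )
            )
    return DEScan(results=results, skipped=skipped)
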