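"""Expression- and mutation-drug-response association on cell-line panels.

Expression is log2(x+1)-transformed before Pearson correlation with log-IC50
(linear abundance scales would let a handful of high expressers dominate r).
Binary mutation markers are tested by two-group one-way ANOVA of log-IC50 and
called significant only under the dual gate raw P < 1e-3 AND BH FDR <= 25%,
the GDSC-style association rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CellLinePanel

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_FDR_THRESHOLD = 0.25
DEFAULT_MIN_LINES = 10

SENSITIZING = "sensitizing"
RESISTANCE = "resistance"
NOT_SIGNIFICANT = "ns"
PAN_TISSUE = "pan"


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    tissue: str          # one tissue label or "pan"
    r: float
    p_value: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def expr_ic50_scan(
    panel: CellLinePanel,
    genes: Sequence[str],
    min_lines: int = DEFAULT_MIN_LINES,
    log2_expression: bool = True,
    pseudocount: float = 1.0,
) -> list[CorrelationResult]:
    """Correlate each gene's expression with log-IC50, pan-tissue and per tissue.

    Tissues with fewer than ``min_lines`` lines are skipped.  Expression is
    log2(x + pseudocount)-transformed unless ``log2_expression`` is False.
    """
    for g in genes:
        if g not in panel.expression:
            raise KeyError(f"gene {g!r} not in panel expression")
    lines = list(panel.log_ic50.index)
    ic50 = panel.log_ic50.to_numpy()
    results: list[CorrelationResult] = []
    tissue = panel.tissue_type.reindex(lines)
    for g in genes:
        expr = panel.expression.gene_values(g, lines)
        if log2_expression:
            expr = np.log2(expr + pseudocount)
        r, p = pearson_correlation(expr, ic50)
        results.append(CorrelationResult(g, PAN_TISSUE, r, p, len(lines)))
        for t in sorted(tissue.dropna().unique()):
            mask = (tissue == t).to_numpy()
            if mask.sum() < min_lines:
                continue
            r, p = pearson_correlation(expr[mask], ic50[mask])
            results.append(CorrelationResult(g, str(t), r, p, int(mask.sum())))
    return results


@dataclass(frozen=True)
class MarkerAssociation:
    marker: str
    effect: float        # mean log-IC50, mutant minus wild-type (<0 = sensitizing)
    f_statistic: float
    p_value: float
    q_value: float
    n_mut: int
    n_wt: int
    call: str
    computable: bool = True
    reason: str | None = None


def mutation_anova(panel: CellLinePanel, marker: str) -> MarkerAssociation:
    """Two-group one-way ANOVA of log-IC50 by mutation status of one marker.

    Groups with fewer than 2 lines make the cell not-computable.  The q value
    and the significance call are filled in by :func:`mutation_scan`, which
    adjusts across the whole marker family.
    """
    if panel.mutations is None or marker not in panel.mutations.columns:
        raise KeyError(f"marker {marker!r} not in panel mutations")
    lines = list(panel.log_ic50.index)
    status = panel.mutations.loc[lines, marker].to_numpy()
    ic50 = panel.log_ic50.to_numpy()
    mut = ic50[status == 1]
    wt = ic50[status == 0]
    if len(mut) < 2 or len(wt) < 2:
        return MarkerAssociation(
            marker=marker, effect=np.nan, f_statistic=np.nan, p_value=np.nan,
            q_value=np.nan, n_mut=len(mut), n_wt=len(wt), call=NOT_SIGNIFICANT,
            computable=False, reason="group with fewer than 2 lines",
        )
    f, p = stats.f_oneway(mut, wt)
    return MarkerAssociation(
        marker=marker,
        effect=float(mut.mean() - wt.mean()),
        f_statistic=float(f),
        p_value=float(p),
        q_value=np.nan,
        n_mut=len(mut),
        n_wt=len(wt),
        call=NOT_SIGNIFICANT,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def significance_call(
    p: float,
    q: float,
    effect: float,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> str:
    """Dual-gate call: significant iff p < p_threshold and q <= fdr_threshold;
    the sign of the effect decides sensitizing (negative) vs resistance."""
    if not (0 < p_threshold <= 1) or not (0 < fdr_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if np.isnan(p) or np.isnan(q):
        return NOT_SIGNIFICANT
    if p < p_threshold and q <= fdr_threshold:
        return SENSITIZING if effect < 0 else RESISTANCE
    return NOT_SIGNIFICANT


def mutation_scan(
    panel: CellLinePanel,
    markers: Sequence[str] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[MarkerAssociation]:
    """ANOVA every marker, BH-adjust within the scanned family, assign calls."""
    if markers is None:
        markers = panel.marker_genes
    raw = [mutation_anova(panel, m) for m in markers]
    computable = [a for a in raw if a.computable]
    qs = bh_adjust([a.p_value for a in computable]) if computable else []
    q_map = {a.marker: q for a, q in zip(computable, qs)}
    out = []
    for a in raw:
        if not a.computable:
            out.append(a)
            continue
        q = q_map[a.marker]
        out.append(
            MarkerAssociation(
                marker=a.marker, effect=a.effect, f_statistic=a.f_statistic,
                p_value=a.p_value, q_value=q, n_mut=a.n_mut, n_wt=a.n_wt,
                call=significance_call(a.p_value, q, a.effect,
                                       p_threshold, fdr_threshold),
            )
        )
    return out
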