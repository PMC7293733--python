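"""Synthetic TCGA-like cohorts and GDSC-like cell-line panels with planted effects.

Expression is simulated log2-normally and exponentiated to the linear scale:
the analysis cutoffs (positivity) live on the linear scale while biological
effects (fold changes, hazard links, IC50 slopes) are naturally log-additive.
Survival follows a proportional-hazards exponential model with independent
exponential censoring; the censoring rate parameter is solved numerically so
the expected censored fraction matches the requested one.

Everything is reproducible from the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    CENSORED,
    EVENT,
    TISSUE_NORMAL,
    TISSUE_TUMOR,
    CellLinePanel,
    ExpressionMatrix,
    SampleAnnotations,
)

#: Human FGF ligand family (22 members; FGF15 is the rodent ortholog of FGF19)
FGF_GENES = tuple(f"FGF{i}" for i in list(range(1, 15)) + list(range(16, 24)))
FGFR_GENES = ("FGFR1", "FGFR2", "FGFR3", "FGFR4")


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: log2-scale base mean/SD and a planted tumor fold change."""

    symbol: str
    base_log2_mean: float = 10.0
    log2_sd: float = 1.5
    log2fc: float = 0.0


def default_gene_specs(log2fc: float = 0.0) -> list[GeneSpec]:
    """FGF1-23 plus FGFR1-4 with a shared planted fold change (default none)."""
    return [GeneSpec(g, log2fc=log2fc) for g in FGF_GENES + FGFR_GENES]


@dataclass
class SurvivalLink:
    """Proportional-hazards link: per-SD log hazard ratio on one gene's
    standardized log2 expression."""

    gene: str
    log_hazard_ratio_per_sd: float


@dataclass
class CohortSpec:
    """Recipe for one tumor/normal cohort.

    ``baseline_hazard`` is in events per day (on the scale of overall-survival
    days); ``censor_rate`` is the expected fraction of censored tumors;
    ``matched_fraction`` is the fraction of normals paired with a tumor,
    sharing a latent per-pair log2 intercept (SD ``pair_sd``).
    """

    cohort: str
    n_tumor: int
    n_normal: int
    genes: Sequence[GeneSpec] = field(default_factory=default_gene_specs)
    survival_link: SurvivalLink | None = None
    baseline_hazard: float = 1.0 / 500.0
    censor_rate: float = 0.3
    matched_fraction: float = 0.0
    pair_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 0 or self.n_normal < 0:
            raise ValueError("sample counts must be >= 0")
        if any(g.log2_sd <= 0 for g in self.genes):
            raise ValueError("log2_sd must be > 0 for every gene")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if not 0.0 <= self.matched_fraction <= 1.0:
            raise ValueError("matched_fraction must be in [0, 1]")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate gene symbols in spec")
        if self.survival_link is not None and self.survival_link.gene not in symbols:
            raise ValueError(
                f"survival_link gene {self.survival_link.gene!r} not in gene list"
            )


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Censoring rate c with E[fraction censored] = mean_i c/(c+lambda_i) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        return np.inf

    def f(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(f, lo, hi)))


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SampleAnnotations]:
    """Simulate one cohort's expression matrix and sample annotations.

    Tumor log2 expression of gene g is N(base + log2fc, sd); normals sit at the
    base mean.  Matched normals share a per-pair intercept with their tumor.
    Tumors get exponential survival times with hazard
    ``baseline * exp(beta * z)`` where z is the standardized log2 expression of
    the linked gene (z = 0 for all if no link), censored independently.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    n_t, n_n = spec.n_tumor, spec.n_normal
    tumor_ids = [f"{spec.cohort}-T{i:04d}" for i in range(n_t)]
    normal_ids = [f"{spec.cohort}-N{i:04d}" for i in range(n_n)]

    n_paired = min(int(round(spec.matched_fraction * n_n)), n_t, n_n)
    pair_intercepts = rng.normal(0.0, spec.pair_sd, size=n_paired)

    log2 = np.empty((len(genes), n_t + n_n))
    for gi, g in enumerate(genes):
        t_vals = rng.normal(g.base_log2_mean + g.log2fc, g.log2_sd, size=n_t)
        n_vals = rng.normal(g.base_log2_mean, g.log2_sd, size=n_n)
        # matched pair j links tumor j and normal j; both shift by the pair term
        t_vals[:n_paired] += pair_intercepts
        n_vals[:n_paired] += pair_intercepts
        log2[gi] = np.concatenate([t_vals, n_vals])

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.power(2.0, log2),
            index=[g.symbol for g in genes],
            columns=tumor_ids + normal_ids,
        )
    )

    # survival on tumors only
    if spec.survival_link is not None and n_t > 1:
        gi = [g.symbol for g in genes].index(spec.survival_link.gene)
        x = log2[gi, :n_t]
        z = (x - x.mean()) / x.std(ddof=0)
        hazards = spec.baseline_hazard * np.exp(
            spec.survival_link.log_hazard_ratio_per_sd * z
        )
    else:
        hazards = np.full(n_t, spec.baseline_hazard)

    os_days = np.zeros(n_t)
    os_event: list[str] = []
    if n_t:
        event_times = rng.exponential(1.0 / hazards)
        c_rate = _solve_censor_rate(hazards, spec.censor_rate)
        if c_rate == 0.0:
            times, events = event_times, np.ones(n_t, bool)
        elif spec.censor_rate >= 1.0:
            # full censoring is administrative: observe the drawn times, no events
            times, events = event_times, np.zeros(n_t, bool)
        else:
            censor_times = rng.exponential(1.0 / c_rate, size=n_t)
            events = event_times <= censor_times
            times = np.minimum(event_times, censor_times)
        os_days = np.maximum(np.ceil(times), 1.0)
        os_event = [EVENT if e else CENSORED for e in events]

    rows = []
    for i, sid in enumerate(tumor_ids):
        rows.append(
            dict(
                sample_id=sid,
                cohort=spec.cohort,
                tissue=TISSUE_TUMOR,
                pair_id=f"{spec.cohort}-P{i:04d}" if i < n_paired else pd.NA,
                os_days=float(os_days[i]),
                os_event=os_event[i],
            )
        )
    for i, sid in enumerate(normal_ids):
        rows.append(
            dict(
                sample_id=sid,
                cohort=spec.cohort,
                tissue=TISSUE_NORMAL,
                pair_id=f"{spec.cohort}-P{i:04d}" if i < n_paired else pd.NA,
                os_days=pd.NA,
                os_event=pd.NA,
            )
        )
    annots = SampleAnnotations(pd.DataFrame(rows))
    return matrix, annots


def generate_pancancer(
    specs: Sequence[CohortSpec],
) -> tuple[ExpressionMatrix, SampleAnnotations]:
    """Column-wise merge of several cohorts into one pan-cancer atlas."""
    codes = [s.cohort for s in specs]
    dup = {c for c in codes if codes.count(c) > 1}
    if dup:
        raise ValueError(f"duplicate cohort code(s): {', '.join(sorted(dup))}")
    gene_lists = {tuple(g.symbol for g in s.genes) for s in specs}
    if len(gene_lists) > 1:
        raise ValueError("all cohort specs must share the same gene list")
    matrices, annot_frames = [], []
    for s in specs:
        m, a = generate_cohort(s)
        matrices.append(m.data)
        annot_frames.append(a.df)
    return (
        ExpressionMatrix(pd.concat(matrices, axis=1)),
        SampleAnnotations(pd.concat(annot_frames, ignore_index=True)),
    )


@dataclass
class ResponseLink:
    """Linear link from standardized log2 expression of one gene to log-IC50."""

    gene: str
    slope: float
    intercept: float = 0.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class MarkerSpec:
    """A binary mutation marker with an additive log-IC50 effect."""

    gene: str
    prevalence: float
    effect: float


@dataclass
class PanelSpec:
    """Recipe for a GDSC-like cell-line panel for one drug."""

    n_lines: int
    tissue_mix: dict[str, float] = field(default_factory=lambda: {"PAN": 1.0})
    genes: Sequence[GeneSpec] = field(
        default_factory=lambda: [GeneSpec(g) for g in FGFR_GENES]
    )
    response_link: ResponseLink | None = None
    markers: Sequence[MarkerSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 0:
            raise ValueError("n_lines must be >= 0")
        total = sum(self.tissue_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue fractions must sum to 1, got {total}")
        for m in self.markers:
            if not 0.0 <= m.prevalence <= 1.0:
                raise ValueError(f"marker {m.gene}: prevalence must be in [0, 1]")
        if self.response_link is not None:
            if self.response_link.noise_sd <= 0:
                raise ValueError("noise_sd must be > 0")
            if self.response_link.gene not in [g.symbol for g in self.genes]:
                raise ValueError(
                    f"response_link gene {self.response_link.gene!r} not in gene list"
                )


def generate_panel(spec: PanelSpec) -> CellLinePanel:
    """Simulate a cell-line panel with a planted expression-response link.

    log_ic50 = intercept + slope * z(log2 expr) + sum(effect * marker) + noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines
    line_ids = [f"CL{i:04d}" for i in range(n)]
    tissues = list(spec.tissue_mix)
    probs = np.array([spec.tissue_mix[t] for t in tissues])
    tissue_assign = rng.choice(tissues, size=n, p=probs) if n else np.array([], dtype=str)

    log2 = {
        g.symbol: rng.normal(g.base_log2_mean, g.log2_sd, size=n) for g in spec.genes
    }
    expr = ExpressionMatrix(
        pd.DataFrame(
            {sid: {g: np.power(2.0, log2[g][i]) for g in log2}
             for i, sid in enumerate(line_ids)},
            index=[g.symbol for g in spec.genes],
            columns=line_ids,
            dtype=float,
        )
        if n
        else pd.DataFrame(
            np.empty((len(spec.genes), 0)), index=[g.symbol for g in spec.genes]
        )
    )

    markers = pd.DataFrame(
        {m.gene: rng.binomial(1, m.prevalence, size=n) for m in spec.markers},
        index=line_ids,
        dtype=int,
    ) if spec.markers else None

    ic50 = np.zeros(n)
    if spec.response_link is not None and n > 1:
        x = log2[spec.response_link.gene]
        z = (x - x.mean()) / x.std(ddof=0)
        ic50 = spec.response_link.intercept + spec.response_link.slope * z
        noise_sd = spec.response_link.noise_sd
    else:
        noise_sd = 1.0
    for m in spec.markers:
        if markers is not None:
            ic50 = ic50 + m.effect * markers[m.gene].to_numpy()
    if n:
        ic50 = ic50 + rng.normal(0.0, noise_sd, size=n)

    return CellLinePanel(
        expression=expr,
        log_ic50=pd.Series(ic50, index=line_ids, dtype=float),
        tissue_type=pd.Series(tissue_assign, index=line_ids, dtype=object),
        mutations=markers,
    )
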