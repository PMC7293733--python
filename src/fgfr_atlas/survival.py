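"""Gene-wise overall-survival association per cohort.

Pipeline per (gene, cohort): keep tumors with complete survival data and at
least a minimum follow-up, dichotomize expression at the cutoff maximizing
the two-group log-rank statistic (a maximally selected rank statistic, the
convention popularized by survminer), then report Kaplan-Meier curves, the
log-rank test and a univariate Cox hazard ratio of the high (>= cutoff)
versus low group.

The log-rank p at the selected cutoff is anticonservative by construction
(the cutoff was chosen to maximize it); ``cutpoint_permutation_p`` provides a
selection-corrected permutation p-value, emitted as a clearly labeled extra
column when requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .core import EVENT, ExpressionMatrix, SampleAnnotations

DEFAULT_MIN_DAYS = 30.0
DEFAULT_MIN_PROP = 0.1

ADVERSE = "adverse"
FAVORABLE = "favorable"


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time in days, event status, one gene's expression."""

    sample_id: str
    time: float
    event: bool
    covariate: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if not np.isfinite(self.covariate):
            raise ValueError("covariate must be finite")


def build_survival_records(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    gene: str,
    cohort: str,
) -> list[SurvivalRecord]:
    """Tumor samples of a cohort with complete (time, event, expression) triples."""
    df = annots.for_cohort(cohort)
    df = df[(df["tissue"] == "tumor") & df["os_days"].notna() & df["os_event"].notna()]
    present = set(matrix.samples)
    records = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid not in present or float(row["os_days"]) <= 0:
            continue
        records.append(
            SurvivalRecord(
                sample_id=sid,
                time=float(row["os_days"]),
                event=row["os_event"] == EVENT,
                covariate=float(matrix.gene_values(gene, [sid])[0]),
            )
        )
    return records


def filter_survival(
    records: Sequence[SurvivalRecord], min_days: float = DEFAULT_MIN_DAYS
) -> list[SurvivalRecord]:
    """Keep subjects with at least ``min_days`` of follow-up (inclusive),
    regardless of event status."""
    if min_days < 0:
        raise ValueError("min_days must be >= 0")
    return [r for r in records if r.time >= min_days]


@dataclass
class KMCurve:
    """Product-limit survival estimate with per-step risk-set bookkeeping."""

    times: np.ndarray        # distinct observed times (events and censorings)
    survival: np.ndarray     # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # event_table carries a t=0 bookkeeping row for the initial risk set
    table = kmf.event_table[kmf.event_table.index > 0]
    surv = kmf.survival_function_at_times(table.index.to_numpy()).to_numpy()
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        survival=surv.astype(float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
    )


class LogrankResult(NamedTuple):
    chi2: float
    p_value: float
    degenerate: bool = False


def _logrank_arrays(
    time: np.ndarray, event: np.ndarray, in_a: np.ndarray
) -> tuple[float, float]:
    """(O_a - E_a, variance) of the two-group log-rank statistic.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the risk sets.
    """
    order = np.argsort(time, kind="stable")
    time, event, in_a = time[order], event[order], in_a[order]
    event_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = event & (time == t)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test; p from chi-square with 1 df.

    Degenerate (p = 1) when there are no events or no variance (e.g. the
    groups never overlap in risk sets at event times).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    time = np.array([r.time for r in group_a] + [r.time for r in group_b])
    event = np.array([r.event for r in group_a] + [r.event for r in group_b])
    in_a = np.array([True] * len(group_a) + [False] * len(group_b))
    if not event.any():
        return LogrankResult(chi2=0.0, p_value=1.0, degenerate=True)
    o_minus_e, var = _logrank_arrays(time, event, in_a)
    if var <= 0:
        return LogrankResult(chi2=0.0, p_value=1.0, degenerate=True)
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p_value=float(stats.chi2.sf(chi2, 1)))


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    max_logrank_chi2: float
    n_low: int
    n_high: int
    candidates_evaluated: int


def best_cutpoint(
    records: Sequence[SurvivalRecord], min_prop: float = DEFAULT_MIN_PROP
) -> CutpointResult:
    """Maximally selected log-rank cutpoint over the observed covariate values.

    Every distinct covariate value is a candidate threshold (low: < cutoff,
    high: >= cutoff); candidates leaving less than ``min_prop`` of subjects on
    either side are inadmissible.  Ties in chi-square break toward the
    smaller cutoff.
    """
    n = len(records)
    if n == 0:
        raise ValueError("cohort too small for cutpoint search")
    cov = np.array([r.covariate for r in records])
    time = np.array([r.time for r in records])
    event = np.array([r.event for r in records])
    candidates = np.unique(cov)
    best: tuple[float, float, int, int] | None = None
    evaluated = 0
    for c in candidates:
        high = cov >= c
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) / n < min_prop or min(n_low, n_high) == 0:
            continue
        evaluated += 1
        if not event.any():
            chi2 = 0.0
        else:
            o_minus_e, var = _logrank_arrays(time, event, high)
            chi2 = o_minus_e**2 / var if var > 0 else 0.0
        if best is None or chi2 > best[1] + 1e-12:
            best = (float(c), float(chi2), n_low, n_high)
    if best is None:
        raise ValueError("cohort too small for cutpoint search")
    return CutpointResult(
        cutoff=best[0],
        max_logrank_chi2=best[1],
        n_low=best[2],
        n_high=best[3],
        candidates_evaluated=evaluated,
    )


def cutpoint_permutation_p(
    records: Sequence[SurvivalRecord],
    min_prop: float = DEFAULT_MIN_PROP,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> float:
    """Selection-corrected p for the maximally selected log-rank statistic.

    Permutes the covariate against (time, event), redoes the full cutpoint
    search each time, and reports the fraction of permutation maxima at least
    as large as the observed one (add-one correction).
    """
    observed = best_cutpoint(records, min_prop).max_logrank_chi2
    rng = np.random.default_rng(seed)
    cov = np.array([r.covariate for r in records])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cov)
        shuffled = [
            SurvivalRecord(r.sample_id, r.time, r.event, c)
            for r, c in zip(records, perm)
        ]
        try:
            chi2 = best_cutpoint(shuffled, min_prop).max_logrank_chi2
        except ValueError:
            continue
        if chi2 >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


@dataclass
class CoxResult:
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool


def cox_univariate(
    records: Sequence[SurvivalRecord], group: Sequence[bool]
) -> CoxResult:
    """Univariate Cox regression of survival on a binary high/low assignment.

    Partial likelihood maximized by Newton-Raphson with Efron tie handling;
    Wald 95% CI; HR = exp(beta) for the high group versus low.  If one group
    carries no events the likelihood is monotone: a signed infinite-HR
    sentinel is returned with ``converged=False``.
    """
    group = np.asarray(group, dtype=bool)
    if len(records) != group.size:
        raise ValueError("group assignment length must match records")
    if group.all() or (~group).all():
        raise ValueError("group assignment is constant")
    time = np.array([r.time for r in records])
    event = np.array([r.event for r in records])
    if not event.any():
        raise ValueError("at least one event is required")
    ev_high = event[group].sum()
    ev_low = event[~group].sum()
    if ev_high == 0 or ev_low == 0:
        beta = -np.inf if ev_high == 0 else np.inf
        return CoxResult(
            beta=beta, se=np.inf, hazard_ratio=np.exp(beta),
            ci_low=0.0, ci_high=np.inf, p_value=np.nan, converged=False,
        )
    df = pd.DataFrame({"T": time, "E": event.astype(int), "high": group.astype(int)})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="T", event_col="E")
    row = cph.summary.loc["high"]
    return CoxResult(
        beta=float(row["coef"]),
        se=float(row["se(coef)"]),
        hazard_ratio=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_value=float(row["p"]),
        converged=True,
    )


@dataclass(frozen=True)
class SurvivalFit:
    gene: str
    cohort: str
    cutoff: float
    n_low: int
    n_high: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    cox_p: float
    logrank_chi2: float
    logrank_p: float              # cutpoint-selected: anticonservative
    direction: str                # adverse iff HR > 1
    converged: bool
    permutation_p: float | None = None  # selection-corrected, when requested


@dataclass(frozen=True)
class FailedCell:
    gene: str
    cohort: str
    reason: str


@dataclass
class SurvivalScan:
    fits: list[SurvivalFit]
    failed: list[FailedCell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.__dict__ for f in self.fits])


def survival_scan(
    matrix: ExpressionMatrix,
    annots: SampleAnnotations,
    genes: Sequence[str],
    min_days: float = DEFAULT_MIN_DAYS,
    min_prop: float = DEFAULT_MIN_PROP,
    permutation_reps: int = 0,
    seed: int | None = None,
) -> SurvivalScan:
    """Filter -> cutpoint -> log-rank + Cox for every (gene, cohort) cell.

    Cells that cannot be analyzed (no events, constant covariate, too few
    subjects for an admissible cutpoint) are reported with a reason code,
    never dropped silently.
    """
    for g in genes:
        if g not in matrix:
            raise KeyError(f"gene {g!r} not in expression matrix")
    fits: list[SurvivalFit] = []
    failed: list[FailedCell] = []
    for cohort in annots.cohorts:
        for gene in genes:
            records = build_survival_records(matrix, annots, gene, cohort)
            records = filter_survival(records, min_days)
            if len(records) < 2:
                failed.append(FailedCell(gene, cohort, "too few subjects"))
                continue
            cov = np.array([r.covariate for r in records])
            if np.all(cov == cov[0]):
                failed.append(FailedCell(gene, cohort, "constant covariate"))
                continue
            if not any(r.event for r in records):
                failed.append(FailedCell(gene, cohort, "no events"))
                continue
            try:
                cut = best_cutpoint(records, min_prop)
            except ValueError:
                failed.append(FailedCell(gene, cohort,
                                         "cohort too small for cutpoint search"))
                continue
            high = cov >= cut.cutoff
            lr = logrank_test(
                [r for r, h in zip(records, high) if h],
                [r for r, h in zip(records, high) if not h],
            )
            try:
                cox = cox_univariate(records, high)
            except ValueError as exc:
                failed.append(FailedCell(gene, cohort, str(exc)))
                continue
            perm_p = None
            if permutation_reps > 0:
                perm_p = cutpoint_permutation_p(
                    records, min_prop, permutation_reps, seed
                )
            fits.append(
                SurvivalFit(
                    gene=gene,
                    cohort=cohort,
                    cutoff=cut.cutoff,
                    n_low=cut.n_low,
                    n_high=cut.n_high,
                    hazard_ratio=cox.hazard_ratio,
                    ci_low=cox.ci_low,
                    ci_high=cox.ci_high,
                    cox_p=cox.p_value,
                    logrank_chi2=lr.chi2,
                    logrank_p=lr.p_value,
                    direction=ADVERSE if cox.hazard_ratio > 1 else FAVORABLE,
                    converged=cox.converged,
                    permutation_p=perm_p,
                )
            )
    return SurvivalScan(fits=fits, failed=failed)
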