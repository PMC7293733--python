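"""Shared domain types and TSV input/output for the expression-biomarker pipeline.

Expression values are exchanged on the linear RSEM-like scale everywhere in
this package; log transforms are applied inside individual analysis stages,
never at I/O time, because the positivity cutoff lives on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fgfr_atlas")

TISSUE_TUMOR = "tumor"
TISSUE_NORMAL = "normal"
TISSUES = (TISSUE_TUMOR, TISSUE_NORMAL)

EVENT = "event"
CENSORED = "censored"

#: Annotation columns with a fixed meaning; anything else is carried as-is.
_ANNOT_REQUIRED = ("sample_id", "cohort", "tissue")
_ANNOT_OPTIONAL = ("pair_id", "os_days", "os_event")


class ExpressionMatrix:
    """A dense gene-by-sample grid of non-negative, finite abundances.

    Genes are rows, samples are columns.  Gene symbols and sample IDs are
    unique; values are linear-scale (not log) normalized abundances.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        dup_genes = data.index[data.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene symbol(s): {', '.join(dup_genes)}")
        dup_samples = data.columns[data.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValueError(f"duplicate sample ID(s): {', '.join(dup_samples)}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid expression value {values[i, j]!r} at "
                f"gene {data.index[i]!r}, sample {data.columns[j]!r} "
                "(values must be finite and >= 0)"
            )
        self._data = data.astype(float)

    # -- accessors -------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def genes(self) -> list[str]:
        return list(self._data.index)

    @property
    def samples(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def __contains__(self, gene: str) -> bool:
        return gene in self._data.index

    def gene_values(self, gene: str, samples: Sequence[str] | None = None) -> np.ndarray:
        """Linear-scale values for one gene, optionally restricted to *samples*."""
        if gene not in self._data.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        row = self._data.loc[gene]
        if samples is not None:
            row = row.loc[list(samples)]
        return row.to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._data.columns]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {', '.join(missing)}")
        return ExpressionMatrix(self._data.loc[:, list(samples)])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write genes-in-rows TSV with a ``gene_symbol`` label column."""
        out = self._data.copy()
        out.index.name = "gene_symbol"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, orientation: str = "genes_in_rows") -> "ExpressionMatrix":
        return read_expression_matrix(path, orientation)


def read_expression_matrix(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table (one header line, labels in column one).

    ``orientation`` is ``genes_in_rows`` or ``samples_in_rows``; the returned
    matrix is always genes-in-rows.  Duplicate labels, negative values and
    non-numeric cells are hard errors naming the offending coordinates.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression file: {path}") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression file: {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing cell at row {raw.index[i]!r}, column {raw.columns[j]!r}")
    neg = numeric.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative value {numeric.iat[i, j]} at row {numeric.index[i]!r}, "
            f"column {numeric.columns[j]!r}"
        )
    if orientation == "samples_in_rows":
        numeric = numeric.T
    return ExpressionMatrix(numeric)


class SampleAnnotations:
    """Per-sample metadata: cohort code, tumor/normal status, optional matched
    pair ID and overall-survival fields.

    Backed by a DataFrame with one row per sample.  ``os_event`` is the string
    ``"event"`` or ``"censored"`` in memory (1/0 on disk) and must be present
    exactly when ``os_days`` is.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col in _ANNOT_REQUIRED:
            if col not in df.columns:
                raise ValueError(f"annotation table missing required column {col!r}")
        for col in _ANNOT_OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        df["sample_id"] = df["sample_id"].astype(str)
        dup = df["sample_id"][df["sample_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample ID(s) in annotation: {', '.join(dup)}")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise ValueError(
                f"tissue must be one of {TISSUES}, got {bad_tissue}"
            )
        has_days = df["os_days"].notna()
        has_event = df["os_event"].notna()
        if (has_days != has_event).any():
            sid = df.loc[has_days != has_event, "sample_id"].iloc[0]
            raise ValueError(
                f"sample {sid!r}: os_days and os_event must be present together"
            )
        if has_days.any():
            days = pd.to_numeric(df.loc[has_days, "os_days"], errors="raise")
            if (days < 0).any():
                raise ValueError("os_days must be non-negative")
            df.loc[has_days, "os_days"] = days.astype(float)
            ev = df.loc[has_event, "os_event"]
            bad_ev = sorted(set(ev) - {EVENT, CENSORED})
            if bad_ev:
                raise ValueError(f"os_event must be 'event' or 'censored', got {bad_ev}")
        paired = df[df["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            tissues = sorted(grp["tissue"])
            if tissues != [TISSUE_NORMAL, TISSUE_TUMOR]:
                raise ValueError(
                    f"pair_id {pid!r} must link exactly one tumor and one normal "
                    f"sample, found tissues {list(grp['tissue'])}"
                )
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    @property
    def cohorts(self) -> list[str]:
        return sorted(self._df["cohort"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def for_cohort(self, cohort: str) -> pd.DataFrame:
        return self._df[self._df["cohort"] == cohort]

    def tumor_samples(self, cohort: str | None = None) -> list[str]:
        df = self._df if cohort is None else self.for_cohort(cohort)
        return list(df.loc[df["tissue"] == TISSUE_TUMOR, "sample_id"])

    def normal_samples(self, cohort: str | None = None) -> list[str]:
        df = self._df if cohort is None else self.for_cohort(cohort)
        return list(df.loc[df["tissue"] == TISSUE_NORMAL, "sample_id"])

    def matched_pairs(self, cohort: str | None = None) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) tuples for every matched pair."""
        df = self._df if cohort is None else self.for_cohort(cohort)
        pairs = []
        for pid, grp in df[df["pair_id"].notna()].groupby("pair_id"):
            if len(grp) != 2:  # partner outside this cohort slice
                continue
            t = grp.loc[grp["tissue"] == TISSUE_TUMOR, "sample_id"].iloc[0]
            n = grp.loc[grp["tissue"] == TISSUE_NORMAL, "sample_id"].iloc[0]
            pairs.append((t, n))
        return pairs

    def to_tsv(self, path) -> None:
        out = self._df.copy()
        has = out["os_event"].notna()
        out["os_event"] = out["os_event"].map({EVENT: 1, CENSORED: 0})
        out.loc[~has, "os_event"] = pd.NA
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleAnnotations":
        return read_sample_annotation(path)


def read_sample_annotation(path) -> SampleAnnotations:
    """Read a sample-annotation TSV (os_event encoded 1=event, 0=censored)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    if "os_event" in df.columns:
        mapping = {1: EVENT, 0: CENSORED, 1.0: EVENT, 0.0: CENSORED,
                   "1": EVENT, "0": CENSORED, EVENT: EVENT, CENSORED: CENSORED}
        has = df["os_event"].notna()
        decoded = df.loc[has, "os_event"].map(mapping)
        if decoded.isna().any():
            bad = df.loc[has, "os_event"][decoded.isna()].iloc[0]
            raise ValueError(f"os_event must be 0 or 1 on disk, got {bad!r}")
        df["os_event"] = df["os_event"].astype(object)
        df.loc[has, "os_event"] = decoded
    return SampleAnnotations(df)


@dataclass
class CohortView:
    """One cohort's slice of the atlas: expression + matching annotations."""

    cohort: str
    matrix: ExpressionMatrix
    annotations: SampleAnnotations

    @property
    def n_tumor(self) -> int:
        return len(self.annotations.tumor_samples())

    @property
    def n_normal(self) -> int:
        return len(self.annotations.normal_samples())


def join_cohort(matrix: ExpressionMatrix, annots: SampleAnnotations, cohort: str) -> CohortView:
    """Subset matrix and annotations to one cohort.

    Matrix samples without any annotation are dropped (count logged);
    annotated samples missing from the matrix are an error.
    """
    available = annots.cohorts
    if cohort not in available:
        raise KeyError(f"cohort {cohort!r} not found; available: {', '.join(available)}")
    unannotated = set(matrix.samples) - set(annots.sample_ids)
    if unannotated:
        logger.info("join_cohort: dropping %d matrix sample(s) without annotation",
                    len(unannotated))
    sub = annots.for_cohort(cohort)
    missing = [s for s in sub["sample_id"] if s not in set(matrix.samples)]
    if missing:
        raise KeyError(
            f"annotated sample(s) absent from matrix: {', '.join(missing[:5])}"
        )
    return CohortView(
        cohort=cohort,
        matrix=matrix.subset_samples(list(sub["sample_id"])),
        annotations=SampleAnnotations(sub),
    )


class CellLinePanel:
    """A cell-line pharmacogenomic panel: expression, per-line log-IC50 for one
    drug, tissue labels, and a binary mutation-marker grid.

    ``log_ic50`` is on the natural-log micromolar scale (the GDSC convention).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        log_ic50: pd.Series,
        tissue_type: pd.Series,
        mutations: pd.DataFrame | None = None,
    ):
        lines = expression.samples
        log_ic50 = log_ic50.astype(float)
        extra = set(log_ic50.index) - set(lines)
        if extra:
            raise ValueError(f"log_ic50 keys not in expression: {sorted(extra)[:5]}")
        if not np.isfinite(log_ic50.to_numpy()).all():
            raise ValueError("log_ic50 contains non-finite values")
        extra = set(tissue_type.index) - set(lines)
        if extra:
            raise ValueError(f"tissue_type keys not in expression: {sorted(extra)[:5]}")
        if mutations is not None:
            extra = set(mutations.index) - set(lines)
            if extra:
                raise ValueError(f"mutation rows not in expression: {sorted(extra)[:5]}")
            vals = mutations.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mutation markers must be strictly binary (0/1)")
            mutations = mutations.astype(int)
        self.expression = expression
        self.log_ic50 = log_ic50.reindex(lines).dropna()
        self.tissue_type = tissue_type.reindex(lines)
        self.mutations = mutations

    @property
    def lines(self) -> list[str]:
        return self.expression.samples

    @property
    def is_empty(self) -> bool:
        return len(self.lines) == 0

    @property
    def marker_genes(self) -> list[str]:
        return [] if self.mutations is None else list(self.mutations.columns)


@dataclass
class ResultTable:
    """A flat results table plus the run configuration that produced it."""

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, path) -> None:
        """Write the rows as TSV and metadata as a ``<path>.meta.json`` sidecar."""
        import json

        self.rows.to_csv(path, sep="\t", index=False)
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True, default=str)
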