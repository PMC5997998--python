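"""Tabular I/O: expression matrices, sample metadata and time series.

All pipeline inputs and outputs are plain text: TSV for matrices,
metadata and time series; JSON for descriptor geometry, fitted
parameters and test results.  Expression values are FPKM (fragments per
kilobase of transcript per million mapped reads); they must be finite
and non-negative, and missing values are a hard error (quantifiers emit
0, not NA).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DIURNAL_LABELS = ("light", "dark")
GROWTH_LABELS = ("early", "late")

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "condition",
    "stage",
    "diurnal_phase",
    "growth_phase",
    "replicate",
)

#: format used whenever floats are written to disk; 12 significant
#: digits keeps round-trips lossless for all quantities we produce.
FLOAT_FORMAT = "%.12g"


class DataValidationError(ValueError):
    """An input table violates a structural invariant."""


@dataclass(frozen=True)
class SampleMetadata:
    """Labels attached to one transcriptome sample.

    ``time`` (hours since experiment start) is optional: the state-space
    analysis needs only the categorical labels, growth fitting consumes
    its own time-series tables.
    """

    sample_id: str
    condition: str
    stage: int
    diurnal_phase: str
    growth_phase: str
    replicate: str
    time: float | None = None

    def __post_init__(self) -> None:
        if self.diurnal_phase not in DIURNAL_LABELS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: diurnal_phase must be one of "
                f"{DIURNAL_LABELS}, got {self.diurnal_phase!r}"
            )
        if self.growth_phase not in GROWTH_LABELS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: growth_phase must be one of "
                f"{GROWTH_LABELS}, got {self.growth_phase!r}"
            )
        if int(self.stage) < 1:
            raise DataValidationError(
                f"sample {self.sample_id!r}: stage must be a positive integer"
            )

    @property
    def state(self) -> str:
        """Physiological state label, e.g. ``light-early``."""
        return f"{self.diurnal_phase}-{self.growth_phase}"


class ExpressionMatrix:
    """Genes x samples abundance matrix in FPKM units.

    Wraps a :class:`pandas.DataFrame` (rows = genes, columns = samples)
    and enforces the invariants once at construction: unique ids,
    finite non-negative values.
    """

    __slots__ = ("frame",)

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dupes[:5]}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dupes[:5]}")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(frame)
            raise DataValidationError(f"non-numeric expression value at {bad}")
        if np.isnan(values).any():
            g, s = _first_where(frame, np.isnan(values))
            raise DataValidationError(
                f"missing value (NA) at gene {g!r}, sample {s!r}"
            )
        if not np.isfinite(values).all():
            g, s = _first_where(frame, ~np.isfinite(values))
            raise DataValidationError(
                f"non-finite value at gene {g!r}, sample {s!r}"
            )
        if (values < 0).any():
            g, s = _first_where(frame, values < 0)
            raise DataValidationError(
                f"negative FPKM at gene {g!r}, sample {s!r}: "
                f"{frame.loc[g, s]}"
            )
        self.frame = frame.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def column(self, sample_id: str) -> pd.Series:
        return self.frame[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class TimeSeriesTable:
    """Long-format time series: ``series_id``, ``time``, ``value``.

    ``kind`` selects extra invariants: ``counts`` requires value > 0,
    ``fluorescence`` requires value >= 0.  Extra annotation columns
    (condition, stage, replicate, ...) are carried along untouched.
    """

    CORE_COLUMNS = ("series_id", "time", "value")

    __slots__ = ("frame", "kind")

    def __init__(self, frame: pd.DataFrame, kind: str = "generic"):
        missing = [c for c in self.CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise DataValidationError(f"time series missing columns: {missing}")
        for sid, grp in frame.groupby("series_id", sort=False):
            t = grp["time"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise DataValidationError(
                    f"series {sid!r}: time must be strictly increasing"
                )
        vals = frame["value"].to_numpy(float)
        if not np.isfinite(vals).all():
            raise DataValidationError("time series contains non-finite values")
        if kind == "counts" and (vals <= 0).any():
            raise DataValidationError("cell counts must be > 0")
        if kind == "fluorescence" and (vals < 0).any():
            raise DataValidationError("fluorescence yields must be >= 0")
        self.frame = frame.reset_index(drop=True)
        self.kind = kind

    def series_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["series_id"]))

    def get_series(self, series_id: str) -> pd.DataFrame:
        return self.frame[self.frame["series_id"] == series_id]


@dataclass
class ValidationReport:
    """Findings from cross-checking an expression matrix and its metadata."""

    findings: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-as-rows, samples-as-columns TSV into an ExpressionMatrix."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False)
    frame.index = frame.index.astype(str)
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            gene = frame.index[converted.isna()][0]
            raise DataValidationError(
                f"non-numeric or missing value at gene {gene!r}, "
                f"sample {col!r}: {frame.loc[gene, col]!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a metadata TSV; categorical labels are normalized to lower case."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"metadata missing required columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        time = None
        if "time" in frame.columns and row["time"] != "":
            time = float(row["time"])
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                condition=row["condition"].strip().lower(),
                stage=int(row["stage"]),
                diurnal_phase=row["diurnal_phase"].strip().lower(),
                growth_phase=row["growth_phase"].strip().lower(),
                replicate=row["replicate"],
                time=time,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate sample_id in metadata")
    return records


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Collection of records as a DataFrame (column order fixed)."""
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(REQUIRED_METADATA_COLUMNS) + ["time"])
    return frame


def read_time_series(path: str | Path, kind: str = "generic") -> TimeSeriesTable:
    frame = pd.read_csv(path, sep="\t")
    return TimeSeriesTable(frame, kind=kind)


def write_table(obj, path: str | Path) -> None:
    """Write any pipeline table/result type deterministically.

    TSV for tabular types (fixed column order, 12-significant-digit
    floats), JSON (sorted keys) for dicts.  Repeated calls with the same
    object produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ExpressionMatrix):
        obj.frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                         index_label="gene_id")
    elif isinstance(obj, TimeSeriesTable):
        obj.frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                   index=not _is_default_index(obj))
    elif isinstance(obj, dict):
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    elif isinstance(obj, (list, tuple)) and all(
        isinstance(r, SampleMetadata) for r in obj
    ):
        metadata_frame(obj).to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                                   index=False)
    else:
        raise TypeError(f"write_table does not support {type(obj).__name__}")


def validate_dataset(
    expr: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    strict: bool = False,
) -> ValidationReport:
    """Cross-check samples against metadata; report-only unless strict.

    Findings: samples with no metadata record, metadata records with no
    sample column, and (condition, stage) groups missing one of the four
    diurnal x growth label combinations.
    """
    report = ValidationReport()
    meta_ids = {r.sample_id for r in meta}
    sample_ids = set(expr.sample_ids)
    for sid in expr.sample_ids:
        if sid not in meta_ids:
            report.findings.append(f"sample {sid!r} has no metadata record")
    for r in meta:
        if r.sample_id not in sample_ids:
            report.findings.append(
                f"unmatched metadata: sample {r.sample_id!r} not in matrix"
            )
    groups: dict[tuple[str, int], set[str]] = {}
    for r in meta:
        if r.sample_id in sample_ids:
            groups.setdefault((r.condition, r.stage), set()).add(r.state)
    all_states = {f"{d}-{g}" for d in DIURNAL_LABELS for g in GROWTH_LABELS}
    for (condition, stage), present in sorted(groups.items()):
        for state in sorted(all_states - present):
            report.findings.append(
                f"condition {condition!r} stage {stage}: no sample in "
                f"state {state!r}"
            )
    if strict and not report.ok:
        raise DataValidationError(
            "dataset validation failed:\n" + "\n".join(report.findings)
        )
    return report


def _is_default_index(frame: pd.DataFrame) -> bool:
    return isinstance(frame.index, pd.RangeIndex) and frame.index.start == 0


def _first_where(frame: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(frame.index[i]), str(frame.columns[j])


def _first_non_numeric(frame: pd.DataFrame) -> str:
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            gene = frame.index[converted.isna()][0]
            return f"gene {gene!r}, sample {col!r}"
    return "unknown position"
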