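"""Reading, writing and preprocessing of expression and clinical tables.

Expression matrices travel as tab-delimited "series-matrix"-shaped files:
a header row of sample ids, then one feature per row with the feature id in
the first column.  Clinical covariates travel as CSV keyed on ``sample_id``.

Preprocessing follows microarray conventions: probe-level intensities are
aggregated to gene symbols by averaging (post-log2), then either
mean-centered per feature (when raw data were renormalised) or z-scaled per
feature within each dataset (when only processed values are available).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ProbeGeneMap

__all__ = [
    "ClinicalTable",
    "read_series_matrix",
    "write_series_matrix",
    "aggregate_probes",
    "zscale",
    "mean_center",
    "read_clinical",
    "write_report",
]

logger = logging.getLogger(__name__)

#: clinical columns coerced to float when present
NUMERIC_COVARIATES = (
    "age", "ki67", "tils", "hrd", "tmb", "nlr", "plr", "rs", "time",
)
_STATUS_VALUES = {"positive", "negative", "unknown"}


# ---------------------------------------------------------------------------
# expression files
# ---------------------------------------------------------------------------

def read_series_matrix(path, feature_kind: str = "probe", platform: str = "") -> ExpressionMatrix:
    """Read a tab-delimited features × samples expression file.

    The first row is a header whose cells after the first are sample ids;
    every following row is ``feature_id`` then one numeric value per sample.
    Ragged rows, duplicate ids, empty files and non-numeric cells are
    rejected with descriptive errors.
    """
    with open(path, newline="") as handle:
        rows = [row for row in csv.reader(handle, delimiter="\t") if row]
    if not rows:
        raise ValueError(f"{path}: empty expression file")
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header must contain at least one sample id")
    sample_ids = [cell.strip() for cell in header[1:]]
    seen = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)

    feature_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: ragged row at line {i} "
                f"({len(row)} fields, expected {len(header)})"
            )
        fid = row[0].strip()
        if fid in feature_ids:
            raise ValueError(f"{path}: duplicate feature id {fid!r}")
        feature_ids.append(fid)
        for j, cell in enumerate(row[1:]):
            try:
                values[i - 2, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} for feature {fid!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from exc
    if not feature_ids:
        raise ValueError(f"{path}: no feature rows")
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(frame, feature_kind=feature_kind, platform=platform)


def write_series_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the tab-delimited shape :func:`read_series_matrix` reads."""
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def aggregate_probes(
    matrix: ExpressionMatrix,
    probe_map: ProbeGeneMap,
    method: str = "mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Each gene's row is the per-sample ``method`` (mean by default, median
    optional) of its probes' log2 values.  Probes absent from the annotation
    are dropped with a logged count.
    """
    if matrix.feature_kind != "probe":
        raise ValueError("aggregate_probes expects a probe-level matrix")
    if method not in ("mean", "median"):
        raise ValueError(f"unsupported aggregation method {method!r}")
    mapped = [p for p in matrix.features if p in probe_map]
    dropped = len(matrix.features) - len(mapped)
    if not mapped:
        raise ValueError("no probe in the matrix appears in the probe->gene map")
    if dropped:
        logger.info("aggregate_probes: dropped %d unannotated probes", dropped)
    frame = matrix.data.loc[mapped]
    genes = pd.Index([probe_map.gene_of(p) for p in mapped], name="gene")
    grouped = frame.groupby(genes, sort=True)
    agg = grouped.mean() if method == "mean" else grouped.median()
    return ExpressionMatrix(
        agg,
        feature_kind="gene",
        platform=matrix.platform,
        centered=matrix.centered,
        zscaled=matrix.zscaled,
    )


def _require_multisample(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.shape[1] < 2:
        raise ValueError(f"{op} requires at least 2 samples, got {matrix.shape[1]}")


def zscale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score across samples: (x − mean) / sd with sample sd (n−1).

    Constant rows become all-zero with a warning rather than dividing by zero.
    """
    _require_multisample(matrix, "zscale")
    values = matrix.values()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        names = [matrix.features[i] for i in np.flatnonzero(constant)[:5]]
        warnings.warn(
            f"zscale: {int(constant.sum())} constant feature rows set to zero "
            f"(e.g. {names})",
            stacklevel=2,
        )
    sd[constant, 0] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    frame = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.replace(data=frame, centered=True, zscaled=True)


def mean_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature row's mean across samples."""
    _require_multisample(matrix, "mean_center")
    values = matrix.values()
    centered = values - values.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(centered, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.replace(data=frame, centered=True)


def preprocess(matrix: ExpressionMatrix, mode: str = "zscale") -> ExpressionMatrix:
    """Apply the configured scaling mode: ``zscale``, ``center`` or ``none``."""
    if mode == "zscale":
        return zscale(matrix)
    if mode == "center":
        return mean_center(matrix)
    if mode == "none":
        return matrix
    raise ValueError(f"unknown scaling mode {mode!r}")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClinicalTable:
    """Per-sample clinical covariates and outcomes.

    Wraps a DataFrame keyed on ``sample_id``.  Receptor statuses are the
    categories positive/negative/unknown; ``pcr`` is a nullable boolean
    (pathological complete response: no residual invasive tumor in the
    breast and negative nodes); ``time``/``event`` are the follow-up fields.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("clinical table requires a 'sample_id' column")
        ids = self.data["sample_id"].astype(str)
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
        self.data = self.data.copy()
        self.data["sample_id"] = ids
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        wanted = list(sample_ids)
        frame = self.data.set_index("sample_id").loc[wanted].reset_index()
        return ClinicalTable(frame)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _normalise_status(series: pd.Series) -> pd.Series:
    def norm(value) -> str:
        if pd.isna(value) or str(value).strip() == "":
            return "unknown"
        text = str(value).strip().lower()
        if text in ("positive", "pos", "1", "true"):
            return "positive"
        if text in ("negative", "neg", "0", "false"):
            return "negative"
        if text in ("unknown", "na", "nan"):
            return "unknown"
        raise ValueError(f"unrecognised status value {value!r}")
    return series.map(norm)


def _normalise_pcr(series: pd.Series) -> pd.Series:
    def norm(value):
        if pd.isna(value) or str(value).strip() in ("", "NA", "nan"):
            return pd.NA
        text = str(value).strip()
        if text in ("1", "1.0", "True", "true"):
            return True
        if text in ("0", "0.0", "False", "false"):
            return False
        raise ValueError(f"pCR value must be 0, 1 or NA, got {value!r}")
    return series.map(norm).astype("boolean")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical CSV; types statuses, pCR and numeric covariates."""
    frame = pd.read_csv(path, dtype=str)
    if frame.empty:
        raise ValueError(f"{path}: empty clinical file")
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    for col in ("er", "pgr", "her2"):
        if col in frame.columns:
            frame[col] = _normalise_status(frame[col])
    if "pcr" in frame.columns:
        frame["pcr"] = _normalise_pcr(frame["pcr"])
    for col in ("anti_her2", "event"):
        if col in frame.columns:
            frame[col] = _normalise_pcr(frame[col])
    for col in NUMERIC_COVARIATES:
        if col in frame.columns:
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    return ClinicalTable(frame)


def write_report(obj, path) -> None:
    """Serialise an analysis report (nested dicts/lists/scalars) to JSON."""

    def default(value):
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        if isinstance(value, np.ndarray):
            return value.tolist()
        if isinstance(value, pd.DataFrame):
            return value.to_dict(orient="records")
        if isinstance(value, pd.Series):
            return value.to_dict()
        if value is pd.NA:
            return None
        return str(value)

    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, default=default)
        handle.write("\n")
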