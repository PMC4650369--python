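"""Readers and writers for every table the pipeline consumes or emits.

Canonical on-disk formats are plain tab-separated text:

* expression TSV — wide, features x samples, first column ``feature_id``;
* detection TSV — same shape, cells 0/1, lives next to the expression file;
* sample metadata TSV — columns ``sample_id, hs, disease_status,
  age_at_drawing, drawing_year`` (plus optional ``label``, ``split``);
* result TSVs — deterministic column order, lossless round trip.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datamodel import (
    LABEL_CASE,
    LABEL_CONTROL,
    LABEL_EXCLUDED,
    REQUIRED_SAMPLE_COLUMNS,
    ExpressionMatrix,
    SampleTable,
)

if TYPE_CHECKING:  # pragma: no cover
    from .bootstrap import BootstrapRanking
    from .comparison import ComparisonResult


def _detection_path(path: str) -> str:
    root, ext = os.path.splitext(path)
    return f"{root}.detected{ext or '.tsv'}"


def read_expression(
    path: str,
    detection_path: str | None = None,
    scale_tag: str = "log2",
) -> ExpressionMatrix:
    """Read a wide expression TSV (features x samples).

    The first column holds feature ids, the header row sample ids.  If a
    companion detection file exists (``<stem>.detected.tsv`` by default)
    it is read as the 0/1 detection matrix; otherwise a value counts as
    detected when it is present and finite.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    feature_ids = df.index.astype(str).tolist()
    sample_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for f in feature_ids:
            for s in df.columns:
                try:
                    float(df.loc[f, s])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at feature {f!r}, sample {s!r} in {path}"
                    ) from None
        raise
    if detection_path is None:
        cand = _detection_path(path)
        detection_path = cand if os.path.exists(cand) else None
    if detection_path is not None:
        det_df = pd.read_csv(detection_path, sep="\t", index_col=0)
        if det_df.shape != df.shape:
            raise ValueError(
                f"detection file shape {det_df.shape} does not match "
                f"expression shape {df.shape}"
            )
        detected = det_df.to_numpy(dtype=float).astype(bool)
    else:
        detected = np.isfinite(values)
    mat = ExpressionMatrix(feature_ids, sample_ids, values, detected, scale_tag=scale_tag)
    return mat.to_log2()


def write_expression(mat: ExpressionMatrix, path: str, detection_path: str | None = None) -> None:
    """Write expression values and the parallel detection matrix as TSVs."""
    mat.to_frame().to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")
    if detection_path is None:
        detection_path = _detection_path(path)
    det = pd.DataFrame(
        mat.detected.astype(int), index=mat.feature_ids, columns=mat.sample_ids
    )
    det.to_csv(detection_path, sep="\t", index_label="feature_id")


def read_sample_table(path: str, hs_low: float | None = None, hs_high: float | None = None) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    return SampleTable(df, hs_low=hs_low, hs_high=hs_high)


def write_sample_table(table: SampleTable, path: str) -> None:
    cols = list(REQUIRED_SAMPLE_COLUMNS) + ["label", "split"]
    extra = [c for c in table.data.columns if c not in cols]
    table.data[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.17g")


def label_samples(
    table: SampleTable | pd.DataFrame,
    hs_low: float = 0.057,
    hs_high: float = 0.14,
) -> SampleTable:
    """Assign case/control/excluded labels from the hemolysis score.

    Control iff ``hs <= hs_low``; case iff ``hs > hs_high``; excluded for
    the in-between band.  Boundary semantics follow the printed rule
    exactly: the low threshold is inclusive for controls, the high one is
    exclusive for cases.
    """
    if not hs_low < hs_high:
        raise ValueError(f"hs_low ({hs_low}) must be strictly below hs_high ({hs_high})")
    df = table.data.copy() if isinstance(table, SampleTable) else table.copy()
    if "hs" not in df.columns:
        raise ValueError("sample table has no 'hs' column")
    hs = pd.to_numeric(df["hs"], errors="coerce")
    bad = df.loc[hs.isna(), "sample_id"].astype(str).tolist()
    if bad:
        raise ValueError(f"missing/invalid hemolysis score for sample(s): {bad}")
    label = np.where(
        hs > hs_high, LABEL_CASE, np.where(hs <= hs_low, LABEL_CONTROL, LABEL_EXCLUDED)
    )
    df["label"] = label
    return SampleTable(df, hs_low=hs_low, hs_high=hs_high)


# ---------------------------------------------------------------------------
# result objects


def write_results(obj, path: str) -> None:
    """Write a result object (ComparisonResult, BootstrapRanking, or a list
    of ModelRecord) to a TSV with deterministic column order."""
    from .bootstrap import BootstrapRanking
    from .classify import ModelRecord, model_records_to_frame
    from .comparison import ComparisonResult

    if isinstance(obj, ComparisonResult):
        obj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif isinstance(obj, BootstrapRanking):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, list) and all(isinstance(r, ModelRecord) for r in obj):
        model_records_to_frame(obj).to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_comparison(path: str) -> "ComparisonResult":
    from .comparison import ComparisonResult

    return ComparisonResult.from_frame(
        pd.read_csv(path, sep="\t", dtype={"feature": str}, float_precision="round_trip")
    )


def read_ranking(path: str) -> "BootstrapRanking":
    from .bootstrap import BootstrapRanking

    return BootstrapRanking.from_frame(
        pd.read_csv(path, sep="\t", dtype={"feature": str, "partner": str})
    )


def read_model_records(path: str):
    from .classify import model_records_from_frame

    return model_records_from_frame(
        pd.read_csv(path, sep="\t", float_precision="round_trip")
    )
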