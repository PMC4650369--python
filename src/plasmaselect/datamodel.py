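"""Core data containers shared by every pipeline stage.

The universal carrier is :class:`ExpressionMatrix` — a feature-by-sample
log2 intensity table with a parallel boolean detection matrix.  Sample
metadata (hemolysis score, class label, matching covariates, train /
validation split) lives in :class:`SampleTable`.  Fixed analysis constants
are collected in :class:`AnalysisConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "AnalysisConfig",
    "RatioMatrix",
    "LABEL_CASE",
    "LABEL_CONTROL",
    "LABEL_EXCLUDED",
]

LABEL_CASE = "case"
LABEL_CONTROL = "control"
LABEL_EXCLUDED = "excluded"

SPLIT_TRAINING = "training"
SPLIT_VALIDATION = "validation"
SPLIT_UNASSIGNED = "unassigned"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values plus detection flags.

    Parameters
    ----------
    feature_ids, sample_ids
        Ordered, unique identifiers; rows and columns of ``values``.
    values
        Real matrix, one row per feature.  Log2 intensity units once
        ``scale_tag == "log2"``.
    detected
        Boolean matrix of identical shape; True where the platform called
        the feature detected in that sample.
    scale_tag
        ``"linear"`` or ``"log2"``.  Transforms are recorded here and are
        never silently repeated.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detected: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.values.shape != (nf, ns):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({nf} features, {ns} samples)"
            )
        if self.detected.shape != self.values.shape:
            raise ValueError(
                f"detected shape {self.detected.shape} does not match "
                f"values shape {self.values.shape}"
            )
        if self.scale_tag not in ("linear", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale matrix; no-op (same object) if already log2."""
        if self.scale_tag == "log2":
            return self
        if np.any(self.values <= 0):
            raise ValueError("linear values must be positive for log2 transform")
        return replace(self, values=np.log2(self.values), scale_tag="log2")

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in idx]
        if missing:
            raise KeyError(f"unknown feature id(s): {missing}")
        rows = [idx[f] for f in keep]
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in rows],
            values=self.values[rows],
            detected=self.detected[rows],
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        cols = [idx[s] for s in keep]
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in cols],
            values=self.values[:, cols],
            detected=self.detected[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class RatioMatrix:
    """All-pairs log-ratio features derived from an :class:`ExpressionMatrix`.

    One ratio per unordered feature pair; ``values[k] = log2(A) - log2(B)``
    where A (= ``numerator_ids[k]``) precedes B in the parent's feature
    order.  For ``n`` source features there are exactly ``n*(n-1)/2`` rows.
    """

    ratio_ids: list[str]
    numerator_ids: list[str]
    denominator_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    parent: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        self.ratio_ids = _check_unique(self.ratio_ids, "ratio")
        self.values = np.asarray(self.values, dtype=float)
        if not (
            len(self.numerator_ids)
            == len(self.denominator_ids)
            == len(self.ratio_ids)
            == self.values.shape[0]
        ):
            raise ValueError("ratio id vectors and value rows must be parallel")
        seen: set[frozenset[str]] = set()
        for a, b in zip(self.numerator_ids, self.denominator_ids):
            if a == b:
                raise ValueError(f"self-ratio {a}/{b} not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"pair {{{a},{b}}} appears more than once")
            seen.add(key)

    @property
    def feature_ids(self) -> list[str]:
        # ratio matrices quack like expression matrices for downstream stages
        return self.ratio_ids

    @property
    def n_features(self) -> int:
        return len(self.ratio_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ratio_ids, columns=self.sample_ids)


REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "hs",
    "disease_status",
    "age_at_drawing",
    "drawing_year",
)


@dataclass
class SampleTable:
    """Per-sample metadata: hemolysis score, class label, covariates, split.

    Backed by a DataFrame with columns ``sample_id, hs, disease_status,
    age_at_drawing, drawing_year`` plus the derived ``label`` and ``split``
    columns.  Labels follow the hemolysis-score thresholds: control iff
    ``hs <= hs_low``, case iff ``hs > hs_high``, excluded otherwise.
    """

    data: pd.DataFrame
    hs_low: float | None = None
    hs_high: float | None = None

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing column(s): {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"].tolist(), "sample")
        if "label" not in df.columns:
            df["label"] = LABEL_EXCLUDED
        if "split" not in df.columns:
            df["split"] = SPLIT_UNASSIGNED
        if self.hs_low is not None and self.hs_high is not None:
            if not self.hs_low < self.hs_high:
                raise ValueError("hs_low must be strictly below hs_high")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def ids_with_label(self, label: str) -> list[str]:
        return self.data.loc[self.data["label"] == label, "sample_id"].tolist()

    def ids_in_split(self, split: str) -> list[str]:
        return self.data.loc[self.data["split"] == split, "sample_id"].tolist()

    def label_counts(self) -> dict[str, int]:
        counts = self.data["label"].value_counts().to_dict()
        return {
            k: int(counts.get(k, 0)) for k in (LABEL_CASE, LABEL_CONTROL, LABEL_EXCLUDED)
        }

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = set(map(str, sample_ids))
        df = self.data[self.data["sample_id"].isin(keep)].reset_index(drop=True)
        return SampleTable(df, hs_low=self.hs_low, hs_high=self.hs_high)


@dataclass
class AnalysisConfig:
    """Fixed constants of the analysis strategy.

    Defaults: hemolysis-score thresholds
    0.057 / 0.14, 90 % detection filter, FDR level 0.05, 1000 bootstrap
    replicates, co-occurrence edge filter 300, caliper multiplier 0.2,
    1:2 case:control matching, 1000 bootstrap CI resamples.
    """

    hs_low: float = 0.057
    hs_high: float = 0.14
    detection_frac: float = 0.90
    alpha: float = 0.05
    B_boot: int = 1000
    cooc_min: int = 300
    caliper_mult: float = 0.2
    control_ratio: int = 2
    B_ci: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_frac", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("B_boot", "cooc_min", "control_ratio", "B_ci"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
            setattr(self, name, int(v))
        if not self.hs_low < self.hs_high:
            raise ValueError("hs_low must be strictly below hs_high")
        if self.caliper_mult <= 0:
            raise ValueError("caliper_mult must be positive")
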