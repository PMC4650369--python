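"""Detection-based feature filtering and ratio normalization.

Features are kept when detected in at least a given fraction (default
90 %) of a reference sample set.  Ratio normalization then uses every
retained feature in turn as normalizer, forming one log2 ratio per
unordered feature pair — n features yield n*(n-1)/2 ratio features.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, RatioMatrix

__all__ = ["filter_by_detection", "make_ratio_features", "detection_fractions"]


def detection_fractions(X: ExpressionMatrix, reference_ids: Sequence[str]) -> pd.Series:
    """Per-feature fraction of reference samples in which it is detected."""
    ref = list(dict.fromkeys(map(str, reference_ids)))
    if not ref:
        raise ValueError("reference sample set is empty")
    sub = X.subset_samples(ref)
    frac = sub.detected.mean(axis=1)
    return pd.Series(frac, index=X.feature_ids, name="detection_fraction")


def filter_by_detection(
    X: ExpressionMatrix,
    min_frac: float = 0.90,
    reference_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Keep features detected in at least ``min_frac`` of the reference set.

    The boundary is inclusive: a feature detected in exactly
    ``min_frac * |reference|`` samples is retained.  ``reference_ids``
    defaults to all samples; passing the training-set ids restricts the
    filter to the training samples (avoids leaking validation data).
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if reference_ids is None:
        reference_ids = X.sample_ids
    frac = detection_fractions(X, reference_ids)
    keep = [f for f, fr in frac.items() if fr >= min_frac]
    return X.subset_features(keep)


def make_ratio_features(X: ExpressionMatrix) -> RatioMatrix:
    """Build all-pairs log2 ratio features, each unordered pair once.

    Orientation is fixed by input order: the numerator is the feature
    appearing earlier in ``X.feature_ids``.  Values are computed on the
    log2 scale as numerator minus denominator.
    """
    if X.scale_tag != "log2":
        raise ValueError("ratio features require a log2-scale matrix; call to_log2() first")
    n = X.n_features
    if n < 2:
        raise ValueError(f"need at least 2 features to form ratios, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    values = X.values[iu] - X.values[ju]
    num = [X.feature_ids[i] for i in iu]
    den = [X.feature_ids[j] for j in ju]
    ratio_ids = [f"{a}/{b}" for a, b in zip(num, den)]
    return RatioMatrix(
        ratio_ids=ratio_ids,
        numerator_ids=num,
        denominator_ids=den,
        values=values,
        sample_ids=list(X.sample_ids),
        parent=X,
    )
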