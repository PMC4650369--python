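"""Propensity-score caliper matching and the training/validation split.

Each case is matched to two distinct controls whose propensity logits lie
within the caliper (0.2 x SD of the logit propensity by default), using
greedy nearest-neighbor matching without replacement.  Matched triplets —
not individual samples — are then randomized to the training and
validation halves, so the 1:2 case:control ratio holds exactly in each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .datamodel import (
    LABEL_CASE,
    LABEL_CONTROL,
    SPLIT_TRAINING,
    SPLIT_VALIDATION,
    SampleTable,
)

__all__ = [
    "MatchResult",
    "fit_propensity",
    "caliper_width",
    "match_1to2",
    "split_train_validation",
    "covariate_balance",
]

COVARIATE_COLUMNS = ("disease_status", "age_at_drawing", "drawing_year")


@dataclass
class MatchResult:
    """Outcome of 1:2 caliper matching.

    ``triplets`` holds ``(case_id, control_id_1, control_id_2)`` tuples;
    controls are never reused across triplets.  ``ps`` maps sample id to
    propensity score; ``caliper`` is the logit-scale acceptance radius.
    """

    triplets: list[tuple[str, str, str]]
    unmatched_cases: list[str]
    ps: dict[str, float]
    caliper: float

    def __post_init__(self) -> None:
        used: set[str] = set()
        for case, c1, c2 in self.triplets:
            if c1 == c2:
                raise ValueError(f"triplet for case {case} reuses control {c1}")
            for c in (c1, c2):
                if c in used:
                    raise ValueError(f"control {c} appears in more than one triplet")
                used.add(c)

    @property
    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for case, c1, c2 in self.triplets:
            out.extend((case, c1, c2))
        return out

    @property
    def n_matched_samples(self) -> int:
        return 3 * len(self.triplets)


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def fit_propensity(samples: SampleTable) -> pd.Series:
    """Fit a logistic model of case membership on the matching covariates.

    Covariates are disease status (categorical), age at drawing and
    drawing year.  Returns the fitted probability of being a case for
    every labeled sample, indexed by sample id.
    """
    df = samples.data
    mask = df["label"].isin([LABEL_CASE, LABEL_CONTROL])
    df = df.loc[mask]
    y = (df["label"] == LABEL_CASE).to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one case and one control to fit a propensity model")
    for col in COVARIATE_COLUMNS:
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "sample_id"].tolist()
            raise ValueError(f"missing covariate {col!r} for sample(s): {bad}")
    X = pd.get_dummies(
        df[list(COVARIATE_COLUMNS)], columns=["disease_status"], drop_first=True
    ).astype(float)
    # drop constant columns so the design stays full rank
    X = X.loc[:, X.std(axis=0) > 0]
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X.to_numpy()).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            "complete separation in the propensity model: fitted probabilities "
            "are degenerate and caliper matching is not meaningful"
        ) from exc
    ps = np.clip(fit.predict(X.to_numpy()), 1e-12, 1 - 1e-12)
    return pd.Series(ps, index=df["sample_id"].tolist(), name="ps")


def caliper_width(ps: pd.Series | np.ndarray, mult: float = 0.2) -> float:
    """Caliper = ``mult`` x SD of the propensity logit (n-1 denominator)."""
    p = np.asarray(ps, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    lp = _logit(p)
    sd = float(np.std(lp, ddof=1))
    width = mult * sd
    # guard against pure rounding noise from numerically constant logits
    degenerate = sd <= 1e-12 * max(1.0, float(np.max(np.abs(lp))))
    if degenerate or width <= 0 or not np.isfinite(width):
        raise ValueError(
            "propensity logit has zero spread; caliper width is 0 and no matching is possible"
        )
    return width


def match_1to2(
    cases: list[str],
    controls: list[str],
    ps: pd.Series,
    caliper: float,
) -> MatchResult:
    """Greedy nearest-neighbor 1:2 matching on the logit-propensity scale.

    Cases are processed in descending order of logit-propensity
    extremeness (distance from the mean logit over all listed samples),
    ties broken by sample id; each takes its two closest unused controls
    within the caliper.  A case with fewer than two in-caliper controls
    is reported unmatched and consumes none.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    logit_ps = {s: float(_logit(ps[s])) for s in list(cases) + list(controls)}
    center = float(np.mean([logit_ps[s] for s in cases + controls]))
    order = sorted(cases, key=lambda c: (-abs(logit_ps[c] - center), c))
    available = set(controls)
    triplets: list[tuple[str, str, str]] = []
    unmatched: list[str] = []
    for case in order:
        in_caliper = [
            c for c in available if abs(logit_ps[c] - logit_ps[case]) <= caliper
        ]
        if len(in_caliper) < 2:
            unmatched.append(case)
            continue
        in_caliper.sort(key=lambda c: (abs(logit_ps[c] - logit_ps[case]), c))
        c1, c2 = in_caliper[0], in_caliper[1]
        available.discard(c1)
        available.discard(c2)
        triplets.append((case, c1, c2))
    triplets.sort(key=lambda t: t[0])
    unmatched.sort()
    return MatchResult(
        triplets=triplets,
        unmatched_cases=unmatched,
        ps={s: float(ps[s]) for s in logit_ps},
        caliper=float(caliper),
    )


def split_train_validation(
    matched: MatchResult, samples: SampleTable, seed: int
) -> SampleTable:
    """Randomize whole matched triplets to training / validation halves.

    Keeping triplets intact preserves the exact 1:2 case:control ratio in
    both halves.  With an odd triplet count the extra triplet goes to
    training (with a warning).  Deterministic under ``seed``.
    """
    n = len(matched.triplets)
    if n == 0:
        raise ValueError("no matched triplets to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = n // 2 + n % 2
    if n % 2:
        warnings.warn(
            f"odd number of triplets ({n}); assigning the extra triplet to training",
            stacklevel=2,
        )
    train_idx = set(perm[:n_train].tolist())
    assignment: dict[str, str] = {}
    for i, (case, c1, c2) in enumerate(matched.triplets):
        split = SPLIT_TRAINING if i in train_idx else SPLIT_VALIDATION
        for s in (case, c1, c2):
            assignment[s] = split
    df = samples.data.copy()
    df["split"] = df["sample_id"].map(assignment).fillna("unassigned")
    return SampleTable(df, hs_low=samples.hs_low, hs_high=samples.hs_high)


def covariate_balance(samples: SampleTable, matched: MatchResult) -> pd.DataFrame:
    """Standardized mean differences of matching covariates before/after.

    Categorical covariates are expanded to indicator columns.  Reported
    for the matching report (role of a balance table).
    """
    df = samples.data.set_index("sample_id")
    matched_ids = set(matched.matched_ids)
    rows = []
    expanded = pd.get_dummies(
        df[list(COVARIATE_COLUMNS)], columns=["disease_status"]
    ).astype(float)
    is_case = df["label"] == LABEL_CASE
    for col in expanded.columns:
        v = expanded[col]
        for stage, sel in (
            ("before", pd.Series(True, index=df.index)),
            ("after", df.index.to_series().isin(matched_ids)),
        ):
            x = v[sel & is_case]
            y = v[sel & (df["label"] == LABEL_CONTROL)]
            pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
            smd = 0.0 if pooled == 0 else (x.mean() - y.mean()) / pooled
            rows.append({"covariate": col, "stage": stage, "smd": float(smd)})
    return pd.DataFrame(rows)
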