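"""Class comparison: t-test / Anderson-Darling union rule under BH-FDR.

Every feature is tested twice: a two-sample t-test for location shifts
and a two-sample Anderson-Darling (AD) omnibus test sensitive to any
distributional difference, with extra weight in the tails.  The two
p-value families are adjusted separately by Benjamini-Hochberg, and a
feature is called significant when either adjusted p-value falls below
alpha ("union rule").  Each feature is also placed in a concordance
quadrant: both / t_only / ad_only / neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, RatioMatrix

__all__ = [
    "t_test",
    "ad_test",
    "bh_adjust",
    "compare_classes",
    "ComparisonResult",
    "percent_significant",
]

# AD asymptotic p-values come from interpolating published critical points
# of the standardized statistic; outside the table the value is clipped.
AD_P_MIN = 0.001
AD_P_MAX = 0.25

QUADRANTS = ("both", "t_only", "ad_only", "neither")


def t_test(x, y, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test; positive statistic = up in ``x`` (cases).

    ``variant`` selects the pooled-variance classical test (default) or
    Welch's unequal-variance form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t_test needs at least 2 values per group")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


_AD_CONST_CACHE: dict[tuple[int, int, int], float] = {}


def _ad_sigma(n1: int, n2: int) -> float:
    """Null SD of the two-sample statistic; depends only on (n1, n2)."""
    key = (n1, n2, 0)
    if key in _AD_CONST_CACHE:
        return _AD_CONST_CACHE[key]
    k = 2
    N = n1 + n2
    H = 1.0 / n1 + 1.0 / n2
    h = float(np.sum(1.0 / np.arange(1, N)))
    i = np.arange(1, N - 1, dtype=float)
    # g = sum_{i<j} 1 / ((N - i) j) over 1 <= i < j <= N-1
    inv = 1.0 / np.arange(1, N, dtype=float)
    tail = np.cumsum(inv[::-1])[::-1]  # tail[j-1] = sum_{m >= j} 1/m
    g = float(np.sum(1.0 / (N - i) * tail[1:]))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    sigma = float(np.sqrt(max(var, 0.0)))
    _AD_CONST_CACHE[key] = sigma
    return sigma


def _ad_2sample_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ties-corrected (midrank) two-sample AD statistic and its null SD.

    Returns the raw statistic A2akN and sigma_N so the standardized value
    is ``(A2akN - 1) / sigma_N`` (null mean is k-1 = 1 for two samples).
    """
    samples = [np.sort(x), np.sort(y)]
    Z = np.sort(np.concatenate(samples))
    N = len(Z)
    if Z[0] == Z[-1]:
        raise ValueError("pooled sample has fewer than two distinct values")
    if N >= 2 and np.all(Z[1:] != Z[:-1]):
        # no ties: every pooled value is its own group
        Zstar, counts = Z, np.ones(N)
        cum = np.arange(N, dtype=float)
    else:
        Zstar, counts = np.unique(Z, return_counts=True)
        cum = np.concatenate(([0.0], np.cumsum(counts)[:-1]))
    # B_aj = (# pooled values < z_j) + l_j / 2
    Baj = cum + counts / 2.0
    inner = 0.0
    for sample in samples:
        n_i = len(sample)
        # M_aij = (# sample-i values < z_j) + (# equal to z_j) / 2
        lt = np.searchsorted(sample, Zstar, side="left")
        le = np.searchsorted(sample, Zstar, side="right")
        Maij = lt + (le - lt) / 2.0
        num = (N * Maij - n_i * Baj) ** 2
        den = Baj * (N - Baj) - N * counts / 4.0
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(den > 0, counts / N * num / np.where(den > 0, den, 1.0), 0.0)
        inner += terms.sum() / n_i
    A2akN = (N - 1) / N * inner
    return float(A2akN), _ad_sigma(len(x), len(y))


# Critical points of the standardized statistic tm = b0 + b1/sqrt(m) + b2/m
# (m = k - 1) at the tabulated significance levels.
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, -0.154])

_AD_CRIT = _AD_B0 + _AD_B1 / np.sqrt(1.0) + _AD_B2 / 1.0  # m = k - 1 = 1
_AD_POLY = np.polyfit(_AD_CRIT, np.log(_AD_SIG), 2)


def ad_test(x, y) -> tuple[float, float]:
    """Asymptotic ties-corrected two-sample Anderson-Darling test.

    Returns the standardized statistic ``T = (A2akN - 1) / sigma_N`` and
    an asymptotic p-value obtained by interpolating the published
    critical points of T.  Where the interpolation would extrapolate, p
    is clipped to [0.001, 0.25]; this range is a property of the
    tabulated critical values, not a tunable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("ad_test needs at least 2 values per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    A2akN, sigma = _ad_2sample_stat(x, y)
    if sigma == 0:
        return 0.0, 1.0
    T = (A2akN - 1.0) / sigma
    if T < _AD_CRIT[0]:
        p = AD_P_MAX
    elif T > _AD_CRIT[-1]:
        p = AD_P_MIN
    else:
        p = float(np.exp(np.polyval(_AD_POLY, T)))
        p = float(np.clip(p, AD_P_MIN, AD_P_MAX))
    return float(T), p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class ComparisonResult:
    """Per-feature class-comparison table.

    Columns: feature, fc_log2 (mean case - mean control), t_stat, t_p,
    t_q, ad_stat, ad_p, ad_q, significant, quadrant.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    COLUMNS = (
        "feature",
        "fc_log2",
        "t_stat",
        "t_p",
        "t_q",
        "ad_stat",
        "ad_p",
        "ad_q",
        "significant",
        "quadrant",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"comparison table missing column(s): {missing}")
        self.table = self.table[list(self.COLUMNS)].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float = 0.05) -> "ComparisonResult":
        df = df.copy()
        if "significant" in df.columns:
            df["significant"] = df["significant"].astype(bool)
        return cls(df, alpha=alpha)

    @property
    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()

    def volcano_table(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "feature": t["feature"],
                "fc_log2": t["fc_log2"],
                "neg_log10_t_q": -np.log10(t["t_q"].clip(lower=1e-300)),
            }
        )

    def concordance_table(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "feature": t["feature"],
                "neg_log10_t_q": -np.log10(t["t_q"].clip(lower=1e-300)),
                "neg_log10_ad_q": -np.log10(t["ad_q"].clip(lower=1e-300)),
                "quadrant": t["quadrant"],
            }
        )

    def summary(self) -> dict:
        """Reporting-layer bookkeeping: counts and one-decimal percentages."""
        t = self.table
        n = len(t)
        n_sig = int(t["significant"].sum())
        t_sig = t["t_q"] < self.alpha
        n_up = int((t_sig & (t["fc_log2"] > 0)).sum())
        n_down = int((t_sig & (t["fc_log2"] < 0)).sum())
        return {
            "n_features": n,
            "n_significant": n_sig,
            "pct_significant": percent_significant(n_sig, n),
            "n_t_up": n_up,
            "n_t_down": n_down,
            "n_t_total": n_up + n_down,
            "quadrants": {q: int((t["quadrant"] == q).sum()) for q in QUADRANTS},
        }


def percent_significant(k: int, n: int) -> float:
    """Percentage reported to one decimal place, truncating toward zero.

    Truncation is deliberate (4 of 88 -> 4.5, 224 of 3828 -> 5.8);
    half-up rounding would print 5.9 for the latter.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    return np.floor(1000.0 * k / n + 1e-9) / 10.0


def compare_classes(
    X: ExpressionMatrix | RatioMatrix,
    labels: dict[str, str] | pd.Series,
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> ComparisonResult:
    """Run both tests per feature, adjust each family, apply the union rule.

    ``labels`` maps sample id to "case"/"control"; other samples are
    ignored.  Features constant across all tested samples get p = 1 in
    both tests (kept, so feature indices stay stable).
    """
    labels = pd.Series(labels)
    case_ids = [s for s in X.sample_ids if labels.get(s) == "case"]
    ctrl_ids = [s for s in X.sample_ids if labels.get(s) == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"each class needs >= 2 samples (got {len(case_ids)} cases, "
            f"{len(ctrl_ids)} controls)"
        )
    col = {s: i for i, s in enumerate(X.sample_ids)}
    Xc = X.values[:, [col[s] for s in case_ids]]
    Xk = X.values[:, [col[s] for s in ctrl_ids]]

    nfeat = X.values.shape[0]
    t_stat = np.zeros(nfeat)
    t_p = np.ones(nfeat)
    ad_stat = np.zeros(nfeat)
    ad_p = np.ones(nfeat)
    fc = Xc.mean(axis=1) - Xk.mean(axis=1)
    for i in range(nfeat):
        xi, yi = Xc[i], Xk[i]
        if np.ptp(np.concatenate([xi, yi])) == 0:
            continue
        t_stat[i], t_p[i] = t_test(xi, yi, variant=t_variant)
        ad_stat[i], ad_p[i] = ad_test(xi, yi)

    t_q = bh_adjust(t_p)
    ad_q = bh_adjust(ad_p)
    t_sig = t_q < alpha
    ad_sig = ad_q < alpha
    quadrant = np.where(
        t_sig & ad_sig, "both", np.where(t_sig, "t_only", np.where(ad_sig, "ad_only", "neither"))
    )
    table = pd.DataFrame(
        {
            "feature": X.feature_ids,
            "fc_log2": fc,
            "t_stat": t_stat,
            "t_p": t_p,
            "t_q": t_q,
            "ad_stat": ad_stat,
            "ad_p": ad_p,
            "ad_q": ad_q,
            "significant": t_sig | ad_sig,
            "quadrant": quadrant,
        }
    )
    return ComparisonResult(table, alpha=alpha)
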