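"""Forward-inclusion linear-SVM classifier family with LOOCV selection.

Models are built over the Cartesian grid of (top-k bootstrap-ranked
features, SVM cost, class-weight pair), scored by leave-one-out
cross-validated sensitivity / specificity / Youden index, grouped by
exact (FPR, TPR) position in ROC space, and the parsimonious member of
each group (fewest features) is evaluated on the validation set with
stratified percentile bootstrap confidence intervals.

The positive class is the hemolyzed case; sensitivity is the case
detection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "ModelRecord",
    "youden",
    "loocv_performance",
    "build_model_family",
    "group_models_roc",
    "choose_parsimonious",
    "evaluate_validation",
    "model_records_to_frame",
    "model_records_from_frame",
    "DEFAULT_COST_GRID",
    "DEFAULT_WEIGHT_GRID",
]

DEFAULT_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_WEIGHT_GRID = ((0.5, 0.5), (0.4, 0.6), (0.3, 0.7), (0.2, 0.8))


def youden(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError(f"sens/spec must lie in [0, 1], got ({sens}, {spec})")
    return sens + spec - 1.0


@dataclass
class ModelRecord:
    """One linear-SVM candidate and its cross-validated performance."""

    k: int
    cost: float
    weights: tuple[float, float]  # (w_case, w_control), sums to 1
    features: list[str] = field(default_factory=list)
    loocv: tuple[float, float, float] | None = None  # sens, spec, youden
    group_id: int | None = None
    chosen: bool = False
    validation: dict | None = None

    def __post_init__(self) -> None:
        if self.loocv is not None:
            sens, spec, j = self.loocv
            if abs(j - youden(sens, spec)) > 1e-9:
                raise ValueError("loocv youden does not equal sens + spec - 1")

    @property
    def fpr(self) -> float:
        return 1.0 - self.loocv[1]

    @property
    def tpr(self) -> float:
        return self.loocv[0]


def _svm(cost: float, weights: tuple[float, float]) -> SVC:
    w_case, w_control = weights
    return SVC(kernel="linear", C=cost, class_weight={1: w_case, 0: w_control})


def _extract(X, labels, feature_ids):
    labels = pd.Series(labels)
    keep = [s for s in X.sample_ids if labels.get(s) in ("case", "control")]
    col = {s: i for i, s in enumerate(X.sample_ids)}
    row = {f: i for i, f in enumerate(X.feature_ids)}
    missing = [f for f in feature_ids if f not in row]
    if missing:
        raise KeyError(f"unknown feature id(s): {missing}")
    A = X.values[np.ix_([row[f] for f in feature_ids], [col[s] for s in keep])].T
    y = np.array([1 if labels[s] == "case" else 0 for s in keep])
    return A, y


def _confusion_rates(y_true, y_pred) -> tuple[float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return float(sens), float(spec)


def loocv_performance(
    X_topk, labels, cost: float, weights: tuple[float, float]
) -> tuple[float, float, float]:
    """Leave-one-out cross-validated (sens, spec, Youden).

    Each sample is predicted by a linear SVM with the given fixed cost
    and class weights trained on the remaining n-1 samples; nothing is
    re-tuned per fold.  Deterministic for fixed data.
    """
    A, y = _extract(X_topk, labels, X_topk.feature_ids)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.arange(n) != i
        if len(np.unique(y[mask])) < 2:
            raise ValueError(
                "a LOOCV fold lost an entire class; need >= 2 samples per class"
            )
        clf = _svm(cost, weights)
        clf.fit(A[mask], y[mask])
        preds[i] = int(clf.predict(A[i : i + 1])[0])
    sens, spec = _confusion_rates(y, preds)
    return sens, spec, youden(sens, spec)


def build_model_family(
    X,
    labels,
    rank_order: list[str],
    k_grid=None,
    cost_grid=DEFAULT_COST_GRID,
    weight_grid=DEFAULT_WEIGHT_GRID,
) -> list[ModelRecord]:
    """One LOOCV-scored record per (k, cost, weights) combination.

    Features enter forwardly by bootstrap rank: the k-feature model uses
    the top k of ``rank_order``.  A k beyond the available features is
    truncated (with a warning).
    """
    if not rank_order:
        raise ValueError("rank_order must not be empty")
    if k_grid is None:
        k_grid = range(1, min(50, len(rank_order)) + 1)
    k_list = sorted({int(k) for k in k_grid})
    if not k_list or not list(cost_grid) or not list(weight_grid):
        raise ValueError("all grids must be nonempty")
    if k_list[-1] > len(rank_order):
        warnings.warn(
            f"k={k_list[-1]} exceeds {len(rank_order)} ranked features; truncating",
            stacklevel=2,
        )
        k_list = sorted({min(k, len(rank_order)) for k in k_list})
    records = []
    for k in k_list:
        feats = rank_order[:k]
        X_topk = X.subset_features(feats) if hasattr(X, "subset_features") else _subset(X, feats)
        for cost in cost_grid:
            for weights in weight_grid:
                sens, spec, j = loocv_performance(X_topk, labels, cost, tuple(weights))
                records.append(
                    ModelRecord(
                        k=k,
                        cost=float(cost),
                        weights=tuple(weights),
                        features=list(feats),
                        loocv=(sens, spec, j),
                    )
                )
    return records


def _subset(X, feats):
    row = {f: i for i, f in enumerate(X.feature_ids)}
    idx = [row[f] for f in feats]

    class _View:
        feature_ids = list(feats)
        sample_ids = list(X.sample_ids)
        values = X.values[idx]

    return _View()


def group_models_roc(records: list[ModelRecord]) -> list[ModelRecord]:
    """Group models sharing an exact (FPR, TPR); rank groups by Youden.

    Performances are rationals with denominator n, so exact equality is
    well defined.  group_id 1 is the highest-Youden group.  Records are
    annotated in place and returned.
    """
    groups: dict[tuple[float, float], list[ModelRecord]] = {}
    for rec in records:
        if rec.loocv is None:
            raise ValueError("LOOCV must be filled in before grouping")
        key = (round(rec.fpr, 12), round(rec.tpr, 12))
        groups.setdefault(key, []).append(rec)
    # same-Youden groups tie-break deterministically by (FPR, -TPR)
    ordered = sorted(
        groups.items(), key=lambda kv: (-(kv[1][0].loocv[2]), kv[0][0], -kv[0][1])
    )
    for gid, (_, members) in enumerate(ordered, start=1):
        for rec in members:
            rec.group_id = gid
    return records


def choose_parsimonious(records: list[ModelRecord], group_id: int) -> ModelRecord:
    """Pick the group's smallest model: min k, then min cost, then most
    balanced class weights."""
    members = [r for r in records if r.group_id == group_id]
    if not members:
        raise ValueError(f"no models in group {group_id}")
    best = min(members, key=lambda r: (r.k, r.cost, abs(r.weights[0] - 0.5)))
    best.chosen = True
    return best


def evaluate_validation(
    record: ModelRecord,
    X_train,
    labels_train,
    X_val,
    labels_val,
    B_ci: int = 1000,
    seed: int = 0,
) -> ModelRecord:
    """Refit on the full training set, score the validation set with
    stratified percentile bootstrap 95 % CIs."""
    feats = record.features
    A_tr, y_tr = _extract(X_train, labels_train, feats)
    A_va, y_va = _extract(X_val, labels_val, feats)
    if len(np.unique(y_va)) < 2:
        raise ValueError("validation set must contain both classes")
    clf = _svm(record.cost, record.weights)
    clf.fit(A_tr, y_tr)
    preds = clf.predict(A_va)
    sens, spec = _confusion_rates(y_va, preds)
    j = youden(sens, spec)

    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y_va == 1)
    ctrl_idx = np.flatnonzero(y_va == 0)
    boot = np.empty((B_ci, 3))
    for b in range(B_ci):
        ci_ = case_idx[rng.integers(0, len(case_idx), len(case_idx))]
        ki_ = ctrl_idx[rng.integers(0, len(ctrl_idx), len(ctrl_idx))]
        idx = np.concatenate([ci_, ki_])
        s_, p_ = _confusion_rates(y_va[idx], preds[idx])
        boot[b] = (s_, p_, s_ + p_ - 1.0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    record.validation = {
        "sens": sens,
        "spec": spec,
        "youden": j,
        "ci_sens": (float(lo[0]), float(hi[0])),
        "ci_spec": (float(lo[1]), float(hi[1])),
        "ci_youden": (float(lo[2]), float(hi[2])),
    }
    return record


# ---------------------------------------------------------------------------
# serialization

_MR_COLUMNS = (
    "k",
    "cost",
    "w_case",
    "w_control",
    "features",
    "loocv_sens",
    "loocv_spec",
    "loocv_youden",
    "group_id",
    "chosen",
    "val_sens",
    "val_spec",
    "val_youden",
    "val_ci_sens_lo",
    "val_ci_sens_hi",
    "val_ci_spec_lo",
    "val_ci_spec_hi",
    "val_ci_youden_lo",
    "val_ci_youden_hi",
)


def model_records_to_frame(records: list[ModelRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "k": r.k,
            "cost": r.cost,
            "w_case": r.weights[0],
            "w_control": r.weights[1],
            "features": ";".join(r.features),
            "loocv_sens": r.loocv[0] if r.loocv else np.nan,
            "loocv_spec": r.loocv[1] if r.loocv else np.nan,
            "loocv_youden": r.loocv[2] if r.loocv else np.nan,
            "group_id": r.group_id if r.group_id is not None else -1,
            "chosen": r.chosen,
        }
        v = r.validation or {}
        row.update(
            {
                "val_sens": v.get("sens", np.nan),
                "val_spec": v.get("spec", np.nan),
                "val_youden": v.get("youden", np.nan),
                "val_ci_sens_lo": v.get("ci_sens", (np.nan, np.nan))[0],
                "val_ci_sens_hi": v.get("ci_sens", (np.nan, np.nan))[1],
                "val_ci_spec_lo": v.get("ci_spec", (np.nan, np.nan))[0],
                "val_ci_spec_hi": v.get("ci_spec", (np.nan, np.nan))[1],
                "val_ci_youden_lo": v.get("ci_youden", (np.nan, np.nan))[0],
                "val_ci_youden_hi": v.get("ci_youden", (np.nan, np.nan))[1],
            }
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_MR_COLUMNS))


def model_records_from_frame(df: pd.DataFrame) -> list[ModelRecord]:
    records = []
    for r in df.itertuples():
        loocv = None
        if not np.isnan(r.loocv_sens):
            loocv = (float(r.loocv_sens), float(r.loocv_spec), float(r.loocv_youden))
        validation = None
        if not np.isnan(r.val_sens):
            validation = {
                "sens": float(r.val_sens),
                "spec": float(r.val_spec),
                "youden": float(r.val_youden),
                "ci_sens": (float(r.val_ci_sens_lo), float(r.val_ci_sens_hi)),
                "ci_spec": (float(r.val_ci_spec_lo), float(r.val_ci_spec_hi)),
                "ci_youden": (float(r.val_ci_youden_lo), float(r.val_ci_youden_hi)),
            }
        rec = ModelRecord(
            k=int(r.k),
            cost=float(r.cost),
            weights=(float(r.w_case), float(r.w_control)),
            features=str(r.features).split(";") if r.features else [],
            loocv=loocv,
            group_id=None if r.group_id == -1 else int(r.group_id),
            chosen=bool(r.chosen),
            validation=validation,
        )
        records.append(rec)
    return records
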