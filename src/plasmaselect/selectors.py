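"""Three selection algorithms behind one contract.

Each selector takes a (features x samples) training block with binary
labels and returns a :class:`SelectorResult` with the selected feature id
set, per-feature scores and the tuned hyperparameters:

* :func:`nsc_select` — nearest shrunken centroids (PAM-style soft
  thresholding of standardized centroid differences);
* :func:`boruta_rf_select` — random-forest importances tested against
  shuffled "shadow" copies with binomial decisions (Boruta);
* :func:`elastic_scad_svm_select` — linear SVM with a SCAD + ridge
  penalty fitted by successive quadratic approximation.

All three standardize features internally and are deterministic under a
fixed seed, which makes them exchangeable inside the bootstrap driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectorResult",
    "scad_penalty",
    "scad_derivative",
    "nsc_select",
    "boruta_rf_select",
    "elastic_scad_svm_select",
]


@dataclass
class SelectorResult:
    """Uniform selector output: ids chosen, per-feature scores, tuning."""

    selected: set[str]
    scores: dict[str, float]
    tuning: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = self.selected - set(self.scores)
        if unknown:
            raise ValueError(f"selected ids without scores: {sorted(unknown)}")


def _as_matrix(X, labels):
    """Coerce (features x samples, labels per sample) to arrays.

    Accepts an ExpressionMatrix/RatioMatrix-like object (``feature_ids``,
    ``sample_ids``, ``values``) or a plain array plus feature ids.
    Returns (samples x features array, y in {0,1} with 1 = case,
    feature ids).
    """
    import pandas as pd

    labels = pd.Series(labels)
    if hasattr(X, "values") and hasattr(X, "feature_ids"):
        sample_ids = list(X.sample_ids)
        keep = [s for s in sample_ids if labels.get(s) in ("case", "control")]
        col = {s: i for i, s in enumerate(sample_ids)}
        A = X.values[:, [col[s] for s in keep]].T
        y = np.array([1 if labels[s] == "case" else 0 for s in keep])
        return A, y, list(X.feature_ids)
    raise TypeError("X must expose feature_ids/sample_ids/values")


def _standardize(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (A - mu) / sd


# ---------------------------------------------------------------------------
# nearest shrunken centroids


def _nsc_shrunken_diffs(A, y, delta):
    """Shrunken standardized centroid differences for both classes.

    Returns (dprime, s, s0, centroids, overall) where dprime has shape
    (2, n_features).
    """
    n, p = A.shape
    classes = (0, 1)
    overall = A.mean(axis=0)
    nk = np.array([np.sum(y == c) for c in classes])
    cents = np.vstack([A[y == c].mean(axis=0) for c in classes])
    # pooled within-class SD
    ss = np.zeros(p)
    for ci, c in enumerate(classes):
        ss += ((A[y == c] - cents[ci]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    d = (cents - overall) / (mk[:, None] * (s + s0)[None, :])
    dprime = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return dprime, s, s0, cents, overall


def _nsc_predict_grid(A_test, A_train, y_train, deltas):
    """Predicted classes for every delta at once; shape (len(deltas), n_test)."""
    d_unshrunk, s, s0, cents, overall = _nsc_shrunken_diffs(A_train, y_train, 0.0)
    n = len(y_train)
    nk = np.array([np.sum(y_train == c) for c in (0, 1)])
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    prior = nk / n
    denom = (s + s0) ** 2
    preds = np.empty((len(deltas), A_test.shape[0]), dtype=int)
    for gi, delta in enumerate(deltas):
        dprime = np.sign(d_unshrunk) * np.maximum(np.abs(d_unshrunk) - delta, 0.0)
        shrunk = overall[None, :] + (mk[:, None] * (s + s0)[None, :]) * dprime
        scores = np.stack(
            [
                ((A_test - shrunk[ci]) ** 2 / denom).sum(axis=1) - 2.0 * np.log(prior[ci])
                for ci in range(2)
            ],
            axis=1,
        )
        preds[gi] = np.argmin(scores, axis=1)
    return preds


def nsc_select(
    X,
    labels,
    delta_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectorResult:
    """Nearest-shrunken-centroid (PAM) selection.

    The shrinkage threshold delta is chosen from ``delta_grid`` by
    stratified cross-validated misclassification; ties go to the larger
    delta (fewer features).  Selected features are those with a nonzero
    shrunken difference in either class at the chosen delta.
    """
    A, y, feature_ids = _as_matrix(X, labels)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 4.0, 17)
    delta_grid = np.asarray(list(delta_grid), dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delta_grid must not be empty")
    for c in (0, 1):
        if np.sum(y == c) < 2:
            raise ValueError("need >= 2 samples in each class")

    folds = min(cv_folds, int(np.min(np.bincount(y))))
    if folds >= 2 and delta_grid.size > 1:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        errs = np.zeros(delta_grid.size)
        for tr, te in skf.split(A, y):
            preds = _nsc_predict_grid(A[te], A[tr], y[tr], delta_grid)
            errs += (preds != y[te][None, :]).sum(axis=1)
        best = np.flatnonzero(errs == errs.min())[-1]  # tie -> larger delta
    else:
        best = 0
    delta = float(delta_grid[best])
    dprime, *_ = _nsc_shrunken_diffs(A, y, delta)
    mag = np.abs(dprime).max(axis=0)
    selected = {feature_ids[j] for j in np.flatnonzero(mag > 0)}
    return SelectorResult(
        selected=selected,
        scores={f: float(m) for f, m in zip(feature_ids, mag)},
        tuning={"delta": delta, "cv_folds": folds},
    )


# ---------------------------------------------------------------------------
# Boruta random forest


def _rf_importances(A, y, n_estimators, rng):
    """Random-forest Gini importances via an explicit bagging loop.

    Equivalent to a RandomForestClassifier (bootstrap resample per tree,
    sqrt feature subsampling, mean of per-tree normalized importances)
    but without the per-fit ensemble overhead, which dominates at the
    thousands-of-fits scale of the bootstrap driver.
    """
    n, p = A.shape
    imp = np.zeros(p)
    for _ in range(n_estimators):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(A[idx], y[idx])
        imp += tree.feature_importances_
    return imp / n_estimators


def boruta_rf_select(
    X,
    labels,
    max_iter: int = 50,
    seed: int = 0,
    n_estimators: int = 100,
    alpha: float = 0.01,
) -> SelectorResult:
    """Boruta all-relevant selection around a random forest.

    Each iteration augments the block with per-column shuffled shadow
    copies, fits a forest, and scores a "hit" for every real feature
    whose importance exceeds the best shadow importance.  Hit counts are
    tested against Binomial(iterations, 1/2) two-sidedly at a
    BH-corrected level; confirmed features are selected, tentative
    features at ``max_iter`` are not.
    """
    from .comparison import bh_adjust

    if max_iter < 10:
        raise ValueError("max_iter < 10 leaves the binomial decisions underpowered")
    A, y, feature_ids = _as_matrix(X, labels)
    A = _standardize(A)
    p = len(feature_ids)
    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    decided = np.zeros(p, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        # rejected features leave the design (and lose their shadows),
        # raising power for the survivors — as in the original algorithm
        active = np.flatnonzero(decided >= 0)
        A_act = A[:, active]
        # at least 5 shadow columns (duplicating features as needed), as in
        # the reference algorithm; keeps the max-shadow bar honest when few
        # features remain active
        src = active
        while len(src) < 5:
            src = np.concatenate([src, active[: 5 - len(src)]])
        shadows = A[:, src].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        aug = np.hstack([A_act, shadows])
        imp = _rf_importances(aug, y, n_estimators, rng)
        shadow_max = imp[len(active):].max()
        hits[active] += (imp[: len(active)] > shadow_max).astype(int)
        # two-sided binomial decisions on the still-tentative features
        tentative = decided == 0
        if tentative.any() and n_iter >= 5:
            p_hi = stats.binom.sf(hits[tentative] - 1, n_iter, 0.5)
            p_lo = stats.binom.cdf(hits[tentative], n_iter, 0.5)
            idx = np.flatnonzero(tentative)
            decided[idx[bh_adjust(p_hi) < alpha]] = 1
            decided[idx[bh_adjust(p_lo) < alpha]] = -1
        if not (decided == 0).any():
            break
    selected = {feature_ids[j] for j in np.flatnonzero(decided == 1)}
    return SelectorResult(
        selected=selected,
        scores={f: float(h) / n_iter for f, h in zip(feature_ids, hits)},
        tuning={
            "n_iterations": n_iter,
            "n_estimators": n_estimators,
            "n_tentative": int((decided == 0).sum()),
        },
    )


# ---------------------------------------------------------------------------
# elastic SCAD SVM


def scad_penalty(w, lam: float, a: float = 3.7):
    """SCAD penalty value, elementwise on |w|."""
    if a <= 2:
        raise ValueError("SCAD 'a' must exceed 2")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    t = np.abs(np.asarray(w, dtype=float))
    lin = lam * t
    quad = -(t**2 - 2 * a * lam * t + lam**2) / (2 * (a - 1))
    const = (a + 1) * lam**2 / 2.0
    return np.where(t <= lam, lin, np.where(t <= a * lam, quad, const))


def scad_derivative(w, lam: float, a: float = 3.7):
    """Derivative of the SCAD penalty w.r.t. |w| (elementwise, >= 0)."""
    t = np.abs(np.asarray(w, dtype=float))
    return np.where(
        t <= lam, lam, np.where(t <= a * lam, np.maximum(a * lam - t, 0.0) / (a - 1), 0.0)
    )


def _smoothed_hinge(z, delta=0.05):
    """Huber-smoothed hinge loss of the margin z and its derivative."""
    loss = np.where(
        z >= 1.0,
        0.0,
        np.where(z <= 1.0 - delta, 1.0 - z - delta / 2.0, (1.0 - z) ** 2 / (2.0 * delta)),
    )
    grad = np.where(z >= 1.0, 0.0, np.where(z <= 1.0 - delta, -1.0, -(1.0 - z) / delta))
    return loss, grad


def _fit_scad_svm(A, ysign, lam1, lam2, a=3.7, tol=1e-4, max_outer=200, lbfgs_iter=200):
    """Fit hinge-loss linear SVM with SCAD(lam1) + lam2*||w||^2 penalty.

    Successive convex surrogates: the SCAD term is locally approximated
    by a quadratic q_j * w_j^2 with q_j = p'(|w_j|) / (2 |w_j|), and each
    surrogate is minimized with L-BFGS on a smoothed hinge.
    """
    n, p = A.shape
    eps = 1e-8
    converged = False

    def objective(params, q):
        w_, b_ = params[:p], params[p]
        z = ysign * (A @ w_ + b_)
        loss, grad_z = _smoothed_hinge(z)
        obj = loss.mean() + np.sum((q + lam2) * w_**2)
        gw = (A * (grad_z * ysign)[:, None]).mean(axis=0) + 2 * (q + lam2) * w_
        gb = float(np.mean(grad_z * ysign))
        return obj, np.concatenate([gw, [gb]])

    # ridge-only warm start; starting LQA at w = 0 would pin all weights there
    res = optimize.minimize(
        objective,
        np.zeros(p + 1),
        args=(np.zeros(p),),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": lbfgs_iter},
    )
    w, b = res.x[:p], float(res.x[p])

    for _ in range(max_outer):
        q = scad_derivative(w, lam1, a) / (2.0 * np.maximum(np.abs(w), eps))
        res = optimize.minimize(
            objective,
            np.concatenate([w, [b]]),
            args=(q,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": lbfgs_iter},
        )
        w_new, b_new = res.x[:p], float(res.x[p])
        delta = float(np.max(np.abs(w_new - w))) if p else 0.0
        # converged only when the step is small AND the support stopped
        # changing — vanishing weights keep shrinking by orders of
        # magnitude with tiny absolute steps, and must cross the zero
        # threshold before we stop
        support_stable = np.array_equal(np.abs(w_new) > 1e-8, np.abs(w) > 1e-8)
        w, b = w_new, b_new
        if delta < tol and support_stable:
            converged = True
            break
    w = np.where(np.abs(w) > 1e-8, w, 0.0)
    return w, b, converged


def _svm_cv_error(A, y, lam1, lam2, folds, seed, tol=1e-4, max_outer=200, lbfgs_iter=200):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    err = 0
    for tr, te in skf.split(A, y):
        ysign = np.where(y[tr] == 1, 1.0, -1.0)
        w, b, _ = _fit_scad_svm(A[tr], ysign, lam1, lam2, tol=tol, max_outer=max_outer, lbfgs_iter=lbfgs_iter)
        pred = (A[te] @ w + b > 0).astype(int)
        err += int(np.sum(pred != y[te]))
    return err


def elastic_scad_svm_select(
    X,
    labels,
    lambda1_grid=None,
    lambda2_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_outer: int = 200,
    lbfgs_iter: int = 200,
) -> SelectorResult:
    """Linear SVM with elastic SCAD penalty (SCAD sparsity + ridge).

    The ridge term keeps correlated informative features in the model
    together; SCAD gives near-unbiased sparsity.  (lambda1, lambda2) are
    tuned by stratified CV misclassification, ties resolved toward the
    sparser fitted model.  Features with |w| > 1e-8 after a full-block
    refit are selected.
    """
    A, y, feature_ids = _as_matrix(X, labels)
    A = _standardize(A)
    if lambda1_grid is None:
        lambda1_grid = 2.0 ** np.arange(-8.0, 1.0, 2.0)
    if lambda2_grid is None:
        lambda2_grid = 2.0 ** np.arange(-8.0, 3.0, 2.0)
    lambda1_grid = np.asarray(list(lambda1_grid), dtype=float)
    lambda2_grid = np.asarray(list(lambda2_grid), dtype=float)
    if lambda1_grid.size == 0 or lambda2_grid.size == 0:
        raise ValueError("lambda grids must not be empty")

    folds = min(cv_folds, int(np.min(np.bincount(y))))
    candidates = [(l1, l2) for l1 in lambda1_grid for l2 in lambda2_grid]
    if len(candidates) > 1 and folds >= 2:
        scored = []
        for l1, l2 in candidates:
            err = _svm_cv_error(A, y, l1, l2, folds, seed, tol=tol, max_outer=max_outer, lbfgs_iter=lbfgs_iter)
            scored.append((err, l1, l2))
        best_err = min(s[0] for s in scored)
        finalists = [(l1, l2) for err, l1, l2 in scored if err == best_err]
    else:
        finalists = candidates

    # refit finalists on the full block; ties -> sparser model
    ysign = np.where(y == 1, 1.0, -1.0)
    best = None
    for l1, l2 in finalists:
        w, b, conv = _fit_scad_svm(A, ysign, l1, l2, tol=tol, max_outer=max_outer, lbfgs_iter=lbfgs_iter)
        nnz = int(np.sum(w != 0))
        key = (nnz, l1, l2)
        if best is None or key < best[0]:
            best = (key, w, b, l1, l2, conv)
    _, w, b, l1, l2, conv = best
    selected = {feature_ids[j] for j in np.flatnonzero(np.abs(w) > 1e-8)}
    return SelectorResult(
        selected=selected,
        scores={f: float(abs(wj)) for f, wj in zip(feature_ids, w)},
        tuning={
            "lambda1": float(l1),
            "lambda2": float(l2),
            "cv_folds": folds,
            "converged": bool(conv),
        },
    )
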