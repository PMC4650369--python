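"""Bootstrap triple-algorithm intersection ranking and co-occurrence graph.

Stratified bootstrap replicates of the training samples are drawn (class
proportions preserved), all three selectors run on every replicate, and a
feature scores an occurrence in a replicate only when selected by ALL
three algorithms simultaneously.  Features are ranked by occurrence count
over the B replicates; pairwise co-occurrences feed the "egg-shaped"
network, exported as GraphML with size-proportional node/edge attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .selectors import (
    SelectorResult,
    boruta_rf_select,
    elastic_scad_svm_select,
    nsc_select,
)

__all__ = [
    "BootstrapRanking",
    "stratified_bootstrap",
    "run_bootstrap_selection",
    "rank_features",
    "export_cooccurrence_graph",
    "default_selectors",
]


@dataclass
class BootstrapRanking:
    """Occurrence / co-occurrence counts over B bootstrap replicates.

    ``occ[f]`` counts replicates in which feature ``f`` was selected by
    all three algorithms; ``cooc[(f, g)]`` (keys stored with f < g)
    counts replicates in which both were.  ``rank_order`` excludes
    zero-occurrence features.
    """

    B: int
    occ: dict[str, int]
    cooc: dict[tuple[str, str], int]
    rank_order: list[str] = field(default_factory=list)
    per_replicate_masks: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for f, n in self.occ.items():
            if not 0 <= n <= self.B:
                raise ValueError(f"occ[{f}] = {n} outside [0, B={self.B}]")
        norm = {}
        for (f, g), n in self.cooc.items():
            if f == g:
                raise ValueError(f"self co-occurrence for {f}")
            a, b = sorted((f, g))
            if n > min(self.occ.get(a, 0), self.occ.get(b, 0)):
                raise ValueError(
                    f"cooc[{a},{b}] = {n} exceeds min(occ) = "
                    f"{min(self.occ.get(a, 0), self.occ.get(b, 0))}"
                )
            norm[(a, b)] = int(n)
        self.cooc = norm
        if not self.rank_order:
            self.rank_order = rank_features(self)

    def total_cooc(self, f: str) -> int:
        return sum(n for (a, b), n in self.cooc.items() if f in (a, b))

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialization: occ rows then cooc rows."""
        rows = [
            {"kind": "occ", "feature": f, "partner": "", "count": int(n), "B": self.B}
            for f, n in sorted(self.occ.items())
        ]
        rows += [
            {"kind": "cooc", "feature": a, "partner": b, "count": n, "B": self.B}
            for (a, b), n in sorted(self.cooc.items())
        ]
        return pd.DataFrame(rows, columns=["kind", "feature", "partner", "count", "B"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BootstrapRanking":
        B = int(df["B"].iloc[0]) if len(df) else 0
        occ = {
            str(r.feature): int(r.count)
            for r in df[df["kind"] == "occ"].itertuples()
        }
        cooc = {
            (str(r.feature), str(r.partner)): int(r.count)
            for r in df[df["kind"] == "cooc"].itertuples()
        }
        return cls(B=B, occ=occ, cooc=cooc)


def stratified_bootstrap(
    labels: dict[str, str] | pd.Series, B: int, seed: int
) -> list[list[str]]:
    """Draw B within-class bootstrap resamples of the labeled samples.

    Each replicate draws ``n_case`` ids with replacement from the cases
    and ``n_control`` from the controls, preserving the class proportion
    exactly.  Deterministic under ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels = pd.Series(labels)
    cases = [s for s, l in labels.items() if l == "case"]
    controls = [s for s, l in labels.items() if l == "control"]
    if not cases or not controls:
        raise ValueError("both classes must be present for stratified bootstrap")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(B):
        ci = rng.integers(0, len(cases), size=len(cases))
        ki = rng.integers(0, len(controls), size=len(controls))
        reps.append([cases[i] for i in ci] + [controls[i] for i in ki])
    return reps


def default_selectors(profile: str = "full") -> dict[str, Callable]:
    """Named selector callables sharing the (X, labels, seed) signature.

    ``profile="full"`` uses each algorithm's own tuning defaults;
    ``profile="fast"`` fixes light hyperparameters suitable for running
    thousands of bootstrap replicates on one CPU.
    """
    if profile == "full":
        return {
            "nsc": lambda X, labels, seed: nsc_select(X, labels, seed=seed),
            "boruta": lambda X, labels, seed: boruta_rf_select(X, labels, seed=seed),
            "scadsvm": lambda X, labels, seed: elastic_scad_svm_select(X, labels, seed=seed),
        }
    if profile == "fast":
        return {
            "nsc": lambda X, labels, seed: nsc_select(
                X, labels, delta_grid=np.linspace(0.0, 4.0, 9), cv_folds=3, seed=seed
            ),
            "boruta": lambda X, labels, seed: boruta_rf_select(
                X, labels, max_iter=12, seed=seed, n_estimators=10, alpha=0.3
            ),
            "scadsvm": lambda X, labels, seed: elastic_scad_svm_select(
                X,
                labels,
                lambda1_grid=[0.25],
                lambda2_grid=[0.5],
                seed=seed,
                tol=1e-3,
                max_outer=4,
                lbfgs_iter=50,
            ),
        }
    raise ValueError(f"unknown selector profile {profile!r}")


def _resample_matrix(X, sample_ids: Sequence[str]):
    """Column-resample an expression-like matrix, allowing repeats."""
    col = {s: i for i, s in enumerate(X.sample_ids)}
    idx = [col[s] for s in sample_ids]
    # repeated draws need unique column ids for the selector plumbing
    new_ids = [f"{s}#{k}" for k, s in enumerate(sample_ids)]

    class _View:
        feature_ids = list(X.feature_ids)
        sample_ids = new_ids
        values = X.values[:, idx]

    return _View()


def run_bootstrap_selection(
    X,
    labels: dict[str, str] | pd.Series,
    B: int,
    seed: int,
    selectors: dict[str, Callable] | None = None,
    max_failure_frac: float = 0.10,
    keep_masks: bool = False,
) -> BootstrapRanking:
    """Run all three selectors on B stratified bootstrap replicates.

    Per replicate the joint mask is the intersection of the three
    selected sets; occurrence and co-occurrence counts accumulate over
    replicates.  A replicate where any selector raises is re-drawn with a
    fresh sub-seed (count logged in the result); more than 10 % failures
    aborts.  Sub-seeds are derived from the master seed and replicate
    index, so results do not depend on execution order.
    """
    labels = pd.Series(labels)
    if selectors is None:
        selectors = default_selectors("fast")
    features = list(X.feature_ids)
    occ = dict.fromkeys(features, 0)
    cooc: dict[tuple[str, str], int] = {}
    masks = [] if keep_masks else None
    replicates = stratified_bootstrap(labels, B, seed)
    max_failures = int(np.ceil(max_failure_frac * B))
    n_failures = 0
    for r, rep_ids in enumerate(replicates):
        attempt = 0
        while True:
            sub_seed = int(np.random.default_rng((seed, r, attempt)).integers(2**31 - 1))
            if attempt > 0:
                rep_ids = stratified_bootstrap(labels, 1, sub_seed)[0]
            Xr = _resample_matrix(X, rep_ids)
            rep_labels = {f"{s}#{k}": labels[s] for k, s in enumerate(rep_ids)}
            try:
                joint: set[str] | None = None
                for fn in selectors.values():
                    res: SelectorResult = fn(Xr, rep_labels, sub_seed)
                    joint = res.selected if joint is None else (joint & res.selected)
                joint = joint or set()
                break
            except Exception:
                n_failures += 1
                attempt += 1
                if n_failures > max_failures:
                    raise RuntimeError(
                        f"more than {max_failure_frac:.0%} of bootstrap replicates "
                        f"failed ({n_failures} failures by replicate {r})"
                    )
        for f in joint:
            occ[f] += 1
        sel = sorted(joint)
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                key = (sel[i], sel[j])
                cooc[key] = cooc.get(key, 0) + 1
        if masks is not None:
            masks.append({f: (f in joint) for f in features})
    ranking = BootstrapRanking(
        B=B,
        occ=occ,
        cooc=cooc,
        per_replicate_masks=pd.DataFrame(masks) if masks is not None else None,
    )
    return ranking


def rank_features(ranking: BootstrapRanking) -> list[str]:
    """Order features by descending occurrence; drop zero-occurrence ones.

    Ties break by descending total co-occurrence with all other features,
    then lexicographic id.
    """
    feats = [f for f, n in ranking.occ.items() if n > 0]
    return sorted(feats, key=lambda f: (-ranking.occ[f], -ranking.total_cooc(f), f))


def export_cooccurrence_graph(
    ranking: BootstrapRanking, min_cooc: int = 300, path: str | None = None
) -> nx.Graph:
    """Build (and optionally write) the co-occurrence network.

    Edges with co-occurrence below ``min_cooc`` are removed; nodes are
    the features incident to at least one surviving edge, attributed with
    their occurrence counts.  Written as GraphML when ``path`` is given.
    """
    G = nx.Graph()
    for (a, b), n in sorted(ranking.cooc.items()):
        if n >= min_cooc:
            G.add_edge(a, b, cooc=int(n))
    for node in G.nodes:
        G.nodes[node]["occ"] = int(ranking.occ.get(node, 0))
    if path is not None:
        nx.write_graphml(G, path)
    return G
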