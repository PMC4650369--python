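"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generates feature-by-sample log2 expression with: mean-shifted features
(up in cases), equal-mean features differing only in shape (case-only
variance inflation or a two-component mixture) that only an omnibus test
can flag, a correlated block sharing a latent factor, intensity-dependent
detection dropout, class-conditional hemolysis scores, and a covariate
pool imbalanced before matching.  Everything is deterministic under the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleTable
from .io import label_samples

__all__ = ["SimSpec", "generate_cohort", "generate_matching_pool", "default_sim_spec"]


@dataclass
class SimSpec:
    """Parameters of one synthetic cohort.

    ``de_mean_set`` features get a log2 shift of ``delta`` in cases;
    ``de_shape_set`` features keep equal means but either inflate the
    case variance by ``rho`` or replace a ``pi_mix`` fraction of case
    values with a mean-centered two-component mixture of gap ``gamma``;
    ``block_set`` features share a per-sample latent normal factor with
    loading ``r``.
    """

    n_features: int = 50
    n_case: int = 13
    n_control: int = 26
    de_mean_set: tuple[int, ...] = ()
    de_shape_set: tuple[int, ...] = ()
    block_set: tuple[int, ...] = ()
    delta: float = 1.5
    rho: float = 1.0  # case variance inflation factor (SD ratio = sqrt applied below)
    pi_mix: float = 0.0
    gamma: float = 0.0
    r: float = 0.6
    baseline_mu: np.ndarray | float = 8.0
    baseline_sd: np.ndarray | float = 0.8
    dropout_midpoint: float = 2.0
    dropout_slope: float = 2.0
    hs_mu_case: float = 0.30
    hs_mu_control: float = 0.03
    hs_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.de_mean_set) & set(self.de_shape_set):
            raise ValueError("de_mean_set and de_shape_set must be disjoint")
        for name in ("de_mean_set", "de_shape_set", "block_set"):
            idx = getattr(self, name)
            if any(i < 0 or i >= self.n_features for i in idx):
                raise ValueError(f"{name} contains out-of-range feature indices")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not 0 <= self.pi_mix <= 1:
            raise ValueError("pi_mix must lie in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per class")


def default_sim_spec(seed: int = 0) -> SimSpec:
    """Default hemolysis-like scenario.

    Four strongly up-regulated features in one correlated block plus a
    fifth, weaker one (outside the block) — mirroring the geometry of a
    co-regulated marker set with one subtler companion — at 13 vs 26
    samples and 50 features.
    """
    return SimSpec(
        n_features=50,
        n_case=13,
        n_control=26,
        de_mean_set=(0, 1, 2, 3, 4),
        de_shape_set=(5, 6),
        block_set=(0, 1, 2, 3),
        delta=2.5,
        rho=9.0,
        seed=seed,
    )


def generate_cohort(spec: SimSpec) -> tuple[ExpressionMatrix, SampleTable]:
    """Draw one synthetic cohort (expression matrix + sample table).

    Per feature f and sample s the log2 value is::

        mu[f] + r * Z[s] * 1[f in block] + delta * 1[case, f in de_mean]
              + shape(f, s) + noise(sd[f])

    where shape(f, s) applies only to cases of de_shape features: either
    noise SD inflation by sqrt(rho) (variance ratio rho) or a
    mean-centered +/- gamma mixture with weight pi_mix.  Detection flags
    follow a logistic curve in the expressed intensity; hemolysis scores
    are class-conditional normals clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    p = spec.n_features
    mu = np.broadcast_to(np.asarray(spec.baseline_mu, dtype=float), (p,)).copy()
    sd = np.broadcast_to(np.asarray(spec.baseline_sd, dtype=float), (p,)).copy()

    is_case = np.zeros(n, dtype=bool)
    is_case[: spec.n_case] = True

    V = mu[:, None] + rng.normal(size=(p, n)) * sd[:, None]
    if spec.block_set:
        Z = rng.normal(size=n)
        for f in spec.block_set:
            V[f] += spec.r * Z
    for f in spec.de_mean_set:
        V[f, is_case] += spec.delta
    for f in spec.de_shape_set:
        if spec.pi_mix > 0 and spec.gamma > 0:
            # two-component contamination, mean-centered so the class
            # means stay equal: +gamma with prob pi_mix, shifted back
            comp = rng.random(spec.n_case) < spec.pi_mix
            shift = np.where(comp, spec.gamma, 0.0) - spec.pi_mix * spec.gamma
            V[f, is_case] += shift
        elif spec.rho != 1.0:
            # variance inflation: redraw case noise at SD * sqrt(rho)
            extra = rng.normal(size=spec.n_case) * sd[f] * np.sqrt(spec.rho - 1.0)
            V[f, is_case] += extra

    # intensity-dependent dropout: P(detected) = logistic(slope * (x - mid))
    z = spec.dropout_slope * (V - spec.dropout_midpoint)
    pdet = 1.0 / (1.0 + np.exp(-z))
    detected = rng.random(size=(p, n)) < pdet

    hs = np.where(
        is_case,
        rng.normal(spec.hs_mu_case, spec.hs_sd, size=n),
        rng.normal(spec.hs_mu_control, spec.hs_sd, size=n),
    )
    hs = np.clip(hs, 0.0, None)

    feature_ids = [f"mir{f:03d}" for f in range(p)]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    X = ExpressionMatrix(feature_ids, sample_ids, V, detected, scale_tag="log2")

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "hs": hs,
            "disease_status": rng.integers(0, 2, size=n),
            "age_at_drawing": np.round(rng.normal(55, 8, size=n), 1),
            "drawing_year": rng.integers(1995, 2001, size=n),
            "label": np.where(is_case, "case", "control"),
        }
    )
    return X, SampleTable(meta)


def generate_matching_pool(
    n_cases: int,
    n_controls_pool: int,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
    hs_low: float = 0.057,
    hs_high: float = 0.14,
) -> SampleTable:
    """Covariate pool with class-dependent shifts, imbalanced pre-matching.

    ``covariate_effects`` gives additive case shifts for
    ``age_at_drawing`` and ``drawing_year`` and a log-odds shift for
    ``disease_status``; zero effects produce a balanced pool.  Hemolysis
    scores are drawn so labels reproduce the requested case/control
    split.  Warns when the pool cannot support 1:2 matching.
    """
    import warnings

    if n_controls_pool < 2 * n_cases:
        warnings.warn(
            f"control pool ({n_controls_pool}) below 2x cases ({n_cases}); "
            "some cases will stay unmatched",
            stacklevel=2,
        )
    effects = {"age_at_drawing": 0.0, "drawing_year": 0.0, "disease_status": 0.0}
    effects.update(covariate_effects or {})
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls_pool
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True

    age = rng.normal(55, 8, size=n) + effects["age_at_drawing"] * is_case
    year = rng.integers(1995, 2001, size=n) + np.where(
        is_case, np.round(effects["drawing_year"]).astype(int), 0
    )
    logodds = -0.5 + effects["disease_status"] * is_case
    disease = (rng.random(n) < 1.0 / (1.0 + np.exp(-logodds))).astype(int)

    hs = np.where(
        is_case,
        hs_high + np.abs(rng.normal(0.15, 0.05, size=n)),
        np.clip(rng.normal(0.03, 0.015, size=n), 0.0, hs_low),
    )
    meta = pd.DataFrame(
        {
            "sample_id": [f"P{i:04d}" for i in range(n)],
            "hs": hs,
            "disease_status": disease,
            "age_at_drawing": np.round(age, 1),
            "drawing_year": year,
        }
    )
    return label_samples(SampleTable(meta), hs_low=hs_low, hs_high=hs_high)
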