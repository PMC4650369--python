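import numpy as np
import pandas as pd
import pytest

from plasmaselect.datamodel import SampleTable
from plasmaselect.matching import (
    MatchResult,
    caliper_width,
    covariate_balance,
    fit_propensity,
    match_1to2,
    split_train_validation,
)
from plasmaselect.simulate import generate_matching_pool


def _table(labels, disease=None, age=None, year=None):
    n = len(labels)
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i:03d}" for i in range(n)],
                "hs": [0.2 if l == "case" else 0.01 for l in labels],
                "disease_status": disease if disease is not None else ["x"] * n,
                "age_at_drawing": age if age is not None else [50.0] * n,
                "drawing_year": year if year is not None else [1999] * n,
                "label": labels,
            }
        )
    )


def _logit(p):
    return np.log(p / (1 - p))


class TestFitPropensity:
    def test_intercept_only_gives_prevalence(self):
        t = _table(["case"] * 10 + ["control"] * 30)
        ps = fit_propensity(t)
        np.testing.assert_allclose(ps.values, 0.25, atol=1e-6)

    def test_balanced_binary_covariate_gives_half(self):
        labels = ["case"] * 20 + ["control"] * 20
        disease = (["a"] * 10 + ["b"] * 10) * 2
        ps = fit_propensity(_table(labels, disease=disease))
        np.testing.assert_allclose(ps.values, 0.5, atol=1e-6)

    def test_coefficient_recovery(self):
        # logistic model with known coefficients, n = 600
        rng = np.random.default_rng(99)
        n = 600
        age = rng.normal(55, 8, size=n)
        year = rng.integers(1995, 2001, size=n)
        beta_age, beta_year = 0.08, -0.3
        eta = beta_age * (age - 55) + beta_year * (year - 1997.5) - 0.7
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        t = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(n)],
                    "hs": np.where(y, 0.2, 0.01),
                    "disease_status": ["x"] * n,
                    "age_at_drawing": age,
                    "drawing_year": year,
                    "label": np.where(y, "case", "control"),
                }
            )
        )
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([age, year]))
        fit = sm.Logit(y.astype(float), X).fit(disp=0)
        se_age, se_year = fit.bse[1], fit.bse[2]
        assert abs(fit.params[1] - beta_age) < 3 * se_age
        assert abs(fit.params[2] - beta_year) < 3 * se_year
        # package propensities agree with the reference fit
        ps = fit_propensity(t)
        np.testing.assert_allclose(ps.values, fit.predict(X), atol=1e-6)

    def test_separation_raises(self):
        labels = ["case"] * 10 + ["control"] * 10
        age = [80.0] * 10 + [30.0] * 10
        with pytest.raises(ValueError, match="separation"):
            fit_propensity(_table(labels, age=age))

    def test_needs_both_classes(self):
        with pytest.raises(ValueError, match="case"):
            fit_propensity(_table(["control"] * 5))


class TestCaliperWidth:
    def test_definition_sd_one(self):
        # construct ps whose logits have SD exactly 1.0
        logits = np.array([-1.0, 1.0, -1.0, 1.0, 0.0, 0.0, np.sqrt(1.5), -np.sqrt(1.5)])
        logits = logits / np.std(logits, ddof=1)
        ps = 1 / (1 + np.exp(-logits))
        assert caliper_width(ps, 0.2) == pytest.approx(0.2, abs=1e-12)

    def test_constant_ps_errors(self):
        with pytest.raises(ValueError, match="no matching"):
            caliper_width(np.full(10, 0.3))

    def test_formula_oracle(self, rng):
        ps = rng.uniform(0.05, 0.95, size=50)
        expected = 0.2 * np.std(np.log(ps / (1 - ps)), ddof=1)
        assert caliper_width(ps, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_ps(self):
        with pytest.raises(ValueError, match="strictly"):
            caliper_width(np.array([0.0, 0.5]))


class TestMatch1to2:
    def test_full_cohort_size_26_cases(self):
        # 26 matchable cases with abundant in-caliper controls -> 78 samples
        rng = np.random.default_rng(5)
        cases = [f"C{i:02d}" for i in range(26)]
        controls = [f"K{i:03d}" for i in range(200)]
        ps = pd.Series(
            np.concatenate([rng.uniform(0.4, 0.6, 26), rng.uniform(0.35, 0.65, 200)]),
            index=cases + controls,
        )
        res = match_1to2(cases, controls, ps, caliper=2.0)
        assert len(res.triplets) == 26
        assert res.n_matched_samples == 78
        assert res.unmatched_cases == []

    def test_single_triplet(self):
        ps = pd.Series({"c": 0.5, "k1": 0.52, "k2": 0.48})
        res = match_1to2(["c"], ["k1", "k2"], ps, caliper=1.0)
        assert res.triplets == [("c", "k2", "k1")] or res.triplets == [("c", "k1", "k2")]

    def test_case_without_two_controls_unmatched(self):
        ps = pd.Series({"c": 0.5, "k1": 0.51, "k2": 0.99})
        res = match_1to2(["c"], ["k1", "k2"], ps, caliper=0.1)
        assert res.triplets == []
        assert res.unmatched_cases == ["c"]

    def test_greedy_equals_bruteforce_on_enumerable_instance(self):
        # 3 cases, 6 controls with hand-set propensities; replicate the
        # documented greedy rule independently and compare
        ps = pd.Series(
            {
                "c1": 0.30,
                "c2": 0.50,
                "c3": 0.70,
                "k1": 0.28,
                "k2": 0.33,
                "k3": 0.48,
                "k4": 0.52,
                "k5": 0.68,
                "k6": 0.72,
            }
        )
        cases, controls = ["c1", "c2", "c3"], ["k1", "k2", "k3", "k4", "k5", "k6"]
        caliper = 1.0
        res = match_1to2(cases, controls, ps, caliper)

        # independent oracle: explicit greedy over the documented order
        lp = {s: _logit(ps[s]) for s in ps.index}
        center = np.mean([lp[s] for s in cases + controls])
        order = sorted(cases, key=lambda c: (-abs(lp[c] - center), c))
        avail = set(controls)
        expected = {}
        for c in order:
            inside = sorted(
                (k for k in avail if abs(lp[k] - lp[c]) <= caliper),
                key=lambda k: (abs(lp[k] - lp[c]), k),
            )
            took = inside[:2]
            avail -= set(took)
            expected[c] = set(took)
        got = {t[0]: {t[1], t[2]} for t in res.triplets}
        assert got == expected

    def test_no_control_reuse_and_caliper_holds(self):
        rng = np.random.default_rng(11)
        cases = [f"C{i}" for i in range(10)]
        controls = [f"K{i}" for i in range(40)]
        ps = pd.Series(
            rng.uniform(0.2, 0.8, size=50), index=cases + controls
        )
        caliper = caliper_width(ps, 0.2)
        res = match_1to2(cases, controls, ps, caliper)
        used = [c for t in res.triplets for c in t[1:]]
        assert len(used) == len(set(used))
        for case, k1, k2 in res.triplets:
            for k in (k1, k2):
                assert abs(_logit(ps[case]) - _logit(ps[k])) <= caliper + 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(21)
        cases = [f"C{i}" for i in range(8)]
        controls = [f"K{i}" for i in range(30)]
        ps = pd.Series(rng.uniform(0.3, 0.7, 38), index=cases + controls)
        res1 = match_1to2(cases, controls, ps, 0.5)
        res2 = match_1to2(cases[::-1], controls[::-1], ps, 0.5)
        assert res1.triplets == res2.triplets

    def test_control_reuse_rejected_by_datamodel(self):
        with pytest.raises(ValueError, match="more than one"):
            MatchResult(
                triplets=[("c1", "k1", "k2"), ("c2", "k1", "k3")],
                unmatched_cases=[],
                ps={},
                caliper=0.1,
            )


class TestSplitTrainValidation:
    def _matched(self, n_triplets):
        triplets = [(f"C{i}", f"K{2*i}", f"K{2*i+1}") for i in range(n_triplets)]
        ids = [s for t in triplets for s in t]
        ps = {s: 0.5 for s in ids}
        return MatchResult(triplets, [], ps, 0.2), ids

    def _table_for(self, ids):
        labels = ["case" if s.startswith("C") else "control" for s in ids]
        return _table_with_ids(ids, labels)

    def test_26_triplets_give_39_per_set(self):
        matched, ids = self._matched(26)
        table = self._table_for(ids)
        out = split_train_validation(matched, table, seed=0)
        for split in ("training", "validation"):
            sub = out.data[out.data["split"] == split]
            assert len(sub) == 39
            assert (sub["label"] == "case").sum() == 13
            assert (sub["label"] == "control").sum() == 26

    def test_two_triplets_split_one_one(self):
        matched, ids = self._matched(2)
        out = split_train_validation(matched, self._table_for(ids), seed=1)
        assert (out.data["split"] == "training").sum() == 3
        assert (out.data["split"] == "validation").sum() == 3

    def test_odd_count_warns_extra_to_training(self):
        matched, ids = self._matched(3)
        with pytest.warns(UserWarning, match="odd"):
            out = split_train_validation(matched, self._table_for(ids), seed=0)
        assert (out.data["split"] == "training").sum() == 6
        assert (out.data["split"] == "validation").sum() == 3

    def test_seed_determinism(self):
        matched, ids = self._matched(8)
        t = self._table_for(ids)
        a = split_train_validation(matched, t, seed=7).data["split"].tolist()
        b = split_train_validation(matched, t, seed=7).data["split"].tolist()
        c = split_train_validation(matched, t, seed=8).data["split"].tolist()
        assert a == b
        assert any(a != c for a, c in [(a, c)])  # generally different

    def test_triplets_stay_together(self):
        matched, ids = self._matched(10)
        out = split_train_validation(matched, self._table_for(ids), seed=3)
        split_of = dict(zip(out.data["sample_id"], out.data["split"]))
        for case, k1, k2 in matched.triplets:
            assert split_of[case] == split_of[k1] == split_of[k2]


def _table_with_ids(ids, labels):
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "hs": [0.2 if l == "case" else 0.01 for l in labels],
                "disease_status": ["x"] * len(ids),
                "age_at_drawing": [50.0] * len(ids),
                "drawing_year": [1999] * len(ids),
                "label": labels,
            }
        )
    )


class TestBalance:
    def test_matching_improves_age_balance(self):
        improved = 0
        for seed in range(20):
            pool = generate_matching_pool(
                15, 150, {"age_at_drawing": 5.0}, seed=seed
            )
            ps = fit_propensity(pool)
            cal = caliper_width(ps, 0.2)
            res = match_1to2(
                pool.ids_with_label("case"), pool.ids_with_label("control"), ps, cal
            )
            bal = covariate_balance(pool, res).set_index(["covariate", "stage"])["smd"]
            if abs(bal[("age_at_drawing", "after")]) < abs(bal[("age_at_drawing", "before")]):
                improved += 1
        assert improved >= 15  # balance improves in the large majority of runs
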