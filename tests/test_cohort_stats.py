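import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats
from scipy.special import expit

from kinesym.cohort_stats import (
    derive_success,
    fit_logistic,
    kruskal_wallis,
    lid_presence_classify,
    pair_nearest_assessment,
    purposeful_selection,
    roc_youden,
    success_criteria,
)


def brute_force_roc(scores, outcome):
    """Exhaustive oracle: J over every candidate cutpoint, AUC by explicit
    pair counting (ties half)."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    pos, neg = scores[outcome == 1], scores[outcome == 0]
    pairs = 0.0
    for p in pos:
        for q in neg:
            pairs += 1.0 if p > q else (0.5 if p == q else 0.0)
    auc = pairs / (len(pos) * len(neg))
    best_j, best_t = -np.inf, None
    for t in sorted(set(scores)) + [np.inf]:
        j = np.mean(pos >= t) + np.mean(neg < t) - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return auc, best_j, best_t


class TestLidPresence:
    def test_rule_arithmetic(self):
        res = lid_presence_classify({"P1": 3.5}, [1.0, 2.0, 3.0])
        assert res.threshold == pytest.approx(3.0)
        assert res.labels["P1"] is True

    def test_override_flips_with_reason(self):
        res = lid_presence_classify(
            {"P1": 2.9}, [1.0, 2.0, 3.0],
            overrides={"P1": (True, "video shows chorea")},
        )
        assert res.labels["P1"] is True
        assert res.overridden["P1"] == "video shows chorea"

    def test_no_controls_fatal(self):
        with pytest.raises(ValueError, match="control"):
            lid_presence_classify({"P1": 1.0}, [2.0])

    def test_gaussian_tail_operating_point(self):
        # threshold mu+sigma: sensitivity Phi(2) = 97.7%, specificity
        # Phi(1) = 84.1% for patients shifted by 3 sigma
        rng = np.random.default_rng(42)
        controls = rng.normal(10.0, 2.0, 1000)
        patients = rng.normal(16.0, 2.0, 1000)
        stats = {f"C{i}": v for i, v in enumerate(controls)}
        stats.update({f"P{i}": v for i, v in enumerate(patients)})
        truth = {k: k.startswith("P") for k in stats}
        res = lid_presence_classify(stats, controls, truth=truth)
        sens = res.confusion["tp"] / (res.confusion["tp"] + res.confusion["fn"])
        spec = res.confusion["tn"] / (res.confusion["tn"] + res.confusion["fp"])
        assert sens == pytest.approx(0.977, abs=0.03)
        assert spec == pytest.approx(0.841, abs=0.03)


class TestSuccessCriteria:
    def make_cohort(self, control_times, patient_rows):
        rows = [
            {"participant_id": f"C{i}", "group": "control", "task_id": "A",
             "time_s": t, "error_count": 0}
            for i, t in enumerate(control_times)
        ]
        rows += patient_rows
        return pd.DataFrame(rows)

    def test_time_threshold(self):
        cohort = self.make_cohort(
            [8.0, 10.0, 12.0],  # mean 10, sd 2
            [{"participant_id": "P1", "group": "patient", "task_id": "A",
              "time_s": 13.9, "error_count": 0}],
        )
        out = derive_success(cohort)
        assert success_criteria(cohort)["A"].time_threshold == pytest.approx(14.0)
        assert bool(out[out.participant_id == "P1"]["success"].iloc[0]) is True

    def test_time_over_threshold_fails(self):
        cohort = self.make_cohort(
            [8.0, 10.0, 12.0],
            [{"participant_id": "P1", "group": "patient", "task_id": "A",
              "time_s": 14.1, "error_count": 0}],
        )
        out = derive_success(cohort)
        assert bool(out[out.participant_id == "P1"]["success"].iloc[0]) is False

    def test_degenerate_error_sd(self):
        cohort = self.make_cohort(
            [8.0, 10.0, 12.0],
            [{"participant_id": "P1", "group": "patient", "task_id": "A",
              "time_s": 9.0, "error_count": 1}],
        )
        crit = success_criteria(cohort)["A"]
        assert crit.error_threshold == 0.0
        assert crit.degenerate_error_sd
        out = derive_success(cohort)
        assert bool(out[out.participant_id == "P1"]["success"].iloc[0]) is False

    def test_single_control_task_skipped(self):
        cohort = pd.DataFrame([
            {"participant_id": "C1", "group": "control", "task_id": "B",
             "time_s": 5.0, "error_count": 0},
            {"participant_id": "P1", "group": "patient", "task_id": "B",
             "time_s": 5.0, "error_count": 0},
        ])
        with pytest.warns(UserWarning, match="fewer than 2"):
            crit = success_criteria(cohort)
        assert "B" not in crit

    def test_threshold_monotone_in_slow_controls(self, rng):
        base = list(rng.normal(10, 2, 20))
        t0 = None
        for extra in (14.0, 18.0, 25.0):
            cohort = self.make_cohort(base + [extra], [])
            thr = success_criteria(cohort)["A"].time_threshold
            if t0 is not None:
                assert thr >= t0
            t0 = thr


class TestKruskalWallis:
    def test_two_group_example(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups(self):
        h, p = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert h == 0.0 and p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 4))
            groups = [rng.integers(0, 8, int(rng.integers(3, 15))).astype(float)
                      for _ in range(k)]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            h, p = kruskal_wallis(*groups)
            ref = spstats.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestLogistic:
    def test_null_predictor_small_coefficient(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        y = rng.integers(0, 2, 1000).astype(float)
        fit = fit_logistic(y, x)
        assert abs(fit.params[1]) < 0.2
        assert fit.pvalues[1] > 0.01

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = (rng.uniform(size=2000) < expit(-1.0 + 2.0 * x)).astype(float)
        fit = fit_logistic(y, x)
        assert abs(fit.params[0] - (-1.0)) < 3 * fit.se[0]
        assert abs(fit.params[1] - 2.0) < 3 * fit.se[1]

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        y = (rng.uniform(size=300) < expit(0.5 + X[:, 0] - 0.5 * X[:, 1])).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = (x > 3.5).astype(float)
        fit = fit_logistic(y, x)
        assert fit.separation


class TestPurposefulSelection:
    def test_single_strong_predictor_retained(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = (rng.uniform(size=300) < expit(1.5 * x)).astype(float)
        sel = purposeful_selection(y, pd.DataFrame({"x": x}))
        assert sel.retained_names == ["x"]
        assert sel.retained[0].pvalue < 0.05

    def test_all_null_intercept_only(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 400).astype(float)
        sel = purposeful_selection(y, X)
        assert sel.retained == []
        assert len(sel.dropped) == 3

    def test_confounder_retained_when_estimate_shifts(self):
        # x2 is a cause of both x1 and the outcome-generating signal, so
        # removing it shifts the x1 coefficient substantially
        rng = np.random.default_rng(8)
        n = 600
        x2 = rng.normal(size=n)
        x1 = 0.7 * x2 + np.sqrt(1 - 0.49) * rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(1.0 * x1 + 0.35 * x2)).astype(float)
        sel = purposeful_selection(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert "x1" in sel.retained_names

    def test_backward_elimination_limit(self):
        # alpha_enter=1 admits everything; infinite confounding tolerance
        # reduces the procedure to plain backward elimination
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        y = (rng.uniform(size=500) < expit(1.2 * X["a"])).astype(float)
        sel = purposeful_selection(y, X, alpha_enter=1.0, confound_pct=np.inf)
        assert "a" in sel.retained_names
        assert not any(r.confounder for r in sel.retained)


class TestRocYouden:
    def test_perfect_separation(self):
        roc = roc_youden(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert roc.auc == 1.0
        assert roc.youden_j == 1.0
        assert 0.2 < roc.cutpoint <= 0.8

    def test_one_class_fatal(self):
        with pytest.raises(ValueError, match="classes"):
            roc_youden(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_equals_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            outcome = rng.integers(0, 2, n)
            if outcome.min() == outcome.max():
                continue
            roc = roc_youden(scores, outcome)
            auc, j, t = brute_force_roc(scores, outcome)
            assert roc.auc == pytest.approx(auc, abs=1e-12)
            assert roc.youden_j == pytest.approx(j, abs=1e-12)
            assert roc.cutpoint == pytest.approx(t)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=200)
        outcome = rng.integers(0, 2, 200)
        a = roc_youden(scores, outcome).auc
        b = roc_youden(np.exp(scores), outcome).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_sub_half_auc_allowed_as_is(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 100), rng.normal(0, 1, 100)])
        outcome = np.concatenate([np.zeros(100), np.ones(100)])
        roc = roc_youden(scores, outcome, direction="as-is")
        assert roc.auc < 0.5
        auto = roc_youden(scores, outcome, direction="auto")
        assert auto.flipped
        assert auto.auc > 0.5


class TestPairing:
    def test_nearest(self):
        assert pair_nearest_assessment(18.0, [0.0, 20.0, 40.0]) == 20.0

    def test_gap_exceeded_missing(self):
        assert pair_nearest_assessment(55.0, [0.0, 20.0, 40.0], max_gap_s=10.0) is None

    def test_tie_prefers_earlier(self):
        assert pair_nearest_assessment(10.0, [0.0, 20.0]) == 0.0

    def test_values_returned(self):
        v = pair_nearest_assessment(18.0, [0.0, 20.0], values=np.array(["a", "b"]))
        assert v == "b"

    def test_empty(self):
        assert pair_nearest_assessment(1.0, []) is None
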