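import numpy as np
import pandas as pd
import pytest

from esometh.evaluation import (
    ConfusionSummary,
    assign_risk_levels,
    confusion_summary,
    cox_table,
    km_logrank,
    micro_average_auc,
    risk_stratify,
    round2,
    time_dependent_auc,
)
from esometh.exceptions import ValidationError

CLASS_LABELS = ["NSE", "BE", "EAC", "ESCC"]


def counts_frame(rows):
    return pd.DataFrame(rows, index=CLASS_LABELS, columns=CLASS_LABELS)


# Worked-example 4x4 confusion layouts (hypothesized x true); per-class
# accuracy is diagonal over column total.
TRAINING_COUNTS = counts_frame(
    [[90, 2, 3, 1], [2, 64, 4, 0], [3, 3, 143, 2], [1, 0, 2, 57]]
)
TEST_COUNTS = counts_frame(
    [[45, 2, 1, 0], [1, 29, 2, 0], [1, 3, 71, 1], [0, 0, 2, 29]]
)
VALIDATION_COUNTS = counts_frame(
    [[60, 4, 0, 0], [4, 59, 1, 1], [1, 6, 22, 7], [1, 0, 0, 18]]
)


class TestConfusionSummary:
    @pytest.mark.parametrize(
        "counts,overall,per_class",
        [
            (TRAINING_COUNTS, 93.90, [93.75, 92.75, 94.08, 95.00]),
            (TEST_COUNTS, 93.05, [95.74, 85.29, 93.42, 96.67]),
            (VALIDATION_COUNTS, 86.41, [90.91, 85.51, 95.65, 69.23]),
        ],
    )
    def test_worked_examples_from_printed_tables(self, counts, overall, per_class):
        cs = ConfusionSummary.from_counts(counts)
        assert cs.overall_accuracy == overall
        assert cs.per_class_accuracy.tolist() == per_class

    def test_identity_predictions_are_perfect(self):
        labels = ["a"] * 5 + ["b"] * 5
        cs = confusion_summary(labels, labels, labels=["a", "b"])
        assert cs.overall_accuracy == 100.0
        assert cs.ci[1] == 100.0
        assert (cs.per_class_accuracy == 100.0).all()

    def test_overall_is_weighted_mean_of_per_class(self):
        cs = ConfusionSummary.from_counts(TRAINING_COUNTS)
        col_tot = cs.counts.sum(axis=0)
        diag = np.diag(cs.counts.to_numpy())
        weighted = 100.0 * diag.sum() / col_tot.sum()
        assert cs.overall_accuracy == round2(weighted)

    def test_ci_contains_point_estimate_and_shrinks(self):
        small = ConfusionSummary.from_counts(counts_frame(np.eye(4, dtype=int) * 3 + 1))
        big = ConfusionSummary.from_counts(counts_frame(np.eye(4, dtype=int) * 300 + 100))
        for cs in (small, big):
            assert cs.ci[0] <= cs.overall_accuracy <= cs.ci[1]
        assert (big.ci[1] - big.ci[0]) < (small.ci[1] - small.ci[0])

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValidationError):
            confusion_summary(["a", "x"], ["a", "a"], labels=["a", "b"])


def oracle_pooled_auc(y, s):
    """Exhaustive concordant-pair count over pooled binary instances."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMicroAverageAUC:
    def test_perfect_probabilities(self):
        labels = ["a", "b", "c", "a"]
        probs = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]],
            columns=["a", "b", "c"],
            dtype=float,
        )
        assert micro_average_auc(labels, probs).auc == 1.0

    def test_uniform_probabilities_are_chance(self):
        labels = ["a", "b"] * 10
        probs = pd.DataFrame(np.full((20, 2), 0.5), columns=["a", "b"])
        assert micro_average_auc(labels, probs).auc == pytest.approx(0.5)

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(["a", "b", "c"], 8)
        if len(set(labels)) < 2:
            labels[0] = "a" if labels[0] != "a" else "b"
        raw = rng.random((8, 3))
        probs = pd.DataFrame(raw / raw.sum(1, keepdims=True), columns=["a", "b", "c"])
        res = micro_average_auc(labels, probs)
        indicator = np.array(
            [[1 if lab == c else 0 for c in probs.columns] for lab in labels]
        ).ravel()
        assert res.auc == pytest.approx(
            oracle_pooled_auc(indicator, probs.to_numpy().ravel()), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["a", "b"], 30)
        labels[:2] = ["a", "b"]
        raw = rng.random((30, 2))
        probs = pd.DataFrame(raw / raw.sum(1, keepdims=True), columns=["a", "b"])
        a1 = micro_average_auc(labels, probs).auc
        # strictly monotone transform applied uniformly; renormalized rows no
        # longer sum to 1, so compare through the rank statistic directly
        from sklearn.metrics import roc_auc_score

        indicator = np.array(
            [[1 if lab == c else 0 for c in probs.columns] for lab in labels]
        ).ravel()
        a2 = roc_auc_score(indicator, np.sqrt(probs.to_numpy()).ravel())
        assert a1 == pytest.approx(a2)

    def test_single_class_truth_rejected(self):
        probs = pd.DataFrame(np.full((4, 2), 0.5), columns=["a", "b"])
        with pytest.raises(ValidationError):
            micro_average_auc(["a"] * 4, probs)


class TestKMLogrank:
    def test_km_equals_one_minus_ecdf_without_censoring(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = km_logrank(times, np.ones(5, dtype=int), ["g"] * 5)
        curve = res.curves["g"]
        surv = curve.set_index("time")["survival"]
        for k, t in enumerate(times):
            assert surv.loc[t] == pytest.approx(1.0 - (k + 1) / 5)

    def test_identical_groups_give_null_statistic(self):
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        groups = ["a"] * 3 + ["b"] * 3
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_tables_match_hand_computation(self):
        """A: events at 1, 3; B: events at 2, 4 — hand-worked hypergeometric tables."""
        times = np.array([1.0, 3.0, 2.0, 4.0])
        events = np.ones(4, dtype=int)
        groups = ["A", "A", "B", "B"]
        # t=1: n=4, nA=2, d=1 -> E=0.5, V=(2*2*1*3)/(16*3)=0.25
        # t=2: n=3, nA=1, d=1 -> E=1/3, V=(1*2*1*2)/(9*2)=2/9
        # t=3: n=2, nA=1, d=1 -> E=0.5, V=0.25
        # t=4: n=1, nA=0 -> E=0, V=0
        o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5) + 0.0
        var = 0.25 + 2 / 9 + 0.25
        expected_stat = o_minus_e**2 / var
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(expected_stat, rel=1e-9)

    def test_survival_non_increasing_from_one(self, survival_cohort):
        matrix, sheet, truth, tumors = survival_cohort
        res = km_logrank(
            sheet.loc[tumors, "os_time"].to_numpy(),
            sheet.loc[tumors, "os_event"].to_numpy(dtype=int),
            ["all"] * len(tumors),
        )
        s = res.curves["all"]["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)


class TestTimeDependentAUC:
    def test_perfect_ranking_gives_one(self):
        times = np.array([0.5, 0.6, 0.7, 5.0, 6.0, 7.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 0.5])
        assert time_dependent_auc(scores, times, events, 2.0) == pytest.approx(1.0)

    def test_reduces_to_static_auc_without_censoring(self):
        rng = np.random.default_rng(6)
        n = 60
        scores = rng.normal(size=n)
        times = rng.exponential(1 / np.exp(0.8 * scores))
        events = np.ones(n, dtype=int)
        t0 = np.median(times)
        auc_t = time_dependent_auc(scores, times, events, t0)
        cases = scores[times <= t0]
        controls = scores[times > t0]
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
        s = np.concatenate([cases, controls])
        assert auc_t == pytest.approx(oracle_pooled_auc(y, s), abs=1e-9)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(5):
            n = 300
            times = rng.exponential(5, n)
            events = (rng.random(n) < 0.8).astype(int)
            scores = rng.normal(size=n)
            aucs.append(time_dependent_auc(scores, times, events, np.median(times)))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_undefined_when_no_cases(self):
        times = np.array([5.0, 6.0, 7.0, 8.0])
        events = np.array([0, 0, 0, 0])
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isnan(time_dependent_auc(scores, times, events, 1.0))


class TestCoxTable:
    def test_null_factors_near_unit_hr(self):
        rng = np.random.default_rng(8)
        n = 400
        factors = pd.DataFrame(
            {"f1": rng.normal(size=n), "f2": rng.integers(0, 2, n).astype(float)}
        )
        times = rng.exponential(5, n)
        table = cox_table(factors, times, np.ones(n, dtype=int))
        assert np.allclose(table["hr_uni"], 1.0, atol=0.25)
        assert np.allclose(table["hr_multi"], 1.0, atol=0.25)

    def test_duplicated_factor_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        factors = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValidationError):
            cox_table(factors, rng.exponential(1, 50), np.ones(50, dtype=int))

    def test_planted_group_effect_covered_by_ci(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(5):
            n = 300
            group = rng.integers(0, 2, n).astype(float)
            times = rng.exponential(1 / (0.1 * np.exp(1.6 * group)))
            factors = pd.DataFrame({"group": group, "noise": rng.normal(size=n)})
            table = cox_table(factors, times, np.ones(n, dtype=int))
            if table.loc["group", "ci_lower_multi"] <= np.exp(1.6) <= table.loc[
                "group", "ci_upper_multi"
            ]:
                hits += 1
        assert hits >= 4


class TestRiskStratify:
    def make_cohort(self, seed=0, n=300, level_effect=0.0):
        rng = np.random.default_rng(seed)
        ann = pd.DataFrame(
            {
                "age": rng.integers(40, 80, n),
                "gender": rng.choice(["male", "female"], n),
                "bmi": rng.uniform(18, 35, n),
                "smoking": rng.choice(["yes", "no"], n),
                "alcohol": rng.choice(["yes", "no"], n),
                "ajcc_stage": rng.choice(["I", "II", "III", "IV"], n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        risk = pd.Series(rng.choice(["low", "high"], n), index=ann.index)
        level = assign_risk_levels(risk, ann["ajcc_stage"]).map(
            {"G1": 0, "G2": 1, "G3": 2, "G4": 3}
        )
        ann["os_time"] = rng.exponential(1 / (0.1 * np.exp(level_effect * level)))
        ann["os_event"] = 1
        return risk, ann

    def test_level_assignment_partitions_cohort(self):
        risk, ann = self.make_cohort(seed=1)
        levels = assign_risk_levels(risk, ann["ajcc_stage"])
        assert set(levels.unique()) <= {"G1", "G2", "G3", "G4"}
        g1 = levels == "G1"
        assert ((risk[g1] == "low") & ann.loc[g1, "ajcc_stage"].isin(["I", "II"])).all()

    def test_null_survival_gives_unit_hrs(self):
        risk, ann = self.make_cohort(seed=2, level_effect=0.0)
        strat = risk_stratify(risk, ann)
        assert np.nanmax(np.abs(np.log(strat.hr_table["hr"].astype(float)))) < 0.8
        assert strat.trend_p > 0.001

    def test_planted_monotone_hazards_detected(self):
        risk, ann = self.make_cohort(seed=3, level_effect=0.7)
        strat = risk_stratify(risk, ann)
        hrs = strat.hr_table["hr"].astype(float)
        assert hrs.is_monotonic_increasing
        assert strat.trend_p < 0.01

    def test_single_level_cohort_reports_missing_contrasts(self):
        risk, ann = self.make_cohort(seed=4)
        risk[:] = "low"
        ann["ajcc_stage"] = "I"
        strat = risk_stratify(risk, ann)
        assert strat.hr_table["hr"].isna().all()
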