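"""Decision-factor statistic, finding interpretation and categorisation."""

import math
import random

import numpy as np
import pytest

from ecgxai.attribution import AttributionMatrix
from ecgxai.criteria import (CategorySet, DecisionCriterion, DecisionFactor,
                             FindingCategory, categorize,
                             extract_decision_factors, interpret_criteria)
from ecgxai.geometry import ClusterAssignment
from ecgxai.schema import default_schema, lead_param


def assignment(labels, min_cluster_size=1):
    labels = np.asarray(labels)
    K = labels.max() + 1
    resp = np.eye(K)[labels]
    return ClusterAssignment(labels, resp, K, min_cluster_size)


def attr_of(values, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return AttributionMatrix(values, 0.0,
                             [f"r{i}" for i in range(len(values))], names)


class TestExtractDecisionFactors:
    def test_three_parameter_hand_arithmetic(self):
        # medians {0.5, 0.1, 0.0}: mean 0.2, population SD 0.21602,
        # threshold 0.41602 -> only the first parameter qualifies
        attr = attr_of([[0.5, 0.1, 0.0]])
        factors = extract_decision_factors(attr, assignment([0]))
        assert [f.parameter for f in factors] == ["f0"]
        expected_thr = 0.2 + math.sqrt(((0.3) ** 2 + (0.1) ** 2 + (0.2) ** 2) / 3)
        assert factors[0].threshold_used == pytest.approx(expected_thr, abs=1e-12)
        assert factors[0].median_shap == 0.5

    def test_equal_medians_give_no_factors(self):
        attr = attr_of([[0.2, 0.2, 0.2], [0.2, 0.2, 0.2]])
        assert extract_decision_factors(attr, assignment([0, 0])) == []

    def test_agrees_with_naive_recomputation_on_random_matrices(self):
        # independent code path: sort-based median and two-pass SD
        rng = random.Random(0)
        for trial in range(20):
            n, p, K = rng.randint(4, 12), rng.randint(2, 9), rng.randint(1, 3)
            vals = [[rng.gauss(0, 1) for _ in range(p)] for _ in range(n)]
            labels = [rng.randrange(K) for _ in range(n)]
            attr = attr_of(vals)
            got = {(f.cluster, f.parameter)
                   for f in extract_decision_factors(attr, assignment(labels))}
            want = set()
            for c in sorted(set(labels)):
                rows = [vals[i] for i in range(n) if labels[i] == c]
                meds = []
                for j in range(p):
                    col = sorted(r[j] for r in rows)
                    m = len(col)
                    meds.append(col[m // 2] if m % 2 else
                                0.5 * (col[m // 2 - 1] + col[m // 2]))
                mean = sum(meds) / p
                sd = math.sqrt(sum((v - mean) ** 2 for v in meds) / p)
                want |= {(c, f"f{j}") for j in range(p) if meds[j] > mean + sd}
            assert got == want, f"trial {trial}"

    def test_factors_sorted_by_descending_median_within_cluster(self):
        attr = attr_of([[0.1, 0.9, 0.5, 0.0, 0.0, 0.0, 0.0]])
        factors = extract_decision_factors(attr, assignment([0]))
        meds = [f.median_shap for f in factors]
        assert meds == sorted(meds, reverse=True)

    def test_unexplained_clusters_are_skipped(self):
        attr = attr_of([[0.5, 0.0, 0.0]] * 9 + [[0.0, 0.5, 0.0]] * 12)
        ca = assignment([0] * 9 + [1] * 12, min_cluster_size=10)
        ca.unexplained = [0]
        factors = extract_decision_factors(attr, ca)
        assert {f.cluster for f in factors} == {1}

    def test_entries_reading_is_available_behind_flag(self):
        attr = attr_of([[0.5, 0.1, 0.0], [0.7, 0.1, 0.0]])
        a = extract_decision_factors(attr, assignment([0, 0]))
        b = extract_decision_factors(attr, assignment([0, 0]),
                                     threshold_over="entries")
        assert {f.parameter for f in a} == {"f0"}
        assert all(f.threshold_used != a[0].threshold_used for f in b)

    def test_factor_invariant_enforced(self):
        with pytest.raises(ValueError):
            DecisionFactor(0, "x", 0.1, 0.2)


class TestInterpretCriteria:
    @pytest.fixture()
    def scenario(self, schema):
        """One cluster whose factor parameters realise classic findings."""
        from ecgxai.synthetic import baseline_mean_sd
        mean, sd = baseline_mean_sd(schema)
        ref = np.tile(mean, (50, 1))            # reference at baseline exactly
        cohort = np.tile(mean, (11, 1))
        shifts = {
            lead_param("T_amp", "I"): -0.35, lead_param("T_amp", "V5"): -0.40,
            lead_param("T_amp", "V6"): -0.35, lead_param("T_amp", "aVR"): +0.30,
            lead_param("R_amp", "II"): -0.60, lead_param("R_amp", "V4"): -0.55,
            lead_param("R_amp", "V5"): -0.60,
            lead_param("S_dur", "V3"): +30.0,
            "age": +15.0,
        }
        for name, d in shifts.items():
            cohort[:, schema.index(name)] += d
        factors = [DecisionFactor(0, name, 0.1, 0.05) for name in shifts]
        return factors, cohort, ref

    def test_classic_cluster_reads_out_expected_findings(self, schema, scenario):
        factors, cohort, ref = scenario
        crits = interpret_criteria(factors, cohort, np.zeros(11, int), ref, schema)
        # the age factor yields no criterion; aVR's raised T reads "tall T wave"
        assert {c.finding for c in crits} == {
            "negative T-wave inversion", "low voltage",
            "S-wave prolongation", "tall T wave"}
        t = [c for c in crits if c.finding == "negative T-wave inversion"]
        assert len(t) == 1 and t[0].leads == ["I", "V5", "V6"]
        assert t[0].direction == "negative"
        lv = [c for c in crits if c.finding == "low voltage"]
        assert len(lv) == 1 and lv[0].leads == ["II", "V4", "V5"]
        s = [c for c in crits if c.finding == "S-wave prolongation"]
        assert len(s) == 1 and s[0].leads == ["V3"]
        # aVR's raised T wave is not an inversion
        assert "aVR" not in t[0].leads

    def test_qtc_factor_reads_as_qtc_prolongation(self, schema):
        from ecgxai.synthetic import baseline_mean_sd
        mean, _ = baseline_mean_sd(schema)
        ref = np.tile(mean, (30, 1))
        cohort = np.tile(mean, (8, 1))
        for ld in ["V1", "V2", "V3"]:
            cohort[:, schema.index(lead_param("QTc_lead", ld))] += 60.0
        factors = [DecisionFactor(0, lead_param("QTc_lead", ld), 0.1, 0.0)
                   for ld in ["V1", "V2", "V3"]]
        crits = interpret_criteria(factors, cohort, np.zeros(8, int), ref, schema)
        assert [c.finding for c in crits] == ["QTc prolongation"]
        assert crits[0].leads == ["V1", "V2", "V3"]

    def test_no_shift_emits_no_criterion(self, schema):
        from ecgxai.synthetic import baseline_mean_sd
        mean, _ = baseline_mean_sd(schema)
        ref = np.tile(mean, (30, 1))
        cohort = np.tile(mean, (8, 1))
        factors = [DecisionFactor(0, lead_param("R_amp", "V5"), 0.1, 0.0)]
        assert interpret_criteria(factors, cohort, np.zeros(8, int), ref, schema) == []

    def test_sub_threshold_shift_is_suppressed(self, schema):
        rng = np.random.default_rng(0)
        ref = rng.standard_normal((200, len(schema)))
        cohort = ref[:10].copy()
        j = schema.index(lead_param("R_amp", "V5"))
        cohort[:, j] = np.median(ref[:, j]) - 0.1 * ref[:, j].std()  # < 0.2 SD
        factors = [DecisionFactor(0, lead_param("R_amp", "V5"), 0.1, 0.0)]
        assert interpret_criteria(factors, cohort, np.zeros(10, int), ref,
                                  schema) == []

    def test_unknown_parameter_rejected(self, schema):
        factors = [DecisionFactor(0, "mystery", 0.1, 0.0)]
        with pytest.raises(ValueError, match="mystery"):
            interpret_criteria(factors, np.zeros((2, len(schema))),
                               np.zeros(2, int), np.zeros((2, len(schema))),
                               schema)


class TestCategorize:
    def test_low_voltage_plus_q_wave_cluster(self):
        crits = [
            DecisionCriterion(3, "low voltage", ["I", "II", "V4", "V5", "V6"], "low"),
            DecisionCriterion(3, "Q wave", ["V4", "V5", "V6"], "present"),
        ]
        cats = categorize(crits)
        assert cats[3].categories == {FindingCategory.LOW_VOLTAGE_I_II_V46,
                                      FindingCategory.Q_WAVE_V36}
        assert not cats[3].conduction_delay

    def test_conduction_delay_cluster_with_four_categories(self):
        crits = [
            DecisionCriterion(2, "negative T-wave inversion", ["I", "II", "V5", "V6"],
                              "negative"),
            DecisionCriterion(2, "VAT prolongation", ["V5", "V6"], "high"),
            DecisionCriterion(2, "low voltage", ["V4"], "low"),
            DecisionCriterion(2, "QTc prolongation", ["V1", "V2", "V3"], "high"),
            DecisionCriterion(2, "S-wave prolongation", ["V3"], "high"),
        ]
        cats = categorize(crits)
        assert cats[2].categories == {
            FindingCategory.NEG_T_INVERSION_I_V56,
            FindingCategory.VAT_PROLONG_I_V56,
            FindingCategory.LOW_VOLTAGE_I_II_V46,
            FindingCategory.QTC_PROLONG,
            FindingCategory.S_PROLONG_V23,
        }
        assert cats[2].conduction_delay

    def test_empty_criteria_empty_categories(self):
        assert categorize([]) == {}

    def test_unmappable_finding_reported_not_dropped(self):
        crits = [DecisionCriterion(0, "ST depression", ["V2"], "low"),
                 DecisionCriterion(0, "S-wave prolongation", ["V6"], "high")]
        cats = categorize(crits)
        assert cats[0].categories == set()
        assert len(cats[0].outside) == 2

    def test_order_independence_of_interpret_and_categorize(self, schema):
        from ecgxai.synthetic import baseline_mean_sd
        mean, _ = baseline_mean_sd(schema)
        ref = np.tile(mean, (20, 1))
        cohort = np.tile(mean, (6, 1))
        names = [lead_param("T_amp", "I"), lead_param("T_amp", "V5"),
                 lead_param("VAT", "V6"), lead_param("S_dur", "V2")]
        cohort[:, schema.index(names[0])] -= 0.4
        cohort[:, schema.index(names[1])] -= 0.4
        cohort[:, schema.index(names[2])] += 30.0
        cohort[:, schema.index(names[3])] += 30.0
        factors = [DecisionFactor(0, n, 0.1, 0.0) for n in names]
        a = interpret_criteria(factors, cohort, np.zeros(6, int), ref, schema)
        b = interpret_criteria(factors[::-1], cohort, np.zeros(6, int), ref, schema)
        key = lambda cs: sorted((c.cluster, c.finding, tuple(c.leads)) for c in cs)
        assert key(a) == key(b)
        assert ({c.value for c in categorize(a)[0].categories}
                == {c.value for c in categorize(b)[0].categories})
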