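"""Diagnostic metrics, bootstrap intervals and the clustered paired test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgxai.evalstats import (ReaderStudy, auroc, bootstrap_ci,
                              confusion_metrics, obuchowski_test,
                              permutation_test, population_sd, reader_summary)
from ecgxai.examples import (READER_PERFORMANCE, READER_SUMMARY_PUBLISHED,
                             reader_study_from_table)


class TestConfusionMetrics:
    def test_reader_one_reconstructed_counts(self):
        # TP=26 FN=24 TN=36 FP=14 at 50/50 prevalence
        truth = np.array([True] * 50 + [False] * 50)
        calls = np.r_[np.arange(50) < 26, np.arange(50) >= 36]
        assert confusion_metrics(calls, truth) == (62.0, 52.0, 72.0)

    def test_perfect_calls(self):
        truth = np.array([True, False, True])
        assert confusion_metrics(truth, truth) == (100.0, 100.0, 100.0)

    def test_single_class_truth_flags_undefined_metrics(self):
        truth = np.zeros(5, bool)
        acc, sens, spec = confusion_metrics(np.zeros(5, bool), truth)
        assert acc == 100.0 and sens is None and spec == 100.0

    def test_random_calls_approach_fifty_percent(self):
        rng = np.random.default_rng(0)
        acc, _, _ = confusion_metrics(rng.random(20000) < 0.5,
                                      rng.random(20000) < 0.5)
        assert abs(acc - 50.0) < 1.5


class TestAuroc:
    def test_perfect_separation_and_all_ties(self):
        truth = np.array([True, True, False, False])
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]), truth) == 1.0
        assert auroc(np.zeros(4), truth) == 0.5

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            truth = rng.random(50) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.random(50), 1)        # force ties
            pos, neg = scores[truth], scores[~truth]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert abs(auroc(scores, truth) - wins / (len(pos) * len(neg))) < 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)),
                    min_size=6, max_size=40),
           st.integers(1, 2 ** 16))
    def test_invariant_under_strictly_increasing_transforms(self, scores, seed):
        scores = np.asarray(scores)
        truth = np.random.default_rng(seed).random(len(scores)) < 0.5
        if truth.all() or not truth.any():
            return
        base = auroc(scores, truth)
        assert auroc(3.0 * scores + 7.0, truth) == pytest.approx(base, abs=1e-12)
        assert auroc(np.tanh(scores / 100), truth) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.2]), np.array([True, True]))


class TestBootstrap:
    def test_constant_metric_gives_zero_width_interval(self):
        data = (np.ones(50, bool), np.ones(50, bool))
        lo, hi = bootstrap_ci(lambda c, t: confusion_metrics(c, t)[0], data,
                              B=200, seed=0)
        assert lo == hi == 100.0

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(2)
        data = (rng.random(80) < 0.6, rng.random(80) < 0.5)
        f = lambda c, t: confusion_metrics(c, t)[0]
        assert bootstrap_ci(f, data, B=300, seed=9) == \
               bootstrap_ci(f, data, B=300, seed=9)

    def test_degenerate_resamples_are_redrawn(self):
        truth = np.array([True] + [False] * 9)          # sens often undefined
        calls = truth.copy()
        lo, hi = bootstrap_ci(lambda c, t: confusion_metrics(c, t)[1],
                              (calls, truth), B=100, seed=0)
        assert lo == hi == 100.0

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda x: float(x.mean()), (np.arange(5.0),), B=10)


def study_from_counts(bc_pairs, n=100):
    """Build a study with prescribed per-reader (b_k, c_k) discordance."""
    frames = []
    truth = np.ones(n, bool)
    for r, (b, c) in enumerate(bc_pairs):
        correct_b = np.ones(n, bool)
        correct_a = np.ones(n, bool)
        correct_a[:b] = False                        # correct before, wrong after
        correct_b[b:b + c] = False                   # wrong before, correct after
        frames.append(pd.DataFrame({
            "reader_id": f"R{r}", "ecg_id": [f"E{i}" for i in range(n)],
            "truth": truth,
            "call_before": np.where(correct_b, truth, ~truth),
            "call_after": np.where(correct_a, truth, ~truth)}))
    return ReaderStudy(pd.concat(frames, ignore_index=True))


class TestObuchowskiTest:
    def test_balanced_discordance_gives_null_result(self):
        res = obuchowski_test(study_from_counts([(3, 3), (5, 5), (2, 2)]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_no_discordance_flagged(self):
        res = obuchowski_test(study_from_counts([(0, 0), (0, 0)]))
        assert res.no_discordance and res.p_value == 1.0

    def test_invariant_under_reader_relabelling_and_ecg_reordering(self):
        rng = np.random.default_rng(3)
        rs = study_from_counts([(2, 7), (1, 9), (4, 6), (0, 8)])
        base = obuchowski_test(rs)
        relabelled = rs.df.copy()
        relabelled["reader_id"] = relabelled["reader_id"].map(
            {"R0": "Z", "R1": "A", "R2": "M", "R3": "B"})
        shuffled = relabelled.sample(frac=1.0, random_state=4)
        res = obuchowski_test(ReaderStudy(shuffled))
        assert res.statistic == pytest.approx(base.statistic)
        assert res.p_value == pytest.approx(base.p_value)

    def test_reduces_to_classical_mcnemar_for_singleton_clusters(self):
        # one paired observation per reader: T = (b-c)^2/(b+c), McNemar exactly
        from scipy.stats import chi2
        for pattern in [(1, 0), (0, 1)] , [(1, 0)] * 5 + [(0, 1)] * 2:
            rs = study_from_counts(list(pattern), n=1)
            res = obuchowski_test(rs)
            b = sum(p[0] for p in pattern)
            c = sum(p[1] for p in pattern)
            mcnemar_stat = (b - c) ** 2 / (b + c)
            assert res.statistic == pytest.approx(mcnemar_stat)
            assert res.p_value == pytest.approx(float(chi2.sf(mcnemar_stat, 1)))

    def test_strong_improvement_rejects_and_matches_permutation(self):
        rs = study_from_counts([(0, 12), (1, 10), (0, 9), (2, 14), (1, 11),
                                (0, 13), (1, 9)])
        assert obuchowski_test(rs).p_value < 0.05
        assert permutation_test(rs).p_value <= 0.05

    def test_single_reader_rejected(self):
        with pytest.raises(ValueError):
            obuchowski_test(study_from_counts([(1, 2)]))


class TestReaderSummary:
    @pytest.mark.parametrize("phase", ["before", "after"])
    def test_published_reader_table_summary_is_reproduced(self, phase):
        rs = reader_study_from_table()
        table, mean, sd = reader_summary(rs, phase)
        expected = READER_SUMMARY_PUBLISHED[phase]
        assert mean == expected["mean"]
        assert sd == expected["sd"]
        np.testing.assert_allclose(table["accuracy"],
                                   READER_PERFORMANCE[f"accuracy_{phase}"])

    def test_population_sd_convention(self):
        # sample SD of the before-accuracies would be 4.2, not the printed 3.9
        vals = READER_PERFORMANCE["accuracy_before"]
        assert round(population_sd(vals), 1) == 3.9
        assert round(float(np.std(vals, ddof=1)), 1) == 4.2

    def test_single_reader_sd_is_zero(self):
        rs = study_from_counts([(2, 3)])
        _, mean, sd = reader_summary(rs, "before")
        assert sd["accuracy"] == 0.0

    def test_mismatched_ecg_sets_rejected(self):
        df = study_from_counts([(1, 1), (2, 2)]).df.copy()
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="identical ECG set"):
            ReaderStudy(df)
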