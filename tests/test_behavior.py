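"""Behavioral decision metrics: confusion, false alarms, d', RT/accuracy,
pairwise 2AFC discrimination and the 4-way combination contrast."""

import numpy as np
import pandas as pd
import pytest

from screamcalls import behavior, stats, synth
from screamcalls.behavior import MISSED, ConfusionMatrix, TrialLog
from screamcalls.synth import ConfusionSpec, RTSpec
from screamcalls.taxonomy import SCREAM_TYPES


def _log_from_rows(rows, task="7AFC", window=3000.0):
    return TrialLog(trials=pd.DataFrame(rows), task_kind=task,
                    response_window_ms=window)


def _row(p, block, true, resp, rt):
    return {"participant": p, "block": block, "stimulus_id": f"s{p}{block}{true}{rt}",
            "true_type": true, "response": resp, "rt_ms": rt}


class TestConfusionFromLog:
    def test_all_correct_is_diagonal(self):
        rows = [_row("p0", 0, t, t, 500.0) for t in SCREAM_TYPES for _ in range(3)]
        conf = behavior.confusion_from_log(_log_from_rows(rows)).pooled
        assert np.all(conf.counts == 3 * np.eye(7, dtype=int))

    def test_row_sums_exclude_missed(self):
        rows = [_row("p0", 0, "fear", "fear", 400.0),
                _row("p0", 0, "fear", MISSED, np.nan),
                _row("p0", 0, "fear", "anger", 600.0)]
        conf = behavior.confusion_from_log(_log_from_rows(rows)).pooled
        fear_idx = SCREAM_TYPES.index("fear")
        assert conf.counts[fear_idx].sum() == 2

    def test_recovers_generating_confusion_spec(self):
        """Row-normalized empirical matrix converges to the planted one."""
        k = 7
        probs = np.full((k, k), 0.05)
        np.fill_diagonal(probs, 1 - 0.05 * (k - 1))
        spec = ConfusionSpec(SCREAM_TYPES, probs)
        log = synth.make_afc_log(spec, RTSpec.uniform(), 4, 500, 0)  # 2000/type
        conf = behavior.confusion_from_log(log).pooled
        np.testing.assert_allclose(conf.row_normalized(), probs, atol=0.03)

    def test_empty_log_errors(self):
        log = _log_from_rows([_row("p0", 0, "fear", "fear", 1.0)])
        log = TrialLog(trials=log.trials.iloc[:0], task_kind="7AFC",
                       response_window_ms=3000.0)
        with pytest.raises(ValueError, match="empty"):
            behavior.confusion_from_log(log)


class TestFalseAlarmRates:
    def test_single_sink_category(self):
        counts = 5 * np.eye(7, dtype=int)
        counts[0, 3] = 4  # every misclassification lands on category 3
        rates = behavior.false_alarm_rates(ConfusionMatrix(counts, SCREAM_TYPES))
        assert rates.iloc[3] == 1.0
        assert rates.drop(rates.index[3]).sum() == 0.0

    def test_uniform_offdiagonal_and_sum_to_one(self):
        counts = np.ones((7, 7), dtype=int)
        rates = behavior.false_alarm_rates(ConfusionMatrix(counts, SCREAM_TYPES))
        np.testing.assert_allclose(rates, 1 / 7, atol=1e-12)
        assert rates.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_misclassifications_flagged(self):
        counts = 5 * np.eye(7, dtype=int)
        with pytest.warns(UserWarning, match="undefined"):
            rates = behavior.false_alarm_rates(ConfusionMatrix(counts, SCREAM_TYPES))
        assert rates.isna().all()


class TestDPrime:
    def test_equal_rates_zero_dprime(self):
        # uniform rows: every category's hit rate equals its false-alarm rate
        counts = np.full((4, 4), 10, dtype=int)
        res = behavior.dprime_table(ConfusionMatrix(counts, SCREAM_TYPES[:4]))
        np.testing.assert_allclose(res.table["d_prime"], 0.0, atol=1e-12)

    def test_hit84_fa16_matches_quantile_oracle(self):
        """hit .84 / FA .16: d' = Z(.84) - Z(.16) ~ 2 * 0.99446."""
        # 2 categories, 100 presentations each, arranged to give exact rates
        counts = np.array([[84, 16], [16, 84]])
        res = behavior.dprime_table(ConfusionMatrix(counts, ("a", "b")))
        expected = stats.z_quantile(0.84) - stats.z_quantile(0.16)
        assert res.table.loc["a", "d_prime"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2 * 0.99446, abs=1e-4)

    def test_swapping_hit_and_fa_negates(self):
        # [[84,16],[16,84]] gives category a hit .84 / FA .16;
        # [[16,84],[84,16]] realizes the swapped rates .16 / .84
        res = behavior.dprime_table(ConfusionMatrix(np.array([[84, 16], [16, 84]]),
                                                    ("a", "b")))
        swapped = behavior.dprime_table(ConfusionMatrix(np.array([[16, 84], [84, 16]]),
                                                        ("a", "b")))
        assert res.table.loc["a", "d_prime"] == pytest.approx(
            -swapped.table.loc["a", "d_prime"], abs=1e-9
        )

    def test_extreme_rates_corrected(self):
        counts = np.array([[50, 0], [0, 50]])  # perfect performance
        res = behavior.dprime_table(ConfusionMatrix(counts, ("a", "b")))
        assert np.isfinite(res.table["d_prime"]).all()
        assert (res.table["hit_rate"] < 1).all()
        assert (res.table["false_alarm_rate"] > 0).all()

    def test_closed_form_consistency_with_generated_log(self):
        """d' from a generated log matches the value implied by the planted
        response probabilities."""
        k = 3
        probs = np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.05, 0.25, 0.7]])
        spec = ConfusionSpec(SCREAM_TYPES[:k], probs)
        log = synth.make_afc_log(spec, RTSpec.uniform(categories=SCREAM_TYPES[:k]),
                                 5, 1000, 1)
        res = behavior.dprime_table(behavior.confusion_from_log(log).pooled)
        for i, cat in enumerate(SCREAM_TYPES[:k]):
            hit = probs[i, i]
            fa = probs[:, i][np.arange(k) != i].mean()  # equal presentations
            expected = stats.z_quantile(hit) - stats.z_quantile(fa)
            assert res.table.loc[cat, "d_prime"] == pytest.approx(expected, abs=0.05)


class TestRtAccuracySummary:
    def test_known_log(self):
        rows = (
            [_row("p0", 0, "joy", "joy", 500.0) for _ in range(4)]
            + [_row("p0", 0, "fear", "fear", 800.0) for _ in range(2)]
            + [_row("p0", 0, "fear", "joy", 900.0) for _ in range(2)]
            + [_row("p0", 0, "fear", MISSED, np.nan)]
        )
        out = behavior.rt_accuracy_summary(_log_from_rows(rows)).set_index("level")
        assert out.loc["joy", "mean_rt_ms"] == 500.0
        assert out.loc["joy", "accuracy"] == 1.0
        assert out.loc["fear", "mean_rt_ms"] == 800.0  # incorrect trials excluded
        assert out.loc["fear", "accuracy"] == pytest.approx(0.5)  # missed excluded

    def test_three_level_pooling_matches_trial_level(self):
        spec = ConfusionSpec.identity(miss_rate=0.1)
        log = synth.make_afc_log(spec, RTSpec.uniform(), 5, 20, 2)
        grouping = behavior.three_level_grouping()
        out = behavior.rt_accuracy_summary(log, grouping)
        df = log.trials.assign(level=log.trials["true_type"].map(grouping))
        for (p, lev), g in df.groupby(["participant", "level"]):
            row = out[(out.participant == p) & (out.level == lev)].iloc[0]
            correct = g[(g["response"] == g["true_type"])]
            responded = g[g["response"] != MISSED]
            assert row["accuracy"] == pytest.approx(len(correct) / len(responded))
            assert row["mean_rt_ms"] == pytest.approx(correct["rt_ms"].mean())

    def test_no_correct_trials_gives_nan_rt(self):
        rows = [_row("p0", 0, "fear", "anger", 700.0)]
        out = behavior.rt_accuracy_summary(_log_from_rows(rows))
        assert np.isnan(out.iloc[0]["mean_rt_ms"])

    def test_planted_rt_ordering_recovered(self):
        medians = {t: 800.0 + 150.0 * i for i, t in enumerate(SCREAM_TYPES)}
        log = synth.make_afc_log(ConfusionSpec.identity(),
                                 RTSpec(medians, sigma=0.2), 8, 60, 3)
        out = behavior.rt_accuracy_summary(log)
        means = out.groupby("level")["mean_rt_ms"].mean()
        ordered = [means[t] for t in SCREAM_TYPES]
        assert all(a < b for a, b in zip(ordered, ordered[1:]))


class TestAfc2Pairwise:
    def test_21_pairs_and_symmetric_null(self):
        log = synth.make_2afc_log(0.9, RTSpec.uniform(), 12, trials_per_type=20,
                                  miss_rate=0.0, seed=5)
        results = behavior.afc2_pairwise(log)
        assert len(results) == 21
        # identical generating parameters for both types: differences ~ 0
        assert np.mean([abs(r.norm_rt_diff) for r in results]) < 0.05
        sig = sum(r.rt_p_fdr < 0.05 for r in results)
        assert sig <= 2

    def test_planted_rt_gap_detected_only_for_that_pair(self):
        medians = {t: 1000.0 for t in SCREAM_TYPES}
        medians["fear"] = 1600.0  # all fear-containing pairs get a gap
        log = synth.make_2afc_log(0.95, RTSpec(medians, sigma=0.15), 20,
                                  trials_per_type=25, miss_rate=0.0, seed=6)
        results = behavior.afc2_pairwise(log)
        for r in results:
            has_fear = "fear" in r.pair
            assert (r.rt_p_fdr < 0.05) == has_fear, r.pair

    def test_missing_pair_errors(self):
        log = synth.make_2afc_log(0.9, RTSpec.uniform(), 3, trials_per_type=4, seed=7)
        truncated = log.trials[log.trials["block"] != 0]
        broken = TrialLog(trials=truncated, task_kind="2AFC", response_window_ms=3000.0)
        with pytest.raises(ValueError, match="missing pair"):
            behavior.afc2_pairwise(broken)

    def test_fdr_adjusted_at_least_raw(self):
        log = synth.make_2afc_log(0.9, RTSpec.uniform(), 8, trials_per_type=10, seed=8)
        for r in behavior.afc2_pairwise(log):
            assert r.rt_p_fdr >= r.rt_p - 1e-12
            assert r.acc_p_fdr >= r.acc_p - 1e-12


class TestComboCategories:
    def test_pair_taxonomy(self):
        assert behavior.combo_category_of_pair("fear", "anger") == "alarm_vs_alarm"
        assert behavior.combo_category_of_pair("neutral", "joy") == "neutral_vs_scream"
        assert behavior.combo_category_of_pair("joy", "pleasure") == "nonalarm_vs_nonalarm"
        assert behavior.combo_category_of_pair("joy", "pain") == "alarm_vs_nonalarm"

    def test_class_sizes_6_3_9_3(self):
        log = synth.make_2afc_log(0.9, RTSpec.uniform(), 4, trials_per_type=4, seed=9)
        combo = behavior.afc2_combo_categories(log)
        assert combo.class_sizes == {
            "neutral_vs_scream": 6,
            "nonalarm_vs_nonalarm": 3,
            "alarm_vs_nonalarm": 9,
            "alarm_vs_alarm": 3,
        }
        assert sum(combo.class_sizes.values()) == 21

    def test_planted_class_ordering_recovered(self):
        medians = {t: 900.0 for t in SCREAM_TYPES}
        for t in ("pain", "fear", "anger"):
            medians[t] = 1400.0
        medians["neutral"] = 600.0
        log = synth.make_2afc_log(0.95, RTSpec(medians, sigma=0.15), 12,
                                  trials_per_type=12, miss_rate=0.0, seed=10)
        combo = behavior.afc2_combo_categories(log)
        means = combo.summary.groupby("combo")["mean_rt_ms"].mean()
        assert means["neutral_vs_scream"] < means["nonalarm_vs_nonalarm"]
        assert means["nonalarm_vs_nonalarm"] < means["alarm_vs_nonalarm"]
        assert means["alarm_vs_nonalarm"] < means["alarm_vs_alarm"]
        assert combo.rt_anova.p_value < 0.001


def test_bookkeeping_invariant_on_generated_logs():
    for seed in range(5):
        log = synth.make_afc_log(ConfusionSpec.identity(miss_rate=0.2),
                                 RTSpec.uniform(), 3, 30, seed)
        book = log.bookkeeping()
        assert (book["missed"] + book["correct"] + book["incorrect"]
                == book["total"]).all()


def test_trial_log_io_round_trip(tmp_path):
    log = synth.make_afc_log(ConfusionSpec.identity(miss_rate=0.1),
                             RTSpec.uniform(), 2, 5, 0)
    behavior.write_trial_log(tmp_path / "log.csv", log)
    back = behavior.read_trial_log(tmp_path / "log.csv", "7AFC", 3000.0)
    assert len(back.trials) == len(log.trials)
    assert (back.trials["response"] == log.trials["response"]).all()


def test_trial_log_invariant_violations_rejected():
    with pytest.raises(ValueError, match="rt"):
        _log_from_rows([_row("p0", 0, "fear", "fear", 5000.0)])  # beyond window
    with pytest.raises(ValueError, match="category"):
        _log_from_rows([_row("p0", 0, "surprise", "fear", 100.0)])
    # a 2AFC block with three true types is malformed
    rows = [_row("p0", 0, t, t, 100.0) for t in ("fear", "anger", "joy")]
    with pytest.raises(ValueError, match="exactly 2"):
        _log_from_rows(rows, task="2AFC")
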