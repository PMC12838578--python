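"""Alarm post-processing and evaluation statistics vs brute-force oracles."""

import numpy as np
import pytest

from seizkd.alarms import AlarmPolicy, kofn_alarms, smooth_detection_alarms
from seizkd.metrics import (EvalProtocol, evaluate_detection,
                            evaluate_prediction, loocv_folds,
                            random_predictor_pvalue, roc_auc, sweep_policy)
from seizkd.synthetic import SeizureEvent


def _brute_force_kofn(probs, times, policy, warm=None):
    """Re-count the trailing window at every step (oracle)."""
    pos = np.asarray(probs) >= policy.prob_threshold
    if warm is not None:
        pos = pos & ~np.asarray(warm, bool)
    alarms, last = [], -np.inf
    for i in range(len(pos)):
        if i < policy.n - 1:
            continue
        if pos[max(0, i - policy.n + 1): i + 1].sum() >= policy.k and \
                times[i] - last >= policy.refractory:
            alarms.append(float(times[i]))
            last = times[i]
    return alarms


# ----------------------------------------------------------------- k-of-n


def test_kofn_all_positive_fires_once_within_refractory():
    times = np.arange(60.0)
    alarms = kofn_alarms(np.ones(60), times, AlarmPolicy())
    assert alarms == [9.0]  # first time 8-of-10 holds is window index 9


def test_kofn_no_positives_no_alarms():
    times = np.arange(30.0)
    assert kofn_alarms(np.zeros(30), times, AlarmPolicy()) == []


def test_kofn_short_stream_yields_nothing():
    assert kofn_alarms(np.ones(5), np.arange(5.0), AlarmPolicy()) == []


def test_kofn_matches_brute_force_on_random_streams():
    policy = AlarmPolicy(k=8, n=10, refractory=20.0)
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(5, 120))
        probs = rng.random(n)
        times = np.arange(n, dtype=float)
        warm = np.arange(n) < 10
        got = kofn_alarms(probs, times, policy, warm)
        want = _brute_force_kofn(probs, times, policy, warm)
        assert got == want


def test_kofn_respects_refractory_gap():
    policy = AlarmPolicy(k=2, n=3, refractory=15.0)
    rng = np.random.default_rng(1)
    for _ in range(100):
        probs = rng.random(80)
        alarms = kofn_alarms(probs, np.arange(80.0), policy)
        gaps = np.diff(alarms)
        assert (gaps >= policy.refractory).all()


def test_kofn_warm_up_windows_never_positive():
    policy = AlarmPolicy(k=1, n=1, refractory=0.0)
    probs = np.ones(5)
    warm = np.array([True, True, False, False, False])
    assert kofn_alarms(probs, np.arange(5.0), policy, warm) == [2.0, 3.0, 4.0]


# ----------------------------------------------------------------- smoothing


def test_smoothed_detection_interval_opens_after_average_crosses():
    policy = AlarmPolicy(smooth_len=5.0, det_threshold=0.5)
    probs = np.concatenate([np.zeros(5), np.ones(10), np.zeros(10)])
    times = np.arange(len(probs), dtype=float)
    intervals = smooth_detection_alarms(probs, times, policy)
    assert len(intervals) == 1
    start, end = intervals[0]
    assert start == 7.0   # 3 of 5 trailing ones -> average 0.6 > 0.5
    assert end == 17.0    # trailing average falls to 0.4 at t=17


def test_single_spike_cannot_trigger_smoothed_alarm():
    policy = AlarmPolicy(smooth_len=5.0, det_threshold=0.5)
    probs = np.zeros(20)
    probs[10] = 1.0  # trailing average peaks at 0.2
    assert smooth_detection_alarms(probs, np.arange(20.0), policy) == []


def test_all_zero_probabilities_no_intervals():
    assert smooth_detection_alarms(np.zeros(30), np.arange(30.0),
                                   AlarmPolicy()) == []


# ----------------------------------------------------------------- SPH/SOP


def test_alarm_validity_window():
    protocol = EvalProtocol(sph=300.0, sop=1800.0)
    events = [SeizureEvent(1000.0, 1030.0)]
    # onset 600 s after the alarm: inside [300, 2100) -> valid
    sen, fpr, _ = evaluate_prediction([400.0], events, protocol, 1.0)
    assert sen == 1.0 and fpr == 0.0
    # onset 120 s after the alarm: still inside the SPH -> invalid
    sen, fpr, _ = evaluate_prediction([880.0], events, protocol, 1.0)
    assert sen == 0.0 and fpr == 1.0


def test_fpr_uses_full_unedited_duration():
    protocol = EvalProtocol()
    _, fpr, _ = evaluate_prediction([10.0, 20.0], [], protocol, 4.0)
    assert fpr == pytest.approx(0.5)  # 2 invalid alarms over 4 h
    _, fpr_half, _ = evaluate_prediction([10.0, 20.0], [], protocol, 2.0)
    assert fpr_half == pytest.approx(1.0)  # truncating doubles the rate


def test_sensitivity_undefined_without_events():
    sen, _, _ = evaluate_prediction([10.0], [], EvalProtocol(), 1.0)
    assert sen is None


def test_one_alarm_validates_only_nearest_event():
    protocol = EvalProtocol(sph=0.0, sop=1000.0)
    events = [SeizureEvent(100.0, 110.0), SeizureEvent(500.0, 510.0)]
    sen, fpr, table = evaluate_prediction([50.0], events, protocol, 1.0)
    assert sen == 0.5
    assert table["event"].tolist() == [0]


# ----------------------------------------------------------------- AUC


def test_roc_auc_examples():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75
    with pytest.raises(ValueError):
        roc_auc([1, 1], [0.2, 0.4])


def _pair_counting_auc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_matches_pair_counting_with_ties():
    rng = np.random.default_rng(0)
    for n in range(2, 13):
        for _ in range(20):
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.4, 0.4, 0.9], size=n)
            assert roc_auc(labels, scores) == \
                pytest.approx(_pair_counting_auc(labels, scores), abs=1e-9)


# ----------------------------------------------------------------- p-value


def test_random_predictor_closed_forms():
    p, sig = random_predictor_pvalue(0.5, 0.5, 5, 0)
    assert p == pytest.approx(1.0)
    p, sig = random_predictor_pvalue(0.0, 0.5, 5, 1)
    assert p == pytest.approx(0.0) and sig
    p, _ = random_predictor_pvalue(0.1, 0.5, 5, 5)
    want = (1 - np.exp(-0.05)) ** 5
    assert p == pytest.approx(want, rel=1e-6)
    assert p == pytest.approx(2.76e-7, rel=0.01)


def test_random_predictor_pvalue_monotone_in_fpr():
    ps = [random_predictor_pvalue(f, 0.5, 6, 4)[0]
          for f in np.linspace(0.0, 3.0, 20)]
    assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))


# ----------------------------------------------------------------- detection


def test_detection_confusion_arithmetic():
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.2, 0.1, 0.3, 0.2, 0.6])
    out = evaluate_detection(labels, probs, det_threshold=0.5)
    assert out["sen"] == pytest.approx(0.75)      # TP=3, FN=1
    assert out["spe"] == pytest.approx(5 / 6)     # TN=5, FP=1
    assert out["acc"] == pytest.approx(0.8)


def test_detection_auc_symmetry_under_inversion():
    labels = np.array([1, 0, 1, 0])
    probs = np.array([0.9, 0.2, 0.6, 0.4])
    a = evaluate_detection(labels, probs)["auc"]
    b = evaluate_detection(labels, 1 - probs)["auc"]
    assert a == pytest.approx(1 - b)


def test_perfect_probabilities_are_perfect_everywhere():
    labels = np.array([0, 1, 0, 1])
    out = evaluate_detection(labels, labels.astype(float))
    assert out["acc"] == out["sen"] == out["spe"] == out["auc"] == 1.0


# ----------------------------------------------------------------- LOOCV


def test_loocv_folds_partition_pairs():
    pairs = list("abcde")
    folds = loocv_folds(pairs)
    assert len(folds) == 5
    tests = [t for _, t in folds]
    assert sorted(tests) == sorted(pairs)
    for train, test in folds:
        assert test not in train and len(train) == 4
    with pytest.raises(ValueError):
        loocv_folds(["only"])


def test_cohort_mean_is_unweighted():
    assert np.mean([0.9, 1.0]) == pytest.approx(0.95)


# ----------------------------------------------------------------- sweep


@pytest.fixture(scope="module")
def sweep_streams():
    rng = np.random.default_rng(0)
    streams = {}
    for s in range(3):
        n = 600
        probs = rng.random(n) * 0.6
        probs[250:300] += 0.4  # a burst of positives
        streams[f"S{s}"] = {
            "probs": probs, "times": np.arange(n, dtype=float),
            "events": [SeizureEvent(400.0, 430.0)],
            "duration_hours": n / 3600.0,
        }
    return streams


def test_sweep_fpr_nonincreasing_in_k(sweep_streams):
    table = sweep_policy(sweep_streams, k_values=[1, 3, 5, 8, 10],
                         rp_values=[30.0])
    fpr = table.sort_values("k")["mean_fpr_h"].to_numpy()
    assert (np.diff(fpr) <= 1e-12).all()


def test_sweep_sen_nonincreasing_in_refractory(sweep_streams):
    table = sweep_policy(sweep_streams, k_values=[2],
                         rp_values=[0.0, 30.0, 120.0, 600.0])
    sen = table.sort_values("rp_s")["mean_sen"].to_numpy()
    assert (np.diff(sen) <= 1e-12).all()


def test_sweep_k1_rp0_fires_on_any_positive(sweep_streams):
    table = sweep_policy(sweep_streams, k_values=[1], rp_values=[0.0],
                         base_policy=AlarmPolicy(k=1, n=1))
    assert (table["mean_fpr_h"] > 0).all() or (table["mean_sen"] > 0).all()
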