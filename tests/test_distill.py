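"""Distillation losses against hand arithmetic; training-loop contracts."""

import math

import numpy as np
import pytest

from seizkd import nn
from seizkd.autodiff import Tensor
from seizkd.distill import (LossWeights, WindowStream, confidence_weights,
                            feature_alignment_loss, sample_teacher_pair,
                            soft_label_loss, temporal_consistency_loss,
                            total_loss, train_student, _np_softmax)
from seizkd.preprocess import EXCLUDED
from seizkd.student import StudentConfig
from seizkd.teachers import TeacherConfig, train_teacher

# ----------------------------------------------------------------- soft labels


def test_soft_label_loss_zero_when_matching_and_nonnegative():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(5, 2)).astype(np.float32)
    assert soft_label_loss(Tensor(logits), logits, tau=2.0).item() == \
        pytest.approx(0.0, abs=1e-6)
    other = rng.normal(size=(5, 2)).astype(np.float32)
    assert soft_label_loss(Tensor(logits), other, tau=2.0).item() >= 0.0


def test_soft_label_loss_hand_kl_value():
    """teacher (ln 3, 0) vs student (0, 0) at tau=1:
    KL((0.75,0.25)||(0.5,0.5)) = 0.75 ln 1.5 + 0.25 ln 0.5 ~= 0.1308."""
    teacher = np.array([[math.log(3.0), 0.0]], np.float32)
    student = Tensor(np.zeros((1, 2), np.float32))
    want = 0.75 * math.log(1.5) + 0.25 * math.log(0.5)
    assert soft_label_loss(student, teacher, tau=1.0).item() == \
        pytest.approx(want, abs=1e-5)


def test_soft_label_loss_at_unit_temperature_is_plain_kl():
    rng = np.random.default_rng(1)
    t_logits = rng.normal(size=(4, 2)).astype(np.float32)
    s_logits = rng.normal(size=(4, 2)).astype(np.float32)
    p_t, p_s = _np_softmax(t_logits), _np_softmax(s_logits)
    plain = (p_t * (np.log(p_t) - np.log(p_s))).sum(axis=1).mean()
    assert soft_label_loss(Tensor(s_logits), t_logits, tau=1.0).item() == \
        pytest.approx(plain, abs=1e-5)


# ----------------------------------------------------------------- alignment


def test_feature_alignment_mse_and_frozen_teacher():
    rng = np.random.default_rng(0)
    proj = nn.Linear(3, 3, rng)
    proj.weight.data = np.eye(3, dtype=np.float32)
    proj.bias.data = np.zeros(3, np.float32)
    v = rng.normal(size=(2, 3)).astype(np.float32)
    assert feature_alignment_loss(Tensor(v), v, proj).item() == \
        pytest.approx(0.0, abs=1e-6)
    loss = feature_alignment_loss(Tensor(v), v + 1.0, proj)
    assert loss.item() == pytest.approx(1.0, abs=1e-5)
    # teacher features enter as constants: gradient flows only to the
    # projection and the student feature
    student_feat = Tensor(v, requires_grad=True)
    feature_alignment_loss(student_feat, v + 1.0, proj).backward()
    assert student_feat.grad is not None and proj.weight.grad is not None


def test_feature_alignment_dim_mismatch_raises():
    rng = np.random.default_rng(0)
    proj = nn.Linear(3, 4, rng)
    with pytest.raises(ValueError):
        feature_alignment_loss(Tensor(np.zeros((2, 3), np.float32)),
                               np.zeros((2, 3), np.float32), proj)


# ----------------------------------------------------------------- time reg


def test_temporal_consistency_zero_offset_and_hand_value():
    p = np.array([0.1, 0.4, 0.2], np.float32)
    assert temporal_consistency_loss(Tensor(p), p).item() == \
        pytest.approx(0.0, abs=1e-7)
    # a constant offset changes no increment
    assert temporal_consistency_loss(Tensor(p + 0.3), p).item() == \
        pytest.approx(0.0, abs=1e-6)
    # teacher (0.1, 0.2), student (0.1, 0.1) -> ((0) - (0.1))^2 / 1 = 0.01
    got = temporal_consistency_loss(Tensor(np.array([0.1, 0.1], np.float32)),
                                    np.array([0.1, 0.2], np.float32))
    assert got.item() == pytest.approx(0.01, abs=1e-6)
    with pytest.raises(ValueError):
        temporal_consistency_loss(Tensor(np.array([0.1], np.float32)),
                                  np.array([0.1], np.float32))


# ----------------------------------------------------------------- confidence


def test_confidence_weights_examples():
    # equal logits -> raw confidence 0.5 at any temperature
    logits = np.zeros((1, 2), np.float32)
    conf = _np_softmax(logits, 2.0).max(axis=-1)
    assert conf[0] == pytest.approx(0.5)
    # identical samples -> all weights 1 after mean-1 rescale
    same = np.tile([[2.0, -1.0]], (4, 1)).astype(np.float32)
    assert np.allclose(confidence_weights(same), 1.0)
    # raw confidences (0.5, 1.0) -> weights (2/3, 4/3); build via logits
    logits = np.array([[0.0, 0.0], [40.0, -40.0]], np.float32)
    w = confidence_weights(logits, tau=1.0)
    assert np.allclose(w, [2 / 3, 4 / 3], atol=1e-3)


# ----------------------------------------------------------------- pairing


def test_sample_teacher_pair_uniform_and_seeded():
    rng = np.random.default_rng(0)
    assert sample_teacher_pair(["p"], ["d"], rng) == ("p", "d")
    counts = {}
    rng = np.random.default_rng(1)
    for _ in range(10_000):
        pair = sample_teacher_pair(["p0", "p1"], ["d0", "d1"], rng)
        counts[pair] = counts.get(pair, 0) + 1
    for c in counts.values():
        assert abs(c / 10_000 - 0.25) <= 0.02
    a = [sample_teacher_pair([0, 1], [0, 1], np.random.default_rng(5))
         for _ in range(1)]
    b = [sample_teacher_pair([0, 1], [0, 1], np.random.default_rng(5))
         for _ in range(1)]
    assert a == b
    with pytest.raises(ValueError):
        sample_teacher_pair([], ["d"], rng)


# ----------------------------------------------------------------- total loss


def _outputs(n, h=4, seed=0):
    rng = np.random.default_rng(seed)
    return {
        "logits_det": Tensor(rng.normal(size=(n, 2)).astype(np.float32)),
        "logits_pred": Tensor(rng.normal(size=(n, 2)).astype(np.float32)),
        "det_feature": Tensor(rng.normal(size=(n, h)).astype(np.float32)),
        "pred_feature": Tensor(rng.normal(size=(n, h)).astype(np.float32)),
        "film_pred_gamma": None, "film_pred_beta": None,
        "pred_prob_seq": None,
    }


def test_total_loss_reduces_to_supervised_sum_without_kd():
    outputs = _outputs(6)
    det = np.array([0, 1, 0, 1, 0, 1])
    pred = np.array([1, 0, 1, 0, 1, 0])
    w = LossWeights(alpha=1.0, beta=0.0, gamma=0.0, prior_reg_w=0.0)
    loss, report = total_loss(outputs, {}, det, pred, w)
    ce = nn.cross_entropy(outputs["logits_det"], det).item() + \
        nn.cross_entropy(outputs["logits_pred"], pred).item()
    assert loss.item() == pytest.approx(ce, abs=1e-5)


def test_total_loss_masks_prediction_terms_exactly():
    outputs = _outputs(4)
    det = np.array([0, 1, 0, 1])
    pred = np.full(4, EXCLUDED)
    t_out = {"prediction": (np.zeros((4, 2), np.float32),
                            np.zeros((4, 4), np.float32))}
    loss, report = total_loss(outputs, t_out, det, pred, LossWeights())
    assert report["ce_pred"] == 0.0
    assert report["kd_pred"] == 0.0
    assert report["time_reg"] == 0.0


def test_total_loss_weighted_sum_matches_hand_arithmetic():
    outputs = _outputs(1)
    det = np.array([1])
    pred = np.array([0])
    t_logits = np.array([[0.4, -0.2]], np.float32)
    t_out = {"detection": (t_logits, None), "prediction": (t_logits, None)}
    w = LossWeights(alpha=1.0, beta=0.5, gamma=0.1, prior_reg_w=0.0)
    loss, report = total_loss(outputs, t_out, det, pred, w)
    want = (report["ce_det"] + report["ce_pred"]) + \
        0.5 * (report["kd_det"] + report["kd_pred"]) + 0.1 * report["time_reg"]
    assert loss.item() == pytest.approx(want, abs=1e-5)


# ----------------------------------------------------------------- training


def _streams_for_training(seed=0):
    rng = np.random.default_rng(seed)
    n = 150
    x = rng.normal(size=(n, 3, 512)).astype(np.float32)
    det = np.zeros(n, np.int64)
    pred = np.zeros(n, np.int64)
    det[100:130] = 1          # an "ictal" stretch
    pred[20:80] = 1           # a "preictal" stretch
    x[det == 1] *= 4.0
    x[pred == 1] *= 2.0
    starts = np.arange(n, dtype=float)
    return [WindowStream(x=x, det=det, pred=pred, starts=starts)]


def test_train_student_smoke_and_history():
    streams = _streams_for_training()
    cfg = StudentConfig(n_channels=3)
    student, history = train_student(streams, None, cfg, LossWeights(),
                                     mode="none", lr=0.003,
                                     window_batches_per_epoch=2,
                                     chunk_batches_per_epoch=1, chunk_len=16,
                                     max_epochs=2, patience=2, seed=0)
    assert len(history) == 2
    assert all(np.isfinite(h["val_loss"]) for h in history)
    assert {"ce_det", "ce_pred", "total"} <= set(history[0])


def test_train_student_is_deterministic_given_seed():
    streams = _streams_for_training()
    cfg = StudentConfig(n_channels=3)
    kwargs = dict(mode="none", lr=0.003, window_batches_per_epoch=2,
                  chunk_batches_per_epoch=1, chunk_len=16, max_epochs=2,
                  patience=2, seed=9)
    s1, _ = train_student(streams, None, cfg, LossWeights(), **kwargs)
    s2, _ = train_student(streams, None, cfg, LossWeights(), **kwargs)
    for (k1, p1), (k2, p2) in zip(sorted(s1.state_dict().items()),
                                  sorted(s2.state_dict().items())):
        assert k1 == k2 and np.array_equal(p1, p2)


def test_early_stopping_halts_when_validation_cannot_improve():
    """With a zero learning rate the validation loss never decreases, so
    training stops after `patience` stale epochs and keeps epoch-0 weights."""
    streams = _streams_for_training()
    cfg = StudentConfig(n_channels=3)
    student, history = train_student(streams, None, cfg, LossWeights(),
                                     mode="none", lr=0.0,
                                     window_batches_per_epoch=1,
                                     chunk_batches_per_epoch=1, chunk_len=16,
                                     max_epochs=20, patience=3, seed=1)
    assert len(history) == 4  # epoch 0 best, then 3 stale epochs
    vals = [h["val_loss"] for h in history]
    assert all(v == pytest.approx(vals[0], rel=1e-6) for v in vals)


def test_frozen_teacher_checksum_constant_through_distillation():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(120, 3, 512)).astype(np.float32)
    y = rng.integers(0, 2, 120)
    x[y == 1] *= 3.0
    tcfg = TeacherConfig(task="detection", n_channels=3, window_samples=512,
                         n_tokens=8, d_model=16, seed=0)
    teacher, _ = train_teacher(x, y, "detection", tcfg, seed=0, max_epochs=2)
    before = teacher.checksum()
    streams = _streams_for_training()
    train_student(streams, {"detection": [teacher]},
                  StudentConfig(n_channels=3), LossWeights(),
                  mode="single_det", lr=0.003, window_batches_per_epoch=2,
                  chunk_batches_per_epoch=1, chunk_len=16, max_epochs=2,
                  patience=2, seed=3)
    assert teacher.checksum() == before


def test_multi_mode_requires_both_pools():
    with pytest.raises(ValueError):
        train_student(_streams_for_training(), {}, StudentConfig(n_channels=3),
                      LossWeights(), mode="multi")
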