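"""Multi-teacher knowledge distillation for the streaming student.

The training objective combines, with fixed weights,

``L = alpha*(CE_det + CE_pred) + beta*(KD_det + KD_pred) + gamma*TimeReg``

where each KD term is temperature-softened soft-label KL (scaled by tau^2)
plus an intermediate feature-alignment MSE on the corresponding post-FiLM
branch feature, down-weighted per sample by teacher confidence; TimeReg
matches the student's prediction-probability *increments* to the teacher's
over short chronological chunks; and an L2 amplitude penalty keeps the
prior-conditioned FiLM coefficients small.  One prediction teacher and one
detection teacher are sampled uniformly per mini-batch; teachers are frozen
and never receive gradients.

Training data is consumed as chronological window streams.  Each epoch
mixes class-balanced window batches (fresh stream state, diverse samples)
with chunks of consecutive windows whose recurrent state is carried
causally across the chunk (gradients truncated at each window boundary);
the chunks supply the temporal-consistency sequences and expose the heads
to evolved ring-buffer/GRU states.  Balancing applies to the training
portion only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad
from .preprocess import EXCLUDED, LabeledWindow
from .student import StudentConfig, StudentModel, StreamState
from .teachers import class_weights

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "WindowStream",
    "soft_label_loss",
    "feature_alignment_loss",
    "temporal_consistency_loss",
    "confidence_weights",
    "total_loss",
    "sample_teacher_pair",
    "train_student",
]


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0        # supervision
    beta: float = 0.5         # distillation
    gamma: float = 0.1        # temporal consistency
    tau: float = 2.0          # distillation temperature
    align_w: float = 0.5      # feature-alignment sub-weight inside KD
    prior_reg_w: float = 1e-4  # amplitude regularisation of prior FiLM coeffs

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.align_w, self.prior_reg_w) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class WindowStream:
    """Chronological, contiguous window stream of one subject segment."""

    x: np.ndarray          # (N, C, T)
    det: np.ndarray        # (N,) {0,1}
    pred: np.ndarray       # (N,) {0,1} or EXCLUDED
    starts: np.ndarray     # (N,) seconds

    @classmethod
    def from_labeled(cls, windows: list[LabeledWindow]) -> "WindowStream":
        return cls(
            x=np.stack([np.asarray(w.data, np.float32) for w in windows]),
            det=np.array([w.det_label for w in windows], np.int64),
            pred=np.array([w.pred_label for w in windows], np.int64),
            starts=np.array([w.start for w in windows], np.float64),
        )

    def __len__(self):
        return len(self.x)


# ----------------------------------------------------------------- losses


def _np_softmax(logits: np.ndarray, tau: float = 1.0) -> np.ndarray:
    z = np.asarray(logits, np.float64) / tau
    z -= z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_label_loss(student_logits: Tensor, teacher_logits: np.ndarray,
                    tau: float = 2.0,
                    sample_weights: np.ndarray | None = None) -> Tensor:
    """KL(softmax(teacher/tau) || softmax(student/tau)) * tau^2, averaged
    with optional per-sample weights.  The tau^2 factor keeps the gradient
    magnitude comparable across temperatures."""
    p_t = _np_softmax(teacher_logits, tau)
    logp_t = np.log(np.clip(p_t, 1e-12, None))
    logp_s = nn.log_softmax(student_logits * (1.0 / tau), axis=-1)
    kl = (Tensor(p_t.astype(np.float32)) * (Tensor(logp_t.astype(np.float32)) - logp_s)
          ).sum(axis=-1) * (tau ** 2)
    if sample_weights is None:
        return kl.mean()
    w = Tensor(np.asarray(sample_weights, np.float32))
    return (kl * w).sum() / float(len(p_t))


def feature_alignment_loss(student_feature: Tensor, teacher_penultimate: np.ndarray,
                           projection: nn.Linear) -> Tensor:
    """MSE between the student branch feature and the (trainable) linear
    projection of the frozen teacher's penultimate feature."""
    target = projection(Tensor(np.asarray(teacher_penultimate, np.float32)))
    if target.shape != student_feature.shape:
        raise ValueError(
            f"projected teacher feature {target.shape} does not match "
            f"student feature {student_feature.shape}"
        )
    diff = student_feature - target
    return (diff * diff).mean()


def temporal_consistency_loss(student_probs: Tensor, teacher_probs: np.ndarray
                              ) -> Tensor:
    """Mean squared mismatch of successive probability increments:
    (1/(T-1)) sum_t ((p^_{t+1}-p^_t) - (p_{t+1}-p_t))^2.

    Accepts (T,) sequences or (B, T) batches of sequences (mean over B).
    Depends only on increments, so a constant offset between student and
    teacher incurs no penalty.
    """
    t_len = student_probs.shape[-1]
    if t_len < 2:
        raise ValueError("temporal consistency needs at least two time steps")
    d_s = student_probs[..., 1:] - student_probs[..., :-1]
    d_t = np.asarray(teacher_probs, np.float32)[..., 1:] - \
        np.asarray(teacher_probs, np.float32)[..., :-1]
    diff = d_s - Tensor(d_t)
    return (diff * diff).sum(axis=-1).mean() * (1.0 / (t_len - 1))


def confidence_weights(teacher_logits: np.ndarray, tau: float = 2.0) -> np.ndarray:
    """Per-sample weight = max softmax(teacher/tau) probability, rescaled to
    mean 1 over the batch (low-confidence teacher outputs are down-weighted)."""
    conf = _np_softmax(teacher_logits, tau).max(axis=-1)
    return (conf / conf.mean()).astype(np.float32)


def sample_teacher_pair(pred_pool: list, det_pool: list,
                        rng: np.random.Generator) -> tuple:
    """Uniform independent draw of one (prediction, detection) teacher pair."""
    if not pred_pool or not det_pool:
        raise ValueError("teacher pools must be non-empty")
    return (pred_pool[rng.integers(len(pred_pool))],
            det_pool[rng.integers(len(det_pool))])


def total_loss(outputs: dict, teacher_outputs: dict, det_labels: np.ndarray,
               pred_labels: np.ndarray, weights: LossWeights,
               projections: dict | None = None,
               det_class_weights: np.ndarray | None = None
               ) -> tuple[Tensor, dict]:
    """Assemble the composite objective; returns (loss, component report).

    `outputs` carries flat per-window tensors: ``logits_det``, ``logits_pred``,
    ``det_feature``, ``pred_feature``, optionally ``pred_prob_seq`` (B, T)
    with ``teacher_pred_prob_seq`` alongside, and ``film_pred_gamma/beta``.
    `teacher_outputs` maps task -> (logits, penultimate) numpy pairs (or is
    missing the task when no teacher covers it).  Windows with
    ``pred_labels == EXCLUDED`` contribute zero to every prediction term.
    """
    report: dict[str, float] = {}
    zero = Tensor(np.zeros(()))
    pred_mask = np.asarray(pred_labels) != EXCLUDED

    ce_det = nn.cross_entropy(
        outputs["logits_det"], det_labels,
        det_class_weights[det_labels] if det_class_weights is not None else None)
    ce_pred = zero
    if pred_mask.any():
        ce_pred = nn.cross_entropy(outputs["logits_pred"][pred_mask],
                                   np.asarray(pred_labels)[pred_mask])
    report["ce_det"], report["ce_pred"] = ce_det.item(), ce_pred.item()

    kd_det = kd_pred = zero
    if "detection" in teacher_outputs:
        t_logits, t_penult = teacher_outputs["detection"]
        w = confidence_weights(t_logits, weights.tau)
        kd_det = soft_label_loss(outputs["logits_det"], t_logits, weights.tau, w)
        if projections and "detection" in projections:
            kd_det = kd_det + weights.align_w * feature_alignment_loss(
                outputs["det_feature"], t_penult, projections["detection"])
    if "prediction" in teacher_outputs and pred_mask.any():
        t_logits, t_penult = teacher_outputs["prediction"]
        w = confidence_weights(t_logits[pred_mask], weights.tau)
        kd_pred = soft_label_loss(outputs["logits_pred"][pred_mask],
                                  t_logits[pred_mask], weights.tau, w)
        if projections and "prediction" in projections:
            kd_pred = kd_pred + weights.align_w * feature_alignment_loss(
                outputs["pred_feature"][pred_mask], t_penult[pred_mask],
                projections["prediction"])
    report["kd_det"], report["kd_pred"] = kd_det.item(), kd_pred.item()

    time_reg = zero
    if ("pred_prob_seq" in outputs and outputs["pred_prob_seq"] is not None
            and pred_mask.any()):
        time_reg = temporal_consistency_loss(outputs["pred_prob_seq"],
                                             outputs["teacher_pred_prob_seq"])
    report["time_reg"] = time_reg.item()

    prior_reg = zero
    if outputs.get("film_pred_gamma") is not None:
        g, b = outputs["film_pred_gamma"], outputs["film_pred_beta"]
        prior_reg = (g * g).sum() * (1.0 / g.shape[0]) + \
                    (b * b).sum() * (1.0 / b.shape[0])
    report["prior_reg"] = prior_reg.item()

    loss = (weights.alpha * (ce_det + ce_pred)
            + weights.beta * (kd_det + kd_pred)
            + weights.gamma * time_reg
            + weights.prior_reg_w * prior_reg)
    report["total"] = loss.item()
    return loss, report


# ------------------------------------------------------------ training loop



# ------------------------------------------------------------ training loop


def _sequence_pools(stream_ids: np.ndarray, det: np.ndarray, pred: np.ndarray,
                    seq_len: int, stride: int) -> tuple[list, list, list]:
    """Start indices of `seq_len`-window contiguous runs, grouped into
    ictal-containing, preictal-containing and negative pools."""
    pools: tuple[list, list, list] = ([], [], [])
    n = len(det)
    for s in range(0, n - seq_len + 1, stride):
        if stream_ids[s] != stream_ids[s + seq_len - 1]:
            continue  # runs must not cross a stream boundary
        sl = slice(s, s + seq_len)
        if (det[sl] == 1).any():
            pools[0].append(s)
        elif (pred[sl] == 1).any():
            pools[1].append(s)
        else:
            pools[2].append(s)
    return pools



def train_student(streams: list[WindowStream],
                  teachers: dict[str, list] | None,
                  cfg: StudentConfig = StudentConfig(),
                  weights: LossWeights = LossWeights(),
                  *, mode: str = "multi", lr: float = 0.01,
                  window_batches_per_epoch: int = 8, window_batch_size: int = 32,
                  chunk_batches_per_epoch: int = 2, chunk_len: int = 64,
                  max_epochs: int = 5, patience: int = 5,
                  max_val_chunks: int = 4, seed: int = 0,
                  model: StudentModel | None = None, restore_best: bool = True
                  ) -> tuple[StudentModel, list[dict]]:
    """Distil the student from frozen teachers on chronological streams.

    `mode`: "multi" (one teacher per task), "single_pred" / "single_det"
    (one teacher, KD only for the covered task), or "none" (plain
    supervised training).

    Each epoch mixes two batch kinds.  *Window batches* are class-balanced
    draws of single windows, each processed from a fresh stream state whose
    FiLM conditioning scalars (previous detection probability, SFPM prior)
    are drawn uniformly -- on contiguous streams their true values correlate
    with the labels, and training on them would let the modulation
    generators latch onto the feedback signal instead of the EEG.  *Stream
    chunks* are `chunk_len`-window contiguous runs whose recurrent state is
    carried causally across the chunk (gradients truncated at each window
    boundary); they expose the heads to evolved GRU/ring-buffer states and
    carry the temporal-consistency term.  Chunk gradients are computed by
    recording the per-step state constants in a tape-free pass and
    rebuilding all steps in one differentiable batch (exact under the
    truncation).  Early stopping tracks the supervised loss component on
    the chronologically last quarter of each chunk pool; the best-epoch
    weights are restored.
    """
    if mode not in ("multi", "single_pred", "single_det", "none"):
        raise ValueError(f"unknown distillation mode {mode!r}")
    teachers = teachers or {}
    pred_pool = teachers.get("prediction", []) if mode in ("multi", "single_pred") else []
    det_pool = teachers.get("detection", []) if mode in ("multi", "single_det") else []
    if mode == "multi" and (not pred_pool or not det_pool):
        raise ValueError("multi-teacher mode needs both teacher pools")

    x = np.concatenate([st.x for st in streams])
    det = np.concatenate([st.det for st in streams])
    pred = np.concatenate([st.pred for st in streams])
    stream_ids = np.concatenate([np.full(len(st), i) for i, st in enumerate(streams)])

    rng = np.random.default_rng(seed)
    if model is None:
        model = StudentModel(cfg, seed=int(rng.integers(2**31 - 1)))
    opt = nn.Adam(model.parameters(), lr=lr)
    val_weights = LossWeights(alpha=weights.alpha, beta=0.0,
                              gamma=weights.gamma, tau=weights.tau,
                              align_w=0.0, prior_reg_w=weights.prior_reg_w)

    projections: dict[str, dict[int, nn.Linear]] = {"prediction": {}, "detection": {}}

    def proj_for(task: str, teacher) -> nn.Linear:
        key = id(teacher)
        if key not in projections[task]:
            proj = nn.Linear(teacher.cfg.d_model, cfg.gru_hidden, rng)
            projections[task][key] = proj
            opt.params.extend(proj.parameters())
            opt.m.extend(np.zeros_like(p.data) for p in proj.parameters())
            opt.v.extend(np.zeros_like(p.data) for p in proj.parameters())
        return projections[task][key]

    # teachers are frozen: their per-window outputs are constants, cached once
    _teacher_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def teacher_outputs_for(teacher) -> tuple[np.ndarray, np.ndarray]:
        key = id(teacher)
        if key not in _teacher_cache:
            logits = np.zeros((len(x), 2), np.float32)
            penult = None
            with no_grad():
                for lo in range(0, len(x), 256):
                    t_out = teacher(x[lo:lo + 256])
                    if penult is None:
                        penult = np.zeros((len(x), t_out.penultimate.shape[-1]),
                                          np.float32)
                    logits[lo:lo + 256] = t_out.logits.data
                    penult[lo:lo + 256] = t_out.penultimate.data
            _teacher_cache[key] = (logits, penult)
        return _teacher_cache[key]

    # ---------------- chunk pools with a stratified validation hold-out
    pool_d, pool_p, pool_n = _sequence_pools(stream_ids, det, pred,
                                             chunk_len, chunk_len // 2)
    if not (pool_d or pool_p or pool_n):
        raise ValueError("streams too short to form any training chunk")
    val_chunks: list[int] = []
    chunk_pools: list[list[int]] = []
    for pool in (pool_p, pool_d, pool_n):
        if not pool:
            continue
        n_val = max(len(pool) // 4, 1) if len(pool) > 1 else 0
        if n_val:
            val_chunks.extend(pool[-n_val:])
            pool = pool[:-n_val]
        if pool:
            chunk_pools.append(pool)
    val_chunks.sort()
    if not chunk_pools:
        raise ValueError("no training chunks left after the validation split")
    if len(val_chunks) > max_val_chunks:
        keep = np.linspace(0, len(val_chunks) - 1, max_val_chunks).round().astype(int)
        val_chunks = [val_chunks[i] for i in keep]

    # window-level class pools, excluding windows covered by validation chunks
    val_mask = np.zeros(len(x), bool)
    for s in val_chunks:
        val_mask[s:s + chunk_len] = True
    w_det_pos = np.flatnonzero((det == 1) & ~val_mask)
    w_pred_pos = np.flatnonzero((pred == 1) & ~val_mask)
    w_neg = np.flatnonzero((det == 0) & (pred == 0) & ~val_mask)

    det_cw = class_weights(det) if len(np.unique(det)) == 2 else None

    # ---------------- batch execution
    def sample_pair() -> dict:
        pair = {}
        if pred_pool:
            pair["prediction"] = pred_pool[rng.integers(len(pred_pool))]
        if det_pool:
            pair["detection"] = det_pool[rng.integers(len(det_pool))]
        return pair

    def initial_state(batch: int, training: bool) -> StreamState:
        state = StreamState.fresh(cfg, batch=batch)
        if training:
            state.prev_det = rng.random(batch).astype(np.float32)
            state.s = rng.random(batch).astype(np.float32)
        return state

    def run_window_batch(idx: np.ndarray, training: bool,
                         loss_weights: LossWeights | None = None):
        pair = sample_pair()
        t_out = {task: tuple(arr[idx] for arr in teacher_outputs_for(t))
                 for task, t in pair.items()}
        feats = model.encode_windows(x[idx], rng, training)
        _, out = model.recurrent_step(feats, initial_state(len(idx), training))
        outputs = {
            "logits_det": out.logits_det, "logits_pred": out.logits_pred,
            "det_feature": out.det_feature, "pred_feature": out.pred_feature,
            "film_pred_gamma": out.film_pred_gamma,
            "film_pred_beta": out.film_pred_beta, "pred_prob_seq": None,
        }
        proj = {task: proj_for(task, t) for task, t in pair.items()}
        return total_loss(outputs, t_out, det[idx], pred[idx],
                          loss_weights or weights, projections=proj,
                          det_class_weights=det_cw)

    def run_chunk_batch(chunk_starts: list[int], training: bool,
                        loss_weights: LossWeights | None = None):
        idx = np.concatenate([np.arange(s, s + chunk_len) for s in chunk_starts])
        b = len(chunk_starts)
        pair = sample_pair()
        t_out = {task: tuple(arr[idx] for arr in teacher_outputs_for(t))
                 for task, t in pair.items()}
        feats = model.encode_windows(x[idx], rng, training)
        _, consts = model.unroll_constants(
            feats.data.reshape(b, chunk_len, cfg.d_model),
            initial_state(b, training))
        out = model.batched_step(feats, {k: v.reshape(b * chunk_len, -1)
                                         for k, v in consts.items()})
        outputs = {
            "logits_det": out.logits_det, "logits_pred": out.logits_pred,
            "det_feature": out.det_feature, "pred_feature": out.pred_feature,
            "film_pred_gamma": out.film_pred_gamma,
            "film_pred_beta": out.film_pred_beta, "pred_prob_seq": None,
        }
        if "prediction" in t_out:
            outputs["pred_prob_seq"] = \
                nn.softmax(out.logits_pred, axis=-1)[:, 1].reshape(b, chunk_len)
            t_probs = _np_softmax(t_out["prediction"][0]).astype(np.float32)[:, 1]
            outputs["teacher_pred_prob_seq"] = t_probs.reshape(b, chunk_len)
        proj = {task: proj_for(task, t) for task, t in pair.items()}
        return total_loss(outputs, t_out, det[idx], pred[idx],
                          loss_weights or weights, projections=proj,
                          det_class_weights=det_cw)

    def draw_window_batch() -> np.ndarray:
        quarter = max(window_batch_size // 4, 1)
        parts = []
        if len(w_det_pos):
            parts.append(rng.choice(w_det_pos, quarter))
        if len(w_pred_pos):
            parts.append(rng.choice(w_pred_pos, quarter))
        n_rest = window_batch_size - sum(len(p) for p in parts)
        parts.append(rng.choice(w_neg if len(w_neg) else np.arange(len(x)), n_rest))
        return np.concatenate(parts)

    history: list[dict] = []
    best = (np.inf, None)
    bad = 0
    for epoch in range(max_epochs):
        epoch_chunks = [
            int(chunk_pools[i % len(chunk_pools)][
                rng.integers(len(chunk_pools[i % len(chunk_pools)]))])
            for i in range(chunk_batches_per_epoch)
        ]
        plans: list[tuple[str, object]] = [
            ("window", draw_window_batch())
            for _ in range(window_batches_per_epoch)
        ]
        if epoch_chunks:
            plans.append(("chunk", epoch_chunks))
        comp_sums: dict[str, float] = {}
        for kind, batch in plans:
            if kind == "window":
                loss, report = run_window_batch(batch, True)
            else:
                loss, report = run_chunk_batch(batch, True)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {report}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in report.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + v
        # model selection tracks the supervised part of the objective; the
        # distillation terms measure teacher match, not generalisation
        with no_grad():
            val_loss = run_chunk_batch(val_chunks, False,
                                       loss_weights=val_weights)[0].item()
        entry = {k: v / max(len(plans), 1) for k, v in comp_sums.items()}
        entry.update(epoch=epoch, val_loss=val_loss)
        history.append(entry)
        logger.info("epoch %d: %s", epoch,
                    {k: round(v, 4) for k, v in entry.items() if k != "epoch"})
        if val_loss < best[0]:
            best = (val_loss, model.state_dict())
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    if restore_best and best[1] is not None:
        model.load_state_dict(best[1])
    return model, history
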