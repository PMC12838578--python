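"""The causal streaming student network for joint seizure detection/prediction.

Architecture, per 2-s window (one step of the 1-Hz stream):

1. **Conv front end** -- a depthwise (k=3) + pointwise stem expanding the
   multichannel input to 16 feature maps, then two inverted-residual MBConv
   blocks (expand x4, depthwise k=3, compress) to 24 and 32 channels.  Time
   length is preserved (same padding).
2. **Rate-aware tokenisation + Transformer** -- average-pool time with a
   stride of ``fs*win/64`` so every window becomes exactly 64 tokens at any
   sampling rate, project to ``d_model``, add fixed sinusoidal positions,
   run a 2-layer / 4-head / feed-forward-128 encoder, and mean-pool the
   tokens into the window feature ``F_t``.
3. **GRU memory** -- ``F_t`` drives a GRU whose hidden state accumulates
   context across windows.
4. **Ring buffer** -- the current hidden state is written into a circular
   buffer of length ``L`` (pointer advances modulo L, oldest slot
   overwritten; at stream start all L slots are cold-start-filled), and the
   uniform mean of the stored states forms the temporal summary.
5. **FiLM task modulation** -- the detection branch modulates the summary
   with per-channel scale/shift generated from the previous detection
   probability; the prediction branch is conditioned on the self-feedback
   prior ``s_t`` (exponentially smoothed detection probability, stop-
   gradient) through ``(1 + gamma) * h + beta``.  Both generators are
   zero-initialised so an untrained model starts at the exact identity.
6. **Heads** -- one 2-logit softmax head per task.

Strict causality: every quantity at step ``t`` depends only on windows
``<= t``, and per-step cost is independent of stream length.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad
from .preprocess import stride_for_rate

__all__ = [
    "StudentConfig",
    "StreamState",
    "StudentOutput",
    "StudentModel",
    "ring_update",
    "sfpm_update",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class StudentConfig:
    n_channels: int = 22
    fs: float = 256.0
    win_len: float = 2.0
    stem_out: int = 16
    mbconv_out: tuple[int, int] = (24, 32)
    expansion: int = 4
    d_model: int = 64
    n_layers: int = 2
    ff_dim: int = 128
    n_heads: int = 4
    dropout: float = 0.1
    gru_hidden: int = 32
    buffer_len: int = 10
    sfpm_lambda: float = 0.9
    film_hidden: int = 16

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be >= 1")
        if not 0.0 <= self.sfpm_lambda <= 1.0:
            raise ValueError("sfpm_lambda must lie in [0, 1]")

    @property
    def window_samples(self) -> int:
        return int(round(self.fs * self.win_len))

    @property
    def stride(self) -> int:
        return stride_for_rate(self.fs, self.win_len)


@dataclass
class StreamState:
    """Mutable causal runtime state for one (batch of) stream(s)."""

    buffer: np.ndarray      # (B, L, H) stored hidden states
    pointer: int
    h: np.ndarray           # (B, H) GRU hidden
    s: np.ndarray | None    # (B,) SFPM prior; None before the first window
    prev_det: np.ndarray    # (B,) previous detection probability
    step: int

    @classmethod
    def fresh(cls, cfg: StudentConfig, batch: int = 1) -> "StreamState":
        return cls(
            buffer=np.zeros((batch, cfg.buffer_len, cfg.gru_hidden), np.float32),
            pointer=0,
            h=np.zeros((batch, cfg.gru_hidden), np.float32),
            s=None,
            prev_det=np.full(batch, 0.5, np.float32),
            step=0,
        )


@dataclass
class StudentOutput:
    y_det: np.ndarray          # (B,) detection probability
    y_pred: np.ndarray         # (B,) prediction probability
    logits_det: Tensor
    logits_pred: Tensor
    det_feature: Tensor        # D_t, post-FiLM detection feature
    pred_feature: Tensor       # h~_t^pred, post-FiLM prediction feature
    s: np.ndarray              # (B,) SFPM value used for this step
    warm_up: bool
    film_pred_gamma: Tensor = None
    film_pred_beta: Tensor = None


def ring_update(state: StreamState, h_t: np.ndarray
                ) -> tuple[StreamState, np.ndarray]:
    """Write h_t (B, H) into the ring buffer and read the uniform-mean
    summary of the stored states.

    The pointer advances modulo L, overwriting the oldest slot; on the
    first write after a reset every slot is filled with h_t (cold-start
    fill).  Per-step cost is independent of stream length.
    """
    h_t = np.asarray(h_t, np.float32)
    buffer = state.buffer.copy()
    if state.step == 0:
        buffer[:] = h_t[:, None, :]
    else:
        buffer[:, state.pointer, :] = h_t
    new_state = StreamState(
        buffer=buffer,
        pointer=(state.pointer + 1) % buffer.shape[1],
        h=h_t.copy(), s=state.s, prev_det=state.prev_det,
        step=state.step + 1,
    )
    return new_state, buffer.mean(axis=1)


def _np_prob1(logits: np.ndarray) -> np.ndarray:
    """Probability of class 1 from 2-class logits (plain numpy)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return (e[:, 1] / e.sum(axis=-1)).astype(np.float32)


def sfpm_update(s_prev: np.ndarray | float, y_det: np.ndarray | float,
                lam: float) -> np.ndarray:
    """Exponential smoothing of the detection probability (self-feedback
    prior): s_t = lam*s_{t-1} + (1-lam)*y_det, clipped to [0, 1]."""
    s = lam * np.asarray(s_prev, np.float32) + (1.0 - lam) * np.asarray(y_det, np.float32)
    return np.clip(s, 0.0, 1.0)


class _MBConv(nn.Module):
    """Inverted residual: 1x1 expand, depthwise k=3, 1x1 compress, residual."""

    def __init__(self, c_in: int, c_out: int, expansion: int, rng):
        c_mid = c_in * expansion
        self.expand = nn.Linear(c_in, c_mid, rng)
        self.depthwise = nn.DepthwiseConv1d(c_mid, 3, rng)
        self.compress = nn.Linear(c_mid, c_out, rng)
        self.residual = c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:  # (B, T, C_in)
        z = self.expand(x).relu()
        z = self.depthwise(z).relu()
        z = self.compress(z)
        return x + z if self.residual else z


class _FiLMGenerator(nn.Module):
    """Scalar condition -> per-channel (gamma, beta); zero-initialised final
    layer so the modulation starts as the exact identity."""

    def __init__(self, hidden: int, n_out: int, rng):
        self.fc1 = nn.Linear(1, hidden, rng)
        self.fc2 = nn.Linear(hidden, 2 * n_out, rng, zero_init=True)
        self.n_out = n_out

    def __call__(self, cond: Tensor) -> tuple[Tensor, Tensor]:
        z = self.fc2(self.fc1(cond).tanh())
        return z[..., : self.n_out], z[..., self.n_out:]


class StudentModel(nn.Module):
    def __init__(self, cfg: StudentConfig = StudentConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        c1, c2 = cfg.mbconv_out
        self.stem_dw = nn.DepthwiseConv1d(cfg.n_channels, 3, rng)
        self.stem_pw = nn.Linear(cfg.n_channels, cfg.stem_out, rng)
        self.mbconv1 = _MBConv(cfg.stem_out, c1, cfg.expansion, rng)
        self.mbconv2 = _MBConv(c1, c2, cfg.expansion, rng)
        self.token_proj = nn.Linear(c2, cfg.d_model, rng)
        self.layers = [
            nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads, cfg.ff_dim,
                                       cfg.dropout, rng, attn_bias=False)
            for _ in range(cfg.n_layers)
        ]
        self.gru = nn.GRUCell(cfg.d_model, cfg.gru_hidden, rng)
        self.film_det = _FiLMGenerator(cfg.film_hidden, cfg.gru_hidden, rng)
        self.film_pred = _FiLMGenerator(cfg.film_hidden, cfg.gru_hidden, rng)
        self.head_det = nn.Linear(cfg.gru_hidden, 2, rng)
        self.head_pred = nn.Linear(cfg.gru_hidden, 2, rng)
        self._posenc = nn.sinusoidal_positions(64, cfg.d_model)

    # ------------------------------------------------------------- per window
    def conv_front_end(self, x: Tensor) -> Tensor:
        """(B, T, C_in) microvolt windows -> (B, T, 32) feature maps."""
        z = self.stem_pw(self.stem_dw(x))
        return self.mbconv2(self.mbconv1(z))

    def transformer_encode(self, feats: Tensor, rng=None,
                           training: bool = False) -> Tensor:
        """(B, T, 32) -> (B, d_model) window feature F_t (64 tokens)."""
        tokens = nn.avg_pool_tokens(feats, self.cfg.stride)
        tokens = self.token_proj(tokens) + Tensor(self._posenc)
        for layer in self.layers:
            tokens = layer(tokens, rng, training)
        return tokens.mean(axis=1)

    def encode_windows(self, windows: np.ndarray, rng=None,
                       training: bool = False) -> Tensor:
        """Raw windows (B, C, T) -> window features (B, d_model)."""
        windows = np.asarray(windows, np.float32)
        if windows.ndim == 2:
            windows = windows[None]
        if windows.shape[1] != self.cfg.n_channels or \
                windows.shape[2] != self.cfg.window_samples:
            raise ValueError(
                f"window shape {windows.shape[1:]} does not match config "
                f"({self.cfg.n_channels}, {self.cfg.window_samples})"
            )
        x = Tensor(np.swapaxes(windows, 1, 2))  # (B, T, C)
        return self.transformer_encode(self.conv_front_end(x), rng, training)

    # ------------------------------------------------------------- recurrence
    def film_modulate(self, summary: Tensor, prev_det: np.ndarray,
                      s_t: np.ndarray) -> tuple[Tensor, Tensor]:
        """Task-specific FiLM of the temporal summary: the detection branch
        is conditioned on the previous detection probability, the
        prediction branch on the SFPM prior (both enter as constants, so
        no gradient reaches the detection branch through the prior)."""
        gamma_d, beta_d = self.film_det(Tensor(np.asarray(prev_det,
                                                          np.float32)[:, None]))
        det_feat = (1.0 + gamma_d) * summary + beta_d
        gamma_p, beta_p = self.film_pred(Tensor(np.asarray(s_t,
                                                           np.float32)[:, None]))
        pred_feat = (1.0 + gamma_p) * summary + beta_p
        return det_feat, pred_feat

    def recurrent_step(self, f_t: Tensor, state: StreamState
                       ) -> tuple[StreamState, StudentOutput]:
        """One causal step given window feature F_t (B, d_model).

        The recurrent state (GRU hidden, ring buffer, SFPM, previous
        detection probability) enters as a constant, so gradients are
        truncated at the window boundary (TBPTT horizon 1); within the step
        everything downstream of F_t is differentiable.
        """
        cfg = self.cfg
        L = cfg.buffer_len
        h_t = self.gru(f_t, Tensor(state.h))

        # ring buffer write + uniform-mean read; on the first write after a
        # reset every slot receives h_t (cold-start fill)
        if state.step == 0:
            n_current = L
            rest = np.zeros_like(state.h)
        else:
            n_current = 1
            rest = state.buffer.sum(axis=1) - state.buffer[:, state.pointer, :]
        summary = h_t * (n_current / L) + Tensor(rest / L)

        # detection branch: FiLM from the previous detection probability
        gamma_d, beta_d = self.film_det(Tensor(state.prev_det[:, None]))
        det_feat = (1.0 + gamma_d) * summary + beta_d
        logits_det = self.head_det(det_feat)
        y_det = _np_prob1(logits_det.data)

        # self-feedback prior (stop-gradient by construction: numpy values)
        if state.s is None:
            s_t = y_det.astype(np.float32)
        else:
            s_t = sfpm_update(state.s, y_det, cfg.sfpm_lambda)

        # prediction branch: FiLM conditioned on the prior
        gamma_p, beta_p = self.film_pred(Tensor(s_t[:, None]))
        pred_feat = (1.0 + gamma_p) * summary + beta_p
        logits_pred = self.head_pred(pred_feat)
        y_pred = _np_prob1(logits_pred.data)

        new_buffer = state.buffer.copy()
        if state.step == 0:
            new_buffer[:] = h_t.data[:, None, :]
        else:
            new_buffer[:, state.pointer, :] = h_t.data
        new_state = StreamState(
            buffer=new_buffer,
            pointer=(state.pointer + 1) % L,
            h=h_t.data.copy(),
            s=s_t.copy(),
            prev_det=y_det.astype(np.float32).copy(),
            step=state.step + 1,
        )
        out = StudentOutput(
            y_det=y_det, y_pred=y_pred,
            logits_det=logits_det, logits_pred=logits_pred,
            det_feature=det_feat, pred_feature=pred_feat,
            s=s_t, warm_up=new_state.step <= L,
            film_pred_gamma=gamma_p, film_pred_beta=beta_p,
        )
        return new_state, out

    def unroll_constants(self, feats: np.ndarray, state: StreamState
                         ) -> tuple[StreamState, dict[str, np.ndarray]]:
        """Run the recurrence over (B, S, d) window features without a tape
        and collect the per-step constants that the gradient-truncated
        training pass needs (previous hidden state, ring-buffer remainder,
        cold-start fill factor, FiLM conditioning scalars).

        Because gradients are truncated at every window boundary, the
        training graphs of all S steps are independent given these
        constants, so :meth:`batched_step` can rebuild them in one pass.
        """
        b, s, _ = feats.shape
        L = self.cfg.buffer_len
        h = self.cfg.gru_hidden
        consts = {
            "h_prev": np.empty((b, s, h), np.float32),
            "rest": np.empty((b, s, h), np.float32),
            "fill": np.empty((b, s, 1), np.float32),
            "prev_det": np.empty((b, s, 1), np.float32),
            "s": np.empty((b, s, 1), np.float32),
        }
        with no_grad():
            for t in range(s):
                consts["h_prev"][:, t] = state.h
                if state.step == 0:
                    consts["fill"][:, t, 0] = L
                    consts["rest"][:, t] = 0.0
                else:
                    consts["fill"][:, t, 0] = 1.0
                    consts["rest"][:, t] = (state.buffer.sum(axis=1)
                                            - state.buffer[:, state.pointer, :])
                consts["prev_det"][:, t, 0] = state.prev_det
                state, out = self.recurrent_step(Tensor(feats[:, t, :]), state)
                consts["s"][:, t, 0] = out.s
        return state, consts

    def batched_step(self, f_flat: Tensor, consts: dict[str, np.ndarray]
                     ) -> StudentOutput:
        """Recompute every step's outputs in one differentiable pass from
        the flat window features (B*S, d) and the recorded constants.
        Identical arithmetic to :meth:`recurrent_step`, vectorised over
        steps (valid because the recurrent state is gradient-constant)."""
        L = self.cfg.buffer_len
        n = f_flat.shape[0]
        flat = {k: Tensor(v.reshape(n, -1)) for k, v in consts.items()}
        h_t = self.gru(f_flat, flat["h_prev"])
        summary = h_t * (flat["fill"] * (1.0 / L)) + flat["rest"] * (1.0 / L)
        gamma_d, beta_d = self.film_det(flat["prev_det"])
        det_feat = (1.0 + gamma_d) * summary + beta_d
        logits_det = self.head_det(det_feat)
        gamma_p, beta_p = self.film_pred(flat["s"])
        pred_feat = (1.0 + gamma_p) * summary + beta_p
        logits_pred = self.head_pred(pred_feat)
        return StudentOutput(
            y_det=nn.softmax(logits_det).data[:, 1],
            y_pred=nn.softmax(logits_pred).data[:, 1],
            logits_det=logits_det, logits_pred=logits_pred,
            det_feature=det_feat, pred_feature=pred_feat,
            s=consts["s"].reshape(-1), warm_up=False,
            film_pred_gamma=gamma_p, film_pred_beta=beta_p,
        )

    def stream_step(self, state: StreamState, window: np.ndarray
                    ) -> tuple[StreamState, StudentOutput]:
        """Inference-mode step on one raw window (C, T) or a batch (B, C, T)."""
        with no_grad():
            f_t = self.encode_windows(window)
            return self.recurrent_step(f_t, state)

    def stream(self, windows: np.ndarray, state: StreamState | None = None,
               batch_encode: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run a whole stream (N, C, T); returns (y_det, y_pred, warm_up).

        The per-window encoder is batched for speed; the recurrence is the
        same causal per-step update as :meth:`stream_step`.
        """
        n = len(windows)
        if state is None:
            state = StreamState.fresh(self.cfg, batch=1)
        y_det = np.zeros(n, np.float32)
        y_pred = np.zeros(n, np.float32)
        warm = np.zeros(n, bool)
        with no_grad():
            for lo in range(0, n, batch_encode):
                feats = self.encode_windows(np.asarray(windows[lo:lo + batch_encode]))
                for j in range(feats.shape[0]):
                    state, out = self.recurrent_step(feats[j:j + 1], state)
                    y_det[lo + j] = out.y_det[0]
                    y_pred[lo + j] = out.y_pred[0]
                    warm[lo + j] = out.warm_up
        return y_det, y_pred, warm


def count_parameters(cfg: StudentConfig = StudentConfig()) -> int:
    """Total number of trainable scalars in the assembled student."""
    return StudentModel(cfg, seed=0).n_parameters()


# ---------------------------------------------------------------- checkpoints


def save_checkpoint(model: StudentModel | nn.Module, path, config=None):
    """Single-file weight archive with an embedded JSON config header."""
    state = model.state_dict()
    cfg = config if config is not None else getattr(model, "cfg", None)
    header = json.dumps(asdict(cfg)) if cfg is not None else "{}"
    np.savez(path, __config__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read a weight archive; returns (raw config dict, state dict)."""
    with np.load(path) as archive:
        header = bytes(archive["__config__"]).decode()
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    return json.loads(header), state


def load_student(path) -> StudentModel:
    raw, state = load_checkpoint(path)
    if "mbconv_out" in raw:
        raw["mbconv_out"] = tuple(raw["mbconv_out"])
    model = StudentModel(StudentConfig(**raw), seed=0)
    model.load_state_dict(state)
    return model
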