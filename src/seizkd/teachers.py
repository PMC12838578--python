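"""Reference teacher networks supplying the two complementary supervision
sources for distillation.

* :class:`PredictionTeacher` -- a Transformer encoder over within-window
  tokens whose global features feed an LSTM and a GRU in parallel; their
  final states are fused by a sigmoid gate (convex combination) before the
  linear head.  It emphasises the slowly evolving preictal cues.
* :class:`DetectionTeacher` -- a strided 1-D CNN feature extractor, an LSTM
  over the resulting frames, and a self-attention pooling step
  (``alpha_j = softmax(q k_j / sqrt(d_k))``) that weights seizure-relevant
  frames.  It emphasises burst rhythms and spike-wave patterns.

Both consume the same preprocessed 2-s windows as the student (window-wise,
no cross-window state) and expose logits plus a penultimate feature vector
for alignment.  Teachers are several-fold larger than the student; after
training they are frozen and act as pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate, no_grad

__all__ = [
    "TeacherConfig",
    "TeacherOutput",
    "PredictionTeacher",
    "DetectionTeacher",
    "make_teacher",
    "TEACHER_REGISTRY",
    "class_weights",
    "train_teacher",
    "fit_classifier",
]


@dataclass(frozen=True)
class TeacherConfig:
    task: str = "prediction"          # {"prediction", "detection"}
    n_channels: int = 22
    window_samples: int = 512
    n_tokens: int = 32
    d_model: int = 128
    n_heads: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("prediction", "detection"):
            raise ValueError("task must be 'prediction' or 'detection'")
        if self.window_samples % self.n_tokens != 0:
            raise ValueError("window_samples must be divisible by n_tokens")


@dataclass
class TeacherOutput:
    logits: Tensor        # (N, 2)
    penultimate: Tensor   # (N, D)
    task: str


class PredictionTeacher(nn.Module):
    def __init__(self, cfg: TeacherConfig = TeacherConfig(task="prediction")):
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.cfg = cfg
        self.embed = nn.Linear(cfg.n_channels, d, rng)
        self.encoder = nn.TransformerEncoderLayer(d, cfg.n_heads, 2 * d, 0.1, rng)
        self.lstm = nn.LSTMCell(d, d, rng)
        self.gru = nn.GRUCell(d, d, rng)
        self.gate = nn.Linear(2 * d, d, rng)
        self.head = nn.Linear(d, 2, rng)
        self._posenc = nn.sinusoidal_positions(cfg.n_tokens, d)
        self.frozen = False

    def __call__(self, windows: np.ndarray, rng=None, training: bool = False
                 ) -> TeacherOutput:
        cfg = self.cfg
        x = _tokenize(windows, cfg)                  # (B, n_tokens, C)
        z = self.embed(x) + Tensor(self._posenc)
        z = self.encoder(z, rng, training)           # global token features
        b = z.shape[0]
        d = cfg.d_model
        h_l = Tensor(np.zeros((b, d), np.float32))
        c_l = Tensor(np.zeros((b, d), np.float32))
        h_g = Tensor(np.zeros((b, d), np.float32))
        for t in range(cfg.n_tokens):
            x_t = z[:, t, :]
            h_l, c_l = self.lstm(x_t, h_l, c_l)
            h_g = self.gru(x_t, h_g)
        g = self.gate(concatenate([h_l, h_g], axis=-1)).sigmoid()
        fused = g * h_l + (1.0 - g) * h_g            # convex gated fusion
        return TeacherOutput(self.head(fused), fused, "prediction")


class DetectionTeacher(nn.Module):
    def __init__(self, cfg: TeacherConfig = TeacherConfig(task="detection")):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        d = cfg.d_model
        self.conv1 = nn.Conv1d(cfg.n_channels, 48, kernel=7, rng=rng, stride=4, same=False)
        self.conv2 = nn.Conv1d(48, d, kernel=5, rng=rng, stride=8, same=False)
        self.lstm = nn.LSTMCell(d, d, rng)
        self.d_k = d // 2
        self.wq = nn.Linear(d, self.d_k, rng, bias=False)
        self.wk = nn.Linear(d, self.d_k, rng, bias=False)
        self.head = nn.Linear(d, 2, rng)
        self.frozen = False

    def attention_pool(self, states: Tensor, query_state: Tensor
                       ) -> tuple[Tensor, Tensor]:
        """alpha_j = softmax(q k_j^T / sqrt(d_k)); returns (pooled, alpha)."""
        q = self.wq(query_state)[:, None, :]          # (B, 1, d_k)
        k = self.wk(states)                           # (B, F, d_k)
        scores = (q * k).sum(axis=-1) * (1.0 / np.sqrt(self.d_k))
        alpha = nn.softmax(scores, axis=-1)           # (B, F)
        pooled = (states * alpha[:, :, None]).sum(axis=1)
        return pooled, alpha

    def __call__(self, windows: np.ndarray, rng=None, training: bool = False
                 ) -> TeacherOutput:
        windows = np.asarray(windows, np.float32)
        if windows.ndim == 2:
            windows = windows[None]
        x = Tensor(np.swapaxes(windows, 1, 2))        # (B, T, C)
        z = self.conv2(self.conv1(x).relu()).relu()   # (B, frames, d)
        b, n_frames, d = z.shape
        h = Tensor(np.zeros((b, d), np.float32))
        c = Tensor(np.zeros((b, d), np.float32))
        hs = []
        for t in range(n_frames):
            h, c = self.lstm(z[:, t, :], h, c)
            hs.append(h)
        states = concatenate([s.reshape(b, 1, d) for s in hs], axis=1)
        pooled, _ = self.attention_pool(states, h)
        return TeacherOutput(self.head(pooled), pooled, "detection")


def _tokenize(windows: np.ndarray, cfg: TeacherConfig) -> Tensor:
    windows = np.asarray(windows, np.float32)
    if windows.ndim == 2:
        windows = windows[None]
    b, c, t = windows.shape
    if c != cfg.n_channels or t != cfg.window_samples:
        raise ValueError(f"window shape {(c, t)} does not match teacher config")
    stride = t // cfg.n_tokens
    pooled = windows.reshape(b, c, cfg.n_tokens, stride).mean(axis=3)
    return Tensor(np.swapaxes(pooled, 1, 2))          # (B, n_tokens, C)


TEACHER_REGISTRY = {
    "prediction": PredictionTeacher,
    "detection": DetectionTeacher,
}


def make_teacher(cfg: TeacherConfig) -> nn.Module:
    return TEACHER_REGISTRY[cfg.task](cfg)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights per class, rescaled to mean 1."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2).astype(np.float64)
    if (counts == 0).any():
        raise ValueError("both classes must be present")
    w = 1.0 / counts
    return (w / w.mean()).astype(np.float32)


def fit_classifier(model: nn.Module, x: np.ndarray, y: np.ndarray, *,
                   seed: int = 0, lr: float = 1e-3, batch_size: int = 32,
                   max_epochs: int = 30, patience: int = 10,
                   weighted: bool = False, val_frac: float = 0.25
                   ) -> list[dict]:
    """Mini-batch Adam training with chronological validation split and
    early stopping (stop after `patience` epochs without improvement,
    restore the best-epoch weights)."""
    x = np.asarray(x, np.float32)
    y = np.asarray(y, np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    n_val = max(int(round(len(x) * val_frac)), 1)
    x_tr, y_tr = x[:-n_val], y[:-n_val]
    x_val, y_val = x[-n_val:], y[-n_val:]
    cw = class_weights(y) if weighted else None
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    best = (np.inf, None, -1)
    history: list[dict] = []
    bad = 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(x_tr))
        tr_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            out = model(x_tr[idx], rng=rng, training=True)
            sw = cw[y_tr[idx]] if cw is not None else None
            loss = nn.cross_entropy(out.logits, y_tr[idx], sw)
            if not np.isfinite(loss.item()):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_loss += loss.item()
            n_batches += 1
        with no_grad():
            vout = model(x_val)
            sw = cw[y_val] if cw is not None else None
            val_loss = nn.cross_entropy(vout.logits, y_val, sw).item()
        history.append({"epoch": epoch, "train_loss": tr_loss / max(n_batches, 1),
                        "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, model.state_dict(), epoch)
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    if best[1] is not None:
        model.load_state_dict(best[1])
    return history


def train_teacher(x: np.ndarray, y: np.ndarray, task: str,
                  cfg: TeacherConfig | None = None, seed: int = 0,
                  **fit_kwargs) -> tuple[nn.Module, list[dict]]:
    """Train one teacher on its own task and return it frozen.

    Detection uses cross-entropy with inverse-class-frequency weighting;
    prediction uses plain cross-entropy on the preictal/interictal labels.
    """
    if cfg is None:
        x = np.asarray(x)
        cfg = TeacherConfig(task=task, n_channels=x.shape[1],
                            window_samples=x.shape[2], seed=seed)
    model = make_teacher(cfg)
    history = fit_classifier(model, x, y, seed=seed,
                             weighted=(task == "detection"), **fit_kwargs)
    for p in model.parameters():
        p.requires_grad = False
    model.frozen = True
    return model, history
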