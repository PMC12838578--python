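"""Neural-network layers and optimisation on top of :mod:`seizkd.autodiff`.

Conventions: sequence tensors are laid out ``(batch, time, channels)``; all
parameters are float32.  Initialisation uses a caller-supplied
``numpy.random.Generator`` so that every model build is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate

# --------------------------------------------------------------------- module


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        seen: set[int] = set()
        for name, value in vars(self).items():
            for sub, p in _collect_named(value, f"{prefix}{name}"):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append((sub, p))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def checksum(self) -> float:
        """Cheap fingerprint of all weights (frozen-teacher contract checks)."""
        return float(sum(float(np.abs(p.data).sum()) for p in self.parameters()))


def _collect(value):
    if isinstance(value, Tensor):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_named(value, name):
    if isinstance(value, Tensor):
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=name + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{name}.{i}")
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _collect_named(v, f"{name}.{k}")


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


# --------------------------------------------------------------------- layers


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            bound = math.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.weight = parameter(w)
        self.bias = parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return _layer_norm_apply(x, self.gamma, self.beta, self.eps)


def _layer_norm_apply(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Fused layer normalisation (single tape node, analytic backward)."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0),
                         own=True)
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))), own=True)
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gy - m1 - xhat * m2), own=True)

    return Tensor._make(out, (x, gamma, beta), backward)


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None,
                 training: bool) -> Tensor:
        if not training or self.p <= 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


def stack_steps(tensors: list[Tensor]) -> Tensor:
    """Stack S per-step tensors of shape (B, ...) into (B*S, ...) flat
    window order (b0s0, b0s1, ..., b1s0, ...)."""
    s = len(tensors)
    expanded = [t.reshape(t.shape[0], 1, *t.shape[1:]) for t in tensors]
    cat = concatenate(expanded, axis=1)
    return cat.reshape(cat.shape[0] * s, *cat.shape[2:])


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax (single tape node, analytic backward)."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - inner), own=True)

    return Tensor._make(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  sample_weights: np.ndarray | None = None) -> Tensor:
    """Mean (optionally weighted) negative log-likelihood for integer labels."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=np.int64)]
    if sample_weights is None:
        return -picked.mean()
    w = Tensor(np.asarray(sample_weights, dtype=np.float32))
    return -(picked * w).sum() / float(n)


# ------------------------------------------------------------- convolutional


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, kernel: int,
           stride: int = 1, same: bool = False) -> Tensor:
    """1-D convolution over (B, T, C_in) with weight (kernel*C_in, C_out).

    Implemented as gather-into-frames + matmul so the autodiff engine only
    needs indexing and matmul primitives.
    """
    if same:
        left = (kernel - 1) // 2
        x = x.pad_axis(1, left, kernel - 1 - left)
    t = x.shape[1]
    n_out = (t - kernel) // stride + 1
    idx = (np.arange(n_out)[:, None] * stride + np.arange(kernel)[None, :])
    frames = x[:, idx, :]                      # (B, n_out, kernel, C_in)
    b, _, _, cin = frames.shape
    y = frames.reshape(b, n_out, kernel * cin) @ weight
    if bias is not None:
        y = y + bias
    return y


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, same: bool = False):
        fan_in = kernel * c_in
        bound = math.sqrt(6.0 / (fan_in + c_out))
        self.weight = parameter(rng.uniform(-bound, bound, size=(fan_in, c_out)))
        self.bias = parameter(np.zeros(c_out))
        self.kernel, self.stride, self.same = kernel, stride, same

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.kernel, self.stride, self.same)


class DepthwiseConv1d(Module):
    """Per-channel (depthwise) convolution, kernel applied along time."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / (kernel + 1))
        self.weight = parameter(rng.uniform(-bound, bound, size=(kernel, channels)))
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:  # x: (B, T, C)
        k = self.kernel
        left = (k - 1) // 2
        xp = x.pad_axis(1, left, k - 1 - left)
        return _depthwise_apply(xp, self.weight, x.shape[1], k)


def _depthwise_apply(xp: Tensor, w: Tensor, t: int, k: int) -> Tensor:
    """Fused shifted-slice depthwise convolution: a single tape node with a
    hand-written backward avoids the large broadcast temporaries that the
    generic mul/add composition would allocate per kernel tap."""
    xd, wd = xp.data, w.data
    out = xd[:, 0:t, :] * wd[0]
    for i in range(1, k):
        out += xd[:, i:i + t, :] * wd[i]

    def backward(g):
        if xp.requires_grad:
            gx = np.zeros_like(xd)
            for i in range(k):
                gx[:, i:i + t, :] += g * wd[i]
            xp._accum(gx, own=True)
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(k):
                gw[i] = np.einsum("btc,btc->c", g, xd[:, i:i + t, :],
                                  optimize=True)
            w._accum(gw, own=True)

    return Tensor._make(out, (xp, w), backward)


def avg_pool_tokens(x: Tensor, stride: int) -> Tensor:
    """Non-overlapping average pooling along time: (B, T, C) -> (B, T//stride, C)."""
    b, t, c = x.shape
    if t % stride != 0:
        raise ValueError(f"time length {t} not divisible by pooling stride {stride}")
    return x.reshape(b, t // stride, stride, c).mean(axis=2)


# ----------------------------------------------------------------- attention


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention; heads concatenated and projected."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 bias: bool = True):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng, bias=bias)
        self.wk = Linear(d_model, d_model, rng, bias=bias)
        self.wv = Linear(d_model, d_model, rng, bias=bias)
        self.wo = Linear(d_model, d_model, rng, bias=bias)

    def _split(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        return x.reshape(b, n, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Row-stochastic attention matrices (B, heads, N, N), no grad."""
        q, k = self._split(self.wq(x)), self._split(self.wk(x))
        s = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        return softmax(s, axis=-1).data

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        q, k, v = (self._split(p(x)) for p in (self.wq, self.wk, self.wv))
        s = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        a = softmax(s, axis=-1)
        o = (a @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(o)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer (attention + position-wise feed-forward)."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 dropout: float, rng: np.random.Generator,
                 attn_bias: bool = True):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng, bias=attn_bias)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng=None, training: bool = False) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)), rng, training)
        x = x + self.drop(self.ff2(self.ff1(self.ln2(x)).relu()), rng, training)
        return x


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding (parameter-free)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


# ------------------------------------------------------------------ recurrent


class GRUCell(Module):
    """Gated recurrent unit: update/reset gates, candidate state, convex mix."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        def mat(a, b):
            bound = math.sqrt(6.0 / (a + b))
            return parameter(rng.uniform(-bound, bound, size=(a, b)))

        # update-gate bias starts negative so the fresh state tracks its
        # input instead of holding memory; long-stream hidden states would
        # otherwise be prone to freezing at a fixed point
        self.wz, self.uz, self.bz = mat(n_in, n_hidden), mat(n_hidden, n_hidden), parameter(np.full(n_hidden, -1.0))
        self.wr, self.ur, self.br = mat(n_in, n_hidden), mat(n_hidden, n_hidden), parameter(np.zeros(n_hidden))
        self.wh, self.uh, self.bh = mat(n_in, n_hidden), mat(n_hidden, n_hidden), parameter(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h_prev: Tensor) -> Tensor:
        z = (x @ self.wz + h_prev @ self.uz + self.bz).sigmoid()
        r = (x @ self.wr + h_prev @ self.ur + self.br).sigmoid()
        h_cand = (x @ self.wh + (r * h_prev) @ self.uh + self.bh).tanh()
        return z * h_prev + (1.0 - z) * h_cand


class LSTMCell(Module):
    """Standard LSTM; the hidden state is o_t * tanh(c_t)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / (n_in + n_hidden + 4 * n_hidden))
        self.w = parameter(rng.uniform(-bound, bound, size=(n_in + n_hidden, 4 * n_hidden)))
        self.b = parameter(np.zeros(4 * n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        n = self.n_hidden
        gates = concatenate([x, h], axis=-1) @ self.w + self.b
        i = gates[..., 0:n].sigmoid()
        f = gates[..., n:2 * n].sigmoid()
        o = gates[..., 2 * n:3 * n].sigmoid()
        g = gates[..., 3 * n:4 * n].tanh()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


# ------------------------------------------------------------------ optimiser


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float | None = 5.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.grad_clip = grad_clip
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        if self.grad_clip is not None:
            total = 0.0
            for p in self.params:
                if p.grad is not None:
                    total += float((p.grad.astype(np.float64) ** 2).sum())
            norm = math.sqrt(total)
            scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
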