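"""Neural layers built on the autograd Tensor: linear, LSTM, attention,
transformer block, layer norm, pooling helpers."""

from __future__ import annotations

import numpy as np

from facedep.nn.autograd import Tensor, concatenate, softmax


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive traversal and (de)serialization."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{key}")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise KeyError(
                f"state mismatch: missing {sorted(set(own) - set(state))}, "
                f"unexpected {sorted(set(state) - set(own))}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, activation: str | None = None):
        self.W = Parameter(_glorot(rng, in_features, out_features,
                                   (in_features, out_features)))
        self.b = Parameter(np.zeros(out_features))
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "relu":
            return out.relu()
        if self.activation == "tanh":
            return out.tanh()
        if self.activation == "sigmoid":
            return out.sigmoid()
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_forward(x: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
                 reverse: bool = False) -> Tensor:
    """Fused LSTM over (B, T, F): one graph node for the whole unroll.

    The per-timestep loop runs in plain numpy with cached gate activations
    and a hand-written full-sequence BPTT backward; this is an order of
    magnitude faster than composing the recurrence from elementary autograd
    ops, which matters for 30-step windows replicated hundreds of times.
    """
    B, T, _ = x.shape
    H = Wh.shape[0]
    steps = range(T - 1, -1, -1) if reverse else range(T)

    xw = x.data @ Wx.data + b.data            # (B, T, 4H) input contribution
    hs = np.zeros((B, T, H))
    cache = {}
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in steps:
        z = xw[:, t] + h @ Wh.data
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        cache[t] = (i, f, g, o, c_prev, tc)

    h_prevs = {}  # hidden state fed into step t
    prev = np.zeros((B, H))
    for t in steps:
        h_prevs[t] = prev
        prev = hs[:, t]

    def backward(gh: np.ndarray) -> None:
        dWx = np.zeros_like(Wx.data)
        dWh = np.zeros_like(Wh.data)
        db = np.zeros_like(b.data)
        dx = np.zeros_like(x.data) if x.requires_grad else None
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(list(steps)):
            i, f, g, o, c_prev, tc = cache[t]
            dh = gh[:, t] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = np.concatenate([
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                dh * tc * o * (1.0 - o),
            ], axis=1)
            dWx += x.data[:, t].T @ dz
            dWh += h_prevs[t].T @ dz
            db += dz.sum(axis=0)
            if dx is not None:
                dx[:, t] = dz @ Wx.data.T
            dh_next = dz @ Wh.data.T
            dc_next = dc * f
        if x.requires_grad:
            x._accumulate(dx)
        if Wx.requires_grad:
            Wx._accumulate(dWx)
        if Wh.requires_grad:
            Wh._accumulate(dWh)
        if b.requires_grad:
            b._accumulate(db)

    return Tensor._result(hs, (x, Wx, Wh, b), backward)


class LSTM(Module):
    """Single-direction LSTM returning all hidden states (B, T, H)."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator, reverse: bool = False):
        h = hidden_size
        self.hidden_size = h
        self.reverse = reverse
        self.Wx = Parameter(_glorot(rng, input_size, 4 * h, (input_size, 4 * h)))
        self.Wh = Parameter(_glorot(rng, h, 4 * h, (h, 4 * h)))
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias
        self.b = Parameter(b)

    def forward(self, x: Tensor) -> Tensor:
        return lstm_forward(x, self.Wx, self.Wh, self.b, reverse=self.reverse)


class BiLSTM(Module):
    """Bidirectional LSTM; concatenated hidden states (B, T, 2H)."""

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        self.fwd = LSTM(input_size, hidden_size, rng, reverse=False)
        self.bwd = LSTM(input_size, hidden_size, rng, reverse=True)

    def forward(self, x: Tensor) -> Tensor:
        return concatenate([self.fwd(x), self.bwd(x)], axis=-1)


class AdditiveAttention(Module):
    """Additive (tanh-scored) attention pooling over the second-to-last axis.

    ``score_t = v . tanh(W h_t + b)``; softmax weights over t; output is the
    weighted sum of the hidden states.  Works on any (..., T, D) input.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 proj_dim: int | None = None):
        p = proj_dim or dim
        self.W = Parameter(_glorot(rng, dim, p, (dim, p)))
        self.b = Parameter(np.zeros(p))
        self.v = Parameter(_glorot(rng, p, 1, (p, 1)))

    def forward(self, h: Tensor, return_weights: bool = False):
        scores = (h @ self.W + self.b).tanh() @ self.v    # (..., T, 1)
        weights = softmax(scores, axis=-2)
        pooled = (weights * h).sum(axis=-2)               # (..., D)
        if return_weights:
            return pooled, weights
        return pooled


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gain + self.bias


class TransformerBlock(Module):
    """Pre-norm-free (post-LN) transformer encoder block, single-layer MHA."""

    def __init__(self, d_model: int, head_size: int, n_heads: int,
                 ff_dim: int, rng: np.random.Generator):
        if n_heads != 1:
            raise NotImplementedError("only single-head attention is supported")
        self.head_size = head_size
        self.Wq = Parameter(_glorot(rng, d_model, head_size, (d_model, head_size)))
        self.Wk = Parameter(_glorot(rng, d_model, head_size, (d_model, head_size)))
        self.Wv = Parameter(_glorot(rng, d_model, head_size, (d_model, head_size)))
        self.Wo = Parameter(_glorot(rng, head_size, d_model, (head_size, d_model)))
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng, activation="relu")
        self.ff2 = Linear(ff_dim, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        q, k, v = x @ self.Wq, x @ self.Wk, x @ self.Wv
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_size))
        attn = softmax(scores, axis=-1) @ v               # (B, T, head)
        x = self.ln1(x + attn @ self.Wo)
        return self.ln2(x + self.ff2(self.ff1(x)))


def avg_pool_time(x: Tensor, stride: int) -> Tensor:
    """Non-overlapping mean pooling along the time axis of (B, T, D).

    A trailing remainder shorter than ``stride`` is dropped.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return x
    B, T, D = x.shape
    t2 = (T // stride) * stride
    if t2 == 0:
        raise ValueError(f"sequence of length {T} shorter than stride {stride}")
    if t2 != T:
        x = x[:, :t2, :]
    return x.reshape(B, t2 // stride, stride, D).mean(axis=2)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional-encoding matrix (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
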