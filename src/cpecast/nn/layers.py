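"""Building blocks for the small sequence classifiers.

Layers operate on batched sequence tensors of shape (batch, time, features)
and return ``(sequence, summary)``: the per-step outputs plus the fixed-size
representation consumed by the dense prediction head (the final hidden state;
for the bidirectional layer, both directions' final states concatenated).

The LSTM — the workhorse of the pipeline — uses a fused step with a
hand-derived backward-through-time pass, recorded on the autodiff tape as a
single node; the other recurrences go through the generic per-step ops.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Module", "Dense", "RNNLayer", "LSTMLayer", "GRULayer", "BiLSTMLayer",
    "Conv1dLayer", "LayerNorm", "TransformerBlock", "RecurrentClassifier",
    "TransformerClassifier", "sinusoidal_positions", "glorot", "lstm_seq",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


try:  # JIT-compiled recurrence kernels; plain numpy fallback below
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True, fastmath=True)
def _lstm_fwd_kernel(zx, Wh, hs_prev, gates, cs, tanh_c, seq):
    B, T, H4 = zx.shape
    H = H4 // 4
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        hs_prev[:, t] = h
        z = zx[:, t] + h @ Wh
        for bi in range(B):
            for j in range(H):
                i = 1.0 / (1.0 + np.exp(-z[bi, j]))
                f = 1.0 / (1.0 + np.exp(-z[bi, H + j]))
                g = np.tanh(z[bi, 2 * H + j])
                o = 1.0 / (1.0 + np.exp(-z[bi, 3 * H + j]))
                cv = f * c[bi, j] + i * g
                tc = np.tanh(cv)
                c[bi, j] = cv
                gates[bi, t, j] = i
                gates[bi, t, H + j] = f
                gates[bi, t, 2 * H + j] = g
                gates[bi, t, 3 * H + j] = o
                cs[bi, t, j] = cv
                tanh_c[bi, t, j] = tc
                h[bi, j] = o * tc
        seq[:, t] = h


@_njit(cache=True, fastmath=True)
def _lstm_bwd_kernel(grad, Wh, hs_prev, gates, cs, tanh_c, dWh, dz_all):
    B, T, H = grad.shape
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dz = dz_all[:, t]
        for bi in range(B):
            for j in range(H):
                i = gates[bi, t, j]
                f = gates[bi, t, H + j]
                g = gates[bi, t, 2 * H + j]
                o = gates[bi, t, 3 * H + j]
                tc = tanh_c[bi, t, j]
                c_prev = cs[bi, t - 1, j] if t > 0 else 0.0
                dh = grad[bi, t, j] + dh_next[bi, j]
                dc = dh * o * (1.0 - tc * tc) + dc_next[bi, j]
                dz[bi, j] = dc * g * i * (1.0 - i)
                dz[bi, H + j] = dc * c_prev * f * (1.0 - f)
                dz[bi, 2 * H + j] = dc * i * (1.0 - g * g)
                dz[bi, 3 * H + j] = dh * tc * o * (1.0 - o)
                dc_next[bi, j] = dc * f
        dWh += hs_prev[:, t].T @ dz
        dh_next[:] = dz @ Wh.T


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.data.shape} vs {w.shape}")
            p.data = w.copy()

    def save_weights(self, path) -> None:
        """Checkpoint to numpy's .npz container."""
        np.savez(path, *self.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as archive:
            self.set_weights([archive[k] for k in archive.files])


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


# ---------------------------------------------------------------------------
# fused LSTM
# ---------------------------------------------------------------------------

def lstm_seq(X: Tensor, W: Parameter, b: Parameter) -> Tensor:
    """Run a whole LSTM pass over (batch, T, n_in) in one tape node.

    ``W`` has shape (n_in + H, 4H) with gate order (input, forget, cell,
    output); the backward closure replays the recurrence in reverse, which is
    an order of magnitude cheaper than taping every gate op.
    """
    x = X.data
    B, T, n_in = x.shape
    H = W.data.shape[1] // 4
    Wx, Wh = W.data[:n_in], W.data[n_in:]
    bd = b.data

    # input contribution for every step in one matmul
    zx = x.reshape(B * T, n_in) @ Wx
    zx = zx.reshape(B, T, 4 * H) + bd

    seq = np.empty((B, T, H))
    # caches for the backward pass
    hs_prev = np.empty((B, T, H))
    gates = np.empty((B, T, 4 * H))   # sigm(i), sigm(f), tanh(g), sigm(o)
    cs = np.empty((B, T, H))
    tanh_c = np.empty((B, T, H))
    if _HAVE_NUMBA:
        _lstm_fwd_kernel(zx, Wh, hs_prev, gates, cs, tanh_c, seq)
    else:
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for t in range(T):
            hs_prev[:, t] = h
            z = zx[:, t] + h @ Wh
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t, :H] = i
            gates[:, t, H:2 * H] = f
            gates[:, t, 2 * H:3 * H] = g
            gates[:, t, 3 * H:] = o
            cs[:, t] = c
            tanh_c[:, t] = tc
            seq[:, t] = h

    def backward(grad):
        grad = np.ascontiguousarray(grad)
        dWh = np.zeros_like(Wh)
        dz_all = np.empty((B, T, 4 * H))
        if _HAVE_NUMBA:
            _lstm_bwd_kernel(grad, Wh, hs_prev, gates, cs, tanh_c, dWh, dz_all)
        else:
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            zero = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i = gates[:, t, :H]
                f = gates[:, t, H:2 * H]
                g = gates[:, t, 2 * H:3 * H]
                o = gates[:, t, 3 * H:]
                tc = tanh_c[:, t]
                c_prev = cs[:, t - 1] if t > 0 else zero
                dh = grad[:, t] + dh_next
                dc = dh * o * (1.0 - tc * tc) + dc_next
                dz = dz_all[:, t]
                dz[:, :H] = dc * g * i * (1.0 - i)
                dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
                dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
                dz[:, 3 * H:] = dh * tc * o * (1.0 - o)
                dWh += hs_prev[:, t].T @ dz
                dh_next = dz @ Wh.T
                dc_next = dc * f
        dz_flat = dz_all.reshape(B * T, 4 * H)
        if W.requires_grad:
            dW = np.empty_like(W.data)
            dW[:n_in] = x.reshape(B * T, n_in).T @ dz_flat
            dW[n_in:] = dWh
            W._accum(dW)
        if b.requires_grad:
            b._accum(dz_flat.sum(axis=0))
        if X.requires_grad:
            X._accum((dz_flat @ Wx.T).reshape(B, T, n_in))

    return Tensor._make(seq, (X, W, b), backward)


class LSTMLayer(Module):
    """Fused-gate LSTM; forget-gate bias starts at 1."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, n_in + hidden, 4 * hidden,
                                  shape=(n_in + hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden:2 * hidden] = 1.0
        self.b = Parameter(bias)
        self.hidden = hidden

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        seq = lstm_seq(X, self.W, self.b)
        return seq, seq[:, -1, :]


class RNNLayer(Module):
    """Elman recurrence: h_t = tanh([x_t, h_{t-1}] W + b)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, n_in + hidden, hidden))
        self.b = Parameter(np.zeros(hidden))
        self.hidden = hidden

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        from .autograd import stack

        B, T, _ = X.shape
        h = Tensor(np.zeros((B, self.hidden)))
        out = []
        for t in range(T):
            h = (concat([X[:, t, :], h], axis=1) @ self.W + self.b).tanh()
            out.append(h)
        return stack(out, axis=1), h


class GRULayer(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.W_zr = Parameter(glorot(rng, n_in + hidden, 2 * hidden,
                                     shape=(n_in + hidden, 2 * hidden)))
        self.b_zr = Parameter(np.zeros(2 * hidden))
        self.W_n = Parameter(glorot(rng, n_in + hidden, hidden))
        self.b_n = Parameter(np.zeros(hidden))
        self.hidden = hidden

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        from .autograd import stack

        B, T, _ = X.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        out = []
        for t in range(T):
            x = X[:, t, :]
            zr = concat([x, h], axis=1) @ self.W_zr + self.b_zr
            z = zr[:, 0:H].sigmoid()
            r = zr[:, H:2 * H].sigmoid()
            n = (concat([x, r * h], axis=1) @ self.W_n + self.b_n).tanh()
            h = z * h + (1.0 - z) * n
            out.append(h)
        return stack(out, axis=1), h


class BiLSTMLayer(Module):
    """Forward and reversed LSTM passes, outputs concatenated per step.

    The summary joins both directions' final states, so it reflects the whole
    window from both ends.
    """

    def __init__(self, n_in: int, hidden_per_dir: int, rng: np.random.Generator):
        self.fwd = LSTMLayer(n_in, hidden_per_dir, rng)
        self.bwd = LSTMLayer(n_in, hidden_per_dir, rng)

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        seq_f, last_f = self.fwd.forward(X)
        seq_b_rev, last_b = self.bwd.forward(X.flip(axis=1))
        seq = concat([seq_f, seq_b_rev.flip(axis=1)], axis=2)
        return seq, concat([last_f, last_b], axis=1)


class Conv1dLayer(Module):
    """Width-3, same-padded 1-D convolution along time, ReLU activation."""

    def __init__(self, n_in: int, channels: int, rng: np.random.Generator):
        self.kernels = [Parameter(glorot(rng, 3 * n_in, channels, shape=(n_in, channels)))
                        for _ in range(3)]
        self.b = Parameter(np.zeros(channels))
        self.channels = channels

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        B, T, F = X.shape
        zero = Tensor(np.zeros((B, 1, F)))
        padded = concat([zero, X, zero], axis=1)    # (B, T+2, F)
        out = (padded[:, 0:T, :] @ self.kernels[0]
               + padded[:, 1:T + 1, :] @ self.kernels[1]
               + padded[:, 2:T + 2, :] @ self.kernels[2]
               + self.b).relu()
        return out, out[:, -1, :]


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + 1e-5) ** -0.5 * self.gamma + self.beta


class TransformerBlock(Module):
    """One post-norm encoder layer: 2-head self-attention + feed-forward."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.qkv = Dense(d_model, 3 * d_model, rng)
        self.proj = Dense(d_model, d_model, rng)
        self.ff1 = Dense(d_model, d_model, rng)
        self.ff2 = Dense(d_model, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.n_heads = n_heads
        self.d_model = d_model

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H = self.n_heads
        dh = D // H
        qkv = self.qkv(x)                                            # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, H, dh).transpose(2, 0, 3, 1, 4)   # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = att.softmax(axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = self.ln1(x + self.proj(ctx))
        x = self.ln2(x + self.ff2(self.ff1(x).relu()))
        return x


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((n_pos, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class RecurrentClassifier(Module):
    """Stacked recurrent/conv blocks + dense sigmoid head over the summary.

    Raw integer NRS inputs are scaled by 1/10 into [0, 1] at this boundary;
    the binned matrices themselves stay integer.
    """

    def __init__(self, blocks: list[Module], summary_dim: int, output_bins: int,
                 rng: np.random.Generator, input_scale: float = 0.1):
        self.blocks = blocks
        self.head = Dense(summary_dim, output_bins, rng)
        self.input_scale = input_scale

    def forward(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float64) * self.input_scale
        seq = Tensor(x[:, :, None])
        summary = None
        for block in self.blocks:
            seq, summary = block.forward(seq)
        return self.head(summary).sigmoid()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data


class TransformerClassifier(Module):
    def __init__(self, d_model: int, n_heads: int, n_blocks: int, output_bins: int,
                 max_len: int, rng: np.random.Generator, input_scale: float = 0.1):
        self.embed = Dense(1, d_model, rng)
        self.blocks = [TransformerBlock(d_model, n_heads, rng) for _ in range(n_blocks)]
        self.head = Dense(d_model, output_bins, rng)
        self.pos = sinusoidal_positions(max_len, d_model)
        self.input_scale = input_scale

    def forward(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float64) * self.input_scale
        B, T = x.shape
        h = self.embed(Tensor(x[:, :, None])) + Tensor(self.pos[:T])
        for block in self.blocks:
            h = block(h)
        last = h[:, -1, :]
        return self.head(last).sigmoid()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data
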