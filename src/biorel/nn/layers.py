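"""Model layers: multi-head self-attention, position-wise feed-forward,
multi-filter 1-D convolution, bidirectional LSTM, and additive attention.

All layers operate on single (unbatched) sentences — an (n, d) matrix of
per-token feature combinations — and return either a transformed matrix
or a pooled feature vector.  Parameters are plain autograd tensors.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, stack_rows

__all__ = [
    "Linear",
    "scaled_dot_product_attention",
    "MultiHeadAttentionEncoder",
    "CnnEncoder",
    "BiLstmEncoder",
    "AdditiveAttentionPooling",
    "zero_rows",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def zero_rows(k: int, d: int) -> Tensor:
    return Tensor(np.zeros((k, d), dtype=np.float32))


class Linear:
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = (
            Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


def scaled_dot_product_attention(Q: Tensor, K: Tensor, V: Tensor, d_k: int):
    """Attention(Q, K, V) = softmax(Q Kᵀ / sqrt(d_k)) V.

    Returns (context, attention weights); every weight row is a
    probability distribution over the keys.
    """
    if not np.all(np.isfinite(Q.data)) or not np.all(np.isfinite(K.data)):
        raise FloatingPointError("non-finite attention inputs")
    scores = (Q @ K.transpose_last()) * (1.0 / math.sqrt(d_k))
    weights = scores.softmax_rows()
    context = weights @ V
    return context, weights


class MultiHeadAttentionEncoder:
    """Single-layer multi-head self-attention sentence encoder.

    Eight scaled dot-product attention heads with unshared query/key/
    value projections split the d-dimensional feature combination into
    d/8-wide channels; the concatenated head outputs pass through a
    position-wise feed-forward network with a residual connection to
    the input, and the sentence vector is the column-wise max over
    tokens.  The softmax scale is sqrt(d_head) by default (configurable
    to sqrt(d)).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        d: int,
        heads: int = 8,
        d_ff: int | None = None,
        scale_dim: str = "head",
    ):
        if d % heads != 0:
            raise ValueError(f"model dim {d} not divisible by {heads} heads")
        self.d = d
        self.heads = heads
        self.d_head = d // heads
        self.d_k = self.d_head if scale_dim == "head" else d
        # per-head projections stored as disjoint column blocks of one matrix
        self.Wq = Linear(rng, d, d, bias=False)
        self.Wk = Linear(rng, d, d, bias=False)
        self.Wv = Linear(rng, d, d, bias=False)
        d_ff = d if d_ff is None else d_ff
        self.ff1 = Linear(rng, d, d_ff)
        self.ff2 = Linear(rng, d_ff, d)
        self.out_dim = d

    def head_weights(self, which: str, i: int) -> np.ndarray:
        """Per-head projection block W_{q,k,v} of head ``i`` (d, d_head)."""
        W = {"q": self.Wq, "k": self.Wk, "v": self.Wv}[which].W.data
        return W[:, i * self.d_head : (i + 1) * self.d_head]

    def multi_head(self, X: Tensor) -> Tensor:
        """Concatenated attention-head outputs, an (n, d) matrix."""
        Q, K, V = self.Wq(X), self.Wk(X), self.Wv(X)
        outs = []
        for i in range(self.heads):
            a, b = i * self.d_head, (i + 1) * self.d_head
            ctx, _w = scaled_dot_product_attention(
                Q.cols(a, b), K.cols(a, b), V.cols(a, b), self.d_k
            )
            outs.append(ctx)
        return concat(outs, axis=-1)

    def encode(self, X: Tensor) -> Tensor:
        """Sentence vector: max-pool over FFN(MultiHead(X)) + X."""
        mh = self.multi_head(X)
        y = self.ff2(self.ff1(mh).relu()) + X
        return y.max(axis=0)

    def parameters(self):
        return (
            self.Wq.parameters()
            + self.Wk.parameters()
            + self.Wv.parameters()
            + self.ff1.parameters()
            + self.ff2.parameters()
        )


class CnnEncoder:
    """Multi-filter 1-D convolution with ReLU and max-over-positions pooling.

    One convolution layer; one filter bank per window size; the pooled
    outputs are concatenated, giving ``len(windows) * filters`` features.
    Inputs shorter than the largest window are zero-padded (biases are
    initialised to zero, so pad rows contribute the bias value only).
    """

    def __init__(self, rng, d_in: int, windows=(2, 3, 4), filters: int = 128):
        if any(w <= 0 for w in windows):
            raise ValueError("window sizes must be positive")
        self.windows = tuple(windows)
        self.filters = filters
        self.d_in = d_in
        self.banks = [Linear(rng, w * d_in, filters) for w in self.windows]
        self.out_dim = len(self.windows) * filters

    def _pad(self, X: Tensor) -> Tensor:
        need = max(self.windows) - X.shape[0]
        if need > 0:
            X = concat([X, zero_rows(need, self.d_in)], axis=0)
        return X

    def encode(self, X: Tensor) -> Tensor:
        X = self._pad(X)
        pooled = []
        for w, bank in zip(self.windows, self.banks):
            conv = bank(X.unfold_windows(w)).relu()
            pooled.append(conv.max(axis=0))
        return concat(pooled, axis=-1)

    def feature_map(self, X: Tensor, w_index: int = 0) -> Tensor:
        """Per-position (pre-pool) feature map for one window size."""
        X = self._pad(X)
        w = self.windows[w_index]
        return self.banks[w_index](X.unfold_windows(w)).relu()

    def parameters(self):
        return [p for bank in self.banks for p in bank.parameters()]


class _LstmCell:
    def __init__(self, rng, d_in: int, hidden: int):
        self.hidden = hidden
        self.W = Tensor(glorot(rng, d_in + hidden, 4 * hidden), requires_grad=True)
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        z = concat([x, h], axis=-1) @ self.W + self.b
        H = self.hidden
        i = z.cols(0, H).sigmoid()
        f = z.cols(H, 2 * H).sigmoid()
        g = z.cols(2 * H, 3 * H).tanh()
        o = z.cols(3 * H, 4 * H).sigmoid()
        c2 = f * c + i * g
        h2 = o * c2.tanh()
        return h2, c2

    def run(self, rows: list[Tensor]) -> list[Tensor]:
        H = self.hidden
        h = Tensor(np.zeros(H, dtype=np.float32))
        c = Tensor(np.zeros(H, dtype=np.float32))
        out = []
        for x in rows:
            h, c = self.step(x, h, c)
            out.append(h)
        return out

    def parameters(self):
        return [self.W, self.b]


class BiLstmEncoder:
    """Bidirectional LSTM; per-token outputs are the concatenated states.

    ``encode`` pools with a column-wise max; ``final_states`` returns the
    concatenation of the two directions' last hidden states.
    """

    def __init__(self, rng, d_in: int, hidden: int = 128):
        self.fwd = _LstmCell(rng, d_in, hidden)
        self.bwd = _LstmCell(rng, d_in, hidden)
        self.out_dim = 2 * hidden

    def _rows(self, X: Tensor) -> list[Tensor]:
        n, d = X.shape
        return [X.rows(i, i + 1).reshape(d) for i in range(n)]

    def outputs(self, X: Tensor) -> Tensor:
        rows = self._rows(X)
        f = self.fwd.run(rows)
        b = self.bwd.run(rows[::-1])[::-1]
        return stack_rows([concat([hf, hb], axis=-1) for hf, hb in zip(f, b)])

    def encode(self, X: Tensor) -> Tensor:
        return self.outputs(X).max(axis=0)

    def final_states(self, X: Tensor) -> Tensor:
        rows = self._rows(X)
        f = self.fwd.run(rows)
        b = self.bwd.run(rows[::-1])
        return concat([f[-1], b[-1]], axis=-1)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class AdditiveAttentionPooling:
    """Single-query additive attention: scores u·tanh(W h + b), softmax
    over tokens, weighted sum of the per-token features."""

    def __init__(self, rng, d_in: int):
        self.proj = Linear(rng, d_in, d_in)
        self.u = Tensor(
            (rng.standard_normal(d_in) * 0.05).astype(np.float32),
            requires_grad=True,
        )
        self.out_dim = d_in

    def encode(self, H: Tensor) -> Tensor:
        scores = self.proj(H).tanh() @ self.u.reshape(-1, 1)
        weights = scores.reshape(1, -1).softmax_rows()
        return (weights @ H).reshape(-1)

    def parameters(self):
        return self.proj.parameters() + [self.u]
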