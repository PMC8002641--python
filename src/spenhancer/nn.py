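"""NumPy neural-network primitives for the sequence classifier.

Implements exactly the layers the classifier needs — trainable embedding,
bidirectional LSTM, batch normalization, additive attention pooling,
inverted dropout, and a dense output — with hand-derived backward passes
and an Adam optimizer.  Analytic gradients are validated against central
finite differences in the test suite.

Shapes follow the (batch, time, features) convention.  All arithmetic is
float64; training is deterministic given one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Embedding:
    """ID -> dense vector lookup; row 0 serves the unknown-k-mer ID."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.W = Param("embedding/W", rng.uniform(-0.05, 0.05, size=(vocab_size, dim)))
        self.params = [self.W]
        self._ids: np.ndarray | None = None

    def forward(self, ids: np.ndarray, train: bool) -> np.ndarray:
        self._ids = ids
        return self.W.value[ids]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.W.grad, self._ids, dout)
        return None


class _LSTMDirection:
    """One direction of an LSTM, returning the full hidden sequence.

    Gate layout in the fused weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1.
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator, tag: str):
        H = hidden
        self.H = H
        self.Wx = Param(f"lstm/{tag}/Wx", glorot_uniform(rng, (input_dim, 4 * H)))
        self.Wh = Param(f"lstm/{tag}/Wh", glorot_uniform(rng, (H, 4 * H)))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = Param(f"lstm/{tag}/b", b)
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        h_seq = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((h, c_prev, i, f, g, o, tc))
            h = o * tc
            h_seq[:, t] = h
        return h_seq

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


class BiLSTM:
    """Bidirectional LSTM; per-timestep output is the 2H concatenation."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LSTMDirection(input_dim, hidden, rng, "fwd")
        self.bwd = _LSTMDirection(input_dim, hidden, rng, "bwd")
        self.params = self.fwd.params + self.bwd.params

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([h_f, h_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.H
        dx_f = self.fwd.backward(np.ascontiguousarray(dout[:, :, :H]))
        dx_b = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, H:]))
        return dx_f + dx_b[:, ::-1]


class BatchNorm:
    """Per-feature normalization over the batch and time axes.

    Training uses batch statistics and updates exponential running
    moments (momentum 0.9); inference uses the running moments, so
    predictions are independent of batch partitioning.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Param("bn/gamma", np.ones(dim))
        self.beta = Param("bn/beta", np.zeros(dim))
        self.params = [self.gamma, self.beta]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not self._train:
            return dxhat * inv_std
        N = dout.shape[0] * dout.shape[1]
        return (
            inv_std
            / N
            * (
                N * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )


class Attention:
    """Additive attention pooling over timesteps.

    score_t = v^T tanh(W h_t + b); alpha = softmax(score); the output is
    the alpha-weighted sum of the per-timestep features — one vector per
    record, with weights that are nonnegative and sum to 1.
    """

    def __init__(self, input_dim: int, attn_dim: int, rng: np.random.Generator):
        self.W = Param("attn/W", glorot_uniform(rng, (input_dim, attn_dim)))
        self.b = Param("attn/b", np.zeros(attn_dim))
        self.v = Param("attn/v", glorot_uniform(rng, (attn_dim, 1))[:, 0])
        self.params = [self.W, self.b, self.v]
        self.last_weights: np.ndarray | None = None

    def forward(self, h: np.ndarray, train: bool) -> np.ndarray:
        u = np.tanh(h @ self.W.value + self.b.value)      # (B,T,A)
        s = u @ self.v.value                               # (B,T)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        alpha = e / e.sum(axis=1, keepdims=True)
        self._h, self._u, self._alpha = h, u, alpha
        self.last_weights = alpha
        return np.einsum("bt,btf->bf", alpha, h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, u, alpha = self._h, self._u, self._alpha
        dalpha = np.einsum("bf,btf->bt", dout, h)
        dh = alpha[:, :, None] * dout[:, None, :]
        ds = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        self.v.grad += np.einsum("bta,bt->a", u, ds)
        du = ds[:, :, None] * self.v.value
        dpre = du * (1.0 - u * u)
        self.W.grad += np.einsum("btf,bta->fa", h, dpre)
        self.b.grad += dpre.sum(axis=(0, 1))
        dh += dpre @ self.W.value.T
        return dh


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, ratio: float, rng: np.random.Generator):
        if not 0.0 <= ratio < 1.0:
            raise ValueError("dropout ratio must be in [0, 1)")
        self.ratio = ratio
        self.rng = rng
        self.params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.ratio == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.ratio) / (1.0 - self.ratio)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense:
    """Affine output layer producing logits."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.W = Param("dense/W", glorot_uniform(rng, (input_dim, units)))
        self.b = Param("dense/b", np.zeros(units))
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def sigmoid_bce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Binary cross-entropy on logits; returns (loss, probs, dlogits)."""
    z = logits[:, 0]
    p = _sigmoid(z)
    # log(1+exp) in a stable form
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dlogits = ((p - y) / y.size)[:, None]
    return loss, p, dlogits


def softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Categorical cross-entropy on logits for integer labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = y.size
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, p, dlogits / n


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SequenceClassifierNet:
    """Embedding -> BiLSTM -> batch norm -> attention -> dropout -> dense.

    ``output_units=1`` gives a sigmoid binary head; ``output_units=3`` a
    softmax three-class head.
    """

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int,
        lstm_size: int,
        dropout_ratio: float,
        output_units: int,
        rng: np.random.Generator,
        attn_dim: int | None = None,
    ):
        if vocab_size < 1 or embed_dim < 1 or lstm_size < 1 or output_units < 1:
            raise ValueError("all network dimensions must be positive")
        feat = 2 * lstm_size
        self.output_units = output_units
        self.embedding = Embedding(vocab_size, embed_dim, rng)
        self.bilstm = BiLSTM(embed_dim, lstm_size, rng)
        self.bn = BatchNorm(feat)
        self.attention = Attention(feat, attn_dim or lstm_size, rng)
        self.dropout = Dropout(dropout_ratio, rng)
        self.dense = Dense(feat, output_units, rng)
        self.layers = [
            self.embedding,
            self.bilstm,
            self.bn,
            self.attention,
            self.dropout,
            self.dense,
        ]
        self.params: list[Param] = [p for layer in self.layers for p in layer.params]

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        x = ids
        for layer in self.layers:
            x = layer.forward(x, train)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-1 probability (binary) or class probabilities (softmax)."""
        if ids.shape[0] == 0:
            shape = (0,) if self.output_units == 1 else (0, self.output_units)
            return np.empty(shape)
        outs = []
        for start in range(0, ids.shape[0], batch_size):
            logits = self.forward(ids[start : start + batch_size], train=False)
            if self.output_units == 1:
                outs.append(_sigmoid(logits[:, 0]))
            else:
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs)

    def recalibrate_bn(self, ids: np.ndarray, batch_size: int = 256) -> None:
        """Set the normalization moments to their exact dataset values.

        Mini-batch statistics drift quickly during short training runs,
        so inference-mode moments are re-estimated from the full
        training set (precise batch norm).  Keeps inference independent
        of batch partitioning.
        """
        total = np.zeros_like(self.bn.running_mean)
        total_sq = np.zeros_like(self.bn.running_var)
        count = 0
        for start in range(0, ids.shape[0], batch_size):
            x = self.embedding.forward(ids[start : start + batch_size], False)
            h = self.bilstm.forward(x, False)
            flat = h.reshape(-1, h.shape[2])
            total += flat.sum(axis=0)
            total_sq += (flat * flat).sum(axis=0)
            count += flat.shape[0]
        mean = total / count
        self.bn.running_mean = mean
        self.bn.running_var = np.maximum(total_sq / count - mean * mean, 0.0)

    def get_weights(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params}
        state["bn/running_mean"] = self.bn.running_mean.copy()
        state["bn/running_var"] = self.bn.running_var.copy()
        return state

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.value[...] = state[p.name]
        self.bn.running_mean[...] = state["bn/running_mean"]
        self.bn.running_var[...] = state["bn/running_var"]
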