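"""Numpy implementation of the context-attentive LSTM regressor.

Architecture: stacked LSTM layers (fused-gate formulation) -> additive or
bilinear attention whose scores are conditioned on a per-patient clinical
context vector -> concat(pooled state, context) -> tanh dense layer ->
linear output. Gradients are derived by hand (BPTT through the fused
gates) and verified against numerical differentiation in the test suite.

The network is causal and the attention assigns exactly zero weight to
masked steps, so appending masked padding rows to a sequence can never
change the output — the property batching relies on.

Shapes: X (B, T, F) sequence input, C (B, Cd) context, mask (B, T) bool.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, TrainingDivergenceError

__all__ = ["ContextLSTMNet", "AdamState", "attention_forward"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class ContextLSTMNet:
    """Parameter container + forward/backward passes.

    Not user-facing: the sklearn-style estimator in :mod:`afbnp.model`
    owns training, target scaling and early stopping.
    """

    def __init__(
        self,
        input_dim: int,
        context_dim: int,
        lstm_units: tuple[int, ...] = (64, 32, 16),
        attention_dim: int = 16,
        head_hidden: int = 16,
        attention: str = "additive",
        seed: int = 0,
    ):
        if attention not in ("additive", "bilinear"):
            raise ConfigurationError(f"unknown attention form {attention!r}")
        if min(*lstm_units, attention_dim, head_hidden, input_dim) <= 0:
            raise ConfigurationError("all layer sizes must be positive")
        self.input_dim = input_dim
        self.context_dim = context_dim
        self.lstm_units = tuple(lstm_units)
        self.attention_dim = attention_dim
        self.head_hidden = head_hidden
        self.attention = attention
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        d = input_dim
        for l, h in enumerate(self.lstm_units):
            p[f"W{l}"] = _glorot(rng, d, 4 * h)
            p[f"U{l}"] = _glorot(rng, h, 4 * h)
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            p[f"b{l}"] = b
            d = h
        top = self.lstm_units[-1]
        if attention == "additive":
            p["Wh"] = _glorot(rng, top, attention_dim)
            p["Wc"] = _glorot(rng, context_dim, attention_dim)
            p["ba"] = np.zeros(attention_dim)
            p["v"] = _glorot(rng, attention_dim, 1, shape=(attention_dim,))
        else:
            p["Wb"] = _glorot(rng, top, context_dim)
        p["Wd1"] = _glorot(rng, top + context_dim, head_hidden)
        p["bd1"] = np.zeros(head_hidden)
        p["Wd2"] = _glorot(rng, head_hidden, 1)
        p["bd2"] = np.zeros(1)
        self.params = p

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    @property
    def weight_keys(self) -> tuple[str, ...]:
        """Parameters subject to the L2 penalty (weight matrices, not biases)."""
        return tuple(
            k for k in self.params if k[0] in ("W", "U", "v")
        )

    # -- forward ----------------------------------------------------------

    def _lstm_layer_forward(self, x: np.ndarray, l: int):
        W, U, b = self.params[f"W{l}"], self.params[f"U{l}"], self.params[f"b{l}"]
        B, T, D = x.shape
        H = U.shape[0]
        xz = x.reshape(B * T, D) @ W
        xz = xz.reshape(B, T, 4 * H)
        h = np.zeros((B, T, H))
        c = np.zeros((B, T, H))
        gates = np.zeros((B, T, 4 * H))
        tanh_c = np.zeros((B, T, H))
        h_prev = np.zeros((B, H))
        c_prev = np.zeros((B, H))
        for t in range(T):
            z = xz[:, t] + h_prev @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            c[:, t] = c_t
            tanh_c[:, t] = tc
            h[:, t] = h_t
            h_prev, c_prev = h_t, c_t
        return h, {"x": x, "h": h, "c": c, "gates": gates, "tanh_c": tanh_c, "l": l}

    def _lstm_layer_backward(self, cache, dh_out: np.ndarray, grads):
        l = cache["l"]
        W, U = self.params[f"W{l}"], self.params[f"U{l}"]
        x, h, c, gates, tanh_c = (
            cache["x"],
            cache["h"],
            cache["c"],
            cache["gates"],
            cache["tanh_c"],
        )
        B, T, D = x.shape
        H = U.shape[0]
        dz_all = np.zeros((B, T, 4 * H))
        dU = np.zeros_like(U)
        dh_rec = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = tanh_c[:, t]
            dh = dh_out[:, t] + dh_rec
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            c_prev = c[:, t - 1] if t > 0 else 0.0
            di = dc * g
            dg = dc * i
            df = dc * c_prev if t > 0 else np.zeros_like(dc)
            dz = dz_all[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            if t > 0:
                dU += h[:, t - 1].T @ dz
            dh_rec = dz @ U.T
            dc = dc * f
        grads[f"W{l}"] = x.reshape(B * T, D).T @ dz_all.reshape(B * T, 4 * H)
        grads[f"U{l}"] = dU
        grads[f"b{l}"] = dz_all.sum(axis=(0, 1))
        return (dz_all.reshape(B * T, 4 * H) @ W.T).reshape(B, T, D)

    def forward(
        self,
        X: np.ndarray,
        C: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Returns (predictions (B,), attention weights (B, T), cache)."""
        X = np.asarray(X, dtype=np.float64)
        C = np.asarray(C, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if X.ndim != 3:
            raise ConfigurationError("X must be (B, T, F)")
        if X.shape[2] != self.input_dim:
            raise ConfigurationError(
                f"expected {self.input_dim} sequence features, got {X.shape[2]}"
            )
        if not mask.any(axis=1).all():
            raise InsufficientDataError("every sequence needs >=1 unmasked step")
        caches = []
        hcur = X
        for l in range(len(self.lstm_units)):
            hcur, cache = self._lstm_layer_forward(hcur, l)
            caches.append(cache)
        h3 = hcur  # (B, T, H_top)
        a, att_cache = attention_forward(self.params, h3, C, mask, self.attention)
        pooled = np.einsum("bt,bth->bh", a, h3)
        p = self.params
        if train and dropout > 0.0:
            if rng is None:
                raise ConfigurationError("training forward pass needs an rng")
            keep = 1.0 - dropout
            m1 = (rng.random(pooled.shape) < keep) / keep
        else:
            m1 = np.ones_like(pooled)
        pooled_d = pooled * m1
        feat = np.concatenate([pooled_d, C], axis=1)
        a1 = feat @ p["Wd1"] + p["bd1"]
        h1 = np.tanh(a1)
        if train and dropout > 0.0:
            keep = 1.0 - dropout
            m2 = (rng.random(h1.shape) < keep) / keep
        else:
            m2 = np.ones_like(h1)
        h1_d = h1 * m2
        yhat = (h1_d @ p["Wd2"] + p["bd2"]).ravel()
        cache = {
            "caches": caches,
            "h3": h3,
            "a": a,
            "att": att_cache,
            "pooled": pooled,
            "m1": m1,
            "m2": m2,
            "feat": feat,
            "h1": h1,
            "h1_d": h1_d,
            "C": C,
            "mask": mask,
        }
        return yhat, a, cache

    # -- backward ---------------------------------------------------------

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of the scalar loss wrt every parameter; ``dy`` is
        dLoss/dyhat, shape (B,)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        h1_d, h1, feat, m1, m2 = (
            cache["h1_d"],
            cache["h1"],
            cache["feat"],
            cache["m1"],
            cache["m2"],
        )
        dy = dy.reshape(-1, 1)
        grads["Wd2"] = h1_d.T @ dy
        grads["bd2"] = dy.sum(axis=0)
        dh1 = (dy @ p["Wd2"].T) * m2
        da1 = dh1 * (1.0 - h1 * h1)
        grads["Wd1"] = feat.T @ da1
        grads["bd1"] = da1.sum(axis=0)
        dfeat = da1 @ p["Wd1"].T
        H = self.lstm_units[-1]
        dpooled = dfeat[:, :H] * m1
        h3, a = cache["h3"], cache["a"]
        da = np.einsum("bh,bth->bt", dpooled, h3)
        dh3 = a[:, :, None] * dpooled[:, None, :]
        # softmax backward (a is exactly 0 at masked steps, so ds is too)
        ds = a * (da - np.sum(a * da, axis=1, keepdims=True))
        att = cache["att"]
        C = cache["C"]
        if self.attention == "additive":
            u = att["u"]
            du = ds[:, :, None] * p["v"]
            grads["v"] = np.einsum("bta,bt->a", u, ds)
            dpre = du * (1.0 - u * u)
            B, T, A = dpre.shape
            grads["Wh"] = h3.reshape(B * T, H).T @ dpre.reshape(B * T, A)
            dh3 = dh3 + dpre @ p["Wh"].T
            sctx = dpre.sum(axis=1)
            grads["Wc"] = C.T @ sctx
            grads["ba"] = dpre.sum(axis=(0, 1))
        else:
            q = att["q"]
            dh3 = dh3 + ds[:, :, None] * q[:, None, :]
            dq = np.einsum("bt,bth->bh", ds, h3)
            grads["Wb"] = dq.T @ C
        dh_out = dh3
        for cache_l in reversed(cache["caches"]):
            dh_out = self._lstm_layer_backward(cache_l, dh_out, grads)
        return grads


def attention_forward(
    params: dict[str, np.ndarray],
    h: np.ndarray,
    C: np.ndarray,
    mask: np.ndarray,
    kind: str = "additive",
):
    """Context-conditioned attention weights over time steps.

    Additive (default): e_t = v . tanh(Wh h_t + Wc c + ba); bilinear:
    e_t = h_t . (Wb c). Masked steps receive an effectively -inf score and
    exactly zero weight; weights over unmasked steps form a simplex.
    Returns (weights (B, T), cache).
    """
    if not mask.any(axis=1).all():
        raise InsufficientDataError("all steps masked for at least one sequence")
    if kind == "additive":
        pre = h @ params["Wh"] + (C @ params["Wc"] + params["ba"])[:, None, :]
        u = np.tanh(pre)
        s = u @ params["v"]
        cache = {"u": u}
    elif kind == "bilinear":
        q = C @ params["Wb"].T
        s = np.einsum("bth,bh->bt", h, q)
        cache = {"q": q}
    else:
        raise ConfigurationError(f"unknown attention form {kind!r}")
    s = np.where(mask, s, -np.inf)
    m = np.max(s, axis=1, keepdims=True)
    e = np.where(mask, np.exp(s - m), 0.0)
    a = e / e.sum(axis=1, keepdims=True)
    return a, cache


class AdamState:
    """Adam optimizer with an additive L2 penalty on weight matrices."""

    def __init__(self, net: ContextLSTMNet, lr: float = 1e-3, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in net.params.items()}
        self._weight_keys = set(net.weight_keys)

    def step(self, net: ContextLSTMNet, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in net.params.items():
            g = grads[k].reshape(p.shape)
            if not np.all(np.isfinite(g)):
                raise TrainingDivergenceError(f"non-finite gradient in {k}")
            if self.l2 > 0.0 and k in self._weight_keys:
                g = g + 2.0 * self.l2 * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
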