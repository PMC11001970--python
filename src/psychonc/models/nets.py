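"""Numpy neural networks for document classification.

Small, fully self-contained implementations with explicit backprop:

* ``CNNNet`` — parallel 1-d convolutions over token embeddings (widths
  {2,3,4} by default), ReLU, global max-pool, dropout, linear score.
* ``BiLSTMNet`` — one bidirectional LSTM layer, masked mean-pool over
  time of the concatenated direction states, linear score.
* ``TransformerNet`` — learned embeddings + sinusoidal positions, one
  single-head self-attention block with residual and a ReLU feed-forward
  layer, masked mean-pool, linear score.  Positional capacity is fixed at
  construction (``n_positions``), mirroring encoder token limits.
* ``MeanPoolNet`` — logistic regression over mean-pooled embeddings; its
  score is linear in the embedded input, which gives attribution methods
  a closed-form reference.

Every net maps a batch of embedded documents ``X (B, L, D)`` with a
validity mask ``(B, L)`` to one logit per document and can backpropagate
to both parameters and ``X`` — the latter is what integrated gradients
differentiates.  All operations are deterministic given the seeds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNNNet", "BiLSTMNet", "TransformerNet", "MeanPoolNet", "Adam"]


def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 5e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            if k not in params:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------


class MeanPoolNet:
    """logit = w . meanpool(X) + b — linear in the embedded input."""

    def __init__(self, embed_dim: int):
        self.embed_dim = embed_dim

    def init_params(self, rng) -> dict:
        return {"w": rng.normal(0, 0.1, size=self.embed_dim),
                "b": np.zeros(1)}

    def forward(self, params, X, mask, *, train=False, drop_rng=None):
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (X * mask[:, :, None]).sum(axis=1) / denom
        logit = pooled @ params["w"] + params["b"][0]
        return logit, (X, mask, denom, pooled)

    def backward(self, params, cache, dlogit):
        X, mask, denom, pooled = cache
        grads = {"w": dlogit @ pooled, "b": np.array([dlogit.sum()])}
        dpool = dlogit[:, None] * params["w"][None, :]
        dX = (dpool[:, None, :] / denom[:, :, None]) * mask[:, :, None]
        return grads, dX


class CNNNet:
    """Parallel 1-d convolutions, ReLU, global max-pool, dropout, linear."""

    def __init__(self, embed_dim: int, widths=(2, 3, 4), n_filters: int = 64,
                 dropout: float = 0.5):
        self.embed_dim = embed_dim
        self.widths = tuple(widths)
        self.n_filters = n_filters
        self.dropout = dropout

    def init_params(self, rng) -> dict:
        p = {}
        for w in self.widths:
            p[f"W{w}"] = _glorot(rng, (w * self.embed_dim, self.n_filters))
            p[f"c{w}"] = np.zeros(self.n_filters)
        total = self.n_filters * len(self.widths)
        p["w_out"] = rng.normal(0, 0.05, size=total)
        p["b_out"] = np.zeros(1)
        return p

    @staticmethod
    def _windows(X, w):
        # (B, L-w+1, w*D) sliding windows, as a strided view
        B, L, D = X.shape
        s0, s1, s2 = X.strides
        view = np.lib.stride_tricks.as_strided(
            X, shape=(B, L - w + 1, w, D), strides=(s0, s1, s1, s2))
        return view.reshape(B, L - w + 1, w * D)

    def forward(self, params, X, mask, *, train=False, drop_rng=None):
        B, L, D = X.shape
        wmax = max(self.widths)
        if L < wmax:  # pad so every width has at least one window
            X = np.concatenate(
                [X, np.zeros((B, wmax - L, D))], axis=1)
            mask = np.concatenate(
                [mask, np.zeros((B, wmax - L))], axis=1)
            L = wmax
        pooled_parts, caches = [], []
        for w in self.widths:
            cols = self._windows(X, w)
            pre = cols @ params[f"W{w}"] + params[f"c{w}"]
            # a window is valid only if all its tokens are real; ReLU output
            # is >= 0, so zeroing invalid windows keeps the max correct
            wmask = np.ones((B, L - w + 1))
            for j in range(w):
                wmask *= mask[:, j:L - w + 1 + j]
            act = np.maximum(pre, 0.0) * wmask[:, :, None]
            arg = act.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            caches.append((cols, pre, wmask, arg))
        feat = np.concatenate(pooled_parts, axis=1)
        if train and self.dropout > 0:
            keep = (drop_rng.random(feat.shape) >= self.dropout)
            feat_d = feat * keep / (1.0 - self.dropout)
        else:
            keep = None
            feat_d = feat
        logit = feat_d @ params["w_out"] + params["b_out"][0]
        return logit, (X.shape, caches, feat, feat_d, keep, mask)

    def backward(self, params, cache, dlogit):
        (B, L, D), caches, feat, feat_d, keep, mask = cache
        grads = {"w_out": dlogit @ feat_d,
                 "b_out": np.array([dlogit.sum()])}
        dfeat = dlogit[:, None] * params["w_out"][None, :]
        if keep is not None:
            dfeat = dfeat * keep / (1.0 - self.dropout)
        dX = np.zeros((B, L, D))
        off = 0
        for w, (cols, pre, wmask, arg) in zip(self.widths, caches):
            F = self.n_filters
            dpool = dfeat[:, off:off + F]
            off += F
            dact = np.zeros_like(pre)  # (B, P, F)
            np.put_along_axis(dact, arg[:, None, :], dpool[:, None, :], axis=1)
            dpre = dact * (pre > 0) * wmask[:, :, None]
            P = cols.shape[1]
            grads[f"W{w}"] = (cols.reshape(B * P, -1).T
                              @ dpre.reshape(B * P, F))
            grads[f"c{w}"] = dpre.sum(axis=(0, 1))
            dcols = dpre @ params[f"W{w}"].T  # (B, P, w*D)
            dcols = dcols.reshape(B, -1, w, D)
            for j in range(w):
                dX[:, j:dcols.shape[1] + j, :] += dcols[:, :, j, :]
        return grads, dX


def _masked_pool(hs, mask, pooling):
    """Pool (B, L, D) over time; returns (pooled, cache-for-backward)."""
    if pooling == "mean":
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (hs * mask[:, :, None]).sum(axis=1) / denom
        return pooled, ("mean", mask, denom)
    masked = np.where(mask[:, :, None] > 0, hs, -1e9)
    arg = masked.argmax(axis=1)  # (B, D)
    pooled = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
    return pooled, ("max", mask, arg)


def _masked_pool_backward(dpool, cache, shape):
    kind = cache[0]
    if kind == "mean":
        _, mask, denom = cache
        return (dpool[:, None, :] / denom[:, :, None]) * mask[:, :, None]
    _, mask, arg = cache
    dh = np.zeros(shape)
    np.put_along_axis(dh, arg[:, None, :], dpool[:, None, :], axis=1)
    return dh * mask[:, :, None]


class BiLSTMNet:
    """One bidirectional LSTM layer, masked pooling over time, linear score.

    ``pooling='max'`` (default) takes the feature-wise maximum over
    positions, which preserves single-token evidence regardless of
    document length; ``'mean'`` averages over positions.
    """

    def __init__(self, embed_dim: int, hidden_dim: int = 128,
                 pooling: str = "max"):
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        if pooling not in ("max", "mean"):
            raise ValueError("pooling must be 'max' or 'mean'")
        self.pooling = pooling

    def init_params(self, rng) -> dict:
        D, H = self.embed_dim, self.hidden_dim
        p = {}
        for tag in ("f", "r"):
            p[f"W_{tag}"] = _glorot(rng, (D + H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            p[f"b_{tag}"] = b
        p["w_out"] = rng.normal(0, 0.05, size=2 * H)
        p["b_out"] = np.zeros(1)
        return p

    @staticmethod
    def _sigmoid(x):
        return 0.5 * (1.0 + np.tanh(0.5 * x))

    def _run(self, params, X, mask, tag):
        B, L, D = X.shape
        H = self.hidden_dim
        W, b = params[f"W_{tag}"], params[f"b_{tag}"]
        order = range(L) if tag == "f" else range(L - 1, -1, -1)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        hs = np.zeros((B, L, H))
        for t in order:
            m = mask[:, t:t + 1]
            z = np.concatenate([X[:, t, :], h], axis=1) @ W + b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = self._sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append((t, h.copy(), c.copy(), i, f, g, o, c_new, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            hs[:, t, :] = h
        return hs, steps

    def forward(self, params, X, mask, *, train=False, drop_rng=None):
        hs_f, steps_f = self._run(params, X, mask, "f")
        hs_r, steps_r = self._run(params, X, mask, "r")
        hs = np.concatenate([hs_f, hs_r], axis=2)  # (B, L, 2H)
        pooled, pcache = _masked_pool(hs, mask, self.pooling)
        logit = pooled @ params["w_out"] + params["b_out"][0]
        return logit, (X, mask, pcache, hs.shape, pooled, steps_f, steps_r)

    def _bptt(self, params, X, mask, dh_seq, steps, tag):
        B, L, D = X.shape
        H = self.hidden_dim
        W = params[f"W_{tag}"]
        dW = np.zeros_like(W)
        db = np.zeros(4 * H)
        dX = np.zeros_like(X)
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        for (t, h_prev, c_prev, i, f, g, o, c_new, m) in reversed(steps):
            dh_total = dh_seq[:, t, :] + dh_carry
            # state carried forward only where mask=1; held otherwise
            dh_new = dh_total * m
            dh_prev_hold = dh_total * (1 - m)
            dc_new = dc_carry * m
            dc_prev_hold = dc_carry * (1 - m)
            tanh_c = np.tanh(c_new)
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1 - tanh_c ** 2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_new * f + dc_prev_hold
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            inp = np.concatenate([X[:, t, :], h_prev], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ W.T
            dX[:, t, :] += dinp[:, :D]
            dh_carry = dinp[:, D:] + dh_prev_hold
            dc_carry = dc_prev
        return dW, db, dX

    def backward(self, params, cache, dlogit):
        X, mask, pcache, hs_shape, pooled, steps_f, steps_r = cache
        H = self.hidden_dim
        grads = {"w_out": dlogit @ pooled,
                 "b_out": np.array([dlogit.sum()])}
        dpool = dlogit[:, None] * params["w_out"][None, :]
        dh_seq = _masked_pool_backward(dpool, pcache, hs_shape)
        dW_f, db_f, dX_f = self._bptt(
            params, X, mask, dh_seq[:, :, :H], steps_f, "f")
        dW_r, db_r, dX_r = self._bptt(
            params, X, mask, dh_seq[:, :, H:], steps_r, "r")
        grads.update({"W_f": dW_f, "b_f": db_f, "W_r": dW_r, "b_r": db_r})
        return grads, dX_f + dX_r


class TransformerNet:
    """Single-head self-attention block with residuals, mean-pool, linear.

    ``n_positions`` bounds the sequence length the encoder can represent;
    longer inputs must be truncated upstream.
    """

    def __init__(self, embed_dim: int, n_positions: int = 512,
                 attn_dim: int | None = None, ff_dim: int = 32,
                 pooling: str = "max", pos_scale: float = 0.1):
        self.embed_dim = embed_dim
        self.n_positions = n_positions
        self.attn_dim = attn_dim or embed_dim
        self.ff_dim = ff_dim
        if pooling not in ("max", "mean"):
            raise ValueError("pooling must be 'max' or 'mean'")
        self.pooling = pooling
        pos = np.arange(n_positions)[:, None]
        dim = np.arange(embed_dim)[None, :]
        angle = pos / np.power(10000.0, (2 * (dim // 2)) / embed_dim)
        pe = np.where(dim % 2 == 0, np.sin(angle), np.cos(angle))
        # damped so position does not swamp the content embeddings
        self.positional = pos_scale * pe  # (n_positions, D)

    def init_params(self, rng) -> dict:
        D, Dk, F = self.embed_dim, self.attn_dim, self.ff_dim
        return {
            "Wq": _glorot(rng, (D, Dk)), "Wk": _glorot(rng, (D, Dk)),
            "Wv": _glorot(rng, (D, D)),
            "W1": _glorot(rng, (D, F)), "b1": np.zeros(F),
            "W2": _glorot(rng, (F, D)), "b2": np.zeros(D),
            "w_out": rng.normal(0, 0.05, size=D), "b_out": np.zeros(1),
        }

    def forward(self, params, X, mask, *, train=False, drop_rng=None):
        B, L, D = X.shape
        if L > self.n_positions:
            raise ValueError(
                f"sequence length {L} exceeds positional capacity "
                f"{self.n_positions}")
        Xp = X + self.positional[None, :L, :]
        Q = Xp @ params["Wq"]
        K = Xp @ params["Wk"]
        V = Xp @ params["Wv"]
        scale = 1.0 / np.sqrt(self.attn_dim)
        S = (Q @ K.transpose(0, 2, 1)) * scale
        S = S - 1e9 * (1.0 - mask[:, None, :])  # mask keys
        S = S - S.max(axis=2, keepdims=True)
        expS = np.exp(S)
        A = expS / expS.sum(axis=2, keepdims=True)
        Hd = A @ V
        R = Xp + Hd
        pre = R @ params["W1"] + params["b1"]
        act = np.maximum(pre, 0.0)
        Fo = act @ params["W2"] + params["b2"]
        U = R + Fo
        pooled, pcache = _masked_pool(U, mask, self.pooling)
        logit = pooled @ params["w_out"] + params["b_out"][0]
        cache = (Xp, mask, Q, K, V, A, R, pre, act, pcache, U.shape,
                 pooled, scale)
        return logit, cache

    def backward(self, params, cache, dlogit):
        (Xp, mask, Q, K, V, A, R, pre, act, pcache, U_shape, pooled,
         scale) = cache
        grads = {"w_out": dlogit @ pooled,
                 "b_out": np.array([dlogit.sum()])}
        dpool = dlogit[:, None] * params["w_out"][None, :]
        dU = _masked_pool_backward(dpool, pcache, U_shape)
        dR = dU.copy()
        dFo = dU
        B, L, D = Xp.shape
        act2 = act.reshape(B * L, -1)
        dFo2 = dFo.reshape(B * L, D)
        grads["W2"] = act2.T @ dFo2
        grads["b2"] = dFo2.sum(axis=0)
        dact = dFo @ params["W2"].T
        dpre = dact * (pre > 0)
        grads["W1"] = R.reshape(B * L, D).T @ dpre.reshape(B * L, -1)
        grads["b1"] = dpre.sum(axis=(0, 1))
        dR += dpre @ params["W1"].T
        dHd = dR
        dA = dHd @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dHd
        # softmax backward, row-wise over keys
        dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))
        dS = dS * scale
        dQ = dS @ K
        dK = dS.transpose(0, 2, 1) @ Q
        dXp = dR.copy()  # residual path
        dXp += dQ @ params["Wq"].T
        dXp += dK @ params["Wk"].T
        dXp += dV @ params["Wv"].T
        Xp2 = Xp.reshape(B * L, D)
        grads["Wq"] = Xp2.T @ dQ.reshape(B * L, -1)
        grads["Wk"] = Xp2.T @ dK.reshape(B * L, -1)
        grads["Wv"] = Xp2.T @ dV.reshape(B * L, -1)
        return grads, dXp
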