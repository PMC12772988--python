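"""Minimal recurrent network engine for framewise sequence classification.

Implements exactly the architecture the boundary detector needs — a stack of
bidirectional LSTM layers followed by two fully-connected layers and a
framewise softmax — as plain numpy with hand-derived backpropagation through
time and an Adam optimizer.  Everything is deterministic given a seed.

Gradients are exact (they are verified against central finite differences in
the test suite), and all state lives in a flat ``name -> ndarray`` parameter
dictionary so checkpoints serialize to a single ``.npz``.

Shapes: inputs are (batch, time, features); gate order is (input, forget,
cell, output); bidirectional layers concatenate forward and backward hidden
states, so their output width is ``2 * hidden``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BLSTMClassifier", "Adam", "softmax", "weighted_ce_loss"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _lstm_forward(x, Wx, Wh, b):
    """Unidirectional LSTM over (B, T, D) input; returns outputs and cache."""
    B, T, D = x.shape
    H = Wh.shape[0]
    pre = x.reshape(B * T, D) @ Wx
    pre = pre.reshape(B, T, 4 * H)
    gates = np.empty((T, B, 4 * H), dtype=x.dtype)
    cs = np.empty((T, B, H), dtype=x.dtype)
    tcs = np.empty((T, B, H), dtype=x.dtype)
    hs = np.zeros((T + 1, B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    for t in range(T):
        a = pre[:, t] + hs[t] @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        hs[t + 1] = o * tc
        gates[t, :, :H], gates[t, :, H:2 * H] = i, f
        gates[t, :, 2 * H:3 * H], gates[t, :, 3 * H:] = g, o
        cs[t], tcs[t] = c, tc
    out = hs[1:].transpose(1, 0, 2)  # (B, T, H)
    cache = (x, gates, cs, tcs, hs)
    return out, cache


def _lstm_backward(dout, cache, Wx, Wh):
    """BPTT for :func:`_lstm_forward`; returns (dx, dWx, dWh, db)."""
    x, gates, cs, tcs, hs = cache
    B, T, D = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=x.dtype)
    dpre = np.empty((B, T, 4 * H), dtype=x.dtype)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    dout_t = dout.transpose(1, 0, 2)  # (T, B, H)
    for t in range(T - 1, -1, -1):
        i = gates[t, :, :H]
        f = gates[t, :, H:2 * H]
        g = gates[t, :, 2 * H:3 * H]
        o = gates[t, :, 3 * H:]
        c_prev = cs[t - 1] if t > 0 else np.zeros((B, H), dtype=x.dtype)
        dh = dout_t[t] + dh_next
        tc = tcs[t]
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWh += hs[t].T @ da
        db += da.sum(axis=0)
        dh_next = da @ Wh.T
        dpre[:, t] = da
    dWx = x.reshape(B * T, D).T @ dpre.reshape(B * T, 4 * H)
    dx = (dpre.reshape(B * T, 4 * H) @ Wx.T).reshape(B, T, D)
    return dx, dWx, dWh, db


def weighted_ce_loss(logits, y, class_weights=None):
    """Framewise weighted cross-entropy.

    ``logits``: (B, T, C); ``y``: (B, T) int labels.  Returns (loss, dlogits)
    where the loss is sum(w_y * ce) / sum(w_y).
    """
    B, T, C = logits.shape
    p = softmax(logits)
    yf = y.reshape(-1)
    pf = p.reshape(-1, C)
    w = np.ones(C, dtype=logits.dtype) if class_weights is None else np.asarray(
        class_weights, dtype=logits.dtype)
    wy = w[yf]
    logp = np.log(np.clip(pf[np.arange(len(yf)), yf], 1e-12, None))
    wsum = wy.sum()
    loss = float(-(wy * logp).sum() / wsum)
    dlog = pf.copy()
    dlog[np.arange(len(yf)), yf] -= 1.0
    dlog *= (wy / wsum)[:, None]
    return loss, dlog.reshape(B, T, C)


class BLSTMClassifier:
    """Stacked BLSTM + two FC layers + framewise softmax over 2 classes."""

    FORMAT_VERSION = 1

    def __init__(self, n_input=80, hidden=128, fc_hidden=256, n_layers=2,
                 n_classes=2, seed=0, dtype=np.float32):
        self.n_input, self.hidden, self.fc_hidden = n_input, hidden, fc_hidden
        self.n_layers, self.n_classes = n_layers, n_classes
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        d_in = n_input
        for layer in range(n_layers):
            for direction in ("fw", "bw"):
                s = 1.0 / np.sqrt(hidden)
                pre = f"l{layer}_{direction}"
                self.params[f"{pre}_Wx"] = rng.uniform(-s, s, (d_in, 4 * hidden))
                self.params[f"{pre}_Wh"] = rng.uniform(-s, s, (hidden, 4 * hidden))
                b = np.zeros(4 * hidden)
                b[hidden:2 * hidden] = 1.0  # forget-gate bias init
                self.params[f"{pre}_b"] = b
            d_in = 2 * hidden
        s1 = 1.0 / np.sqrt(d_in)
        self.params["fc1_W"] = rng.uniform(-s1, s1, (d_in, fc_hidden))
        self.params["fc1_b"] = np.zeros(fc_hidden)
        s2 = 1.0 / np.sqrt(fc_hidden)
        self.params["fc2_W"] = rng.uniform(-s2, s2, (fc_hidden, n_classes))
        self.params["fc2_b"] = np.zeros(n_classes)
        for k in self.params:
            self.params[k] = self.params[k].astype(self.dtype)

    # -- forward / backward ------------------------------------------------

    def forward(self, x, want_cache=False):
        """Logits (B, T, n_classes) for input (B, T, n_input)."""
        x = np.asarray(x, dtype=self.dtype)
        caches = []
        h = x
        for layer in range(self.n_layers):
            pre_f, pre_b = f"l{layer}_fw", f"l{layer}_bw"
            out_f, cache_f = _lstm_forward(
                h, self.params[f"{pre_f}_Wx"], self.params[f"{pre_f}_Wh"],
                self.params[f"{pre_f}_b"])
            out_b, cache_b = _lstm_forward(
                h[:, ::-1], self.params[f"{pre_b}_Wx"], self.params[f"{pre_b}_Wh"],
                self.params[f"{pre_b}_b"])
            h = np.concatenate([out_f, out_b[:, ::-1]], axis=2)
            caches.append((cache_f, cache_b))
        z1 = h @ self.params["fc1_W"] + self.params["fc1_b"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ self.params["fc2_W"] + self.params["fc2_b"]
        if want_cache:
            return logits, (caches, h, z1, a1)
        return logits

    def backward(self, dlogits, cache):
        caches, h, z1, a1 = cache
        grads = {}
        dlogits = dlogits.astype(self.dtype)
        B, T, _ = dlogits.shape
        grads["fc2_W"] = a1.reshape(B * T, -1).T @ dlogits.reshape(B * T, -1)
        grads["fc2_b"] = dlogits.sum(axis=(0, 1))
        da1 = dlogits @ self.params["fc2_W"].T
        dz1 = da1 * (z1 > 0)
        grads["fc1_W"] = h.reshape(B * T, -1).T @ dz1.reshape(B * T, -1)
        grads["fc1_b"] = dz1.sum(axis=(0, 1))
        dh = dz1 @ self.params["fc1_W"].T
        for layer in range(self.n_layers - 1, -1, -1):
            cache_f, cache_b = caches[layer]
            H = self.hidden
            pre_f, pre_b = f"l{layer}_fw", f"l{layer}_bw"
            dx_f, dWx, dWh, db = _lstm_backward(
                dh[:, :, :H], cache_f,
                self.params[f"{pre_f}_Wx"], self.params[f"{pre_f}_Wh"])
            grads[f"{pre_f}_Wx"], grads[f"{pre_f}_Wh"], grads[f"{pre_f}_b"] = dWx, dWh, db
            dx_b, dWx, dWh, db = _lstm_backward(
                dh[:, ::-1, H:], cache_b,
                self.params[f"{pre_b}_Wx"], self.params[f"{pre_b}_Wh"])
            grads[f"{pre_b}_Wx"], grads[f"{pre_b}_Wh"], grads[f"{pre_b}_b"] = dWx, dWh, db
            dh = dx_f + dx_b[:, ::-1]
        return grads

    def loss_and_grads(self, x, y, class_weights=None):
        logits, cache = self.forward(x, want_cache=True)
        loss, dlogits = weighted_ce_loss(logits, np.asarray(y), class_weights)
        return loss, self.backward(dlogits, cache)

    def predict_proba(self, x):
        """Framewise class probabilities (B, T, n_classes)."""
        return softmax(self.forward(x))

    # -- persistence -------------------------------------------------------

    def save(self, path):
        """Checkpoint as .npz: hyperparameters under ``meta_*`` keys."""
        meta = dict(
            meta_version=self.FORMAT_VERSION, meta_n_input=self.n_input,
            meta_hidden=self.hidden, meta_fc_hidden=self.fc_hidden,
            meta_n_layers=self.n_layers, meta_n_classes=self.n_classes,
        )
        np.savez(path, **self.params, **{k: np.array(v) for k, v in meta.items()})

    @classmethod
    def load(cls, path):
        data = np.load(path)
        if int(data["meta_version"]) != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {int(data['meta_version'])}")
        net = cls(
            n_input=int(data["meta_n_input"]), hidden=int(data["meta_hidden"]),
            fc_hidden=int(data["meta_fc_hidden"]), n_layers=int(data["meta_n_layers"]),
            n_classes=int(data["meta_n_classes"]))
        for k in net.params:
            net.params[k] = data[k]
        return net


class Adam:
    """Adam optimizer over a parameter dictionary."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
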