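"""Numpy implementation of the multi-resolution recurrent classifier.

Architecture (stage 1): one LSTM branch per pooling stride, each reading
a fixed-length pooled sequence of temporal synergy patterns; the final
hidden states of all branches are concatenated and passed through a
fully connected block (linear -> ReLU -> linear -> log-softmax) that
scores the future motion state.  Stage 2 is a single linear layer over a
buffer of recent stage-1 log-posteriors that enforces temporally
plausible transitions.

Everything is written against plain numpy arrays with hand-derived
backpropagation (verified by finite differences in the test suite), so
the model trains and runs with no deep-learning runtime.  Gate layout in
the fused weight matrices is ``[input, forget, output, cell]`` (the three
sigmoid gates first, so one vectorized call covers them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def weighted_nll(logp: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted negative log-likelihood and its gradient w.r.t. logits.

    ``w`` holds one weight per class; the loss is normalized by the total
    weight of the batch (the convention of standard NLL implementations).
    """
    B = logp.shape[0]
    wy = w[y]
    sw = wy.sum()
    loss = -(wy * logp[np.arange(B), y]).sum() / sw
    p = np.exp(logp)
    dlogits = p * wy[:, None]
    dlogits[np.arange(B), y] -= wy
    return float(loss), dlogits / sw


# ----------------------------------------------------------------------
# layers


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run an LSTM over ``x`` (B, T, n_in); return the final hidden state.

    Internally the sequence is processed time-major so that every
    per-step slice is contiguous; the cache holds the per-step gate
    activations needed by the backward pass.
    """
    B, T, _ = x.shape
    hid = Wh.shape[0]
    dt = Wx.dtype
    xt = np.ascontiguousarray(x.transpose(1, 0, 2), dtype=dt)  # (T, B, n_in)
    XW = (xt.reshape(T * B, -1) @ Wx).reshape(T, B, 4 * hid)
    XW += b
    I = np.empty((T, B, hid), dtype=dt)
    F = np.empty_like(I)
    O = np.empty_like(I)
    Gg = np.empty_like(I)
    C = np.empty_like(I)
    TC = np.empty_like(I)  # tanh(c), reused by the backward pass
    Hs = np.empty_like(I)
    h = np.zeros((B, hid), dtype=dt)
    c = np.zeros((B, hid), dtype=dt)
    for t in range(T):
        z = XW[t] + h @ Wh
        gates = _sigmoid(z[:, : 3 * hid])
        i = gates[:, :hid]
        f = gates[:, hid : 2 * hid]
        o = gates[:, 2 * hid : 3 * hid]
        g = np.tanh(z[:, 3 * hid :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        I[t], F[t], O[t], Gg[t] = i, f, o, g
        C[t], TC[t], Hs[t] = c, tc, h
    cache = (xt, I, F, O, Gg, C, TC, Hs)
    return h, cache


def lstm_backward(dh_T: np.ndarray, cache, Wh: np.ndarray):
    """BPTT for :func:`lstm_forward`; returns (dWx, dWh, db)."""
    xt, I, F, O, Gg, C, TC, Hs = cache
    T, B, hid = I.shape
    dZ = np.empty((T, B, 4 * hid), dtype=I.dtype)
    dh = dh_T.astype(I.dtype, copy=True)
    dc = np.zeros((B, hid), dtype=I.dtype)
    for t in range(T - 1, -1, -1):
        i, f, o, g = I[t], F[t], O[t], Gg[t]
        tc = TC[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        c_prev = C[t - 1] if t > 0 else np.zeros_like(dc)
        df = dc * c_prev
        dz = dZ[t]
        dz[:, :hid] = di * i * (1.0 - i)
        dz[:, hid : 2 * hid] = df * f * (1.0 - f)
        dz[:, 2 * hid : 3 * hid] = do * o * (1.0 - o)
        dz[:, 3 * hid :] = dg * (1.0 - g * g)
        dh = dz @ Wh.T
        dc = dc * f
    # weight gradients via large GEMMs over all timesteps
    dZf = dZ.reshape(T * B, 4 * hid)
    dWx = xt.reshape(T * B, -1).T @ dZf
    Hprev = np.concatenate(
        [np.zeros((1, B, hid), dtype=I.dtype), Hs[:-1]], axis=0
    ).reshape(T * B, hid)
    dWh = Hprev.T @ dZf
    db = dZf.sum(axis=0)
    return dWx, dWh, db


# ----------------------------------------------------------------------
# full model


@dataclass
class NetConfig:
    n_inputs: int
    strides: tuple[int, ...]
    hidden: int
    fc1_units: int
    n_classes: int
    buffer_len: int
    dtype: str = "float32"


class MultiResolutionNet:
    """Stage-1 multi-branch LSTM classifier plus stage-2 transition layer."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        dt = np.dtype(cfg.dtype)
        rng = np.random.default_rng([seed, 77])
        k = 1.0 / np.sqrt(cfg.hidden)
        p = {}
        for s in cfg.strides:
            p[f"Wx_s{s}"] = rng.uniform(-k, k, (cfg.n_inputs, 4 * cfg.hidden))
            p[f"Wh_s{s}"] = rng.uniform(-k, k, (cfg.hidden, 4 * cfg.hidden))
            b = rng.uniform(-k, k, 4 * cfg.hidden)
            b[cfg.hidden : 2 * cfg.hidden] += 1.0  # forget-gate bias
            p[f"b_s{s}"] = b
        concat = cfg.hidden * len(cfg.strides)
        k1 = 1.0 / np.sqrt(concat)
        p["W1"] = rng.uniform(-k1, k1, (concat, cfg.fc1_units))
        p["b1"] = rng.uniform(-k1, k1, cfg.fc1_units)
        k2 = 1.0 / np.sqrt(cfg.fc1_units)
        p["Wout"] = rng.uniform(-k2, k2, (cfg.fc1_units, cfg.n_classes))
        p["bout"] = rng.uniform(-k2, k2, cfg.n_classes)
        nf2 = (cfg.buffer_len + 1) * cfg.n_classes
        k3 = 1.0 / np.sqrt(nf2)
        p["W2"] = rng.uniform(-k3, k3, (nf2, cfg.n_classes))
        p["b2"] = rng.uniform(-k3, k3, cfg.n_classes)
        self.params = {name: arr.astype(dt) for name, arr in p.items()}

    # -- stage 1 -------------------------------------------------------

    def stage1_forward(self, xs: list[np.ndarray], need_cache: bool = False):
        """``xs``: one (B, T, n_inputs) array per stride; returns log-probs."""
        p = self.params
        hs, caches = [], []
        for s, x in zip(self.cfg.strides, xs):
            h, cache = lstm_forward(
                x.astype(p[f"Wx_s{s}"].dtype, copy=False),
                p[f"Wx_s{s}"],
                p[f"Wh_s{s}"],
                p[f"b_s{s}"],
            )
            hs.append(h)
            caches.append(cache)
        hcat = np.concatenate(hs, axis=1)
        a1 = hcat @ p["W1"] + p["b1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ p["Wout"] + p["bout"]
        logp = log_softmax(logits)
        if not need_cache:
            return logp, None
        return logp, (caches, hcat, a1, r1)

    def stage1_backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        caches, hcat, a1, r1 = cache
        grads: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(r1.dtype, copy=False)
        grads["Wout"] = r1.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
        dr1 = dlogits @ p["Wout"].T
        da1 = dr1 * (a1 > 0)
        grads["W1"] = hcat.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dhcat = da1 @ p["W1"].T
        hid = self.cfg.hidden
        for bi, s in enumerate(self.cfg.strides):
            dh = dhcat[:, bi * hid : (bi + 1) * hid]
            dWx, dWh, db = lstm_backward(dh, caches[bi], p[f"Wh_s{s}"])
            grads[f"Wx_s{s}"], grads[f"Wh_s{s}"], grads[f"b_s{s}"] = dWx, dWh, db
        return grads

    # -- stage 2 -------------------------------------------------------

    def fc2_forward(self, feats: np.ndarray):
        """``feats``: (B, (buffer_len+1) * n_classes) stacked log-posteriors."""
        z = feats.astype(self.params["W2"].dtype, copy=False) @ self.params["W2"]
        return log_softmax(z + self.params["b2"])

    def fc2_backward(self, feats: np.ndarray, dlogits: np.ndarray):
        feats = feats.astype(dlogits.dtype, copy=False)
        return {"W2": feats.T @ dlogits, "b2": dlogits.sum(axis=0)}

    # -- utilities -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.params[k].dtype)


class SGD:
    """SGD with classical momentum and global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], momentum: float = 0.9,
                 clip_norm: float = 5.0):
        self.params = params
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = 1.0 if norm <= self.clip_norm else self.clip_norm / (norm + 1e-12)
        for k, g in grads.items():
            v = self.vel[k]
            v *= self.momentum
            v -= lr * scale * g
            self.params[k] += v


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip_norm: float = 5.0):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = 1.0 if norm <= self.clip_norm else self.clip_norm / (norm + 1e-12)
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            self.params[k] -= lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )
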