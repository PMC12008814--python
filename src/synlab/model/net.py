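"""A small dilated-convolution sequence-to-profile network in pure NumPy.

Architecture (BPNet-shaped, scaled to CPU): one wide first convolution, a
stack of exponentially dilated residual 3-wide convolutions, a wide
convolutional profile head (per task: 2 strands x L logits) and a global
average-pool + linear counts head (per task: log1p total counts).

Forward, backward (including gradients with respect to the input, used for
attribution) and the Adam update are implemented directly on ndarrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def _im2col(x: np.ndarray, K: int, dil: int) -> np.ndarray:
    """x (B,C,L) -> column matrix (C*K, B*L) for a same-padded dilated conv."""
    B, C, L = x.shape
    pad = dil * (K // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
    sB, sC, sL = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, K, L), strides=(sB, sC, dil * sL, sL))
    return view.transpose(1, 2, 0, 3).reshape(C * K, B * L)


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray, dil: int = 1,
            col_out: Optional[list] = None) -> np.ndarray:
    """Same-padded 1-D convolution. x (B,C,L), W (F,C,K) -> (B,F,L).

    If col_out is a list, the im2col matrix is appended for reuse in backward.
    """
    B, C, L = x.shape
    F, _, K = W.shape
    col = _im2col(x, K, dil)                        # (C*K, B*L)
    y = (W.reshape(F, C * K) @ col).reshape(F, B, L).transpose(1, 0, 2)
    y = y + b[None, :, None]
    if col_out is not None:
        col_out.append(col)
    return np.ascontiguousarray(y)


def _conv1d_backward(col: np.ndarray, x_shape: Tuple[int, int, int],
                     W: np.ndarray, dil: int, dy: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward from the cached column matrix; returns (dx, dW, db).

    dx is computed as a same-padded convolution of dy with the
    channel-transposed, kernel-flipped weights (exact for zero padding),
    which avoids materializing the gradient of the column matrix.
    """
    B, C, L = x_shape
    F, _, K = W.shape
    db = dy.sum(axis=(0, 2))
    dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(F, B * L)
    dW = (dy2 @ col.T).reshape(F, C, K)
    Wt = np.ascontiguousarray(W.transpose(1, 0, 2)[:, :, ::-1])
    dx = _conv1d(dy, Wt, np.zeros(C, dtype=dy.dtype), dil)
    return dx, dW, db


@dataclass
class NetConfig:
    tasks: List[str]
    input_length: int = 1000
    filters: int = 32
    first_width: int = 25
    n_dilated: int = 6
    head_width: int = 25

    @property
    def dilations(self) -> List[int]:
        return [2 ** (i + 1) for i in range(self.n_dilated)]


class ProfileNet:
    """Forward/backward network implementing the BindingPredictor internals."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        F, K0, Kh = config.filters, config.first_width, config.head_width
        T = len(config.tasks)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: Dict[str, np.ndarray] = {
            "W0": he((F, 4, K0), 4 * K0), "b0": np.zeros(F, np.float32),
            "Wp": he((2 * T, F, Kh), F * Kh) * 0.1, "bp": np.zeros(2 * T, np.float32),
            # counts head reads mean- and max-pooled trunk features: mean
            # tracks the broad read budget, max detects sparse motif hits
            "Wc": he((2 * F, T), 2 * F) * 0.1, "bc": np.zeros(T, np.float32),
        }
        for i in range(config.n_dilated):
            self.params[f"Wd{i}"] = he((F, F, 3), F * 3)
            self.params[f"bd{i}"] = np.zeros(F, np.float32)

    # -------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, want_cache: bool = False):
        """X (B,4,L) -> (profile logits (B,2T,L), log-counts (B,T))."""
        p = self.params
        cols: Dict[str, list] = {}

        def conv(name, x, W, b, dil=1):
            out = cols.setdefault(name, []) if want_cache else None
            return _conv1d(x, W, b, dil, col_out=out)

        cache = {"X": X, "cols": cols}
        h = conv("c0", X, p["W0"], p["b0"])
        cache["pre0"] = h
        h = np.maximum(h, 0.0)
        layers = []
        for i, dil in enumerate(self.config.dilations):
            pre = conv(f"cd{i}", h, p[f"Wd{i}"], p[f"bd{i}"], dil)
            u = np.maximum(pre, 0.0)
            layers.append((h, pre))
            h = h + u
        cache["layers"] = layers
        cache["h_final"] = h
        logits = conv("cp", h, p["Wp"], p["bp"])
        argmax = h.argmax(axis=2)
        pooled = np.concatenate([h.mean(axis=2),
                                 np.take_along_axis(h, argmax[:, :, None],
                                                    axis=2)[:, :, 0]], axis=1)
        cache["pooled"] = pooled
        cache["argmax"] = argmax
        logc = pooled @ p["Wc"] + p["bc"]
        if want_cache:
            return logits, logc, cache
        return logits, logc

    # ------------------------------------------------------------- backward
    def backward(self, cache, dlogits: Optional[np.ndarray],
                 dlogc: Optional[np.ndarray], want_dx: bool = False):
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        h_final = cache["h_final"]
        cols = cache["cols"]
        B, F, L = h_final.shape
        dh = np.zeros_like(h_final)
        if dlogits is not None:
            dxh, grads["Wp"], grads["bp"] = _conv1d_backward(
                cols["cp"][0], h_final.shape, p["Wp"], 1, dlogits)
            dh += dxh
        else:
            grads["Wp"] = np.zeros_like(p["Wp"])
            grads["bp"] = np.zeros_like(p["bp"])
        if dlogc is not None:
            grads["Wc"] = cache["pooled"].T @ dlogc
            grads["bc"] = dlogc.sum(axis=0)
            dpooled = dlogc @ p["Wc"].T          # (B, 2F)
            dh += dpooled[:, :F, None] / L       # mean-pool path
            dmax = np.zeros_like(h_final)        # max-pool path: route to argmax
            np.put_along_axis(dmax, cache["argmax"][:, :, None],
                              dpooled[:, F:, None], axis=2)
            dh += dmax
        else:
            grads["Wc"] = np.zeros_like(p["Wc"])
            grads["bc"] = np.zeros_like(p["bc"])
        for i in range(self.config.n_dilated - 1, -1, -1):
            h_in, pre = cache["layers"][i]
            du = dh * (pre > 0)
            dx_layer, grads[f"Wd{i}"], grads[f"bd{i}"] = _conv1d_backward(
                cols[f"cd{i}"][0], h_in.shape, p[f"Wd{i}"],
                self.config.dilations[i], du)
            dh = dh + dx_layer
        dh = dh * (cache["pre0"] > 0)
        dX, grads["W0"], grads["b0"] = _conv1d_backward(
            cols["c0"][0], cache["X"].shape, p["W0"], 1, dh)
        if want_dx:
            return grads, dX
        return grads

    def input_gradient(self, X: np.ndarray, task_index: int) -> np.ndarray:
        """d(log-counts of task)/dX for a batch X (B,4,L)."""
        _, logc, cache = self.forward(X, want_cache=True)
        dlogc = np.zeros_like(logc)
        dlogc[:, task_index] = 1.0
        _, dX = self.backward(cache, None, dlogc, want_dx=True)
        return dX

    # ------------------------------------------------------------------ io
    def state(self) -> Dict[str, np.ndarray]:
        return dict(self.params)

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)

    def save(self, path: str) -> None:
        np.savez(path, **self.params)
        sidecar = {
            "tasks": self.config.tasks,
            "input_length": self.config.input_length,
            "filters": self.config.filters,
            "first_width": self.config.first_width,
            "n_dilated": self.config.n_dilated,
            "head_width": self.config.head_width,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ProfileNet":
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        net = cls(NetConfig(tasks=sidecar["tasks"],
                            input_length=sidecar["input_length"],
                            filters=sidecar["filters"],
                            first_width=sidecar["first_width"],
                            n_dilated=sidecar["n_dilated"],
                            head_width=sidecar["head_width"]))
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        net.load_state({k: data[k] for k in data.files})
        return net


class Adam:
    """Adam with optional decoupled weight decay (applied to weights, not biases)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 0.004,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.startswith("W"):
                params[k] -= self.lr * self.weight_decay * params[k]


def profile_loss_and_grads(logits: np.ndarray, logc: np.ndarray,
                           Y: np.ndarray, lambdas: np.ndarray,
                           profile_weights: Optional[np.ndarray] = None
                           ) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """Multinomial NLL over (2 strands x L) plus weighted MSE on log1p counts.

    Y: (B, T, 2, L) observed counts. profile_weights (T,) rebalances the NLL
    across tasks (tasks with heavy read counts otherwise dominate feature
    learning). Returns (nll, mse, dlogits, dlogc).
    """
    B, twoT, L = logits.shape
    T = twoT // 2
    if profile_weights is None:
        profile_weights = np.ones(T)
    w = np.asarray(profile_weights, dtype=float).reshape(1, T, 1)
    lg = logits.reshape(B, T, 2 * L)
    yf = Y.reshape(B, T, 2 * L)
    lg_max = lg.max(axis=2, keepdims=True)
    z = lg - lg_max
    logZ = np.log(np.exp(z).sum(axis=2, keepdims=True))
    logp = z - logZ
    n_obs = yf.sum(axis=2, keepdims=True)
    nll = float(-(w * yf * logp).sum() / B)
    soft = np.exp(logp)
    dlg = w * (soft * n_obs - yf) / B
    totals = Y.sum(axis=(2, 3))
    target = np.log1p(totals)
    diff = logc - target
    mse = float((lambdas[None, :] * diff ** 2).sum() / B)
    dlogc = 2.0 * lambdas[None, :] * diff / B
    return nll, mse, dlg.reshape(B, twoT, L).astype(np.float32), dlogc.astype(np.float32)
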