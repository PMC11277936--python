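"""Model contract and the default CPU backbone.

Any classifier exposing ``train_step`` / ``predict_scores`` /
``snapshot`` / ``restore`` can be driven by the training loop — a large
pretrained convolutional network would plug in the same way. The bundled
default is a deliberately small fully-connected network (flatten -> ReLU
hidden layer with inverted dropout -> sigmoid) trained with Adam on
binary cross-entropy with an L2 penalty; at 64x64 inputs it trains in
minutes on one CPU, which is the scale the synthetic benchmark targets.
"""

from __future__ import annotations

import copy
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["ModelContract", "MlpBackbone", "ConvBackbone", "bce_loss"]


@runtime_checkable
class ModelContract(Protocol):
    def train_step(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float: ...

    def predict_scores(self, images: np.ndarray) -> np.ndarray: ...

    def snapshot(self) -> dict: ...

    def restore(self, snap: dict) -> None: ...


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(scores, eps, 1 - eps)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class MlpBackbone:
    """One-hidden-layer perceptron scorer for small grayscale images.

    Parameters
    ----------
    input_shape : image shape; inputs are flattened and centered at 0.5.
    hidden : hidden width (default 32).
    dropout : inverted-dropout rate on the hidden layer during training.
    l2 : L2 penalty coefficient on the weight matrices.
    seed : seeds both the He initialization and the dropout stream, so two
        models built with the same seed are bit-identical and stay
        identical under identical training streams.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (64, 64),
        hidden: int = 32,
        dropout: float = 0.5,
        l2: float = 1e-4,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        d = int(np.prod(input_shape))
        self.input_shape = tuple(input_shape)
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self.params = {
            "W1": rng.standard_normal((d, hidden)) * np.sqrt(2.0 / d),
            "b1": np.zeros(hidden),
            "W2": rng.standard_normal((hidden, 1)) * np.sqrt(2.0 / hidden),
            "b2": np.zeros(1),
        }
        self._adam = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
                      for k, v in self.params.items()}
        self._t = 0
        self._drop_rng = np.random.default_rng(rng.integers(2**31 - 1))

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float).reshape(len(images), -1)
        return x - 0.5  # center pixel intensities

    def _forward(self, x: np.ndarray, drop_mask: np.ndarray | None):
        p = self.params
        h_pre = x @ p["W1"] + p["b1"]
        h = np.maximum(h_pre, 0.0)
        if drop_mask is not None:
            h = h * drop_mask
        z = (h @ p["W2"] + p["b2"]).ravel()
        return h_pre, h, _sigmoid(z)

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        _, _, s = self._forward(self._flatten(images), None)
        return s

    def train_step(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float:
        x = self._flatten(images)
        y = np.asarray(labels, dtype=float)
        n = len(x)
        if self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (self._drop_rng.random((n, self.params["W1"].shape[1])) < keep)
            mask = mask / keep  # inverted dropout
        else:
            mask = None
        h_pre, h, s = self._forward(x, mask)
        p = self.params
        loss = bce_loss(s, y) + self.l2 * (
            np.sum(p["W1"] ** 2) + np.sum(p["W2"] ** 2)
        )
        dz = (s - y)[:, None] / n
        grads = {
            "W2": h.T @ dz + 2 * self.l2 * p["W2"],
            "b2": dz.sum(axis=0),
        }
        dh = dz @ p["W2"].T
        if mask is not None:
            dh = dh * mask
        dh = dh * (h_pre > 0)
        grads["W1"] = x.T @ dh + 2 * self.l2 * p["W1"]
        grads["b1"] = dh.sum(axis=0)
        self._adam_update(grads, lr)
        return loss

    def _adam_update(self, grads, lr, b1=0.9, b2=0.999, eps=1e-8):
        self._t += 1
        for k, g in grads.items():
            st = self._adam[k]
            st["m"] = b1 * st["m"] + (1 - b1) * g
            st["v"] = b2 * st["v"] + (1 - b2) * g * g
            mhat = st["m"] / (1 - b1**self._t)
            vhat = st["v"] / (1 - b2**self._t)
            self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + eps)

    def snapshot(self) -> dict:
        return copy.deepcopy(self.params)

    def restore(self, snap: dict) -> None:
        self.params = copy.deepcopy(snap)


class _Adam:
    def __init__(self, params: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = b1, b2, eps
        self.t = 0
        self.state = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
                      for k, v in params.items()}

    def update(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        for k, g in grads.items():
            st = self.state[k]
            st["m"] = self.b1 * st["m"] + (1 - self.b1) * g
            st["v"] = self.b2 * st["v"] + (1 - self.b2) * g * g
            mhat = st["m"] / (1 - self.b1**self.t)
            vhat = st["v"] / (1 - self.b2**self.t)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvBackbone:
    """Three-block small convolutional classifier (the default backbone).

    Each block is a non-overlapping patch convolution (stride equals
    kernel size) followed by ReLU: 4x4/8ch, 2x2/16ch, 2x2/32ch on a 64x64
    input, then global average pooling, inverted dropout, and a sigmoid
    head. Non-overlapping patches make both the forward and backward
    passes pure reshapes and matrix products, so the network trains in
    minutes on one CPU while still learning shared local lesion features
    the way a larger convolutional backbone would. Any stronger model
    (e.g. a pretrained EfficientNet wrapper) can replace it through the
    same contract.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (64, 64),
        channels: tuple[int, int, int] = (8, 16, 32),
        kernels: tuple[int, int, int] = (4, 2, 2),
        dropout: float = 0.5,
        l2: float = 1e-4,
        seed: int = 0,
    ):
        h, w = input_shape
        for k in kernels:
            if h % k or w % k:
                raise ValueError("input shape must tile by the kernel sizes")
            h, w = h // k, w // k
        self.input_shape = tuple(input_shape)
        self.kernels = tuple(kernels)
        self.channels = tuple(channels)
        self.dropout = float(dropout)
        self.l2 = float(l2)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = 1
        for i, (k, cout) in enumerate(zip(kernels, channels)):
            fan_in = k * k * cin
            self.params[f"W{i}"] = (
                rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in)
            )
            self.params[f"b{i}"] = np.zeros(cout)
            cin = cout
        self.params["Wh"] = rng.standard_normal((cin, 1)) * np.sqrt(2.0 / cin)
        self.params["bh"] = np.zeros(1)
        self._adam = _Adam(self.params)
        self._drop_rng = np.random.default_rng(rng.integers(2**31 - 1))

    @staticmethod
    def _patchify(x: np.ndarray, k: int) -> np.ndarray:
        # (N,H,W,C) -> (N, H/k * W/k, k*k*C)
        n, h, w, c = x.shape
        x = x.reshape(n, h // k, k, w // k, k, c)
        x = x.transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(n, (h // k) * (w // k), k * k * c)

    @staticmethod
    def _unpatchify(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
        n, h, w, c = shape
        x = cols.reshape(n, h // k, w // k, k, k, c)
        x = x.transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(n, h, w, c)

    def _forward(self, images: np.ndarray, train: bool):
        x = np.asarray(images, dtype=float)
        x = (x - 0.5)[..., None]  # (N,H,W,1), centered
        cache = []
        for i, k in enumerate(self.kernels):
            shape = x.shape
            cols = self._patchify(x, k)
            z = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0)
            cache.append((shape, cols, z))
            side = int(np.sqrt(a.shape[1]))
            x = a.reshape(a.shape[0], side, side, a.shape[2])
        feats = x.mean(axis=(1, 2))  # global average pool
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (self._drop_rng.random(feats.shape) < keep) / keep
        else:
            mask = None
        fdrop = feats * mask if mask is not None else feats
        logits = (fdrop @ self.params["Wh"] + self.params["bh"]).ravel()
        return _sigmoid(logits), (cache, x, feats, fdrop, mask)

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        s, _ = self._forward(images, train=False)
        return s

    def train_step(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float:
        y = np.asarray(labels, dtype=float)
        s, (cache, last_maps, feats, fdrop, mask) = self._forward(images, train=True)
        n = len(y)
        p = self.params
        w_keys = [f"W{i}" for i in range(len(self.kernels))] + ["Wh"]
        loss = bce_loss(s, y) + self.l2 * sum(np.sum(p[k] ** 2) for k in w_keys)
        dz = (s - y) / n  # dL/dlogit
        grads = {
            "Wh": fdrop.T @ dz[:, None] + 2 * self.l2 * p["Wh"],
            "bh": np.array([dz.sum()]),
        }
        dfeat = dz[:, None] @ p["Wh"].T
        if mask is not None:
            dfeat = dfeat * mask
        # backprop through global average pool
        hw = last_maps.shape[1] * last_maps.shape[2]
        dmap = np.broadcast_to(
            dfeat[:, None, None, :] / hw, last_maps.shape
        ).copy()
        for i in reversed(range(len(self.kernels))):
            shape, cols, z = cache[i]
            da = dmap.reshape(dmap.shape[0], -1, dmap.shape[-1])
            dzc = da * (z > 0)
            grads[f"W{i}"] = (
                np.einsum("npk,npc->kc", cols, dzc) + 2 * self.l2 * p[f"W{i}"]
            )
            grads[f"b{i}"] = dzc.sum(axis=(0, 1))
            if i > 0:
                dcols = dzc @ p[f"W{i}"].T
                dmap = self._unpatchify(dcols, shape, self.kernels[i])
        self._adam.update(self.params, grads, lr)
        return loss

    def snapshot(self) -> dict:
        return copy.deepcopy(self.params)

    def restore(self, snap: dict) -> None:
        self.params = copy.deepcopy(snap)
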