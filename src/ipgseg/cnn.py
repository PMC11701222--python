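"""A small 2D CNN on numpy with hand-written backpropagation.

The classification head of the pipeline is deliberately simple: two 3x3
convolution blocks (ReLU, 2x2 max pooling) into global average pooling and
a linear softmax head, trained with plain SGD plus momentum and decoupled-
from-nothing classic L2 weight decay.  At the patch sizes involved (9x9
windows, a few hundred training samples) this is fully tractable in numpy;
im2col turns every convolution into one matrix product, and every backward
pass is written out explicitly and verified against finite differences in
the test suite.

Shapes are NCHW internally.  All randomness flows through one generator, so
a fixed seed reproduces the parameter trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _im2col(x: np.ndarray, ksize: int = 3) -> np.ndarray:
    """(N, C, H, W) with 'same' zero padding -> (N, H*W, C*k*k) columns."""
    n, c, h, w = x.shape
    pad = ksize // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c * ksize * ksize, h * w), dtype=x.dtype)
    idx = 0
    for dy in range(ksize):
        for dx in range(ksize):
            patch = xp[:, :, dy:dy + h, dx:dx + w]
            cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, h * w)
            idx += 1
    return cols.transpose(0, 2, 1)


def _col2im(cols: np.ndarray, shape: tuple[int, ...], ksize: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to the image."""
    n, c, h, w = shape
    pad = ksize // 2
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols_t = cols.transpose(0, 2, 1)
    idx = 0
    for dy in range(ksize):
        for dx in range(ksize):
            xp[:, :, dy:dy + h, dx:dx + w] += (
                cols_t[:, idx * c:(idx + 1) * c, :].reshape(n, c, h, w)
            )
            idx += 1
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2D:
    """3x3 'same' convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 ksize: int = 3) -> None:
        fan_in = in_ch * ksize * ksize
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(out_ch, in_ch, ksize, ksize))
        self.bias = np.zeros(out_ch)
        self.ksize = ksize
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.ksize)                      # (N, HW, C*k*k)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = cols @ wmat.T + self.bias                    # (N, HW, out)
        self._cache = (x.shape, cols)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x_shape, cols = self._cache
        n, _, h, w = x_shape
        out_ch = grad_out.shape[1]
        g = grad_out.reshape(n, out_ch, h * w).transpose(0, 2, 1)  # (N, HW, out)
        wmat = self.weight.reshape(out_ch, -1)
        grad_w = (g.reshape(-1, out_ch).T @ cols.reshape(-1, cols.shape[2])
                  ).reshape(self.weight.shape)
        grad_b = g.sum(axis=(0, 1))
        grad_cols = g @ wmat                                # (N, HW, C*k*k)
        grad_x = _col2im(grad_cols, x_shape, self.ksize)
        return grad_x, grad_w, grad_b


class MaxPool2:
    """2x2 max pooling, stride 2, trailing odd row/column dropped."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xc = x[:, :, :hh * 2, :ww * 2]
        windows = xc.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = windows.reshape(n, c, hh, ww, 4)
        arg = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_shape, arg = self._cache
        n, c, h, w = x_shape
        hh, ww = h // 2, w // 2
        gwin = np.zeros((n, c, hh, ww, 4), dtype=grad_out.dtype)
        np.put_along_axis(gwin, arg[..., None], grad_out[..., None], axis=-1)
        gx = np.zeros(x_shape, dtype=grad_out.dtype)
        gx[:, :, :hh * 2, :ww * 2] = (
            gwin.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hh * 2, ww * 2)
        )
        return gx


class PatchCNN:
    """conv(3x3) -> ReLU -> pool -> conv(3x3) -> ReLU -> pool -> GAP -> linear."""

    def __init__(self, in_channels: int, n_classes: int,
                 widths: tuple[int, int] = (32, 64), seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2D(in_channels, widths[0], rng)
        self.conv2 = Conv2D(widths[0], widths[1], rng)
        self.pool1 = MaxPool2()
        self.pool2 = MaxPool2()
        self.fc_w = rng.normal(0.0, np.sqrt(1.0 / widths[1]),
                               size=(n_classes, widths[1]))
        self.fc_b = np.zeros(n_classes)
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "conv1.weight": self.conv1.weight, "conv1.bias": self.conv1.bias,
            "conv2.weight": self.conv2.weight, "conv2.bias": self.conv2.bias,
            "fc.weight": self.fc_w, "fc.bias": self.fc_b,
        }

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.conv1.weight = params["conv1.weight"]
        self.conv1.bias = params["conv1.bias"]
        self.conv2.weight = params["conv2.weight"]
        self.conv2.bias = params["conv2.bias"]
        self.fc_w = params["fc.weight"]
        self.fc_b = params["fc.bias"]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (N, C, H, W) batch."""
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0.0)
        p1 = self.pool1.forward(r1)
        a2 = self.conv2.forward(p1)
        r2 = np.maximum(a2, 0.0)
        p2 = self.pool2.forward(r2)
        gap = p2.mean(axis=(2, 3))
        logits = gap @ self.fc_w.T + self.fc_b
        self._cache = {"a1": a1, "a2": a2, "p2_shape": p2.shape, "gap": gap}
        return logits

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy over the batch and gradients for every
        parameter.  ``y`` holds 0-based class indices."""
        n = x.shape[0]
        logits = self.forward(x)
        probs = self.softmax(logits)
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad_fc_w = dlogits.T @ self._cache["gap"]
        grad_fc_b = dlogits.sum(axis=0)
        dgap = dlogits @ self.fc_w                                  # (N, C2)
        _, c2, ph, pw = self._cache["p2_shape"]
        dp2 = np.broadcast_to(dgap[:, :, None, None] / (ph * pw),
                              (n, c2, ph, pw)).copy()
        dr2 = self.pool2.backward(dp2)
        da2 = dr2 * (self._cache["a2"] > 0)
        dp1, grad_w2, grad_b2 = self.conv2.backward(da2)
        dr1 = self.pool1.backward(dp1)
        da1 = dr1 * (self._cache["a1"] > 0)
        _, grad_w1, grad_b1 = self.conv1.backward(da1)
        grads = {
            "conv1.weight": grad_w1, "conv1.bias": grad_b1,
            "conv2.weight": grad_w2, "conv2.bias": grad_b2,
            "fc.weight": grad_fc_w, "fc.bias": grad_fc_b,
        }
        return loss, grads


class SGD:
    """SGD with classical momentum and L2 weight decay."""

    def __init__(self, learning_rate: float = 0.05, momentum: float = 0.7,
                 weight_decay: float = 1e-4) -> None:
        if learning_rate < 0 or not 0 <= momentum < 1 or weight_decay < 0:
            raise ValueError("invalid optimizer hyperparameters")
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, p in params.items():
            g = grads[name]
            if self.weight_decay and not name.endswith("bias"):
                g = g + self.weight_decay * p
            v = self._velocity.get(name, np.zeros_like(p))
            v = self.momentum * v - self.learning_rate * g
            self._velocity[name] = v
            out[name] = p + v
        return out
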