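"""Minimal NumPy convolutional-network engine for 2D patch classification.

Implements exactly the pieces the PMI classifier needs: unpadded ("valid")
3x3 convolutions, ReLU, a single 2x2 max-pool, a fully connected layer, and
softmax cross-entropy, trained with SGD (momentum + L2 weight decay).
Forward/backward passes are expressed as im2col matrix products; gradients
are verified against finite differences in the test suite.

Valid convolutions are deliberate: they make the network exactly
translation-covariant, so a whole 2D slice can be pushed through the conv
stack once and the per-voxel patch predictions read off densely
(:meth:`CNN.dense_logits`) instead of re-running overlapping patches.
All math is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3x3", "ReLU", "MaxPool2x2", "Dense", "CNN", "softmax", "SGDMomentum"]

#: fixed affine input standardization for free-water fractions in [0, 1]:
#: (x - CENTER) / SCALE maps the data range to roughly [-2, 2].  A fixed
#: transform, identical for every patch, so absolute free-water level (the
#: class signal) is fully preserved — this is NOT per-patch normalization.
INPUT_CENTER = 0.5
INPUT_SCALE = 0.25


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B, H-2, W-2, C*9) patches for a valid 3x3 conv."""
    # sliding_window_view over H, W gives (B, H-2, W-2, C, 3, 3)
    win = sliding_window_view(x, (3, 3), axis=(1, 2))
    b, h, w, c = win.shape[:4]
    return np.ascontiguousarray(win).reshape(b, h, w, c * 9)


class Conv3x3:
    """Valid (unpadded) 3x3 convolution, channels-last."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # He initialization for ReLU networks
        scale = np.sqrt(2.0 / (9 * c_in))
        self.W = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self._col: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        col = _im2col(x)
        if train:
            self._col = col
        return col @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col = self._col
        n = col.shape[0] * col.shape[1] * col.shape[2]
        self.dW = col.reshape(n, -1).T @ dy.reshape(n, -1)
        self.db = dy.reshape(n, -1).sum(axis=0)
        # dx = valid conv of zero-padded dy with the spatially flipped,
        # channel-transposed kernel
        w = self.W.reshape(self.c_in, 3, 3, self.c_out)
        w_flip = w[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (c_out, 3, 3, c_in)
        w_mat = np.ascontiguousarray(w_flip.transpose(1, 2, 0, 3)).reshape(
            9 * self.c_out, self.c_in
        )
        dy_pad = np.pad(dy, ((0, 0), (2, 2), (2, 2), (0, 0)))
        win = sliding_window_view(dy_pad, (3, 3), axis=(1, 2))  # (B,H,W,c_out,3,3)
        b, h, wdt = win.shape[:3]
        col_dy = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            b, h, wdt, 9 * self.c_out
        )
        self._col = None
        return col_dy @ w_mat

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    params: list = []


class MaxPool2x2:
    """2x2 max-pool, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        r = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        if train:
            self._r_shape = r.shape
            self._mask = r == out[:, :, None, :, None, :]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        dr = self._mask * (dy[:, :, None, :, None, :] / counts)
        b, h2, _, w2, _, c = self._r_shape
        return dr.reshape(b, h2 * 2, w2 * 2, c)

    params: list = []


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        if train:
            self._x = flat
            self._shape = x.shape
        return flat @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return (dy @ self.W.T).reshape(self._shape)

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class CNN:
    """The patch classifier: 6 valid 3x3 convs (+ReLU), one 2x2 max-pool, FC.

    On a ``patch_size`` x ``patch_size`` input the six valid convs shrink the
    grid by 12 (16 -> 4), the pool halves it (4 -> 2), and the fully
    connected layer maps the pooled features to ``n_classes`` logits.
    """

    def __init__(
        self,
        patch_size: int = 16,
        channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32),
        n_classes: int = 2,
        seed: int = 0,
    ):
        if patch_size - 2 * len(channels) < 2:
            raise ValueError("patch too small for this conv stack")
        rng = np.random.default_rng(seed)
        self.patch_size = patch_size
        self.channels = tuple(channels)
        self.conv_layers: list = []
        c_prev = 1
        for c in channels:
            self.conv_layers.append(Conv3x3(c_prev, c, rng))
            self.conv_layers.append(ReLU())
            c_prev = c
        self.pool = MaxPool2x2()
        side = (patch_size - 2 * len(channels)) // 2
        self.fc = Dense(side * side * c_prev, n_classes, rng)
        self.layers = [*self.conv_layers, self.pool, self.fc]

    # ---- patch-batch path -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of patches, x shape (B, patch, patch) or (B, p, p, 1)."""
        if x.ndim == 3:
            x = x[..., None]
        x = (x.astype(np.float32, copy=False) - INPUT_CENTER) / INPUT_SCALE
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean softmax cross-entropy and its gradient w.r.t. parameters."""
        logits = self.forward(x, train=True)
        p = softmax(logits)
        n = len(y)
        loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self.backward(dlogits.astype(np.float32))
        return loss, logits

    # ---- dense (fully convolutional) path ---------------------------------
    def conv_features(self, planes: np.ndarray) -> np.ndarray:
        """Run the conv stack over a batch of 2D planes.

        Input (B, H, W) -> (B, H - 12, W - 12, C) for the 6-conv stack.
        """
        x = (planes.astype(np.float32, copy=False) - INPUT_CENTER) / INPUT_SCALE
        x = x[..., None]
        for layer in self.conv_layers:
            x = layer.forward(x)
        return x

    def dense_logits_batch(self, planes: np.ndarray) -> np.ndarray:
        """Logits of every patch position in each plane, in one pass.

        ``planes`` has shape (B, H, W); output ``L[b, r, c]`` equals
        ``forward`` of the patch whose top-left corner is ``(r, c)`` in plane
        ``b``, for all positions where the full patch fits; shape
        (B, H - patch + 1, W - patch + 1, n_classes).
        """
        f = self.conv_features(planes)  # (B, H-12, W-12, C)
        _, h, w, c = f.shape
        # dense 2x2 max with stride 1; window pooled values are then read at
        # strided offsets, reproducing the patch-level 2x2/stride-2 pool
        m = np.maximum(
            np.maximum(f[:, :-1, :-1], f[:, :-1, 1:]),
            np.maximum(f[:, 1:, :-1], f[:, 1:, 1:]),
        )  # (B, h-1, w-1, c)
        side = (self.patch_size - 2 * len(self.channels)) // 2
        out_h = h - 2 * side + 1
        out_w = w - 2 * side + 1
        w_fc = self.fc.W.reshape(side, side, c, -1)
        logits = np.zeros((len(planes), out_h, out_w, w_fc.shape[-1]), dtype=np.float32)
        for pi in range(side):
            for pj in range(side):
                block = m[:, 2 * pi : 2 * pi + out_h, 2 * pj : 2 * pj + out_w]
                logits += block @ w_fc[pi, pj]
        return logits + self.fc.b

    def dense_logits(self, plane: np.ndarray) -> np.ndarray:
        """Single-plane convenience wrapper around :meth:`dense_logits_batch`."""
        return self.dense_logits_batch(plane[None])[0]

    # ---- parameter access --------------------------------------------------
    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params:
                yield f"layer{li}_{name}", layer, name, arr

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: arr.copy() for key, _, _, arr in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, arr in self.parameters():
            new = np.asarray(state[key], dtype=np.float32)
            if new.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}")
            setattr(layer, name, new)


class SGDMomentum:
    """Classical SGD with momentum and L2 weight decay."""

    def __init__(self, model: CNN, lr: float, momentum: float, weight_decay: float):
        self.model = model
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = {key: np.zeros_like(arr) for key, _, _, arr in model.parameters()}

    def step(self) -> None:
        for key, layer, name, arr in self.model.parameters():
            grad = getattr(layer, "d" + name)
            if self.weight_decay and name == "W":
                grad = grad + self.weight_decay * arr
            v = self.velocity[key]
            v *= self.momentum
            v -= self.lr * grad.astype(np.float32)
            setattr(layer, name, arr + v)
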