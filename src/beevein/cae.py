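"""A compact convolutional autoencoder for image-level anomaly screening.

Implemented directly on NumPy: strided 5x5 convolutions with ReLU in the
encoder, a linear projection to a low-dimensional latent code, and a
resize-convolution decoder (nearest-neighbor upsampling followed by
stride-1 convolution — the standard checkerboard-free alternative to
transposed convolution) ending in a sigmoid.  Training minimizes per-pixel
MSE with Adam, halves the learning rate after a patience of stagnant
epochs, and stops early when the loss plateaus.  Wings reconstruct well
because they dominate the training distribution; torn or occluded wings
reconstruct poorly, so their reconstruction error flags them.

The full-scale layer plan uses encoder widths (32, 64, 128, 256, 512) at
256x256 input; the desk-scale preset (8, 16, 32) at 64x64 trains in
seconds and is the default for synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CAEConfig", "ConvAutoencoder", "DESK_CAE", "FULL_CAE"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> windows (N, C, Ho, Wo, k, k)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


class _Conv:
    """2-D convolution (cross-correlation) with bias; stride and symmetric
    zero padding.  Forward caches what backward needs."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.stride, self.pad = k, stride, pad

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("nihwkl,oikl->nohw", self._cols, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = np.einsum("nihwkl,nohw->oikl", self._cols, grad, optimize=True)
        self.gb = grad.sum(axis=(0, 2, 3))
        n, c, h, w = self._x_shape
        k, s, p = self.k, self.stride, self.pad
        # scatter grad back through the zero-stuffed transpose convolution
        hp, wp = h + 2 * p, w + 2 * p
        up = np.zeros((n, grad.shape[1], hp - k + 1, wp - k + 1))
        up[:, :, ::s, ::s] = grad
        upp = np.pad(up, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        win = sliding_window_view(upp, (k, k), axis=(2, 3))
        w_flip = self.w[:, :, ::-1, ::-1]
        gx = np.einsum("nohwkl,oikl->nihw", win, w_flip, optimize=True)
        return gx[:, :, p : p + h, p : p + w]


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class _Sigmoid:
    def params(self):
        return []

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class _Upsample2x:
    def params(self):
        return []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Flatten:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Reshape:
    def __init__(self, shape):
        self.shape = shape

    def params(self):
        return []

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T


@dataclass(frozen=True)
class CAEConfig:
    """Architecture and training hyperparameters.

    ``widths`` are the encoder channel counts (mirrored by the decoder);
    ``input_size`` must be divisible by 2**len(widths).
    """

    input_size: int = 256
    widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    latent_dim: int = 128
    kernel: int = 5
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 32
    max_epochs: int = 100
    lr_patience: int = 5
    lr_factor: float = 0.5
    early_stop_patience: int = 10
    early_stop_delta: float = 0.001
    seed: int = 0


FULL_CAE = CAEConfig()
DESK_CAE = CAEConfig(input_size=64, widths=(8, 16, 32), max_epochs=30)


class ConvAutoencoder:
    """Symmetric convolutional autoencoder with MSE reconstruction loss."""

    def __init__(self, config: CAEConfig = DESK_CAE):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, pad = config.kernel, config.kernel // 2
        size = config.input_size
        if size % (2 ** len(config.widths)) != 0:
            raise ValueError("input_size must be divisible by 2**len(widths)")

        layers: list = []
        c_in = 1
        for w in config.widths:
            layers += [_Conv(c_in, w, k, stride=2, pad=pad, rng=rng), _ReLU()]
            c_in = w
        bottom = size // (2 ** len(config.widths))
        flat = c_in * bottom * bottom
        layers += [_Flatten(), _Dense(flat, config.latent_dim, rng)]
        self._latent_index = len(layers)
        layers += [_Dense(config.latent_dim, flat, rng), _ReLU(), _Reshape((c_in, bottom, bottom))]
        rev = list(config.widths[:-1])[::-1] + [1]
        for i, w in enumerate(rev):
            layers += [_Upsample2x(), _Conv(c_in, w, k, stride=1, pad=pad, rng=rng)]
            layers.append(_Sigmoid() if i == len(rev) - 1 else _ReLU())
            c_in = w
        self.layers = layers
        self._adam_state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0

    # -- plumbing ---------------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _adam_step(self, lr: float) -> None:
        b1, b2 = self.config.betas
        eps = 1e-8
        self._adam_t += 1
        t = self._adam_t
        for i, layer in enumerate(self.layers):
            grads = {"w": getattr(layer, "gw", None), "b": getattr(layer, "gb", None)}
            for name, _param in layer.params():
                g = grads[name]
                state = self._adam_state.setdefault(i, {})
                if name not in state:
                    state[name] = (np.zeros_like(g), np.zeros_like(g))
                m, v = state[name]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                state[name] = (m, v)
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                param = getattr(layer, name)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API -------------------------------------------------------
    @staticmethod
    def _as_batch(images: "list[np.ndarray] | np.ndarray", size: int) -> np.ndarray:
        from skimage.transform import resize

        arr = []
        for im in images:
            im = np.asarray(im, dtype=np.float64)
            if im.shape != (size, size):
                im = resize(im, (size, size), anti_aliasing=True)
            arr.append(im)
        return np.stack(arr)[:, None, :, :]

    def fit(self, images: "list[np.ndarray] | np.ndarray", verbose: bool = False) -> list[float]:
        """Train on a stack of grayscale images in [0, 1]; images are
        resized to the configured input size.  Returns the per-epoch mean
        training losses."""
        cfg = self.config
        x = self._as_batch(images, cfg.input_size)
        n = len(x)
        if n < 10:
            raise ValueError("need at least 10 images to train")
        rng = np.random.default_rng(cfg.seed + 1)
        lr = cfg.lr
        best = np.inf
        lr_stall = stop_stall = 0
        history: list[float] = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                batch = x[order[start : start + cfg.batch_size]]
                out = self._forward(batch)
                diff = out - batch
                losses.append(float((diff**2).mean()))
                self._backward(2.0 * diff / diff.size)
                self._adam_step(lr)
            loss = float(np.mean(losses))
            history.append(loss)
            if verbose:
                print(f"epoch {epoch:3d}  loss {loss:.5f}  lr {lr:.2e}")
            if loss < best - cfg.early_stop_delta:
                best = loss
                lr_stall = stop_stall = 0
            else:
                lr_stall += 1
                stop_stall += 1
                if lr_stall >= cfg.lr_patience:
                    lr *= cfg.lr_factor
                    lr_stall = 0
                if stop_stall >= cfg.early_stop_patience:
                    break
        return history

    def reconstruct(self, images: "list[np.ndarray] | np.ndarray") -> np.ndarray:
        """Reconstructions at the configured input size, shape (N, H, W)."""
        x = self._as_batch(images, self.config.input_size)
        outs = []
        for start in range(0, len(x), self.config.batch_size):
            outs.append(self._forward(x[start : start + self.config.batch_size]))
        return np.concatenate(outs)[:, 0]

    def reconstruction_errors(self, images: "list[np.ndarray] | np.ndarray") -> np.ndarray:
        """Per-image mean squared reconstruction error."""
        x = self._as_batch(images, self.config.input_size)
        recon = self.reconstruct(images)
        return ((recon - x[:, 0]) ** 2).mean(axis=(1, 2))
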