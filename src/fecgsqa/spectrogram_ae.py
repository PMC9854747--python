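"""Fully convolutional spectrogram autoencoder and the AE_MSE feature.

The autoencoder reconstructs 3-channel spectrogram images.  Trained on
high-quality spectrograms only, it reconstructs clean periodic
time-frequency structure well and noisy images poorly, so the per-image
mean squared reconstruction error

    AE_MSE(s) = sum_{l,m,n} (s_{lmn} - shat_{lmn})^2 / (L * M * N)

rises as signal quality falls and serves as an unsupervised quality
feature.

Architecture: encoder and decoder of 6 FCN layers each (conv/deconv +
batch normalization + ELU) plus a sigmoid output layer.  All kernels are
3x3; filter counts are 64, 32, 32, 32, 64, 1 | 1, 64, 32, 32, 32, 64 and
strides 2, 2, 2, 2, 2, 1 | 1, 2, 2, 2, 2, 2, so a 128x128 input is
compressed to a 4x4 latent map and symmetrically upsampled back.  The
output layer (stride 1) emits one map per image channel so the output
shape equals the input shape.  "Same" padding makes stride-2 layers halve
resolution exactly.

Everything is plain numpy: im2col convolutions, transposed convolutions
as the exact adjoint, batch normalization, Adam.  A desk-scale mode
(``image_size=64``) keeps the identical layer stack on smaller images for
fast CPU runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, NotTrainedError

__all__ = [
    "AEArchitecture",
    "AEModel",
    "build_ae",
    "train_ae",
    "ae_mse",
    "mean_squared_reconstruction_error",
    "DEFAULT_FILTERS",
    "DEFAULT_STRIDES",
]

DEFAULT_FILTERS = (64, 32, 32, 32, 64, 1, 1, 64, 32, 32, 32, 64, 1)
DEFAULT_STRIDES = (2, 2, 2, 2, 2, 1, 1, 2, 2, 2, 2, 2, 1)


# ---------------------------------------------------------------------------
# convolution primitives (NHWC, weights (k, k, c_in, c_out))
# ---------------------------------------------------------------------------

def _same_pad(h: int, k: int, s: int):
    out = -(-h // s)
    total = max((out - 1) * s + k - h, 0)
    return total // 2, total - total // 2


def _pad_input(x: np.ndarray, k: int, stride: int):
    n, h, w, c = x.shape
    pt, pb = _same_pad(h, k, stride)
    pl, pr = _same_pad(w, k, stride)
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))), (pt, pl)


def conv2d(x: np.ndarray, weights: np.ndarray, stride: int) -> np.ndarray:
    """Strided 'same' cross-correlation as k*k shifted matmuls."""
    k, _, c_in, c_out = weights.shape
    xp, _ = _pad_input(x, k, stride)
    ho = -(-x.shape[1] // stride)
    wo = -(-x.shape[2] // stride)
    out = np.zeros((x.shape[0], ho, wo, c_out), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            sl = xp[:, ki:ki + stride * ho:stride,
                    kj:kj + stride * wo:stride]
            out += sl @ weights[ki, kj]
    return out


def conv2d_input_grad(dout: np.ndarray, weights: np.ndarray, stride: int,
                      in_hw: tuple) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input (also the deconv forward map)."""
    k, _, c_in, c_out = weights.shape
    n, ho, wo, _ = dout.shape
    h, w = in_hw
    pt, pb = _same_pad(h, k, stride)
    pl, pr = _same_pad(w, k, stride)
    dxp = np.zeros((n, h + pt + pb, w + pl + pr, c_in), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki:ki + stride * ho:stride,
                kj:kj + stride * wo:stride] += dout @ weights[ki, kj].T
    return dxp[:, pt:pt + h, pl:pl + w]


def conv2d_weight_grad(x: np.ndarray, dout: np.ndarray, wshape: tuple,
                       stride: int) -> np.ndarray:
    """Gradient of conv2d w.r.t. its weights."""
    k, _, c_in, c_out = wshape
    xp, _ = _pad_input(x, k, stride)
    n, ho, wo, _ = dout.shape
    dflat = dout.reshape(-1, c_out)
    dw = np.empty(wshape, dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            sl = xp[:, ki:ki + stride * ho:stride,
                    kj:kj + stride * wo:stride]
            dw[ki, kj] = np.ascontiguousarray(sl).reshape(-1, c_in).T @ dflat
    return dw


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def forward(self, x, training):            # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):                     # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, c_in, c_out, stride, kernel, rng):
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.stride, self.kernel, self.c_in = stride, kernel, c_in
        self.params = {
            "W": rng.normal(0.0, scale,
                            (kernel, kernel, c_in, c_out)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {}

    def forward(self, x, training):
        self._in_hw = x.shape[1:3]
        self._x = x if training else None
        return conv2d(x, self.params["W"], self.stride) + self.params["b"]

    def backward(self, g):
        self.grads["W"] = conv2d_weight_grad(
            self._x, g, self.params["W"].shape, self.stride)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        return conv2d_input_grad(g, self.params["W"], self.stride, self._in_hw)


class ConvTranspose2D(_Layer):
    """Transposed convolution: the exact adjoint of a strided conv."""

    def __init__(self, c_in, c_out, stride, kernel, rng):
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.stride, self.kernel, self.c_out = stride, kernel, c_out
        # weights parameterized as the forward conv they transpose:
        # a conv mapping (out-space, c_out) -> (in-space, c_in)
        self.params = {
            "W": rng.normal(0.0, scale,
                            (kernel, kernel, c_out, c_in)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {}

    def forward(self, x, training):
        self._x = x if training else None
        n, h, w, _ = x.shape
        out_hw = (h * self.stride, w * self.stride)
        y = conv2d_input_grad(x, self.params["W"], self.stride, out_hw)
        return y + self.params["b"]

    def backward(self, g):
        dx = conv2d(g, self.params["W"], self.stride)
        self.grads["W"] = conv2d_weight_grad(
            g, self._x, self.params["W"].shape, self.stride)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        return dx


class BatchNorm2D(_Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=np.float32),
                       "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        xhat = self._xhat
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = g.sum(axis=(0, 1, 2))
        gg = self.params["gamma"] / self._std
        return gg * (g - g.mean(axis=(0, 1, 2))
                     - xhat * (g * xhat).mean(axis=(0, 1, 2)))


class ELU(_Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x, training):
        self._out = np.where(x > 0, x, np.expm1(x))
        self._pos = x > 0
        return self._out

    def backward(self, g):
        return g * np.where(self._pos, 1.0, self._out + 1.0)


class Sigmoid(_Layer):
    params: dict = {}
    grads: dict = {}

    def forward(self, x, training):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


# ---------------------------------------------------------------------------
# architecture / model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AEArchitecture:
    """Layer specification of the FCN autoencoder."""

    filters: tuple = DEFAULT_FILTERS
    strides: tuple = DEFAULT_STRIDES
    kernel: int = 3
    image_size: int = 128
    channels: int = 3

    def validate(self) -> None:
        if len(self.filters) != 13:
            raise ConfigurationError(
                f"filters must list 13 layers, got {len(self.filters)}")
        if len(self.strides) != 13:
            raise ConfigurationError(
                f"strides must list 13 layers, got {len(self.strides)}")
        if self.kernel != 3:
            raise ConfigurationError("all kernels are 3x3")
        n_halvings = sum(1 for s in self.strides[:6] if s == 2)
        if self.image_size % (2 ** n_halvings) != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by "
                f"2^{n_halvings}")
        size = self.image_size
        for i, s in enumerate(self.strides):
            if s not in (1, 2):
                raise ConfigurationError(f"layer {i}: stride must be 1 or 2")

    def shape_table(self) -> list:
        """Per-layer output spatial sizes (encoder halves, decoder doubles)."""
        size = self.image_size
        sizes = []
        for i, s in enumerate(self.strides):
            if i < 7:
                size = -(-size // s)
            else:
                size = size * s
            sizes.append(size)
        return sizes


@dataclass
class AEModel:
    """A (possibly trained) spectrogram autoencoder."""

    architecture: AEArchitecture
    layers: list
    seed: int
    trained: bool = False
    training_metadata: dict = field(default_factory=dict)

    # -- forward/backward over the whole stack ------------------------------
    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def _backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def reconstruct(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Reconstruct a batch of images (N, H, W, C); output in [0, 1]."""
        images = np.asarray(images, dtype=float)
        single = images.ndim == 3
        if single:
            images = images[None]
        s = self.architecture.image_size
        if images.shape[1:3] != (s, s):
            raise ConfigurationError(
                f"expected {s}x{s} images, got {images.shape[1:3]}")
        out = np.concatenate([
            self._forward(images[i:i + batch_size], training=False)
            for i in range(0, len(images), batch_size)])
        out = np.clip(out, 0.0, 1.0)
        return out[0] if single else out

    def parameter_layers(self) -> list:
        return [l for l in self.layers if l.params]


def build_ae(architecture: AEArchitecture | None = None,
             seed: int = 0) -> AEModel:
    """Construct the untrained autoencoder with seeded initialization.

    Layers 0-5 form the encoder (strided convolutions), 6-11 the decoder
    (a stride-1 convolution then five transposed convolutions) and layer
    12 the sigmoid output convolution, which emits ``channels`` maps so
    the output shape equals the input shape.
    """
    arch = architecture or AEArchitecture()
    arch.validate()
    rng = np.random.default_rng(seed)
    layers: list = []
    c_prev = arch.channels
    for i, (f, s) in enumerate(zip(arch.filters, arch.strides)):
        is_output = i == 12
        c_out = arch.channels if is_output else f
        if 7 <= i <= 11:
            layers.append(ConvTranspose2D(c_prev, c_out, s, arch.kernel, rng))
        else:
            layers.append(Conv2D(c_prev, c_out, s, arch.kernel, rng))
        if is_output:
            layers.append(Sigmoid())
        else:
            layers.append(BatchNorm2D(c_out))
            layers.append(ELU())
        c_prev = c_out
    model = AEModel(architecture=arch, layers=layers, seed=seed)
    # sanity: a forward pass must reproduce the input shape
    probe = np.zeros((1, arch.image_size, arch.image_size, arch.channels))
    out = model._forward(probe, training=False)
    if out.shape != probe.shape:
        raise ConfigurationError(
            f"layer stack maps {probe.shape} to {out.shape}")
    return model


class _Adam:
    def __init__(self, layers, lr):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in layers]
        self.layers = layers

    def step(self):
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / corr1
                vhat = self.v[i][k] / corr2
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_pixel_stack(spectrograms) -> np.ndarray:
    arrays = []
    for s in spectrograms:
        arrays.append(np.asarray(getattr(s, "pixels", s), dtype=float))
    return np.stack(arrays)


def train_ae(model: AEModel, spectrograms, epochs: int = 50,
             batch_size: int = 64, learning_rate: float = 1e-3,
             seed: int = 0, patience: int = 5,
             min_delta: float = 1e-5) -> AEModel:
    """Train the autoencoder to reconstruct its inputs (MSE loss, Adam).

    Callers must pass high-quality spectrograms only; training on clean
    images is what widens the reconstruction-error gap between quality
    levels.  The per-epoch mean loss trace is recorded in
    ``training_metadata``; training stops early when the loss plateaus.
    Deterministic given ``seed``.
    """
    if len(spectrograms) == 0:
        raise ConfigurationError("empty training set")
    data = _as_pixel_stack(spectrograms)
    s = model.architecture.image_size
    if data.shape[1:] != (s, s, model.architecture.channels):
        raise ConfigurationError(
            f"training images have shape {data.shape[1:]}, "
            f"architecture expects {(s, s, model.architecture.channels)}")
    rng = np.random.default_rng(seed)
    opt = _Adam(model.parameter_layers(), learning_rate)
    trace = []
    best = np.inf
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(data))
        losses = []
        for i in range(0, len(data), batch_size):
            batch = data[order[i:i + batch_size]]
            out = model._forward(batch, training=True)
            diff = out - batch.astype(np.float32)
            loss = float((diff ** 2).mean())
            model._backward(2.0 * diff / diff.size)
            opt.step()
            losses.append((loss, len(batch)))
        total = sum(n for _, n in losses)
        epoch_loss = sum(l * n for l, n in losses) / total
        trace.append(epoch_loss)
        if epoch_loss < best - min_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.trained = True
    model.training_metadata = {
        "epochs_run": len(trace), "loss_trace": trace,
        "seed": seed, "batch_size": batch_size,
        "learning_rate": learning_rate,
    }
    return model


def mean_squared_reconstruction_error(s: np.ndarray,
                                      s_hat: np.ndarray) -> float:
    """AE_MSE closed form: sum of squared differences over L*M*N."""
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s.shape != s_hat.shape:
        raise ConfigurationError("input and reconstruction shapes differ")
    return float(((s - s_hat) ** 2).mean())


def ae_mse(model: AEModel, spectrogram) -> float:
    """Reconstruction-error quality feature of one spectrogram image."""
    if not model.trained:
        raise NotTrainedError("autoencoder must be trained before ae_mse")
    pixels = np.asarray(getattr(spectrogram, "pixels", spectrogram), dtype=float)
    recon = model.reconstruct(pixels)
    return mean_squared_reconstruction_error(pixels, recon)


def ae_mse_batch(model: AEModel, spectrograms, batch_size: int = 64) -> np.ndarray:
    """Vectorized AE_MSE over many spectrograms."""
    if not model.trained:
        raise NotTrainedError("autoencoder must be trained before ae_mse")
    data = _as_pixel_stack(spectrograms)
    recon = model.reconstruct(data, batch_size=batch_size)
    return ((data - recon) ** 2).mean(axis=(1, 2, 3))


# ---------------------------------------------------------------------------
# serialization (npz weights + JSON descriptor)
# ---------------------------------------------------------------------------

def save_ae(model: AEModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blobs = {}
    for i, layer in enumerate(model.layers):
        for k, v in layer.params.items():
            blobs[f"layer{i}_{k}"] = v
        if isinstance(layer, BatchNorm2D):
            blobs[f"layer{i}_running_mean"] = layer.running_mean
            blobs[f"layer{i}_running_var"] = layer.running_var
    np.savez(directory / "weights.npz", **blobs)
    arch = model.architecture
    (directory / "architecture.json").write_text(json.dumps({
        "filters": list(arch.filters), "strides": list(arch.strides),
        "kernel": arch.kernel, "image_size": arch.image_size,
        "channels": arch.channels, "seed": model.seed,
        "trained": model.trained,
        "training_metadata": model.training_metadata,
    }, indent=2))


def load_ae(directory) -> AEModel:
    directory = Path(directory)
    desc = json.loads((directory / "architecture.json").read_text())
    arch = AEArchitecture(
        filters=tuple(desc["filters"]), strides=tuple(desc["strides"]),
        kernel=desc["kernel"], image_size=desc["image_size"],
        channels=desc["channels"])
    model = build_ae(arch, seed=desc["seed"])
    blobs = np.load(directory / "weights.npz")
    for i, layer in enumerate(model.layers):
        for k in layer.params:
            layer.params[k][...] = blobs[f"layer{i}_{k}"]
        if isinstance(layer, BatchNorm2D):
            layer.running_mean = blobs[f"layer{i}_running_mean"]
            layer.running_var = blobs[f"layer{i}_running_var"]
    model.trained = desc["trained"]
    model.training_metadata = desc.get("training_metadata", {})
    return model
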