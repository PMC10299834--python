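"""Six-layer CNN for foot-strike-frequency classification.

The network maps a 1-s clip of wheel-running video — 30 grayscale frames
stacked on the channel axis — to a softmax distribution over integer
foot-strike-frequency classes (Hz).  Architecture: three 2-D convolution
blocks (4x4 kernels, same padding, unit stride, leaky-ReLU, 2x2 max pool
with stride 2) followed by three fully connected layers, the last of which
has one neuron per frequency class.

Everything is plain NumPy.  Convolutions are evaluated as a sum of GEMMs,
one per kernel offset, which keeps memory flat and lets BLAS do the work;
the backward pass is hand-derived and is validated against finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParams",
    "ConfigError",
    "ShapeError",
    "init_params",
    "forward",
    "softmax_probs",
    "predict_clip",
    "predict_batch",
    "extract_activations",
    "leaky_relu",
    "count_parameters",
    "save_params",
    "load_params",
]


class ConfigError(ValueError):
    """Inconsistent or invalid model configuration."""


class ShapeError(ValueError):
    """Input tensor does not match the configured shape."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description of the foot-strike CNN.

    Parameters
    ----------
    n_classes
        Number of frequency classes N_freq (8 for the aged cohort,
        11 for the young cohort whose gait is faster).
    input_shape
        ``(channels, height, width)`` of one clip; channels is the number
        of frames per second, i.e. 30.
    conv_channels
        Output channels of the three convolution layers.  The first layer
        consumes the 30 frame-channels and produces ``conv_channels[0]``
        maps (default 30, i.e. a first filter bank of shape 4x4x30x30).
    kernel_size
        Spatial extent of every convolution kernel.
    pool_window, pool_stride
        Max-pooling geometry; the default 2x2/stride-2 halves each spatial
        dimension after every block.
    leaky_slope
        Negative-side slope of the leaky-ReLU activations.
    fc_hidden
        Widths of the two hidden fully connected layers; the output layer
        width is ``n_classes``.
    dtype
        Floating dtype of parameters and activations.  float32 for
        training speed; float64 when gradients are compared against
        finite differences.
    """

    n_classes: int
    input_shape: tuple[int, int, int] = (30, 64, 64)
    conv_channels: tuple[int, int, int] = (30, 30, 30)
    kernel_size: tuple[int, int] = (4, 4)
    pool_window: tuple[int, int] = (2, 2)
    pool_stride: tuple[int, int] = (2, 2)
    leaky_slope: float = 0.2
    fc_hidden: tuple[int, int] = (256, 64)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.input_shape) != 3:
            raise ConfigError("input_shape must be (channels, height, width)")
        if len(self.conv_channels) != 3:
            raise ConfigError("exactly three convolution layers are required")
        if len(self.fc_hidden) != 2:
            raise ConfigError("exactly two hidden fully connected layers are required")
        if any(c <= 0 for c in self.conv_channels):
            raise ConfigError("conv_channels must be positive")
        if min(self.input_shape[1:]) < 8:
            raise ConfigError("spatial input dims must be at least 8 for three pooling stages")

    @property
    def conv_specs(self) -> list[tuple[int, int, int, int]]:
        """Per-layer (kernel_h, kernel_w, in_channels, out_channels)."""
        kh, kw = self.kernel_size
        ins = (self.input_shape[0],) + tuple(self.conv_channels[:-1])
        return [(kh, kw, cin, cout) for cin, cout in zip(ins, self.conv_channels)]

    def spatial_dims(self) -> list[tuple[int, int]]:
        """Spatial (height, width) after each of the three conv+pool blocks.

        Same padding keeps the convolution output at the input size; the
        pool then produces ``ceil(dim / stride)``.
        """
        h, w = self.input_shape[1:]
        dims = []
        for _ in range(3):
            h = -(-h // self.pool_stride[0])
            w = -(-w // self.pool_stride[1])
            dims.append((h, w))
        return dims

    @property
    def flat_dim(self) -> int:
        h, w = self.spatial_dims()[-1]
        return h * w * self.conv_channels[-1]

    @property
    def fc_widths(self) -> tuple[int, int, int]:
        return (*self.fc_hidden, self.n_classes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_classes": self.n_classes,
                "input_shape": list(self.input_shape),
                "conv_channels": list(self.conv_channels),
                "kernel_size": list(self.kernel_size),
                "pool_window": list(self.pool_window),
                "pool_stride": list(self.pool_stride),
                "leaky_slope": self.leaky_slope,
                "fc_hidden": list(self.fc_hidden),
                "dtype": self.dtype,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        return cls(
            n_classes=d["n_classes"],
            input_shape=tuple(d["input_shape"]),
            conv_channels=tuple(d["conv_channels"]),
            kernel_size=tuple(d["kernel_size"]),
            pool_window=tuple(d["pool_window"]),
            pool_stride=tuple(d["pool_stride"]),
            leaky_slope=d["leaky_slope"],
            fc_hidden=tuple(d["fc_hidden"]),
            dtype=d["dtype"],
        )


@dataclass
class ModelParams:
    """Weight tensors and biases matching a :class:`ModelConfig`.

    Convolution weights are stored as ``(kh, kw, in_channels, out_channels)``;
    fully connected weights as ``(in_dim, out_dim)``.
    """

    config: ModelConfig
    conv_w: list[np.ndarray] = field(default_factory=list)
    conv_b: list[np.ndarray] = field(default_factory=list)
    fc_w: list[np.ndarray] = field(default_factory=list)
    fc_b: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        specs = self.config.conv_specs
        if len(self.conv_w) != 3 or len(self.fc_w) != 3:
            raise ConfigError("expected 3 conv and 3 fc layers")
        for i, (w, b, spec) in enumerate(zip(self.conv_w, self.conv_b, specs)):
            if w.shape != spec:
                raise ConfigError(f"conv layer {i}: weight shape {w.shape} != {spec}")
            if b.shape != (spec[3],):
                raise ConfigError(f"conv layer {i}: bias shape {b.shape}")
        dims = (self.config.flat_dim, *self.config.fc_widths)
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            if w.shape != (dims[i], dims[i + 1]):
                raise ConfigError(
                    f"fc layer {i}: weight shape {w.shape} != {(dims[i], dims[i + 1])}"
                )
            if b.shape != (dims[i + 1],):
                raise ConfigError(f"fc layer {i}: bias shape {b.shape}")
        for t in self.tensors():
            if not np.all(np.isfinite(t)):
                raise ConfigError("non-finite parameter value")

    def tensors(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, *self.fc_w, *self.fc_b]

    def copy(self) -> "ModelParams":
        return ModelParams(
            config=self.config,
            conv_w=[w.copy() for w in self.conv_w],
            conv_b=[b.copy() for b in self.conv_b],
            fc_w=[w.copy() for w in self.fc_w],
            fc_b=[b.copy() for b in self.fc_b],
        )


def init_params(config: ModelConfig, seed: int) -> ModelParams:
    """He (fan-in) initialization: weights ~ N(0, 2/fan_in), zero biases.

    Deterministic for a given ``(config, seed)`` pair.
    """
    rng = np.random.default_rng(seed)
    dtype = np.dtype(config.dtype)
    conv_w, conv_b, fc_w, fc_b = [], [], [], []
    for kh, kw, cin, cout in config.conv_specs:
        fan_in = kh * kw * cin
        std = np.sqrt(2.0 / fan_in)
        conv_w.append(rng.normal(0.0, std, size=(kh, kw, cin, cout)).astype(dtype))
        conv_b.append(np.zeros(cout, dtype=dtype))
    dims = (config.flat_dim, *config.fc_widths)
    for i in range(3):
        std = np.sqrt(2.0 / dims[i])
        fc_w.append(rng.normal(0.0, std, size=(dims[i], dims[i + 1])).astype(dtype))
        fc_b.append(np.zeros(dims[i + 1], dtype=dtype))
    params = ModelParams(config, conv_w, conv_b, fc_w, fc_b)
    params.validate()
    return params


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _same_pad(k: int) -> tuple[int, int]:
    # TensorFlow-style SAME for stride 1: total pad k-1, excess on the far side
    return (k - 1) // 2, k // 2


def conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2-D convolution (cross-correlation), same padding, unit stride.

    ``x`` is NHWC, ``w`` is (kh, kw, cin, cout).  Implemented as one GEMM
    per kernel offset accumulated into the output.
    """
    n, h, wd, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin_w != cin:
        raise ShapeError(f"input has {cin} channels, kernel expects {cin_w}")
    ph0, ph1 = _same_pad(kh)
    pw0, pw1 = _same_pad(kw)
    xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    out = np.zeros((n * h * wd, cout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :])
            out += patch.reshape(-1, cin) @ w[i, j]
    out += b
    return out.reshape(n, h, wd, cout)


def conv2d_same_backward(
    dy: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv2d_same` w.r.t. input, weights, bias."""
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ph0, ph1 = _same_pad(kh)
    pw0, pw1 = _same_pad(kw)
    xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    dy_flat = dy.reshape(-1, cout)
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :]).reshape(-1, cin)
            dw[i, j] = patch.T @ dy_flat
            dxp[:, i : i + h, j : j + wd, :] += (dy_flat @ w[i, j].T).reshape(n, h, wd, cin)
    db = dy_flat.sum(axis=0)
    dx = dxp[:, ph0 : ph0 + h, pw0 : pw0 + wd, :]
    return dx, dw, db


def maxpool(x: np.ndarray, window: tuple[int, int], stride: tuple[int, int]):
    """Max pooling on NHWC input.  Returns (pooled, argmax cache).

    Only the window == stride case is implemented (the network uses
    2x2/stride 2 throughout).  Ragged edges are padded with -inf so the
    output spatial size is ceil(dim / stride), matching same padding.
    """
    if window != stride:
        raise ConfigError("pooling requires window == stride")
    n, h, wd, c = x.shape
    sh, sw = stride
    oh, ow = -(-h // sh), -(-wd // sw)
    pad_h, pad_w = oh * sh - h, ow * sw - wd
    if pad_h or pad_w:
        x = np.pad(x, ((0, 0), (0, pad_h), (0, pad_w), (0, 0)), constant_values=-np.inf)
    tiles = x.reshape(n, oh, sh, ow, sw, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, sh * sw)
    arg = tiles.argmax(axis=-1)
    pooled = np.take_along_axis(tiles, arg[..., None], axis=-1)[..., 0]
    return pooled, (arg, (h, wd), (pad_h, pad_w))


def maxpool_backward(dy: np.ndarray, cache, stride: tuple[int, int]) -> np.ndarray:
    arg, (h, wd), (pad_h, pad_w) = cache
    n, oh, ow, c = dy.shape
    sh, sw = stride
    dtiles = np.zeros((n, oh, ow, c, sh * sw), dtype=dy.dtype)
    np.put_along_axis(dtiles, arg[..., None], dy[..., None], axis=-1)
    dx = dtiles.reshape(n, oh, ow, c, sh, sw).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, oh * sh, ow * sw, c
    )
    if pad_h or pad_w:
        dx = dx[:, : h, : wd, :]
    return dx


def _as_batch(batch: np.ndarray, config: ModelConfig) -> np.ndarray:
    batch = np.asarray(batch)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.ndim != 4 or batch.shape[1:] != config.input_shape:
        raise ShapeError(
            f"expected batch of shape (n, {', '.join(map(str, config.input_shape))}), "
            f"got {batch.shape}"
        )
    # channels-first clips -> NHWC for the GEMM layout
    return np.ascontiguousarray(batch.transpose(0, 2, 3, 1), dtype=np.dtype(config.dtype))


def forward_with_cache(params: ModelParams, batch: np.ndarray):
    """Full forward pass keeping every intermediate needed for backprop."""
    cfg = params.config
    slope = cfg.leaky_slope
    x = _as_batch(batch, cfg)
    cache: dict = {"inputs": [], "pre": [], "pool": []}
    for w, b in zip(params.conv_w, params.conv_b):
        cache["inputs"].append(x)
        z = conv2d_same(x, w, b)
        cache["pre"].append(z)
        a = leaky_relu(z, slope)
        x, pool_cache = maxpool(a, cfg.pool_window, cfg.pool_stride)
        cache["pool"].append(pool_cache)
    n = x.shape[0]
    flat = x.reshape(n, -1)
    cache["flat_shape"] = x.shape
    cache["fc_inputs"] = []
    cache["fc_pre"] = []
    h = flat
    for i, (w, b) in enumerate(zip(params.fc_w, params.fc_b)):
        cache["fc_inputs"].append(h)
        z = h @ w + b
        cache["fc_pre"].append(z)
        h = leaky_relu(z, slope) if i < 2 else z
    logits = h
    return logits, cache


def forward(params: ModelParams, batch: np.ndarray) -> np.ndarray:
    """Logits (n, n_classes) for a batch of clips shaped (n, 30, H, W)."""
    logits, _ = forward_with_cache(params, batch)
    return logits


def backward(params: ModelParams, cache, dlogits: np.ndarray) -> "ModelParams":
    """Backpropagate d(loss)/d(logits); returns gradients shaped like params."""
    cfg = params.config
    slope = cfg.leaky_slope
    grads = ModelParams(
        config=cfg,
        conv_w=[np.zeros_like(w) for w in params.conv_w],
        conv_b=[np.zeros_like(b) for b in params.conv_b],
        fc_w=[np.zeros_like(w) for w in params.fc_w],
        fc_b=[np.zeros_like(b) for b in params.fc_b],
    )
    dh = dlogits
    for i in (2, 1, 0):
        if i < 2:
            z = cache["fc_pre"][i]
            dh = dh * np.where(z >= 0, 1.0, slope).astype(dh.dtype)
        grads.fc_w[i] = cache["fc_inputs"][i].T @ dh
        grads.fc_b[i] = dh.sum(axis=0)
        dh = dh @ params.fc_w[i].T
        if i == 0:
            dh = dh.reshape(cache["flat_shape"])
    for i in (2, 1, 0):
        dh = maxpool_backward(dh, cache["pool"][i], cfg.pool_stride)
        z = cache["pre"][i]
        dh = dh * np.where(z >= 0, 1.0, slope).astype(dh.dtype)
        dh, grads.conv_w[i], grads.conv_b[i] = conv2d_same_backward(
            dh, cache["inputs"][i], params.conv_w[i]
        )
    return grads


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for overflow safety."""
    logits = np.asarray(logits, dtype=np.float64)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def predict_batch(params: ModelParams, batch: np.ndarray) -> np.ndarray:
    """Predicted frequency class per clip; ties go to the lower frequency.

    ``argmax`` already returns the first maximal index, which is the lower
    class on a tie.
    """
    logits = forward(params, batch)
    return softmax_probs(logits).argmax(axis=-1)


def predict_clip(params: ModelParams, stack) -> int:
    """Predicted foot-strike frequency (Hz) of a single clip."""
    pixels = stack.pixels if hasattr(stack, "pixels") else stack
    return int(predict_batch(params, np.asarray(pixels)[None])[0])


def extract_activations(params: ModelParams, stack) -> list[np.ndarray]:
    """Post-activation output of each of the six layers, for visualization.

    Returns ``[pool1, pool2, pool3, fc1, fc2, logits]`` with the leading
    batch axis dropped.  Convolution-block maps are (H, W, channels).
    """
    pixels = stack.pixels if hasattr(stack, "pixels") else stack
    _, cache = forward_with_cache(params, np.asarray(pixels)[None])
    cfg = params.config
    maps = [cache["inputs"][1][0], cache["inputs"][2][0]]
    maps.append(cache["fc_inputs"][0].reshape(cache["flat_shape"])[0])
    maps.append(leaky_relu(cache["fc_pre"][0], cfg.leaky_slope)[0])
    maps.append(leaky_relu(cache["fc_pre"][1], cfg.leaky_slope)[0])
    maps.append(cache["fc_pre"][2][0])
    return maps


def count_parameters(config: ModelConfig) -> int:
    """Total trainable parameter count implied by the architecture."""
    total = 0
    for kh, kw, cin, cout in config.conv_specs:
        total += kh * kw * cin * cout + cout
    dims = (config.flat_dim, *config.fc_widths)
    for i in range(3):
        total += dims[i] * dims[i + 1] + dims[i + 1]
    return total


def save_params(params: ModelParams, path) -> None:
    """Checkpoint weights plus the embedded architecture description (NPZ)."""
    arrays = {"config_json": np.array(params.config.to_json())}
    for i in range(3):
        arrays[f"conv_w{i}"] = params.conv_w[i]
        arrays[f"conv_b{i}"] = params.conv_b[i]
        arrays[f"fc_w{i}"] = params.fc_w[i]
        arrays[f"fc_b{i}"] = params.fc_b[i]
    np.savez(path, **arrays)


def load_params(path) -> ModelParams:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig.from_json(str(data["config_json"]))
    params = ModelParams(
        config=config,
        conv_w=[data[f"conv_w{i}"] for i in range(3)],
        conv_b=[data[f"conv_b{i}"] for i in range(3)],
        fc_w=[data[f"fc_w{i}"] for i in range(3)],
        fc_b=[data[f"fc_b{i}"] for i in range(3)],
    )
    params.validate()
    return params
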