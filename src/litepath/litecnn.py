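"""The Lite CNN architecture family and its numpy compute engine.

Every variant is a stack of identical canonical blocks

    3x3 same-padded convolution -> batch normalization -> ReLU -> 2x2 max pool

followed by global average pooling, a 256-unit ReLU dense layer, dropout
(rate 0.4) and a softmax classifier over the three tissue classes. Variants
differ only in the number of blocks and their filter widths:

    Lite-V0  3 blocks  16-32-64
    Lite-V1  4 blocks  32-64-128-128
    Lite-V2  5 blocks  32-64-128-256-256
    Lite-V4  6 blocks  32-64-128-256-512-512

(The family intentionally has no "Lite-V3".) Each 2x2 pool halves the
spatial side, so the input size must be divisible by 2^blocks and the
pre-GAP feature map has side input_size / 2^blocks.

The layers are implemented directly on numpy arrays (NHWC layout,
channels-last) with im2col convolutions so forward and backward passes reduce
to BLAS matrix products. Initialization is Glorot-uniform, seed-controlled.
Batch normalization uses epsilon 1e-3 and running-statistics momentum 0.9:
the running estimates must converge within the few hundred optimizer steps a
desk-scale run takes, which rules out the slower 0.99 momentum common in
large-scale settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthgen import ConfigurationError

__all__ = [
    "VariantConfig",
    "variant_config",
    "LayerSpec",
    "ModelSpec",
    "LiteModel",
    "builtin_variants",
    "normalize_variant_name",
    "build_model",
    "count_parameters",
]

BN_MOMENTUM = 0.9
BN_EPSILON = 1e-3


@dataclass(frozen=True)
class VariantConfig:
    """Declarative description of one Lite architecture."""

    name: str
    filters: tuple[int, ...]
    kernel: int = 3
    dense_units: int = 256
    dropout_rate: float = 0.4
    n_classes: int = 3
    input_size: int = 224

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        if not self.filters or any(f < 1 for f in self.filters):
            raise ConfigurationError(f"filters must be non-empty positive, got {self.filters}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate must lie in [0, 1), got {self.dropout_rate}"
            )
        # NOTE: input_size divisibility by 2^blocks is checked at build time,
        # so the declarative family table can exist at any nominal input size.

    @property
    def n_blocks(self) -> int:
        return len(self.filters)

    def check_buildable(self) -> None:
        if self.input_size % (2 ** len(self.filters)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{len(self.filters)} "
                f"(one 2x2 pool per block)"
            )

    def with_input_size(self, input_size: int) -> "VariantConfig":
        return VariantConfig(
            name=self.name, filters=self.filters, kernel=self.kernel,
            dense_units=self.dense_units, dropout_rate=self.dropout_rate,
            n_classes=self.n_classes, input_size=input_size,
        )


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    output_shape: tuple[int, ...]
    n_params: int = 0
    n_params_non_trainable: int = 0
    detail: str = ""


@dataclass(frozen=True)
class ModelSpec:
    """Realized layer inventory of a built variant."""

    config: VariantConfig
    layers: tuple[LayerSpec, ...]
    parameter_count: int = field(init=False)
    non_trainable_count: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "parameter_count", sum(l.n_params for l in self.layers)
        )
        object.__setattr__(
            self, "non_trainable_count",
            sum(l.n_params_non_trainable for l in self.layers),
        )

    def summary(self) -> str:
        lines = [f"Model: {self.config.name} (input {self.config.input_size}x"
                 f"{self.config.input_size}x3)"]
        for layer in self.layers:
            shape = "x".join(map(str, layer.output_shape))
            lines.append(f"  {layer.kind:<12} out {shape:<14} params {layer.n_params:>9}"
                         + (f"  [{layer.detail}]" if layer.detail else ""))
        lines.append(f"Trainable parameters:     {self.parameter_count}")
        lines.append(f"Non-trainable parameters: {self.non_trainable_count}")
        return "\n".join(lines)


_BUILTINS: dict[str, tuple[int, ...]] = {
    "Lite-V0": (16, 32, 64),
    "Lite-V1": (32, 64, 128, 128),
    "Lite-V2": (32, 64, 128, 256, 256),
    "Lite-V4": (32, 64, 128, 256, 512, 512),
}


def builtin_variants(input_size: int = 224) -> dict[str, VariantConfig]:
    """The four built-in Lite variants (note: no Lite-V3 exists)."""
    return {
        name: VariantConfig(name=name, filters=filters, input_size=input_size)
        for name, filters in _BUILTINS.items()
    }


def variant_config(name: str, input_size: int = 224) -> VariantConfig:
    """One built-in variant by (case-insensitive) name at a given input size."""
    canonical = normalize_variant_name(name)
    return VariantConfig(
        name=canonical, filters=_BUILTINS[canonical], input_size=input_size
    )


def normalize_variant_name(name: str) -> str:
    key = name.strip().lower().replace("_", "-")
    for builtin in _BUILTINS:
        if builtin.lower() == key:
            return builtin
    raise KeyError(
        f"unknown variant {name!r}; built-ins are {', '.join(_BUILTINS)}"
    )


# ---------------------------------------------------------------------------
# Layers (NHWC, float32; forward caches whatever backward needs)
# ---------------------------------------------------------------------------

def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, k*k*C) patches of a zero-padded same conv."""
    b, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # windows: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
    return np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
        b * h * w, k * k * c
    )


class Conv2D:
    """3x3 (or k x k) same-padded convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.w = _glorot_uniform(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out, dtype=np.float32)

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        b, h, w, _ = x.shape
        out = self._cols @ self.w.reshape(-1, self.c_out) + self.b
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, _ = self._shape
        dy_flat = dy.reshape(b * h * w, self.c_out)
        self.dw = (self._cols.T @ dy_flat).reshape(self.w.shape)
        self.db = dy_flat.sum(axis=0)
        # gradient w.r.t. input: correlate dy with the flipped kernel
        w_flip = self.w[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.c_in)
        dx = _im2col(dy, self.k) @ w_flip
        self._cols = None
        return dx.reshape(b, h, w, self.c_in)

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm:
    """Per-channel batch normalization (momentum 0.9, epsilon 1e-3)."""

    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    @property
    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                BN_MOMENTUM * self.running_mean + (1 - BN_MOMENTUM) * mean
            ).astype(np.float32)
            self.running_var = (
                BN_MOMENTUM * self.running_var + (1 - BN_MOMENTUM) * var
            ).astype(np.float32)
            self._n = x.size // x.shape[-1]
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_sd = 1.0 / np.sqrt(var + BN_EPSILON)
        self._xhat = (x - mean) * self._inv_sd
        return (self.gamma * self._xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(dy.ndim - 1))
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        n = self._n
        dxhat = dy * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axes)
        ) * self._inv_sd
        self._xhat = None
        return dx.astype(np.float32)

    @property
    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling with stride 2; ties break to the first position."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, h, w, c = x.shape
        patches = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4, c)
        )
        self._argmax = patches.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(patches, self._argmax[..., None, :], axis=3)[
            ..., 0, :
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        patches = np.zeros((b, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(patches, self._argmax[..., None, :], dy[..., None, :], axis=3)
        dx = (
            patches.reshape(b, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )
        self._argmax = None
        return dx


class GlobalAvgPool:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._in_shape).astype(
            dy.dtype
        )


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _glorot_uniform(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.w.T

    @property
    def grads(self):
        return {"w": self.dw, "b": self.db}


class Dropout:
    """Inverted dropout; identity outside training."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Softmax:
    """Softmax output; backward expects d(loss)/d(logits) passed through."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # Training always pairs softmax with cross-entropy; the trainer feeds
        # d(loss)/d(logits) directly, so this is a pass-through.
        return dy


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

class LiteModel:
    """Trainable handle over the layer stack of one variant."""

    def __init__(self, cfg: VariantConfig, seed: int = 42):
        cfg.check_buildable()
        self.config = cfg
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
        self.layers: list = []
        c_in = 3
        for c_out in cfg.filters:
            self.layers.append(Conv2D(c_in, c_out, cfg.kernel, rng))
            self.layers.append(BatchNorm(c_out))
            self.layers.append(ReLU())
            self.layers.append(MaxPool2())
            c_in = c_out
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dense(c_in, cfg.dense_units, rng))
        self.layers.append(ReLU())
        self._dropout = Dropout(cfg.dropout_rate)
        self.layers.append(self._dropout)
        self.layers.append(Dense(cfg.dense_units, cfg.n_classes, rng))
        self.layers.append(Softmax())
        self.spec = _spec_from_config(cfg)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        self._dropout.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities in inference mode (no dropout, running BN stats)."""
        x = np.asarray(x, dtype=np.float32)
        chunks = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def predict_labels(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax over softmax probabilities (lowest index wins ties)."""
        return self.predict(x, batch_size).argmax(axis=1)

    # --- parameter access -------------------------------------------------

    def parameters(self) -> list[tuple[str, object, str]]:
        """(layer_tag, layer, param_name) triples for every trainable array."""
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"layer{i:02d}", layer, name))
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        """All trainable parameters plus BN running statistics, keyed."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i:02d}/{name}"] = arr.copy()
            for name, arr in getattr(layer, "state", {}).items():
                out[f"layer{i:02d}/{name}"] = arr.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                setattr(layer, _attr_for(name), weights[f"layer{i:02d}/{name}"].copy())
            for name in getattr(layer, "state", {}):
                setattr(layer, name, weights[f"layer{i:02d}/{name}"].copy())

    def save_checkpoint(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load_checkpoint(self, path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})


def _attr_for(param_name: str) -> str:
    return param_name  # params are stored under their own attribute names


def _spec_from_config(cfg: VariantConfig) -> ModelSpec:
    cfg.check_buildable()
    layers: list[LayerSpec] = []
    side = cfg.input_size
    c_in = 3
    for block, c_out in enumerate(cfg.filters, start=1):
        layers.append(
            LayerSpec(
                kind="conv3x3",
                output_shape=(side, side, c_out),
                n_params=c_out * (cfg.kernel * cfg.kernel * c_in + 1),
                detail=f"block {block}: {c_in}->{c_out}",
            )
        )
        layers.append(
            LayerSpec(
                kind="batchnorm",
                output_shape=(side, side, c_out),
                n_params=2 * c_out,
                n_params_non_trainable=2 * c_out,
            )
        )
        layers.append(LayerSpec(kind="relu", output_shape=(side, side, c_out)))
        side //= 2
        layers.append(LayerSpec(kind="maxpool2x2", output_shape=(side, side, c_out)))
        c_in = c_out
    layers.append(LayerSpec(kind="gap", output_shape=(c_in,)))
    layers.append(
        LayerSpec(
            kind="dense",
            output_shape=(cfg.dense_units,),
            n_params=cfg.dense_units * (c_in + 1),
            detail=f"{c_in}->{cfg.dense_units}, relu",
        )
    )
    layers.append(LayerSpec(kind="relu", output_shape=(cfg.dense_units,)))
    layers.append(
        LayerSpec(
            kind="dropout", output_shape=(cfg.dense_units,),
            detail=f"rate {cfg.dropout_rate}",
        )
    )
    layers.append(
        LayerSpec(
            kind="dense",
            output_shape=(cfg.n_classes,),
            n_params=cfg.n_classes * (cfg.dense_units + 1),
            detail=f"{cfg.dense_units}->{cfg.n_classes}",
        )
    )
    layers.append(LayerSpec(kind="softmax", output_shape=(cfg.n_classes,)))
    return ModelSpec(config=cfg, layers=tuple(layers))


def build_model(cfg: VariantConfig, seed: int = 42) -> tuple[ModelSpec, LiteModel]:
    """Build a variant; returns its realized ModelSpec and the trainable model."""
    model = LiteModel(cfg, seed=seed)
    return model.spec, model


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count of a built spec."""
    return spec.parameter_count
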