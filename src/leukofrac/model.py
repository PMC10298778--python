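"""Fully-convolutional fraction-regression network.

The network maps a two-channel mosaic of any size (at a fixed physical
pixel size) to a 4-vector of leukocyte fractions: a stack of stride-2
3x3 convolution + ReLU blocks, global average pooling, a 4-unit dense
layer and a softmax. Because pooling is global, the input size is dynamic;
the softmax guarantees the output lies on the probability simplex, matching
the fact that differential counts always sum to 1.

The default "simple_cnn" backbone (five conv blocks, ~240k weights) is
implemented here directly on numpy arrays with hand-written forward and
backward passes, which keeps inference and training fully deterministic
and dependency-light. The large generic-image backbones (ResNet50,
EfficientNetV2B0, MobileNetV2) are recognized configuration names but
require a GPU deep-learning backend and pretrained weight files; selecting
them raises a clear error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import CLASS_NAMES, N_CLASSES, Mosaic

#: Smallest accepted input side, in pixels (five stride-2 stages).
MIN_INPUT_SIZE = 64

#: Negative slope of the backbone's leaky ReLU.
LEAKY_SLOPE = 0.1

PAPER_BACKBONES = ("resnet50", "efficientnetv2b0", "mobilenetv2")


@dataclass
class ModelConfig:
    """Architecture configuration.

    ``backbone`` selects the convolutional trunk ("simple_cnn" is the
    implemented desk-scale option); ``input_channels`` is 2 (THG, 2PEF) or
    3 (RGB composite / 3PEF); ``widths`` are the per-block channel counts
    of the simple backbone; ``seed`` fixes weight initialization.
    """

    backbone: str = "simple_cnn"
    pretrained: bool = False
    input_channels: int = 2
    head_units: int = N_CLASSES
    widths: tuple[int, ...] = (16, 32, 64, 128, 128)
    #: per-block strides; the final block keeps stride 1 so the last
    #: feature map (and hence Grad-CAM) resolves individual cells.
    strides: tuple[int, ...] | None = None
    #: parameter-free mean-pool stem factor (1 = none). A 2x2 stem halves
    #: the working resolution so the conv hierarchy sees whole cells
    #: earlier: lymphocytes (~14 px at 0.5 um/px) fit into the second
    #: block's receptive field and macrophages (~40 px) into the fourth.
    stem_pool: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_units != N_CLASSES:
            raise ValueError(f"head_units must be {N_CLASSES}")
        if self.input_channels not in (2, 3):
            raise ValueError("input_channels must be 2 or 3")


# ---------------------------------------------------------------------------
# Layers (channels-first float32 arrays, manual backprop)
# ---------------------------------------------------------------------------


class _Conv3x3:
    """3x3 convolution, padding 1, configurable stride, via im2col matmul.

    Bias-free: the following instance normalization removes channel means,
    and omitting the bias prevents it from outgrowing the input-dependent
    response under scale-normalized (Adam) updates.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, stride: int):
        fan_in = c_in * 9
        self.weight = (rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.stride = stride
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        c_in, h, w = x.shape
        s = self.stride
        # reflect padding keeps constant inputs constant (no border response)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="reflect")
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))[:, ::s, ::s]  # (Cin,H',W',3,3)
        h_out, w_out = win.shape[1], win.shape[2]
        col = win.transpose(1, 2, 0, 3, 4).reshape(h_out * w_out, c_in * 9)
        y = col @ self.weight.reshape(self.weight.shape[0], -1).T
        if keep_cache:
            self._cache = (col, x.shape, (h_out, w_out))
        return np.ascontiguousarray(y.reshape(h_out, w_out, -1).transpose(2, 0, 1))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col, x_shape, (h_out, w_out) = self._cache
        c_out = dy.shape[0]
        dy_mat = dy.transpose(1, 2, 0).reshape(-1, c_out)
        dw = (dy_mat.T @ col).reshape(self.weight.shape)
        dcol = dy_mat @ self.weight.reshape(c_out, -1)  # (H'W', Cin*9)
        c_in, h, w = x_shape
        dcol = dcol.reshape(h_out, w_out, c_in, 3, 3)
        dxp = np.zeros((c_in, h + 2, w + 2), dtype=np.float32)
        s = self.stride
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + s * h_out : s, kj : kj + s * w_out : s] += dcol[
                    :, :, :, ki, kj
                ].transpose(2, 0, 1)
        # fold reflect-padded gradients back onto their source pixels
        dx = dxp[:, 1 : h + 1, 1 : w + 1].copy()
        dx[:, 1, :] += dxp[:, 0, 1 : w + 1]
        dx[:, h - 2, :] += dxp[:, h + 1, 1 : w + 1]
        dx[:, :, 1] += dxp[:, 1 : h + 1, 0]
        dx[:, :, w - 2] += dxp[:, 1 : h + 1, w + 1]
        dx[:, 1, 1] += dxp[:, 0, 0]
        dx[:, 1, w - 2] += dxp[:, 0, w + 1]
        dx[:, h - 2, 1] += dxp[:, h + 1, 0]
        dx[:, h - 2, w - 2] += dxp[:, h + 1, w + 1]
        return dx, dw


class _InstanceNorm:
    """Per-channel spatial normalization with a trainable gain.

    ``y = g * (x - mean) / sqrt(var + eps)`` per channel. Stabilizes
    optimization at batch size 1 (full-mosaic batches) regardless of the
    absolute intensity scale of the input.
    """

    # variance floor: without it, channels that are nearly silent on an
    # image (empty background) are divided by a vanishing std and their
    # noise is amplified to unit variance, making background texture as
    # salient as cells
    EPS = 3e-3

    def __init__(self, channels: int):
        self.gain = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        mean = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        xhat = (x - mean) / np.sqrt(var + self.EPS)
        if keep_cache:
            self._cache = (xhat, np.sqrt(var + self.EPS))
        return self.gain[:, None, None] * xhat

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xhat, std = self._cache
        dgain = (dy * xhat).sum(axis=(1, 2))
        dxhat = dy * self.gain[:, None, None]
        m = dxhat.mean(axis=(1, 2), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        dx = (dxhat - m - xhat * mx) / std
        return dx.astype(np.float32), dgain.astype(np.float32)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


class FractionRegressor:
    """The simple fully-convolutional fraction-regression network."""

    def __init__(self, config: ModelConfig):
        if config.backbone.lower() in PAPER_BACKBONES:
            raise NotImplementedError(
                f"backbone {config.backbone!r} requires a GPU deep-learning backend "
                "and pretrained weight files; use backbone='simple_cnn'"
            )
        if config.backbone != "simple_cnn":
            raise ValueError(f"unknown backbone {config.backbone!r}")
        if config.pretrained:
            raise ValueError("no generic-image pretrain exists for simple_cnn")
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs: list[_Conv3x3] = []
        self.norms: list[_InstanceNorm | None] = []
        c_prev = config.input_channels
        strides = config.strides
        if strides is None:
            strides = tuple([2] * (len(config.widths) - 1) + [1])
        if len(strides) != len(config.widths):
            raise ValueError("strides must match widths")
        for i, width in enumerate(config.widths):
            self.convs.append(_Conv3x3(rng, c_prev, width, stride=strides[i]))
            # no normalization on the final block: global average pooling
            # must see feature magnitudes that scale with the density of
            # the evidence (instance norm would rescale them per image)
            last = i == len(config.widths) - 1
            self.norms.append(None if last else _InstanceNorm(width))
            c_prev = width
        self.head_w = (rng.standard_normal((N_CLASSES, c_prev)) * np.sqrt(1.0 / c_prev)).astype(
            np.float32
        )
        self.head_b = np.zeros(N_CLASSES, dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[0] != self.config.input_channels:
            raise ValueError(
                f"expected (C={self.config.input_channels}, H, W) input, got {x.shape}"
            )
        if min(x.shape[1], x.shape[2]) < MIN_INPUT_SIZE:
            raise ValueError(
                f"input {x.shape[1]}x{x.shape[2]} is below the backbone minimum "
                f"of {MIN_INPUT_SIZE} px"
            )

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Class probabilities for a (C, H, W) float32 image."""
        self._check_input(x)
        a = x.astype(np.float32, copy=False)
        k = self.config.stem_pool
        if k > 1:
            c, h, w = a.shape
            a = a[:, : h - h % k, : w - w % k]
            a = a.reshape(c, h // k, k, w // k, k).mean(axis=(2, 4))
        self._relu_masks = []
        for conv, norm in zip(self.convs, self.norms):
            z = conv.forward(a, keep_cache=keep_cache)
            if norm is not None:
                z = norm.forward(z, keep_cache=keep_cache)
            # leaky ReLU: a small negative slope keeps gradients alive under
            # the constant-magnitude updates the MAE loss produces
            mask = np.where(z > 0, np.float32(1.0), np.float32(LEAKY_SLOPE))
            a = z * mask
            if keep_cache:
                self._relu_masks.append(mask)
        self._features = a  # last conv block output (post-ReLU)
        pooled = a.mean(axis=(1, 2))
        self._pooled = pooled
        logits = self.head_w @ pooled + self.head_b
        self._probs = _softmax(logits.astype(np.float64))
        return self._probs

    def backward_from_probs(self, dprobs: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(probs); returns a
        name->gradient dict matching :meth:`parameters`. Requires a prior
        ``forward(..., keep_cache=True)``."""
        p = self._probs
        dlogits = (p * (dprobs - float(dprobs @ p))).astype(np.float32)
        grads: dict[str, np.ndarray] = {}
        grads["head_w"] = np.outer(dlogits, self._pooled)
        grads["head_b"] = dlogits
        dpooled = self.head_w.T @ dlogits
        feat = self._features
        n_spatial = feat.shape[1] * feat.shape[2]
        da = np.broadcast_to(
            (dpooled / n_spatial)[:, None, None], feat.shape
        ).astype(np.float32)
        for i in range(len(self.convs) - 1, -1, -1):
            dz = da * self._relu_masks[i]
            if self.norms[i] is not None:
                dz, dgain = self.norms[i].backward(dz)
                grads[f"norm{i}_g"] = dgain
            da, dw = self.convs[i].backward(dz)
            grads[f"conv{i}_w"] = dw
        return grads

    def gradcam_arrays(self, x: np.ndarray, class_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Feature maps of the last conv block and d(logit_c)/d(features).

        With global average pooling directly after the last block, the
        gradient of the pre-softmax class score with respect to each feature
        map is spatially constant: ``head_w[c, k] / (H' * W')``.
        """
        if not 0 <= class_index < N_CLASSES:
            raise ValueError(f"class_index must be in [0, {N_CLASSES})")
        self.forward(x)
        feat = self._features
        n_spatial = feat.shape[1] * feat.shape[2]
        grad = np.broadcast_to(
            (self.head_w[class_index] / n_spatial).astype(np.float32)[:, None, None],
            feat.shape,
        )
        return feat, grad

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"head_w": self.head_w, "head_b": self.head_b}
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            params[f"conv{i}_w"] = conv.weight
            if norm is not None:
                params[f"norm{i}_g"] = norm.gain
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.head_w = params["head_w"].astype(np.float32).copy()
        self.head_b = params["head_b"].astype(np.float32).copy()
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            conv.weight = params[f"conv{i}_w"].astype(np.float32).copy()
            if norm is not None:
                norm.gain = params[f"norm{i}_g"].astype(np.float32).copy()

    def head_parameter_names(self) -> set[str]:
        return {"head_w", "head_b"}

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Checkpoint: weights + config + class order in one .npz."""
        path = Path(path)
        meta = {
            "class_order": list(CLASS_NAMES),
            "backbone": self.config.backbone,
            "input_channels": self.config.input_channels,
            "widths": list(self.config.widths),
            "strides": [c.stride for c in self.convs],
            "stem_pool": self.config.stem_pool,
            "seed": self.config.seed,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.parameters())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FractionRegressor":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if tuple(meta["class_order"]) != CLASS_NAMES:
                raise ValueError("checkpoint class order does not match this build")
            model = cls(
                ModelConfig(
                    backbone=meta["backbone"],
                    input_channels=meta["input_channels"],
                    widths=tuple(meta["widths"]),
                    strides=tuple(meta["strides"]) if meta.get("strides") else None,
                    stem_pool=meta.get("stem_pool", 1),
                    seed=meta["seed"],
                )
            )
            model.set_parameters({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build(config: ModelConfig | None = None) -> FractionRegressor:
    """Build a fraction-regression model from a configuration."""
    return FractionRegressor(config or ModelConfig())


def _mosaic_to_array(m: Mosaic, input_channels: int) -> np.ndarray:
    x = np.moveaxis(np.asarray(m.pixels, dtype=np.float32), -1, 0)
    if x.shape[0] != input_channels:
        raise ValueError(
            f"mosaic has {x.shape[0]} channels, model expects {input_channels}"
        )
    return x


def predict(model: FractionRegressor, m: Mosaic) -> np.ndarray:
    """Predicted fraction vector for a preprocessed mosaic (deterministic)."""
    x = _mosaic_to_array(m, model.config.input_channels)
    return model.forward(x)
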