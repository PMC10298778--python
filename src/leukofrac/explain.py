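"""Grad-CAM model auditing.

Gradient-weighted class activation maps localize the image regions that
drive each of the four fraction outputs: channel-importance weights are the
spatially averaged gradients of the pre-softmax class score with respect to
the last convolutional feature maps; the map is the rectified,
importance-weighted sum of those maps, bilinearly upsampled to input
resolution and min-max normalized. A quantitative audit compares mean
activation over cell pixels vs background (a trustworthy counter activates
on cells, not on glass background or stitching artifacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import transform

from .core import CLASS_NAMES, N_CLASSES, Mosaic
from .model import FractionRegressor, _mosaic_to_array

logger = logging.getLogger(__name__)


@dataclass
class ActivationMap:
    """One per-class activation heat map at input resolution, in [0, 1]."""

    values: np.ndarray
    class_name: str
    mosaic_id: str = ""

    def __post_init__(self) -> None:
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("activation map values must lie in [0, 1]")


def gradcam(model: FractionRegressor, m: Mosaic, class_index: int, mosaic_id: str = "") -> ActivationMap:
    """Grad-CAM map of one class for one mosaic.

    Uses the pre-softmax class score (logit) for the gradients — standard
    practice that avoids inter-class gradient coupling through the softmax.
    A constant map (e.g. from a constant-zero input) normalizes to all
    zeros. Deterministic for a fixed checkpoint and input.
    """
    x = _mosaic_to_array(m, model.config.input_channels)
    features, grad = model.gradcam_arrays(x, class_index)
    weights = grad.mean(axis=(1, 2))  # channel importances
    cam = np.maximum(np.tensordot(weights, features, axes=(0, 0)), 0.0)
    cam = transform.resize(
        cam, (m.height, m.width), order=1, mode="edge", anti_aliasing=False
    )
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        values = np.zeros_like(cam)
    else:
        values = (cam - lo) / (hi - lo)
    return ActivationMap(values=values.astype(np.float64), class_name=CLASS_NAMES[class_index], mosaic_id=mosaic_id)


def gradcam_all_classes(model: FractionRegressor, m: Mosaic, mosaic_id: str = "") -> list[ActivationMap]:
    """Four maps per mosaic, one per leukocyte class."""
    return [gradcam(model, m, c, mosaic_id) for c in range(N_CLASSES)]


#: Four-color ramp lookup table control points (min -> max activation).
_RAMP_COLORS = np.array(
    [
        [0.0, 0.0, 1.0],  # blue
        [0.0, 1.0, 0.0],  # green
        [1.0, 1.0, 0.0],  # yellow
        [1.0, 0.0, 0.0],  # red
    ]
)
_RAMP_POSITIONS = np.array([0.0, 1 / 3, 2 / 3, 1.0])


def ramp_lut(values: np.ndarray) -> np.ndarray:
    """Map activations in [0, 1] through the blue-green-yellow-red ramp."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    rgb = np.empty(v.shape + (3,), dtype=np.float64)
    for c in range(3):
        rgb[..., c] = np.interp(v, _RAMP_POSITIONS, _RAMP_COLORS[:, c])
    return rgb


def render_overlay(
    amap: ActivationMap, m: Mosaic, alpha: float = 0.5, colorbar: bool = True
) -> np.ndarray:
    """Alpha-blend the color-ramped map over the grayscale composite.

    Returns an 8-bit RGB array; a vertical ramp colorbar is embedded along
    the right edge. Activation 0 renders blue, 1 renders red.
    """
    if amap.values.shape != (m.height, m.width):
        raise ValueError(
            f"map {amap.values.shape} does not match mosaic "
            f"{(m.height, m.width)}"
        )
    gray = np.clip(m.pixels.max(axis=2), 0.0, 1.0)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    heat = ramp_lut(amap.values)
    blended = (1 - alpha) * base + alpha * heat
    if colorbar:
        bar_w = max(m.width // 50, 4)
        ramp = ramp_lut(np.linspace(1.0, 0.0, m.height))[:, None, :]
        blended = np.concatenate([blended, np.tile(ramp, (1, bar_w, 1))], axis=1)
    return np.round(np.clip(blended, 0.0, 1.0) * 255).astype(np.uint8)


def activation_audit(
    maps: list[ActivationMap], cell_mask: np.ndarray
) -> dict[str, dict[str, float]]:
    """Mean activation over cell pixels vs background, per class map.

    ``cell_mask`` is the union of ground-truth cell masks. The ratio
    cell/background quantifies whether the model looks at cells; a ratio is
    reported as NaN (undefined) when the background mean is zero.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask: nothing to audit")
    if mask.all():
        raise ValueError("mask covers the whole image: no background to audit")
    out: dict[str, dict[str, float]] = {}
    for amap in maps:
        cell = float(amap.values[mask].mean())
        bg = float(amap.values[~mask].mean())
        out[amap.class_name] = {
            "mean_cell_activation": cell,
            "mean_background_activation": bg,
            "ratio": cell / bg if bg > 0 else float("nan"),
        }
    return out
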