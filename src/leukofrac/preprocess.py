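"""Mosaic preprocessing chain: gamma, background subtraction, CLAHE,
pixel-size normalization and quadrant splitting.

The chain mirrors how raw stitched mosaics are prepared for the
fraction-regression model: acquisition-time gamma correction (factor 0.7),
rolling-ball background subtraction (removes the glass-interface plane in
the THG channel), contrast-limited adaptive histogram equalization, a fixed
0.5 um/px working pixel size obtained by down-scaling, and splitting of
large mosaics (> 2500 x 2500 px) into four quadrants that inherit the
parent's fraction label. The whole chain is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, restoration, transform

from .core import Mosaic

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``gamma`` is applied first (set ``apply_gamma=False`` for inputs already
    gamma-corrected at acquisition save time); ``rolling_ball_radius`` is in
    micrometres and must exceed the largest cell radius; ``target_pixel_size``
    in um/px; ``split_threshold`` in pixels per side.
    """

    gamma: float = 0.7
    apply_gamma: bool = True
    rolling_ball_radius: float = 25.0
    clahe_clip: float = 0.01
    clahe_tile: int = 64
    target_pixel_size: float = 0.5
    split_threshold: int = 2500

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.target_pixel_size <= 0:
            raise ValueError("target_pixel_size must be positive")
        if self.split_threshold <= 0:
            raise ValueError("split_threshold must be positive")


def gamma_correct(m: Mosaic, gamma: float = 0.7) -> Mosaic:
    """Elementwise power-law correction ``out = in ** gamma`` on [0, 1] data."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return m.with_pixels(np.power(np.clip(m.pixels, 0.0, None), gamma))


def subtract_background(m: Mosaic, radius_um: float = 25.0) -> Mosaic:
    """Rolling-ball background subtraction, per channel, clipped at 0.

    The smooth background is estimated by rolling a ball of the given
    physical radius under the intensity surface. Because the background is
    smooth at the cell scale, the estimate is computed on a 4x downsampled
    copy and upsampled back — numerically equivalent for backgrounds varying
    over tens of micrometres and an order of magnitude faster on large
    mosaics.
    """
    radius_px = radius_um / m.pixel_size
    if radius_px < 2:
        raise ValueError(
            f"rolling-ball radius {radius_um} um is under 2 px at "
            f"{m.pixel_size} um/px"
        )
    shrink = 4 if radius_px >= 8 else 1
    # 8-bit intensity convention: with intensities on [0, 1] and the radius
    # in pixels the ball would be nearly flat in intensity units and roll
    # into cell-sized peaks; scaling to the 0-255 range makes it steep
    # enough that only structures wider than the ball count as background.
    scale = 255.0
    out = np.empty_like(m.pixels, dtype=np.float32)
    for c in range(m.n_channels):
        channel = m.pixels[:, :, c].astype(np.float64)
        if shrink > 1:
            small = transform.downscale_local_mean(channel, (shrink, shrink))
        else:
            small = channel
        # pre-smoothing plus a median DC correction: the morphological
        # opening tracks the lower envelope of the noise, which would leave
        # a positive residual floor after subtraction
        small = ndimage.gaussian_filter(small, sigma=1.0)
        bg_small = restoration.rolling_ball(small * scale, radius=radius_px / shrink) / scale
        bg_small += np.median(small - bg_small)
        if shrink > 1:
            bg = transform.resize(
                bg_small, channel.shape, order=1, mode="edge", anti_aliasing=False
            )
        else:
            bg = bg_small
        out[:, :, c] = np.clip(channel - bg, 0.0, None)
    return m.with_pixels(out)


def apply_clahe(m: Mosaic, clip: float = 0.01, tile: int = 64) -> Mosaic:
    """Contrast-limited adaptive histogram equalization per channel.

    Input intensities must lie in [0, 1]; output stays in [0, 1]. Constant
    channels are passed through unchanged (no contrast to equalize).
    """
    if tile > min(m.height, m.width):
        raise ValueError(
            f"CLAHE tile {tile} px exceeds image extent {m.height}x{m.width}"
        )
    out = np.empty_like(m.pixels, dtype=np.float32)
    for c in range(m.n_channels):
        channel = m.pixels[:, :, c]
        if channel.max() - channel.min() < 1e-12:
            out[:, :, c] = channel
            continue
        out[:, :, c] = exposure.equalize_adapthist(
            np.clip(channel, 0.0, 1.0), kernel_size=tile, clip_limit=clip
        )
    return m.with_pixels(np.clip(out, 0.0, 1.0))


def normalize_pixel_size(m: Mosaic, target: float = 0.5) -> Mosaic:
    """Down-scale so the pixel size equals ``target`` um/px.

    Only down-scaling is supported (fixing the working resolution never
    upsamples); an already-matching mosaic is returned unchanged. Integer
    reduction factors use local-mean (area-averaging) binning; non-integer
    factors use anti-aliased resampling. Physical extent is preserved to
    within one pixel.
    """
    if target <= 0:
        raise ValueError("target pixel size must be positive")
    if abs(m.pixel_size - target) < 1e-9:
        return m
    if m.pixel_size > target + 1e-9:
        raise ValueError(
            f"up-scaling from {m.pixel_size} to {target} um/px is not supported "
            "(pixel-size normalization down-scales only)"
        )
    factor = target / m.pixel_size
    if abs(factor - round(factor)) < 1e-9:
        k = int(round(factor))
        h = (m.height // k) * k
        w = (m.width // k) * k
        out = np.stack(
            [
                transform.downscale_local_mean(m.pixels[:h, :w, c].astype(np.float64), (k, k))
                for c in range(m.n_channels)
            ],
            axis=-1,
        ).astype(np.float32)
    else:
        new_h = int(round(m.height / factor))
        new_w = int(round(m.width / factor))
        out = np.stack(
            [
                transform.resize(
                    m.pixels[:, :, c].astype(np.float64),
                    (new_h, new_w),
                    order=1,
                    anti_aliasing=True,
                )
                for c in range(m.n_channels)
            ],
            axis=-1,
        ).astype(np.float32)
    return m.with_pixels(out, pixel_size=target)


def split_mosaic(m: Mosaic, threshold: int = 2500) -> list[Mosaic]:
    """Split a large mosaic into quadrants covering every pixel exactly once.

    With both sides above ``threshold`` pixels the mosaic is divided into
    four (floor/ceil split); with only one side above, into two along that
    side; otherwise it is returned unchanged as a singleton list. Quadrants
    inherit the parent's fraction label downstream (each is treated as an
    individual case).
    """
    split_h = m.height > threshold
    split_w = m.width > threshold
    if not (split_h or split_w):
        return [m]
    ys = [slice(0, m.height // 2), slice(m.height // 2, m.height)] if split_h else [slice(0, m.height)]
    xs = [slice(0, m.width // 2), slice(m.width // 2, m.width)] if split_w else [slice(0, m.width)]
    return [m.with_pixels(m.pixels[y, x]) for y in ys for x in xs]


def preprocess_mosaic(m: Mosaic, config: PreprocessConfig | None = None) -> list[Mosaic]:
    """Full chain: gamma -> background subtraction -> CLAHE -> pixel-size
    normalization -> quadrant split. Returns one or more model-ready mosaics."""
    cfg = config or PreprocessConfig()
    out = m
    if cfg.apply_gamma:
        out = gamma_correct(out, cfg.gamma)
    out = subtract_background(out, cfg.rolling_ball_radius)
    out = apply_clahe(out, cfg.clahe_clip, cfg.clahe_tile)
    out = normalize_pixel_size(out, cfg.target_pixel_size)
    return split_mosaic(out, cfg.split_threshold)
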