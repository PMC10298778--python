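"""Shared types and constants for the leukocyte fraction-regression pipeline.

The project-wide class order is (neutrophil, eosinophil, lymphocyte,
macrophage); every fraction vector, class-weight vector, model head and
report column follows it. Fractions are stored on the 0-1 scale internally;
percentages appear only at report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Fixed project-wide leukocyte class order.
CLASS_NAMES: tuple[str, ...] = ("neutrophil", "eosinophil", "lymphocyte", "macrophage")
N_CLASSES = len(CLASS_NAMES)

#: Channel roles in acquisition order.
CHANNEL_THG = "THG"
CHANNEL_2PEF = "2PEF"
CHANNEL_3PEF = "3PEF"
DEFAULT_CHANNELS: tuple[str, ...] = (CHANNEL_THG, CHANNEL_2PEF)

#: Target physical pixel size of the pipeline, micrometres per pixel.
TARGET_PIXEL_SIZE_UM = 0.5


def as_fractions(values, *, atol: float = 1e-6) -> np.ndarray:
    """Validate and return a 4-vector of leukocyte fractions.

    Components must be non-negative and sum to 1 within ``atol``.
    """
    f = np.asarray(values, dtype=np.float64).reshape(-1)
    if f.size != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} fractions, got {f.size}")
    if np.any(f < -atol):
        raise ValueError(f"fractions must be non-negative, got {f}")
    total = float(f.sum())
    if abs(total - 1.0) > atol:
        raise ValueError(f"fractions must sum to 1 (got {total:.6f})")
    return np.clip(f, 0.0, None)


def fractions_from_counts(counts) -> np.ndarray | None:
    """Realized fractions from per-class counts; ``None`` when no cells exist."""
    c = np.asarray(counts, dtype=np.float64)
    total = c.sum()
    if total == 0:
        return None
    return c / total


@dataclass
class Mosaic:
    """A multi-channel 2D image with a physical pixel size.

    ``pixels`` is an ``(H, W, C)`` float array of non-negative intensities
    (the pipeline operates on the [0, 1] range), ``pixel_size`` is in
    micrometres per pixel, and ``channel_roles`` names each channel
    ("THG", "2PEF", optionally "3PEF").

    Image coordinates use a top-left origin: x grows rightward (columns),
    y downward (rows), 0-based pixel indices.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_roles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("Mosaic pixels must be H x W x C")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("Mosaic must contain at least one pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        if self.channel_roles is None:
            self.channel_roles = (CHANNEL_THG, CHANNEL_2PEF, CHANNEL_3PEF)[
                : self.pixels.shape[2]
            ]
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.pixels.shape[2]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for "
                f"{self.pixels.shape[2]} channels"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (width, height) in micrometres."""
        return (self.width * self.pixel_size, self.height * self.pixel_size)

    @property
    def area_mm2(self) -> float:
        w, h = self.extent_um
        return w * h / 1e6

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D image for a named channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"mosaic has no {role!r} channel") from None
        return self.pixels[:, :, idx]

    def with_pixels(self, pixels: np.ndarray, pixel_size: float | None = None) -> "Mosaic":
        """Copy of this mosaic with new pixel data (and optionally pixel size)."""
        return replace(
            self,
            pixels=pixels,
            pixel_size=self.pixel_size if pixel_size is None else pixel_size,
        )


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from a generator."""
    return int(rng.integers(0, 2**31 - 1))
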