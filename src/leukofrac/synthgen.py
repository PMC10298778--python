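"""Synthetic two-channel (THG, 2PEF) leukocyte mosaic generator.

Emulates the morphology of the four major leukocyte classes as seen in
label-free higher-harmonic-generation microscopy of blood fractions and
bronchoalveolar lavage fluid (BALF): per-class cell diameter distributions,
nuclear lobe counts, and the ordinal THG / 2PEF intensity contrasts
(granulocytes bright in THG, eosinophil cytoplasm bright in 2PEF,
lymphocytes dim in both, macrophages large with varying intensity).
Optional acquisition artifacts reproduce what real stitched mosaics show:
a glass-interface background plane in the THG channel, per-tile intensity
drop toward tile corners, and non-cellular "dirt" objects.

Every mosaic carries exact ground truth: the list of generated cells, a
per-cell label image, and the realized class fractions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .core import (
    CLASS_NAMES,
    DEFAULT_CHANNELS,
    N_CLASSES,
    TARGET_PIXEL_SIZE_UM,
    Mosaic,
    as_fractions,
    fractions_from_counts,
    spawn_seed,
)

logger = logging.getLogger(__name__)

# Qualitative intensity levels mapped onto the [0, 1] dynamic range.
# "high"/"low" preserve the ordinal contrasts reported for the four classes;
# "varying" covers the full high-low span (macrophage cytoplasm can contain
# signal-generating pigments and vesicles or almost none).
INTENSITY_HIGH = 0.7
INTENSITY_LOW = 0.2
NOISE_SD = 0.03
#: Per-cell multiplicative jitter applied to the class intensity level.
GAIN_JITTER = 0.10
#: Nuclei appear dark against the cytoplasm in both channels.
NUCLEUS_ATTENUATION = 0.35

#: Average immune-cell densities (cells per mm^2) per sample type.
SAMPLE_TYPE_DENSITY = {"granulocyte": 4808.0, "PBMC": 6464.0, "BALF": 549.0}

#: Reference differential-count fractions per sample (percent / 100),
#: class order (neutrophil, eosinophil, lymphocyte, macrophage/monocyte).
REFERENCE_FRACTIONS = {
    "GR1": ("granulocyte", (0.945, 0.050, 0.005, 0.000)),
    "GR2": ("granulocyte", (0.940, 0.050, 0.010, 0.000)),
    "GR3": ("granulocyte", (0.883, 0.106, 0.011, 0.000)),
    "GR4": ("granulocyte", (0.692, 0.141, 0.144, 0.023)),
    "PBMC1": ("PBMC", (0.004, 0.000, 0.981, 0.015)),
    "PBMC2": ("PBMC", (0.019, 0.000, 0.946, 0.035)),
    "PBMC3": ("PBMC", (0.029, 0.006, 0.953, 0.012)),
    "BAL1": ("BALF", (0.051, 0.003, 0.353, 0.593)),
    "BAL2": ("BALF", (0.175, 0.042, 0.047, 0.735)),
    "BAL3": ("BALF", (0.927, 0.011, 0.018, 0.044)),
    "BAL4": ("BALF", (0.320, 0.042, 0.064, 0.574)),
    "BAL5": ("BALF", (0.003, 0.001, 0.044, 0.952)),
    "BAL6": ("BALF", (0.030, 0.107, 0.138, 0.725)),
}


@dataclass(frozen=True)
class CellMorphology:
    """Morphological fingerprint of one leukocyte class.

    Diameters in micrometres; ``lobe_range`` is the inclusive interval of
    nuclear lobe counts (mononuclear classes: (1, 1)); intensity levels are
    the qualitative labels "high" / "low" / "varying".
    """

    class_name: str
    diameter_mean: float
    diameter_sd: float
    lobe_range: tuple[int, int]
    shape: str  # "round" or "varying"
    thg_level: str
    mpef_level: str

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be non-negative")
        lo, hi = self.lobe_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("lobe_range must lie within [1, 5]")


def default_morphologies() -> list[CellMorphology]:
    """The measured morphology of the four leukocyte classes.

    Neutrophils and eosinophils are round granulocytes (~9 um) with
    multilobed nuclei and bright THG cytoplasm; eosinophil granules also
    fluoresce strongly in 2PEF. Lymphocytes are small (7.1 um), mononuclear
    and dim in both channels. Macrophages are large (19.6 um), of varying
    shape and intensity.
    """
    return [
        CellMorphology("neutrophil", 8.9, 0.7, (2, 5), "round", "high", "low"),
        CellMorphology("eosinophil", 8.7, 0.6, (2, 3), "round", "high", "high"),
        CellMorphology("lymphocyte", 7.1, 0.8, (1, 1), "round", "low", "low"),
        CellMorphology("macrophage", 19.6, 3.0, (1, 1), "varying", "varying", "varying"),
    ]


@dataclass(frozen=True)
class ArtifactFlags:
    """Which acquisition artifacts to render."""

    glass_background: bool = False
    corner_intensity_drop: bool = False
    dirt_objects: bool = False


@dataclass
class MosaicSpec:
    """Recipe for one synthetic mosaic.

    ``density`` is in cells per mm^2; ``tile_size_px`` is the stitching-grid
    period used for the per-tile corner intensity drop; ``dirt_rate`` in
    objects per mm^2. ``clumping`` relaxes the pairwise non-overlap
    constraint to emulate clumps of touching cells.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size: float = TARGET_PIXEL_SIZE_UM
    fractions: np.ndarray = field(default_factory=lambda: np.full(N_CLASSES, 0.25))
    density: float = SAMPLE_TYPE_DENSITY["BALF"]
    tile_size_px: int = 500
    artifacts: ArtifactFlags = field(default_factory=ArtifactFlags)
    dirt_rate: float = 30.0
    clumping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = as_fractions(self.fractions, atol=1e-9)
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.width_px < 1 or self.height_px < 1 or self.pixel_size <= 0:
            raise ValueError("invalid mosaic geometry")
        if self.tile_size_px < 1:
            raise ValueError("tile_size_px must be positive")

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * self.pixel_size**2 / 1e6


@dataclass
class CellSpec:
    """One synthetic cell with its ground-truth parameters.

    ``center`` is (x, y) in micrometres from the top-left corner; gains are
    the absolute per-channel cytoplasm intensity levels on [0, 1].
    """

    class_name: str
    center: tuple[float, float]
    diameter: float
    n_lobes: int
    orientation: float
    thg_gain: float
    mpef_gain: float


@dataclass
class SyntheticMosaic:
    """A rendered mosaic plus its complete ground truth.

    ``labels`` is an (H, W) int array: 0 = background, i = cell ``cells[i-1]``.
    ``realized_fractions`` is None when no cells were generated.
    """

    image: Mosaic
    cells: list[CellSpec]
    labels: np.ndarray
    realized_fractions: np.ndarray | None
    requested_fractions: np.ndarray
    dirt_mask: np.ndarray | None = None

    def mask(self, index: int) -> np.ndarray:
        """Binary mask of cell ``index`` (0-based into ``cells``)."""
        return self.labels == index + 1

    def cell_union_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def class_counts(self) -> np.ndarray:
        counts = np.zeros(N_CLASSES, dtype=int)
        for c in self.cells:
            counts[CLASS_NAMES.index(c.class_name)] += 1
        return counts


# ---------------------------------------------------------------------------
# Cell sampling
# ---------------------------------------------------------------------------


def _sample_diameter(rng: np.random.Generator, morph: CellMorphology) -> float:
    """Truncated-normal diameter: +-3 SD around the class mean, floored at 0."""
    if morph.diameter_sd == 0:
        return morph.diameter_mean
    lo = max(morph.diameter_mean - 3 * morph.diameter_sd, 1e-6)
    hi = morph.diameter_mean + 3 * morph.diameter_sd
    a = (lo - morph.diameter_mean) / morph.diameter_sd
    b = (hi - morph.diameter_mean) / morph.diameter_sd
    return float(
        truncnorm.rvs(a, b, loc=morph.diameter_mean, scale=morph.diameter_sd,
                      random_state=rng)
    )


def _sample_gain(rng: np.random.Generator, level: str) -> float:
    if level == "high":
        base = INTENSITY_HIGH
    elif level == "low":
        base = INTENSITY_LOW
    elif level == "varying":
        base = rng.uniform(INTENSITY_LOW, INTENSITY_HIGH)
    else:
        raise ValueError(f"unknown intensity level {level!r}")
    return float(np.clip(base * rng.uniform(1 - GAIN_JITTER, 1 + GAIN_JITTER), 0.0, 1.0))


class _PlacementGrid:
    """Uniform spatial hash for non-overlap rejection sampling."""

    def __init__(self, width_um: float, height_um: float, bin_um: float):
        self.bin = bin_um
        self.nx = max(1, int(math.ceil(width_um / bin_um)))
        self.ny = max(1, int(math.ceil(height_um / bin_um)))
        self.bins: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (min(int(x / self.bin), self.nx - 1), min(int(y / self.bin), self.ny - 1))

    def ok(self, x: float, y: float, radius: float, spacing: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for ox, oy, orad in self.bins.get((kx + dx, ky + dy), ()):
                    min_d = spacing * (radius + orad)
                    if (x - ox) ** 2 + (y - oy) ** 2 < min_d**2:
                        return False
        return True

    def add(self, x: float, y: float, radius: float) -> None:
        self.bins.setdefault(self._key(x, y), []).append((x, y, radius))


class PlacementError(RuntimeError):
    """Raised when the requested density cannot be placed without overlap."""


def sample_cells(
    spec: MosaicSpec,
    morphologies: list[CellMorphology] | None = None,
    *,
    max_attempts: int = 6000,
) -> list[CellSpec]:
    """Draw the cell population of one mosaic.

    The number of cells is ``round(density * area)``; each cell's class is
    drawn independently from ``spec.fractions`` (multinomial labelling, so
    realized fractions fluctuate, matching the weak-label setting).
    Diameters follow per-class truncated normals; placement is uniform with
    pairwise non-overlap enforced by rejection sampling (centres at least
    (d_i + d_j)/2 apart, relaxed to 60% with ``clumping``). Cells are
    placed largest-first — placement order does not bias positions or the
    per-cell attribute distributions, but large cells inserted into an
    already crowded field are what makes random sequential placement jam
    at dense blood-fraction packings. Deterministic given ``spec.seed``.
    """
    if morphologies is None:
        morphologies = default_morphologies()
    by_name = {m.class_name: m for m in morphologies}
    missing = [c for c in CLASS_NAMES if c not in by_name]
    if missing:
        raise ValueError(f"missing morphologies for {missing}")

    rng = np.random.default_rng(spec.seed)
    width_um = spec.width_px * spec.pixel_size
    height_um = spec.height_px * spec.pixel_size
    n_cells = int(round(spec.density * spec.area_mm2))
    if n_cells == 0:
        return []

    class_idx = rng.choice(N_CLASSES, size=n_cells, p=spec.fractions)
    spacing = 0.6 if spec.clumping else 1.0
    max_diam = max(m.diameter_mean + 3 * m.diameter_sd for m in morphologies)
    grid = _PlacementGrid(width_um, height_um, bin_um=max_diam)

    # draw all per-cell attributes first, then place largest-first
    attributes = []
    for i in range(n_cells):
        morph = by_name[CLASS_NAMES[class_idx[i]]]
        diameter = _sample_diameter(rng, morph)
        lo, hi = morph.lobe_range
        attributes.append(
            (
                morph.class_name,
                diameter,
                int(rng.integers(lo, hi + 1)),
                float(rng.uniform(0, 2 * math.pi)),
                _sample_gain(rng, morph.thg_level),
                _sample_gain(rng, morph.mpef_level),
            )
        )
    order = sorted(range(n_cells), key=lambda i: -attributes[i][1])

    cells: list[CellSpec] = []
    for rank, i in enumerate(order):
        class_name, diameter, n_lobes, orientation, thg_gain, mpef_gain = attributes[i]
        radius = diameter / 2
        if 2 * radius > min(width_um, height_um):
            raise PlacementError(
                f"cell diameter {diameter:.1f} um exceeds mosaic extent"
            )
        placed = False
        for _ in range(max_attempts):
            x = rng.uniform(radius, width_um - radius)
            y = rng.uniform(radius, height_um - radius)
            if grid.ok(x, y, radius, spacing):
                placed = True
                break
        if not placed:
            achieved = len(cells) / spec.area_mm2
            raise PlacementError(
                f"could not place cell {rank + 1}/{n_cells} without overlap "
                f"after {max_attempts} attempts; achievable density is about "
                f"{achieved:.0f} cells/mm^2 (requested {spec.density:.0f})"
            )
        grid.add(x, y, radius)
        cells.append(
            CellSpec(
                class_name=class_name,
                center=(x, y),
                diameter=diameter,
                n_lobes=n_lobes,
                orientation=orientation,
                thg_gain=thg_gain,
                mpef_gain=mpef_gain,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _cell_boundary_radius(
    morph_shape: str, theta: np.ndarray, base_radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Angular radius profile: circle for round cells, perturbed for varying."""
    if morph_shape != "varying":
        return np.full_like(theta, base_radius)
    r = np.full_like(theta, base_radius)
    for k in range(2, 6):
        amp = rng.uniform(0, 0.15) / (k - 1)
        phase = rng.uniform(0, 2 * math.pi)
        r = r + base_radius * amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.4 * base_radius, 1.5 * base_radius)
    # renormalize so the enclosed area matches the sampled (equivalent-area)
    # diameter: area of r(theta) is mean(r^2) * pi
    r *= base_radius / math.sqrt(float(np.mean(r**2)))
    return r


def _render_cell(
    cell: CellSpec,
    shape_kind: str,
    pixel_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one cell into a local patch.

    Returns (thg_patch, mpef_patch, coverage) where coverage is the
    anti-aliased cell footprint on [0, 1].
    """
    radius_px = cell.diameter / 2 / pixel_size
    pad = int(math.ceil(radius_px * 1.6)) + 2
    size = 2 * pad + 1
    yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1].astype(np.float64)
    rr = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)

    boundary = _cell_boundary_radius(shape_kind, theta, radius_px, rng)
    coverage = np.clip(boundary - rr + 0.5, 0.0, 1.0)  # ~1 px anti-aliased edge

    # Nucleus: low-signal ellipses. Granulocytes get n_lobes overlapping
    # lobes; mononuclear cells one round/kidney-shaped nucleus.
    nucleus = np.zeros((size, size), dtype=np.float64)
    d_px = cell.diameter / pixel_size
    lobe_rng = rng
    for lobe in range(cell.n_lobes):
        if cell.n_lobes == 1:
            ax_a = 0.5 * d_px / 2
            ax_b = 0.40 * d_px / 2
            # kidney-shaped: nucleus centre offset from cell centre
            off = 0.10 * d_px
        else:
            ax_a = lobe_rng.uniform(0.30, 0.45) * d_px / 2
            ax_b = lobe_rng.uniform(0.30, 0.45) * d_px / 2 * 0.7
            off = lobe_rng.uniform(0, 0.25) * d_px
        ang = cell.orientation + lobe * (2 * math.pi / max(cell.n_lobes, 1))
        ang += lobe_rng.uniform(-0.4, 0.4)
        cx = off * math.cos(ang)
        cy = off * math.sin(ang)
        rot = cell.orientation + lobe_rng.uniform(0, math.pi)
        xr = (xx - cx) * math.cos(rot) + (yy - cy) * math.sin(rot)
        yr = -(xx - cx) * math.sin(rot) + (yy - cy) * math.cos(rot)
        ell = (xr / max(ax_a, 0.5)) ** 2 + (yr / max(ax_b, 0.5)) ** 2
        nucleus = np.maximum(nucleus, np.clip(1.5 * (1.0 - ell), 0.0, 1.0))
    nucleus *= coverage

    # Cytoplasm texture: macrophages carry pigment/vesicle speckle.
    texture = np.ones((size, size), dtype=np.float64)
    if shape_kind == "varying":
        speckle = rng.standard_normal((size, size))
        speckle = ndimage.gaussian_filter(speckle, sigma=1.5)
        sd = speckle.std()
        if sd > 0:
            texture = 1.0 + 0.25 * speckle / sd
        texture = np.clip(texture, 0.45, 1.6)

    attenuation = 1.0 - (1.0 - NUCLEUS_ATTENUATION) * nucleus
    thg = cell.thg_gain * coverage * texture * attenuation
    mpef = cell.mpef_gain * coverage * texture * attenuation
    return thg, mpef, coverage


def _tile_corner_drop(height: int, width: int, tile: int, strength: float = 0.35) -> np.ndarray:
    """Multiplicative per-tile vignette: 1 at tile centre, 1-strength at corners."""
    factor = np.ones((height, width), dtype=np.float64)
    for y0 in range(0, height, tile):
        for x0 in range(0, width, tile):
            y1 = min(y0 + tile, height)
            x1 = min(x0 + tile, width)
            th, tw = y1 - y0, x1 - x0
            cy, cx = (th - 1) / 2, (tw - 1) / 2
            yy, xx = np.mgrid[0:th, 0:tw].astype(np.float64)
            r2 = ((yy - cy) / max(cy, 1)) ** 2 + ((xx - cx) / max(cx, 1)) ** 2
            factor[y0:y1, x0:x1] = 1.0 - strength * np.clip(r2 / 2.0, 0.0, 1.0)
    return factor


def _render_dirt(
    height: int, width: int, pixel_size: float, rate: float, area_mm2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Irregular non-cellular objects; returns (thg, mpef, mask)."""
    thg = np.zeros((height, width))
    mpef = np.zeros((height, width))
    mask = np.zeros((height, width), dtype=bool)
    n = rng.poisson(rate * area_mm2)
    for _ in range(n):
        size_um = rng.uniform(2.0, 25.0)
        radius_px = size_um / 2 / pixel_size
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        pad = int(math.ceil(radius_px * 1.8)) + 2
        yy, xx = np.mgrid[-pad : pad + 1, -pad : pad + 1].astype(np.float64)
        theta = np.arctan2(yy, xx)
        boundary = np.full_like(theta, radius_px)
        for k in range(1, 5):
            boundary += radius_px * (rng.uniform(0, 0.5) / k) * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
        blob = np.clip(np.clip(boundary, 0.2 * radius_px, None) - np.hypot(xx, yy) + 0.5, 0, 1)
        y0 = int(round(cy)) - pad
        x0 = int(round(cx)) - pad
        ys = slice(max(y0, 0), min(y0 + blob.shape[0], height))
        xs = slice(max(x0, 0), min(x0 + blob.shape[1], width))
        bys = slice(ys.start - y0, ys.stop - y0)
        bxs = slice(xs.start - x0, xs.stop - x0)
        sub = blob[bys, bxs]
        thg[ys, xs] = np.maximum(thg[ys, xs], rng.uniform(0.1, 0.8) * sub)
        mpef[ys, xs] = np.maximum(mpef[ys, xs], rng.uniform(0.0, 0.5) * sub)
        mask[ys, xs] |= sub > 0.5
    return thg, mpef, mask


def render(spec: MosaicSpec, cells: list[CellSpec] | None = None) -> SyntheticMosaic:
    """Render a mosaic from its spec (sampling cells first if not given).

    Cells are composed onto a dark field by per-pixel maximum; nuclei appear
    as attenuated regions inside the cytoplasm. Artifact layers (glass
    background plane in THG, per-tile corner vignette, dirt objects) are
    applied when flagged, then additive Gaussian sensor noise.
    """
    morphologies = {m.class_name: m for m in default_morphologies()}
    if cells is None:
        cells = sample_cells(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))

    H, W = spec.height_px, spec.width_px
    thg = np.zeros((H, W), dtype=np.float64)
    mpef = np.zeros((H, W), dtype=np.float64)
    labels = np.zeros((H, W), dtype=np.int32)

    for idx, cell in enumerate(cells):
        shape_kind = morphologies[cell.class_name].shape
        cell_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, idx]))
        t_patch, m_patch, coverage = _render_cell(cell, shape_kind, spec.pixel_size, cell_rng)
        pad = (t_patch.shape[0] - 1) // 2
        cx_px = cell.center[0] / spec.pixel_size
        cy_px = cell.center[1] / spec.pixel_size
        y0 = int(round(cy_px)) - pad
        x0 = int(round(cx_px)) - pad
        ys = slice(max(y0, 0), min(y0 + t_patch.shape[0], H))
        xs = slice(max(x0, 0), min(x0 + t_patch.shape[1], W))
        pys = slice(ys.start - y0, ys.stop - y0)
        pxs = slice(xs.start - x0, xs.stop - x0)
        thg[ys, xs] = np.maximum(thg[ys, xs], t_patch[pys, pxs])
        mpef[ys, xs] = np.maximum(mpef[ys, xs], m_patch[pys, pxs])
        solid = coverage[pys, pxs] > 0.5
        labels[ys, xs][solid] = idx + 1

    dirt_mask = None
    if spec.artifacts.dirt_objects:
        d_thg, d_mpef, dirt_mask = _render_dirt(
            H, W, spec.pixel_size, spec.dirt_rate, spec.area_mm2, rng
        )
        thg = np.maximum(thg, d_thg)
        mpef = np.maximum(mpef, d_mpef)

    if spec.artifacts.glass_background:
        # Smooth glass-interface plane, THG channel only: the glass surface
        # generates strong interface THG, well above the sensor noise floor.
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
        plane = 0.15 + 0.03 * np.sin(2 * math.pi * xx / max(W, 1) + rng.uniform(0, 2 * math.pi)) \
            * np.sin(2 * math.pi * yy / max(H, 1) + rng.uniform(0, 2 * math.pi))
        thg = np.maximum(thg, plane)

    if spec.artifacts.corner_intensity_drop:
        vignette = _tile_corner_drop(H, W, spec.tile_size_px)
        thg = thg * vignette
        mpef = mpef * vignette

    thg = np.clip(thg + rng.normal(0.0, NOISE_SD, size=(H, W)), 0.0, 1.0)
    mpef = np.clip(mpef + rng.normal(0.0, NOISE_SD, size=(H, W)), 0.0, 1.0)

    image = Mosaic(
        pixels=np.stack([thg, mpef], axis=-1).astype(np.float32),
        pixel_size=spec.pixel_size,
        channel_roles=DEFAULT_CHANNELS,
    )
    counts = np.zeros(N_CLASSES, dtype=int)
    for c in cells:
        counts[CLASS_NAMES.index(c.class_name)] += 1
    return SyntheticMosaic(
        image=image,
        cells=cells,
        labels=labels,
        realized_fractions=fractions_from_counts(counts),
        requested_fractions=spec.fractions.copy(),
        dirt_mask=dirt_mask,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class CaseConfig:
    """One synthetic case (sample) in a dataset."""

    case_id: str
    sample_type: str  # granulocyte | PBMC | BALF
    split: str  # train | val | test
    n_mosaics: int = 1
    fractions: np.ndarray | None = None  # default: reference row for the type
    density: float | None = None  # default: sample-type density

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPE_DENSITY:
            raise ValueError(f"unknown sample type {self.sample_type!r}")
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"unknown split {self.split!r}")
        if self.fractions is not None:
            self.fractions = as_fractions(self.fractions, atol=1e-4)


@dataclass
class DatasetConfig:
    """Recipe for a full synthetic dataset."""

    cases: list[CaseConfig]
    width_px: int = 512
    height_px: int = 512
    pixel_size: float = TARGET_PIXEL_SIZE_UM
    artifacts: ArtifactFlags = field(default_factory=ArtifactFlags)
    clumping: bool = False
    seed: int = 0


def _default_fractions(sample_type: str) -> np.ndarray:
    first = {"granulocyte": "GR1", "PBMC": "PBMC1", "BALF": "BAL1"}[sample_type]
    return as_fractions(REFERENCE_FRACTIONS[first][1], atol=1e-4)


def balf_like_fractions(
    rng: np.random.Generator, base_index: int | None = None
) -> np.ndarray:
    """Draw a BALF-style composition spanning the observed clinical range.

    A reference BALF row — chosen at random, or ``base_index`` (mod 6) for
    stratified designs — is jittered with a Dirichlet draw concentrated
    around it, so generated cases cover compositions from
    macrophage-dominated to neutrophil-dominated lavages. Cycling
    ``base_index`` guarantees every split of a dataset covers all six
    composition archetypes.
    """
    rows = [f for t, f in REFERENCE_FRACTIONS.values() if t == "BALF"]
    if base_index is None:
        base = np.asarray(rows[rng.integers(len(rows))])
    else:
        base = np.asarray(rows[base_index % len(rows)])
    alpha = base * 40.0 + 0.3
    return as_fractions(rng.dirichlet(alpha), atol=1e-9)


def generate_dataset(config: DatasetConfig, out_dir: str | Path) -> Path:
    """Generate and write a synthetic dataset; returns the manifest path.

    Writes, per mosaic: one 16-bit grayscale TIFF per channel, a composite
    RGB PNG (THG -> green, 2PEF -> blue), and a 16-bit label TIFF of cell
    masks. The manifest CSV stores the *realized* fractions of each mosaic
    (exact ground truth); requested case fractions and the full generator
    config go to a JSON sidecar. Splits are disjoint at case level. Runs
    twice with the same seed produce byte-identical manifests.
    """
    # imported here to keep synthgen import-light for array-only use
    from .io import save_manifest, write_mosaic

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    for split in ("train", "val", "test"):
        types_present = {c.sample_type for c in config.cases if c.split == split}
        for stype in SAMPLE_TYPE_DENSITY:
            if stype not in types_present:
                logger.warning("split %r contains no %s case", split, stype)

    rows: list[dict] = []
    sidecar_cases = []
    for case in config.cases:
        fractions = (
            case.fractions if case.fractions is not None else _default_fractions(case.sample_type)
        )
        density = case.density if case.density is not None else SAMPLE_TYPE_DENSITY[case.sample_type]
        case_seeds = []
        for m in range(case.n_mosaics):
            seed = spawn_seed(rng)
            case_seeds.append(seed)
            spec = MosaicSpec(
                width_px=config.width_px,
                height_px=config.height_px,
                pixel_size=config.pixel_size,
                fractions=fractions,
                density=density,
                artifacts=config.artifacts,
                clumping=config.clumping,
                seed=seed,
            )
            mosaic = render(spec)
            stem = f"{case.case_id}_m{m:02d}"
            write_mosaic(mosaic.image, out_dir / f"{stem}.tiff", composite_png=True)
            _write_labels(mosaic.labels, out_dir / f"{stem}_masks.tiff")
            realized = (
                mosaic.realized_fractions
                if mosaic.realized_fractions is not None
                else fractions
            )
            rows.append(
                {
                    "case_id": case.case_id,
                    "sample_type": case.sample_type,
                    "split": case.split,
                    "mosaic_path": f"{stem}.tiff",
                    "pixel_size_um": config.pixel_size,
                    "f_neut": round(float(realized[0]), 6),
                    "f_eos": round(float(realized[1]), 6),
                    "f_lymph": round(float(realized[2]), 6),
                    "f_mac": round(float(realized[3]), 6),
                }
            )
        sidecar_cases.append(
            {
                "case_id": case.case_id,
                "sample_type": case.sample_type,
                "split": case.split,
                "requested_fractions": [float(x) for x in fractions],
                "density": float(density),
                "mosaic_seeds": case_seeds,
            }
        )

    manifest_path = out_dir / "manifest.csv"
    save_manifest(rows, manifest_path)
    sidecar = {
        "seed": config.seed,
        "width_px": config.width_px,
        "height_px": config.height_px,
        "pixel_size": config.pixel_size,
        "artifacts": dataclasses.asdict(config.artifacts),
        "clumping": config.clumping,
        "class_order": list(CLASS_NAMES),
        "cases": sidecar_cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return manifest_path


def _write_labels(labels: np.ndarray, path: Path) -> None:
    import tifffile

    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many cells for a 16-bit label image")
    tifffile.imwrite(path, labels.astype(np.uint16))
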