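"""Dataset manifests, image readers/writers and config handling.

Manifests are CSV files with one row per mosaic:
``case_id, sample_type, split, mosaic_path, pixel_size_um, f_neut, f_eos,
f_lymph, f_mac`` (optionally ``sd_*`` columns with reference-count SDs).
Fractions are stored on the 0-1 scale; rows given as percentages (summing
to ~100) are auto-detected and converted. All mosaics of one case must
share one split.

Images: multi-channel mosaics are written as one 16-bit grayscale TIFF per
channel plus an optional composite RGB PNG using the acquisition colour
convention (THG shown green, 2PEF blue). 24-bit RGB composites (BMP/PNG)
are read back into channels through the same mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import CHANNEL_2PEF, CHANNEL_3PEF, CHANNEL_THG, DEFAULT_CHANNELS, Mosaic

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "case_id",
    "sample_type",
    "split",
    "mosaic_path",
    "pixel_size_um",
    "f_neut",
    "f_eos",
    "f_lymph",
    "f_mac",
)
FRACTION_COLUMNS = ("f_neut", "f_eos", "f_lymph", "f_mac")
SD_COLUMNS = ("sd_neut", "sd_eos", "sd_lymph", "sd_mac")

#: RGB composite colour convention: THG in green, 2PEF in blue (3PEF, when
#: present, is shown in red; the acquisition software uses purple).
_ROLE_TO_RGB = {CHANNEL_3PEF: 0, CHANNEL_THG: 1, CHANNEL_2PEF: 2}


class ManifestError(ValueError):
    """A dataset manifest violates its contract."""


@dataclass
class DatasetManifest:
    """Validated manifest: a DataFrame plus case-level accessors."""

    table: pd.DataFrame
    path: Path | None = None

    def rows_for_split(self, split: str) -> pd.DataFrame:
        return self.table[self.table["split"] == split]

    def cases_for_split(self, split: str) -> list[str]:
        return sorted(self.rows_for_split(split)["case_id"].unique())

    def fractions(self, row) -> np.ndarray:
        return np.array([row[c] for c in FRACTION_COLUMNS], dtype=np.float64)

    def resolve_path(self, rel: str) -> Path:
        base = self.path.parent if self.path is not None else Path(".")
        return base / rel

    def __len__(self) -> int:
        return len(self.table)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest CSV.

    Percentage-scale rows (summing to ~100) are converted to fractions;
    rows whose fractions miss 1 by more than 0.02 raise; smaller misses
    (reference counts rounded to one decimal) are renormalized with a
    warning. A case spanning two splits is an error.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ManifestError(f"manifest {path} is empty") from None
    if len(table) == 0:
        raise ManifestError(f"manifest {path} contains no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns {missing}")

    frac = table[list(FRACTION_COLUMNS)].to_numpy(dtype=np.float64)
    sums = frac.sum(axis=1)
    percent_rows = np.abs(sums - 100.0) <= 2.0
    if percent_rows.any():
        frac[percent_rows] /= 100.0
        sums = frac.sum(axis=1)
    bad = np.abs(sums - 1.0) > 0.02
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise ManifestError(
            f"row {first} fractions sum to {sums[first]:.3f}, outside 1 +- 0.02"
        )
    off = np.abs(sums - 1.0) > 1e-4
    if off.any():
        warnings.warn(
            f"{int(off.sum())} manifest rows renormalized (fraction sums off 1 "
            "by up to 0.02, consistent with rounded reference counts)",
            stacklevel=2,
        )
    frac /= sums[:, None]
    table = table.copy()
    table[list(FRACTION_COLUMNS)] = frac

    splits_per_case = table.groupby("case_id")["split"].nunique()
    split_violations = splits_per_case[splits_per_case > 1]
    if len(split_violations):
        raise ManifestError(
            f"cases spanning multiple splits: {list(split_violations.index)}"
        )
    if (table["pixel_size_um"] <= 0).any():
        raise ManifestError("pixel_size_um must be positive")
    return DatasetManifest(table=table, path=path)


def save_manifest(rows: list[dict] | pd.DataFrame, path: str | Path) -> Path:
    """Write a manifest CSV (deterministic column order and formatting)."""
    path = Path(path)
    table = pd.DataFrame(rows)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest rows missing columns {missing}")
    ordered = [c for c in REQUIRED_COLUMNS] + [
        c for c in table.columns if c not in REQUIRED_COLUMNS
    ]
    table[ordered].to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def write_mosaic(
    mosaic: Mosaic, path: str | Path, *, composite_png: bool = False
) -> Path:
    """Write a mosaic as a 16-bit multi-channel TIFF (channels-first pages).

    Intensities are assumed in [0, 1] and scaled to the full uint16 range.
    With ``composite_png`` an 8-bit RGB PNG is written alongside using the
    THG->green / 2PEF->blue convention.
    """
    path = Path(path)
    pixels = np.clip(np.asarray(mosaic.pixels, dtype=np.float64), 0.0, 1.0)
    data = np.round(pixels * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        np.moveaxis(data, -1, 0),
        metadata={
            "axes": "CYX",
            "pixel_size_um": mosaic.pixel_size,
            "channel_roles": list(mosaic.channel_roles),
        },
    )
    if composite_png:
        rgb = np.zeros((mosaic.height, mosaic.width, 3), dtype=np.uint8)
        for i, role in enumerate(mosaic.channel_roles):
            if role in _ROLE_TO_RGB:
                rgb[:, :, _ROLE_TO_RGB[role]] = np.round(pixels[:, :, i] * 255).astype(np.uint8)
        iio.imwrite(path.with_suffix(".png"), rgb)
    return path


def read_mosaic(
    path: str | Path,
    pixel_size: float | None = None,
    channel_roles: tuple[str, ...] | None = None,
) -> Mosaic:
    """Read a mosaic from TIFF (multi-channel) or an RGB composite (PNG/BMP).

    ``pixel_size`` (um/px) is required unless the file embeds it (TIFFs
    written by :func:`write_mosaic` do). RGB composites are decomposed via
    the colour convention: green -> THG, blue -> 2PEF. 8-bit and 16-bit
    integer data are rescaled to [0, 1] exactly; round-tripping through
    :func:`write_mosaic` reproduces stored integer values.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    meta_pixel_size = None
    meta_roles = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        meta_pixel_size = meta.get("pixel_size_um")
        roles = meta.get("channel_roles")
        meta_roles = tuple(roles) if roles else None
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"unsupported TIFF shape {arr.shape}")
        channels = np.moveaxis(arr, 0, -1)
        if meta_roles is None:
            meta_roles = DEFAULT_CHANNELS[: channels.shape[-1]]
    elif suffix in (".png", ".bmp", ".jpg", ".jpeg"):
        rgb = iio.imread(path)
        if rgb.ndim == 2:
            channels = rgb[:, :, None]
            meta_roles = (CHANNEL_THG,)
        elif rgb.ndim == 3 and rgb.shape[2] >= 3:
            # composite: green->THG, blue->2PEF (red->3PEF, kept only if nonzero)
            parts = [rgb[:, :, 1], rgb[:, :, 2]]
            roles = [CHANNEL_THG, CHANNEL_2PEF]
            if rgb[:, :, 0].any():
                parts.append(rgb[:, :, 0])
                roles.append(CHANNEL_3PEF)
            channels = np.stack(parts, axis=-1)
            meta_roles = tuple(roles)
        else:
            raise ValueError(f"unsupported image shape {rgb.shape}")
    else:
        raise ValueError(f"unsupported image format {suffix!r}")

    if channels.size == 0:
        raise ValueError(f"{path} contains a zero-size image")
    if channels.dtype == np.uint8:
        pixels = channels.astype(np.float32) / 255.0
    elif channels.dtype == np.uint16:
        pixels = channels.astype(np.float32) / np.iinfo(np.uint16).max
    elif np.issubdtype(channels.dtype, np.floating):
        pixels = channels.astype(np.float32)
    else:
        raise ValueError(f"unsupported bit depth {channels.dtype}")

    final_pixel_size = pixel_size if pixel_size is not None else meta_pixel_size
    if final_pixel_size is None:
        raise ValueError(
            f"{path}: pixel size (um/px) is required and not embedded in the file"
        )
    roles = channel_roles if channel_roles is not None else meta_roles
    return Mosaic(pixels=pixels, pixel_size=float(final_pixel_size), channel_roles=roles)


def read_mosaic_uint16(path: str | Path) -> np.ndarray:
    """Raw uint16 channel stack (C, H, W) of a TIFF, for round-trip checks."""
    return tifffile.imread(Path(path))


def setup_logging(verbose: bool = False, log_file: str | Path | None = None) -> None:
    """Console (+ optional file) logging for the CLI entry points."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
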