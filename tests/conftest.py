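"""Shared fixtures: small synthetic mosaics generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from leukofrac.core import Mosaic
from leukofrac.synthgen import ArtifactFlags, MosaicSpec, render, sample_cells


@pytest.fixture(scope="session")
def mixed_mosaic():
    """~34 cells of all four classes on 512x512 px at 0.5 um/px."""
    spec = MosaicSpec(
        width_px=512,
        height_px=512,
        fractions=(0.25, 0.25, 0.25, 0.25),
        density=520.0,
        seed=42,
    )
    return render(spec)


@pytest.fixture(scope="session")
def artifact_mosaic():
    """Mosaic with glass background, tile vignette and dirt objects."""
    spec = MosaicSpec(
        width_px=512,
        height_px=512,
        fractions=(0.25, 0.25, 0.25, 0.25),
        density=400.0,
        tile_size_px=256,
        artifacts=ArtifactFlags(
            glass_background=True, corner_intensity_drop=True, dirt_objects=True
        ),
        seed=7,
    )
    return render(spec)


@pytest.fixture()
def flat_mosaic():
    """Constant two-channel mosaic."""
    return Mosaic(np.full((128, 128, 2), 0.4, dtype=np.float32), pixel_size=0.5)
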