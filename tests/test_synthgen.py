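"""Synthetic generator: morphology fidelity, sampling statistics, rendering
contrasts, artifacts and dataset writing."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from leukofrac.core import CLASS_NAMES
from leukofrac.synthgen import (
    ArtifactFlags,
    CaseConfig,
    CellMorphology,
    CellSpec,
    DatasetConfig,
    MosaicSpec,
    PlacementError,
    default_morphologies,
    generate_dataset,
    render,
    sample_cells,
)

REFERENCE_MORPHOLOGY = {
    # class -> (mean diameter um, SD um, lobe range)
    "neutrophil": (8.9, 0.7, (2, 5)),
    "eosinophil": (8.7, 0.6, (2, 3)),
    "lymphocyte": (7.1, 0.8, (1, 1)),
    "macrophage": (19.6, 3.0, (1, 1)),
}


class TestDefaultMorphologies:
    def test_reference_values(self):
        morphs = {m.class_name: m for m in default_morphologies()}
        assert set(morphs) == set(CLASS_NAMES)
        for cls, (mean, sd, lobes) in REFERENCE_MORPHOLOGY.items():
            assert morphs[cls].diameter_mean == pytest.approx(mean)
            assert morphs[cls].diameter_sd == pytest.approx(sd)
            assert morphs[cls].lobe_range == lobes
        assert morphs["neutrophil"].thg_level == "high"
        assert morphs["neutrophil"].mpef_level == "low"
        assert morphs["eosinophil"].mpef_level == "high"
        assert morphs["lymphocyte"].thg_level == "low"
        assert morphs["macrophage"].shape == "varying"

    def test_invalid_morphology_rejected(self):
        with pytest.raises(ValueError):
            CellMorphology("x", -1.0, 0.1, (1, 1), "round", "low", "low")
        with pytest.raises(ValueError):
            CellMorphology("x", 5.0, 0.1, (0, 2), "round", "low", "low")


class TestSampleCells:
    def test_expected_count_and_multinomial_classes(self):
        # 1 mm^2 at the BALF density with balanced fractions
        spec = MosaicSpec(
            width_px=2000, height_px=2000, fractions=(0.25,) * 4, density=549, seed=11
        )
        cells = sample_cells(spec)
        assert len(cells) == 549
        counts = np.bincount(
            [CLASS_NAMES.index(c.class_name) for c in cells], minlength=4
        )
        # each class within multinomial spread of ~137
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_class_sampling_matches_fractions_at_large_n(self):
        fractions = (0.5, 0.2, 0.2, 0.1)
        spec = MosaicSpec(
            width_px=2000,
            height_px=2000,
            fractions=fractions,
            density=5_000,
            seed=3,
            clumping=True,
        )
        cells = sample_cells(spec)
        counts = np.bincount(
            [CLASS_NAMES.index(c.class_name) for c in cells], minlength=4
        )
        p = stats.chisquare(counts, f_exp=np.array(fractions) * len(cells)).pvalue
        assert p > 0.001

    def test_diameter_distribution_matches_morphology(self):
        for cls_idx, cls in enumerate(CLASS_NAMES):
            fr = [0.0] * 4
            fr[cls_idx] = 1.0
            spec = MosaicSpec(
                width_px=2400, height_px=2400, fractions=fr, density=160, seed=5
            )
            cells = sample_cells(spec)
            assert len(cells) >= 100
            d = np.array([c.diameter for c in cells])
            mean, sd, _ = REFERENCE_MORPHOLOGY[cls]
            assert abs(d.mean() - mean) < 3 * sd / np.sqrt(len(d))
            assert abs(d.std(ddof=1) - sd) / sd < 0.25

    def test_lobe_counts_stay_in_range(self):
        spec = MosaicSpec(
            width_px=2000, height_px=2000, fractions=(0.25,) * 4, density=500, seed=2
        )
        ranges = {m.class_name: m.lobe_range for m in default_morphologies()}
        for cell in sample_cells(spec):
            lo, hi = ranges[cell.class_name]
            assert lo <= cell.n_lobes <= hi
            if cell.class_name in ("lymphocyte", "macrophage"):
                assert cell.n_lobes == 1

    def test_non_overlap_constraint(self):
        spec = MosaicSpec(
            width_px=1000, height_px=1000, fractions=(0.25,) * 4, density=2000, seed=9
        )
        cells = sample_cells(spec)
        centers = np.array([c.center for c in cells])
        radii = np.array([c.diameter / 2 for c in cells])
        d2 = np.sum((centers[:, None] - centers[None]) ** 2, axis=-1)
        min_d = radii[:, None] + radii[None]
        np.fill_diagonal(d2, np.inf)
        assert np.all(d2 >= (min_d**2) * (1 - 1e-9))

    def test_zero_density_yields_empty_mosaic(self):
        spec = MosaicSpec(width_px=256, height_px=256, density=0.0, seed=0)
        assert sample_cells(spec) == []
        mosaic = render(spec)
        assert mosaic.realized_fractions is None
        assert mosaic.cells == []

    def test_determinism(self):
        spec = MosaicSpec(width_px=512, height_px=512, density=500, seed=123)
        a = sample_cells(spec)
        b = sample_cells(spec)
        assert a == b

    def test_impossible_density_names_achievable_density(self):
        spec = MosaicSpec(width_px=400, height_px=400, density=30_000, seed=0)
        with pytest.raises(PlacementError, match="achievable density"):
            sample_cells(spec, max_attempts=50)


class TestRender:
    def test_cells_fully_inside_and_masks_disjoint(self, mixed_mosaic):
        # label image encodes pairwise-disjoint masks by construction;
        # every cell must own pixels
        n = len(mixed_mosaic.cells)
        present = set(np.unique(mixed_mosaic.labels)) - {0}
        assert present == set(range(1, n + 1))
        for cell in mixed_mosaic.cells:
            x, y = cell.center
            r = cell.diameter / 2
            assert r <= x <= 256 - r and r <= y <= 256 - r

    def test_realized_fractions_from_counts(self, mixed_mosaic):
        counts = mixed_mosaic.class_counts
        np.testing.assert_allclose(
            mixed_mosaic.realized_fractions, counts / counts.sum()
        )

    def _mean_in_mask(self, channel, mosaic, idx):
        return channel[mosaic.mask(idx)].mean()

    def test_eosinophil_brighter_than_neutrophil_in_2pef(self):
        spec = MosaicSpec(width_px=128, height_px=128, density=0.0, seed=4)
        cells = [
            CellSpec("neutrophil", (20.0, 20.0), 8.8, 3, 0.1, 0.7, 0.2),
            CellSpec("eosinophil", (44.0, 44.0), 8.8, 2, 0.1, 0.7, 0.7),
        ]
        sm = render(spec, cells)
        mpef = sm.image.channel("2PEF")
        assert self._mean_in_mask(mpef, sm, 1) > 1.5 * self._mean_in_mask(mpef, sm, 0)

    def test_granulocyte_brighter_than_lymphocyte_in_thg(self, mixed_mosaic):
        thg = mixed_mosaic.image.channel("THG")
        by_class: dict[str, list[float]] = {}
        for i, cell in enumerate(mixed_mosaic.cells):
            by_class.setdefault(cell.class_name, []).append(
                self._mean_in_mask(thg, mixed_mosaic, i)
            )
        gran = np.mean(by_class["neutrophil"] + by_class["eosinophil"])
        assert gran > 1.5 * np.mean(by_class["lymphocyte"])

    def test_corner_intensity_drop(self):
        spec = MosaicSpec(
            width_px=512,
            height_px=512,
            density=0.0,
            tile_size_px=256,
            artifacts=ArtifactFlags(glass_background=True, corner_intensity_drop=True),
            seed=8,
        )
        sm = render(spec)
        thg = sm.image.channel("THG")
        tile = thg[:256, :256]
        h = 256 // 2
        center = tile[h - 64 : h + 64, h - 64 : h + 64]
        corner = tile[:64, :64]
        assert corner.mean() < center.mean()

    def test_glass_background_raises_thg_floor(self):
        base = MosaicSpec(width_px=256, height_px=256, density=0.0, seed=8)
        with_glass = MosaicSpec(
            width_px=256, height_px=256, density=0.0, seed=8,
            artifacts=ArtifactFlags(glass_background=True),
        )
        thg_plain = render(base).image.channel("THG")
        thg_glass = render(with_glass).image.channel("THG")
        assert thg_glass.mean() > thg_plain.mean() + 0.02

    def test_dirt_objects_have_own_mask(self):
        spec = MosaicSpec(
            width_px=512, height_px=512, density=0.0, dirt_rate=120,
            artifacts=ArtifactFlags(dirt_objects=True), seed=21,
        )
        sm = render(spec)
        assert sm.dirt_mask is not None
        assert sm.dirt_mask.any()
        assert not (sm.labels > 0).any()

    def test_render_determinism(self):
        spec = MosaicSpec(width_px=256, height_px=256, density=400, seed=77)
        a = render(spec)
        b = render(spec)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestGenerateDataset:
    def _config(self, seed=0):
        return DatasetConfig(
            cases=[
                CaseConfig("BAL3x", "BALF", "train", n_mosaics=2,
                           fractions=(0.927, 0.011, 0.018, 0.044)),
                CaseConfig("PB1", "PBMC", "val", n_mosaics=1),
                CaseConfig("GR1x", "granulocyte", "test", n_mosaics=1),
            ],
            width_px=384,
            height_px=384,
            seed=seed,
        )

    def test_manifest_stores_case_fractions_and_splits(self, tmp_path):
        from leukofrac.io import load_manifest

        path = generate_dataset(self._config(), tmp_path / "ds")
        manifest = load_manifest(path)
        assert len(manifest) == 4
        bal_rows = manifest.table[manifest.table["case_id"] == "BAL3x"]
        assert len(bal_rows) == 2
        assert set(bal_rows["split"]) == {"train"}
        # realized fractions of a macrophage-poor BAL3-like case stay close
        # to the request (multinomial spread at ~9 cells/mosaic is wide, so
        # only the dominant class is checked)
        assert (bal_rows["f_neut"] > 0.5).all()

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        p1 = generate_dataset(self._config(seed=5), tmp_path / "a")
        p2 = generate_dataset(self._config(seed=5), tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_sample_type_warns_not_raises(self, tmp_path, caplog):
        config = DatasetConfig(
            cases=[CaseConfig("only", "BALF", "train", n_mosaics=1)],
            width_px=128, height_px=128, seed=0,
        )
        with caplog.at_level("WARNING"):
            generate_dataset(config, tmp_path / "ds")
        assert any("contains no" in r.message for r in caplog.records)
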