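import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from opscreen.io import FOVMetadata, SBSImageStack
from opscreen.segment import (
    SegmentParams,
    measure_morphology,
    segment_cells,
    segment_nuclei,
)


def _fov(pixel_size=0.65, size=128):
    return FOVMetadata(fov_id="f", well="A1", stage_x_um=0, stage_y_um=0,
                       pixel_size_um=pixel_size, magnification="10X",
                       height_px=size, width_px=size)


class TestSegmentNuclei:
    def test_blank_image_gives_no_nuclei(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_well_separated_disks_are_recovered(self):
        img = np.full((200, 200), 50.0)
        centers = [(30, 30), (30, 160), (100, 95), (170, 40), (170, 160)]
        for r, c in centers:
            img[draw_disk((r, c), 12)] = 500.0
        labels = segment_nuclei(img)
        assert labels.max() == 5
        from skimage.measure import regionprops

        found = sorted(tuple(np.round(p.centroid).astype(int))
                       for p in regionprops(labels))
        for (fr, fc), (tr, tc) in zip(found, sorted(centers)):
            assert abs(fr - tr) <= 1 and abs(fc - tc) <= 1

    def test_touching_disks_are_split(self):
        img = np.full((100, 120), 50.0)
        img[draw_disk((50, 45), 14)] = 500.0
        img[draw_disk((50, 70), 14)] = 500.0
        labels = segment_nuclei(img, SegmentParams(split_min_distance_px=5))
        assert labels.max() == 2

    def test_pluggable_method_replaces_default(self):
        called = {}

        def fake(img):
            called["yes"] = True
            out = np.zeros(img.shape, dtype=int)
            out[10:20, 10:20] = 1
            return out

        labels = segment_nuclei(np.zeros((32, 32)), method=fake)
        assert called and labels.max() == 1


class TestSegmentCells:
    def _stack_with_cyto(self, cyto_mask, size=128):
        px = np.full((2, 5, size, size), 10.0)
        for cyc in range(2):
            for ch in range(1, 5):
                px[cyc, ch][cyto_mask] = 200.0
        return SBSImageStack(fov=_fov(size=size), pixels=px)

    def test_single_nucleus_grows_into_bright_disk(self):
        nuclei = np.zeros((128, 128), dtype=np.int32)
        nuclei[draw_disk((64, 64), 10)] = 1
        cyto = np.zeros((128, 128), dtype=bool)
        cyto[draw_disk((64, 64), 25)] = True
        cells = segment_cells(nuclei, self._stack_with_cyto(cyto))
        assert set(np.unique(cells)) == {0, 1}
        assert (cells[nuclei == 1] == 1).all()
        assert (cells == 1).sum() > (nuclei == 1).sum()

    def test_two_nuclei_split_connected_region(self):
        nuclei = np.zeros((128, 128), dtype=np.int32)
        nuclei[draw_disk((64, 45), 8)] = 1
        nuclei[draw_disk((64, 85), 8)] = 2
        cyto = np.zeros((128, 128), dtype=bool)
        cyto[50:80, 30:100] = True
        cells = segment_cells(nuclei, self._stack_with_cyto(cyto))
        assert set(np.unique(cells)) == {0, 1, 2}
        # the watershed line separates the two halves around their seeds
        assert cells[64, 40] == 1 and cells[64, 90] == 2

    def test_flat_surface_keeps_cells_equal_to_nuclei(self):
        nuclei = np.zeros((64, 64), dtype=np.int32)
        nuclei[draw_disk((32, 32), 8)] = 1
        stack = SBSImageStack(fov=_fov(size=64),
                              pixels=np.zeros((2, 5, 64, 64)))
        cells = segment_cells(nuclei, stack)
        np.testing.assert_array_equal(cells, nuclei)

    def test_no_nuclei_gives_empty_cells(self):
        stack = SBSImageStack(fov=_fov(size=32),
                              pixels=np.ones((2, 5, 32, 32)))
        assert segment_cells(np.zeros((32, 32), dtype=int), stack).max() == 0

    def test_nucleus_cell_containment_on_simulation(self, noisy_screen):
        stack = noisy_screen.iss_stacks[0]
        nuclei = segment_nuclei(stack.dapi(0))
        cells = segment_cells(nuclei, stack)
        assert nuclei.max() > 0
        m = nuclei > 0
        np.testing.assert_array_equal(cells[m], nuclei[m])
        assert set(np.unique(nuclei)) == set(np.unique(cells))


class TestMorphology:
    def test_disk_area_eccentricity_solidity(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[draw_disk((32, 32), 20)] = 1
        rec = measure_morphology(labels, _fov(0.65, 64)).iloc[0]
        assert rec.area_um2 == pytest.approx(np.pi * 13.0**2, rel=0.02)
        assert rec.eccentricity < 0.1
        assert rec.solidity >= 0.98
        assert rec.perimeter_um == pytest.approx(2 * np.pi * 13.0, rel=0.03)

    def test_two_to_one_ellipse_eccentricity(self):
        labels = np.zeros((128, 128), dtype=np.int32)
        labels[draw_ellipse(64, 64, 40, 20)] = 1
        rec = measure_morphology(labels, _fov(1.0, 128)).iloc[0]
        assert rec.eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_morphology_in_um_is_magnification_invariant(self):
        """The same physical disk measured at 10X and 40X pixel sizes agrees
        in micrometre units - the property cross-magnification matching
        relies on."""
        coarse = np.zeros((80, 80), dtype=np.int32)
        # 6.5 um radius at 0.65 um/px; fractional centers as in real images
        coarse[draw_disk((40.37, 40.21), 10)] = 1
        fine = np.zeros((320, 320), dtype=np.int32)
        fine[draw_disk((160.48, 160.84), 40)] = 1  # same disk at 0.1625 um/px
        a = measure_morphology(coarse, _fov(0.65, 80)).iloc[0]
        b = measure_morphology(fine, _fov(0.1625, 320)).iloc[0]
        assert a.area_um2 == pytest.approx(b.area_um2, rel=0.02)
        assert a.perimeter_um == pytest.approx(b.perimeter_um, rel=0.04)

    def test_tiny_region_flagged_degenerate(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4, 4] = 1
        rec = measure_morphology(labels, _fov()).iloc[0]
        assert rec.degenerate and rec.eccentricity == 0.0

    def test_mean_intensity_per_channel(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[2:6, 2:6] = 1
        img = np.full((16, 16), 7.0)
        rec = measure_morphology(labels, _fov(), {"dapi": img}).iloc[0]
        assert rec.mean_dapi == 7.0
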