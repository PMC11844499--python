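import numpy as np
import pytest

from opscreen.decode import (
    CorrectionMatrix,
    DecodeError,
    assign_reads_to_cells,
    call_bases,
    compute_sd_image,
    consistency_filter,
    correct_intensities,
    decode_stack,
    detect_spots,
    estimate_correction_matrices,
    estimate_correction_matrix,
    extract_intensities,
)
from opscreen.io import FOVMetadata, SBSImageStack
from opscreen.simulate import render_spot

from conftest import match_spots_to_truth


def _fov(size=32):
    return FOVMetadata(fov_id="f", well="A1", stage_x_um=0, stage_y_um=0,
                       pixel_size_um=0.65, magnification="10X",
                       height_px=size, width_px=size)


def _stack(pixels):
    return SBSImageStack(fov=_fov(pixels.shape[-1]), pixels=pixels)


def sd_image_reference(sbs):
    """Independent two-loop implementation of the SD image."""
    n_cyc, n_ch, H, W = sbs.shape
    out = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            acc = 0.0
            for ch in range(n_ch):
                vals = sbs[:, ch, r, c]
                acc += np.sqrt(((vals - vals.mean()) ** 2).mean())
            out[r, c] = acc / n_ch
    return out


class TestSDImage:
    def test_constant_stack_gives_zero(self):
        stack = _stack(np.full((12, 5, 8, 8), 7.0))
        assert (compute_sd_image(stack) == 0).all()

    def test_alternating_pixel_analytic_value(self):
        px = np.zeros((12, 5, 8, 8))
        px[::2, 1, 3, 3] = 1.0  # channel G toggles 0/1, six each
        sd = compute_sd_image(_stack(px))
        assert sd[3, 3] == pytest.approx(0.5 / 4)
        assert sd[0, 0] == 0

    def test_all_channels_alternating_gives_half(self):
        px = np.zeros((12, 5, 8, 8))
        px[::2, 1:, 3, 3] = 1.0
        assert compute_sd_image(_stack(px))[3, 3] == pytest.approx(0.5)

    def test_matches_two_loop_reference_on_random_stacks(self, rng):
        for _ in range(3):
            px = rng.random((6, 5, 16, 16))
            stack = _stack(px)
            np.testing.assert_allclose(
                compute_sd_image(stack), sd_image_reference(stack.sbs()),
                atol=1e-12,
            )

    def test_single_cycle_rejected(self):
        with pytest.raises(DecodeError):
            compute_sd_image(_stack(np.zeros((1, 5, 4, 4))))


class TestDetectSpots:
    def test_flat_image_gives_no_spots(self):
        assert len(detect_spots(np.ones((32, 32)))) == 0

    def test_single_gaussian_bump_found_within_one_pixel(self):
        img = np.zeros((64, 64))
        render_spot(img, (30.4, 41.6), 10.0, 1.5)
        spots = detect_spots(img, threshold_abs=1.0)
        assert len(spots) == 1
        assert abs(spots.iloc[0].row - 30.4) <= 1
        assert abs(spots.iloc[0].col - 41.6) <= 1

    def test_plateau_tie_resolves_to_smallest_row_col(self):
        img = np.zeros((32, 32))
        img[10:12, 10:12] = 5.0
        spots = detect_spots(img, threshold_abs=1.0, min_distance_px=1)
        assert (spots.iloc[0].row, spots.iloc[0].col) == (10, 10)

    def test_default_density_recall_precision(self, noisy_screen):
        """At default density and SNR, detection vs ground truth reaches
        recall and precision >= 0.95 (2 px matching)."""
        tp = fp = fn = 0
        for stack in noisy_screen.iss_stacks:
            from opscreen.register import align_stack

            aligned, _ = align_stack(stack)
            spots = detect_spots(compute_sd_image(aligned))
            truth = noisy_screen.truth.spots[
                noisy_screen.truth.spots.fov_id == stack.fov.fov_id]
            pairs = match_spots_to_truth(spots, truth)
            tp += len(pairs)
            fp += len(spots) - len(pairs)
            fn += len(truth) - len(pairs)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestConsistencyFilter:
    def _spot_stack(self, dropout_cycle=None):
        px = np.full((12, 5, 32, 32), 10.0)
        for cyc in range(12):
            if cyc == dropout_cycle:
                continue
            render_spot(px[cyc, 1], (16, 16), 100.0, 1.5)
        return _stack(px)

    def test_spot_with_signal_every_cycle_is_consistent(self):
        stack = self._spot_stack()
        spots = detect_spots(compute_sd_image(stack), threshold_abs=1.0)
        out = consistency_filter(stack, spots)
        assert out.consistent.all()

    def test_dropout_cycle_breaks_consistency(self):
        stack = self._spot_stack(dropout_cycle=6)
        spots = detect_spots(compute_sd_image(stack), threshold_abs=1.0)
        out = consistency_filter(stack, spots)
        assert not out.consistent.any()

    def test_failed_cycle_excluded_from_denominator(self):
        stack = self._spot_stack(dropout_cycle=6)
        spots = detect_spots(compute_sd_image(stack), threshold_abs=1.0)
        out = consistency_filter(stack, spots, failed_cycles=(6,))
        assert out.consistent.all()

    def test_zero_threshold_degenerates_to_all_consistent(self):
        px = np.zeros((12, 5, 16, 16))
        px[:, 1, 8, 8] = 1.0
        stack = _stack(px)
        spots = detect_spots(compute_sd_image(stack), threshold_abs=0.01)
        out = consistency_filter(stack, spots, k_sigma=0.0)
        assert out.consistent.all()


class TestExtractAndCorrect:
    def test_aperture_zero_reads_center_pixel(self):
        import pandas as pd

        px = np.zeros((2, 5, 16, 16))
        px[:, 1:, 8, 8] = [1, 2, 3, 4]
        spots = pd.DataFrame({"spot_id": [1], "row": [8], "col": [8]})
        raw = extract_intensities(_stack(px), spots, aperture_px=0)
        np.testing.assert_allclose(raw[0, 0], [1, 2, 3, 4])

    def test_identity_matrix_correction_is_noop(self, rng):
        raw = rng.random((5, 3, 4))
        mats = [CorrectionMatrix(c, np.eye(4)) for c in range(3)]
        np.testing.assert_allclose(correct_intensities(raw, mats), raw)

    def test_known_mixing_recovered_and_inverted(self, rng):
        """Spots generated through known crosstalk C: the estimated matrix
        equals C up to column scale and correction restores one-hot."""
        C = np.full((4, 4), 0.2 / 3)
        np.fill_diagonal(C, 0.8)
        bases = rng.integers(0, 4, 200)
        raw = np.zeros((200, 1, 4))
        for i, b in enumerate(bases):
            raw[i, 0] = C[:, b] * 100.0
        cm = estimate_correction_matrix(raw, 0)
        assert not cm.fallback_used
        np.testing.assert_allclose(cm.M, C / C.max(axis=0), atol=1e-9)
        corrected = correct_intensities(raw, [cm])
        for i, b in enumerate(bases):
            assert corrected[i, 0].argmax() == b

    def test_channel_rescaling_leaves_calls_unchanged(self, rng):
        """Correction invariance: positive per-channel rescaling of all raw
        intensities does not change base calls."""
        bases = rng.integers(0, 4, 120)
        raw = np.zeros((120, 2, 4))
        for i, b in enumerate(bases):
            raw[i, :, b] = 100.0
        raw += 10.0
        scale = np.array([1.0, 1.0, 2.0, 0.5])
        scaled = raw * scale
        calls_a = call_bases(
            correct_intensities(raw, estimate_correction_matrices(raw)))
        calls_b = call_bases(
            correct_intensities(scaled, estimate_correction_matrices(scaled)))
        assert (calls_a.barcode == calls_b.barcode).all()

    def test_underpopulated_class_uses_fallback_flag(self, rng):
        raw = np.zeros((50, 1, 4))
        raw[:, 0, 0] = 100.0  # every spot calls G
        cm = estimate_correction_matrix(raw, 0)
        assert cm.fallback_used

    def test_zero_spots_is_an_error(self):
        with pytest.raises(DecodeError):
            estimate_correction_matrix(np.zeros((0, 1, 4)), 0)


class TestCallBases:
    def test_all_cycle_one_hot_g(self):
        corrected = np.zeros((1, 12, 4))
        corrected[0, :, 0] = 5.0
        out = call_bases(corrected)
        assert out.iloc[0].barcode == "G" * 12
        assert out.iloc[0].spot_quality == 1.0

    def test_quality_is_one_minus_second_over_first(self):
        corrected = np.array([[[4.0, 1.0, 0.0, 0.0]]])
        out = call_bases(corrected)
        assert out.iloc[0].barcode == "G"
        assert out.iloc[0].spot_quality == pytest.approx(0.75)

    def test_tie_gives_zero_quality_and_flag(self):
        corrected = np.array([[[3.0, 3.0, 0.0, 0.0]]])
        out = call_bases(corrected)
        assert out.iloc[0].barcode == "G"  # channel-order tiebreak
        assert out.iloc[0].spot_quality == 0.0
        assert bool(out.iloc[0].tie)

    def test_spot_quality_is_min_over_cycles(self):
        corrected = np.zeros((1, 3, 4))
        corrected[0, 0] = [10, 1, 0, 0]
        corrected[0, 1] = [10, 5, 0, 0]
        corrected[0, 2] = [10, 2, 0, 0]
        assert call_bases(corrected).iloc[0].spot_quality == pytest.approx(0.5)


class TestAssignReads:
    def test_labels_taken_at_exact_pixel(self):
        import pandas as pd

        cells = np.zeros((16, 16), dtype=int)
        cells[4:8, 4:8] = 3
        spots = pd.DataFrame({"spot_id": [1, 2, 3],
                              "row": [5, 0, 7], "col": [5, 0, 8]})
        out = assign_reads_to_cells(spots, cells)
        assert out.cell_label.tolist() == [3, 0, 0]


class TestEndToEnd:
    def test_noiseless_consistent_spots_decode_exactly(self, noiseless_screen):
        """Noiseless, jitter-free, identity-crosstalk screens decode every
        consistent spot to its planted 12-nt barcode."""
        sim = noiseless_screen
        n_checked = 0
        for stack in sim.iss_stacks:
            reads = decode_stack(stack)
            truth = sim.truth.spots[sim.truth.spots.fov_id == stack.fov.fov_id]
            pairs = match_spots_to_truth(reads, truth)
            for det_i, gt_i in pairs:
                if reads.iloc[det_i].consistent:
                    assert reads.iloc[det_i].barcode == truth.iloc[gt_i].barcode
                    n_checked += 1
        assert n_checked > 50
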