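"""ISS spot detection, consistency filtering, median-corrected base calling.

Spots are found as local maxima of the cross-cycle standard-deviation (SD)
image: per SBS channel, the population SD of each pixel across all cycles,
averaged over the four channels. A pixel that hosts a sequencing amplicon
flips between channels from cycle to cycle and therefore has high temporal
variance, while constant structures (nuclei, cytoplasm, background) do not.

Base calling is a two-pass median correction: spots are provisionally
classified by raw argmax per cycle; the per-cycle correction matrix M has as
column j the channel-wise median raw vector of the spots provisionally called
base j (columns scaled to unit maximum); corrected vectors are M^-1 · raw.
The call is the argmax of the corrected vector; per-cycle quality is
1 - second/first on the non-negative-clamped corrected intensities, and the
spot quality is the minimum over cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .io import BASES, SBSImageStack

_MAD_TO_SIGMA = 1.4826


class DecodeError(ValueError):
    pass


@dataclass
class CorrectionMatrix:
    cycle: int
    M: np.ndarray
    fallback_used: bool = False


def compute_sd_image(stack: SBSImageStack) -> np.ndarray:
    """Average over the 4 SBS channels of the per-channel cross-cycle SD.

    Population SD (denominator = n_cycles).
    """
    if stack.n_cycles < 2:
        raise DecodeError("SD image requires at least 2 cycles")
    sbs = stack.sbs()  # (cycles, 4, H, W)
    return sbs.std(axis=0, ddof=0).mean(axis=0)


def detect_spots(
    sd_image: np.ndarray,
    min_distance_px: int = 3,
    threshold_abs: float | None = None,
    k_mad: float = 5.0,
) -> pd.DataFrame:
    """Local maxima of the SD image above a threshold.

    Threshold is ``threshold_abs`` if given, else median + k_mad·1.4826·MAD of
    the SD image (a robust background + noise-scale estimate). Plateau ties
    resolve to the smallest (row, col). A flat image yields no spots.
    """
    sd = np.asarray(sd_image, dtype=float)
    if not np.isfinite(sd).all():
        raise DecodeError("SD image must be finite")
    if sd.max() == sd.min():
        return _spot_frame([], sd)
    if threshold_abs is None:
        med = float(np.median(sd))
        mad = float(np.median(np.abs(sd - med)))
        threshold_abs = med + k_mad * _MAD_TO_SIGMA * mad
    peaks = peak_local_max(
        sd, min_distance=min_distance_px, threshold_abs=threshold_abs,
        exclude_border=False,
    )
    order = np.lexsort((peaks[:, 1], peaks[:, 0])) if len(peaks) else []
    return _spot_frame([tuple(peaks[i]) for i in order], sd)


def _spot_frame(positions, sd):
    rows = [
        dict(spot_id=i + 1, row=int(r), col=int(c), sd_score=float(sd[r, c]))
        for i, (r, c) in enumerate(positions)
    ]
    return pd.DataFrame(rows, columns=["spot_id", "row", "col", "sd_score"])


def consistency_filter(
    stack: SBSImageStack,
    spots: pd.DataFrame,
    k_sigma: float = 3.0,
    window_px: int = 2,
    failed_cycles=(),
) -> pd.DataFrame:
    """Flag spots that show signal in every (non-failed) cycle.

    A spot is consistent iff in every non-failed cycle the max over the four
    base channels of its windowed peak intensity exceeds that channel's frame
    background (median) + k_sigma · robust noise scale (1.4826·MAD). Failed
    registration cycles are excluded from the denominator, but any failed
    cycle makes a full-length read impossible, so such spots are dropped
    downstream.
    """
    sbs = stack.sbs()
    n_cycles = sbs.shape[0]
    H, W = sbs.shape[2:]
    med = np.median(sbs, axis=(2, 3))  # (cycles, 4)
    mad = np.median(np.abs(sbs - med[..., None, None]), axis=(2, 3))
    thresh = med + k_sigma * _MAD_TO_SIGMA * mad

    consistent = np.ones(len(spots), dtype=bool)
    for i, sp in enumerate(spots.itertuples(index=False)):
        rlo, rhi = max(sp.row - window_px, 0), min(sp.row + window_px + 1, H)
        clo, chi = max(sp.col - window_px, 0), min(sp.col + window_px + 1, W)
        for c in range(n_cycles):
            if c in failed_cycles:
                continue
            win_max = sbs[c, :, rlo:rhi, clo:chi].max(axis=(1, 2))
            if not (win_max > thresh[c]).any():
                consistent[i] = False
                break
    out = spots.copy()
    out["consistent"] = consistent
    return out


def extract_intensities(
    stack: SBSImageStack,
    spots: pd.DataFrame,
    aperture_px: int = 1,
    stat: str = "mean",
) -> np.ndarray:
    """Per-spot raw intensity tensor, shape (n_spots, n_cycles, 4), order GTAC.

    The statistic ("mean" default, or "max") is taken over a square aperture
    of side 2·aperture_px+1 centred on the spot (clipped at image borders).
    The aperture mean acts as a crude matched filter and is markedly more
    noise-robust than the aperture max.
    """
    sbs = stack.sbs()
    H, W = sbs.shape[2:]
    out = np.zeros((len(spots), sbs.shape[0], 4))
    reduce = {"max": np.max, "mean": np.mean}[stat]
    for i, sp in enumerate(spots.itertuples(index=False)):
        rlo, rhi = max(sp.row - aperture_px, 0), min(sp.row + aperture_px + 1, H)
        clo, chi = max(sp.col - aperture_px, 0), min(sp.col + aperture_px + 1, W)
        out[i] = reduce(sbs[:, :, rlo:rhi, clo:chi], axis=(2, 3))
    return out


def subtract_frame_background(raw: np.ndarray, stack: SBSImageStack) -> np.ndarray:
    """Subtract each (cycle, channel) frame median from the raw tensor.

    Crosstalk is multiplicative on the signal but the camera background is
    additive; removing it first lets the median matrix estimate the mixing
    alone, which sharpens the inversion margins considerably.
    Result clamped at 0.
    """
    sbs = stack.sbs()
    bg = np.median(sbs, axis=(2, 3))  # (cycles, 4)
    return np.clip(raw - bg[None, :, :], 0, None)


def estimate_correction_matrix(
    raw: np.ndarray,
    cycle: int,
    min_spots_per_base: int = 4,
    cond_max: float = 1e4,
) -> CorrectionMatrix:
    """Median correction matrix for one cycle from provisional argmax classes.

    Column j = channel-wise median of raw vectors whose argmax is base j,
    scaled to unit maximum. A base class with too few spots (a barcode set
    need not show every base in every cycle) has its column imputed from the
    well-populated ones: per-channel background = min over populated columns,
    plus the median on-channel amplitude on the diagonal. When fewer than two
    classes are populated, or the matrix is ill-conditioned, the degraded
    mode is a diagonal matrix of per-channel global medians. Either repair
    sets ``fallback_used``.
    """
    if raw.shape[0] == 0:
        raise DecodeError("no spots to estimate correction from")
    vectors = raw[:, cycle, :]  # (spots, 4)
    calls = vectors.argmax(axis=1)
    M = np.zeros((4, 4))
    populated = []
    for j in range(4):
        cls = vectors[calls == j]
        if len(cls) >= min_spots_per_base:
            M[:, j] = np.median(cls, axis=0)
            populated.append(j)
    fallback = len(populated) < 4
    if populated:
        if fallback:
            # impute missing columns: per-channel background from the
            # off-diagonal entries of the populated columns (exact under
            # uniform crosstalk), plus the median on-channel amplitude
            offdiag = [M[ch, j] for j in populated for ch in range(4)
                       if ch != j]
            bg_global = float(np.median(offdiag)) if offdiag else 0.0
            bg = np.empty(4)
            for ch in range(4):
                cands = [M[ch, j] for j in populated if j != ch]
                bg[ch] = min(cands) if cands else bg_global
            on_amp = np.median([M[j, j] - bg[j] for j in populated])
            for j in range(4):
                if j not in populated:
                    M[:, j] = bg
                    M[j, j] = bg[j] + on_amp
        colmax = M.max(axis=0)
        if (colmax > 0).all():
            M = M / colmax
            if np.linalg.cond(M) <= cond_max:
                return CorrectionMatrix(cycle=cycle, M=M,
                                        fallback_used=fallback)
    med = np.median(vectors, axis=0)
    med = np.where(med > 0, med, 1.0)
    return CorrectionMatrix(cycle=cycle, M=np.diag(med / med.max()),
                            fallback_used=True)


def estimate_correction_matrices(raw: np.ndarray, **kw) -> list:
    return [
        estimate_correction_matrix(raw, c, **kw) for c in range(raw.shape[1])
    ]


def correct_intensities(raw: np.ndarray, matrices) -> np.ndarray:
    """Apply per-cycle inverse correction: corrected = M^-1 · raw.

    Values may be negative; callers clamp for quality computation while the
    call itself uses the pre-clamp argmax.
    """
    out = np.empty_like(raw, dtype=float)
    for cm in matrices:
        inv = np.linalg.inv(cm.M)
        out[:, cm.cycle, :] = raw[:, cm.cycle, :] @ inv.T
    return out


def call_bases(corrected: np.ndarray, spot_ids=None) -> pd.DataFrame:
    """Call one base per cycle per spot; derive per-cycle and spot qualities.

    base_c = argmax over channels (tie -> first in G,T,A,C order, tie flag
    set); q_c = 1 - second/first on clamped intensities (0 when first = 0);
    spot_quality = min over cycles of q_c.
    """
    n_spots, n_cycles, _ = corrected.shape
    clamped = np.clip(corrected, 0, None)
    calls = corrected.argmax(axis=2)  # ties -> lowest index = GTAC order
    srt = np.sort(clamped, axis=2)
    first, second = srt[:, :, 3], srt[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(first > 0, 1.0 - second / np.where(first > 0, first, 1.0), 0.0)
    tie = np.isclose(
        np.sort(corrected, axis=2)[:, :, 3], np.sort(corrected, axis=2)[:, :, 2]
    ).any(axis=1)
    if spot_ids is None:
        spot_ids = np.arange(1, n_spots + 1)
    rows = []
    for i in range(n_spots):
        barcode = "".join(BASES[b] for b in calls[i])
        row = dict(spot_id=int(spot_ids[i]), barcode=barcode,
                   spot_quality=float(q[i].min()), tie=bool(tie[i]))
        for c in range(n_cycles):
            row[f"q{c + 1:02d}"] = float(q[i, c])
        rows.append(row)
    cols = ["spot_id", "barcode", "spot_quality", "tie"] + [
        f"q{c + 1:02d}" for c in range(n_cycles)
    ]
    return pd.DataFrame(rows, columns=cols)


def assign_reads_to_cells(spots: pd.DataFrame, cells: np.ndarray) -> pd.DataFrame:
    """cell_label = cell-body label at the spot's pixel (0 = unassigned)."""
    cells = np.asarray(cells)
    out = spots.copy()
    out["cell_label"] = [
        int(cells[sp.row, sp.col]) for sp in spots.itertuples(index=False)
    ]
    return out


def decode_stack(
    stack: SBSImageStack,
    cell_labels: np.ndarray | None = None,
    shifts: pd.DataFrame | None = None,
    min_distance_px: int = 3,
    threshold_abs: float | None = None,
    k_mad: float = 5.0,
    k_sigma: float = 3.0,
    window_px: int = 2,
    aperture_px: int = 1,
    stat: str = "mean",
    use_correction: bool = True,
) -> pd.DataFrame:
    """Full decode of one aligned stack: SD image -> spots -> reads.

    Returns a read table with spot position, SD score, consistency flag,
    barcode, qualities, and (if cell labels are given) owning cell label.
    Spots that fail the consistency filter, or any spot when a registration
    cycle failed, are excluded from base calling but kept in the table with an
    empty barcode.
    """
    failed_cycles = ()
    if shifts is not None and "failed" in shifts:
        failed_cycles = tuple(
            int(c) - 1 for c in shifts.loc[shifts.failed, "cycle"]
        )
    sd = compute_sd_image(stack)
    spots = detect_spots(sd, min_distance_px=min_distance_px,
                         threshold_abs=threshold_abs, k_mad=k_mad)
    spots = consistency_filter(stack, spots, k_sigma=k_sigma,
                               window_px=window_px, failed_cycles=failed_cycles)
    callable_mask = spots["consistent"].to_numpy() & (len(failed_cycles) == 0)
    spots["callable"] = callable_mask
    good = spots[spots["callable"]]
    reads = spots.copy()
    reads["barcode"] = ""
    reads["spot_quality"] = 0.0
    reads["tie"] = False
    if len(good):
        raw = extract_intensities(stack, good, aperture_px=aperture_px, stat=stat)
        raw = subtract_frame_background(raw, stack)
        if use_correction:
            mats = estimate_correction_matrices(raw)
            corrected = correct_intensities(raw, mats)
        else:
            corrected = raw
        called = call_bases(corrected, spot_ids=good["spot_id"].to_numpy())
        reads = reads.set_index("spot_id")
        called = called.set_index("spot_id")
        for col in called.columns:
            reads.loc[called.index, col] = called[col]
        reads = reads.reset_index()
    if cell_labels is not None:
        reads = assign_reads_to_cells(reads, cell_labels)
    reads["fov_id"] = stack.fov.fov_id
    return reads
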