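"""Nuclei and cell-body segmentation plus per-cell morphology.

Nuclei come from the DAPI channel (smoothing + global threshold +
distance-transform watershed split by default; any callable with the same
contract, e.g. a pretrained deep-learning segmenter, can be plugged in). Cell
bodies are grown from the nuclei by a watershed on the per-pixel median of the
four SBS base channels. Morphology is reported in micrometres so that it is
magnification-invariant — the property the cross-magnification matcher
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import BASES, FOVMetadata, SBSImageStack


@dataclass
class SegmentParams:
    smooth_sigma_px: float = 2.0
    threshold: float | None = None  # None -> max(Otsu, noise floor)
    noise_floor_k: float = 10.0  # floor = median + k * 1.4826 * MAD
    min_area_px: int = 40
    split_min_distance_px: int = 7


def segment_nuclei(
    dapi: np.ndarray, params: SegmentParams | None = None, method=None
) -> np.ndarray:
    """Label nuclei in a DAPI image.

    ``method`` may be any callable image -> label image and replaces the
    default classical segmenter entirely (regions below ``min_area_px`` are
    still removed).
    """
    params = params or SegmentParams()
    dapi = np.asarray(dapi, dtype=float)
    if method is not None:
        labels = np.asarray(method(dapi)).astype(np.int32)
    else:
        sm = gaussian(dapi, params.smooth_sigma_px, preserve_range=True)
        if sm.max() == sm.min():
            return np.zeros(dapi.shape, dtype=np.int32)
        if params.threshold is not None:
            thr = params.threshold
        else:
            # Otsu splits pure noise down the middle on empty images; the
            # robust noise floor keeps such tiles empty
            med = float(np.median(sm))
            mad = float(np.median(np.abs(sm - med)))
            thr = max(threshold_otsu(sm),
                      med + params.noise_floor_k * 1.4826 * mad)
        fg = sm > thr
        if not fg.any():
            return np.zeros(dapi.shape, dtype=np.int32)
        # split touching nuclei at distance-transform maxima
        dist = ndi.distance_transform_edt(fg)
        peaks = peak_local_max(
            dist,
            min_distance=params.split_min_distance_px,
            labels=cc_label(fg),
            exclude_border=False,
        )
        markers = np.zeros(dapi.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = watershed(-dist, markers, mask=fg).astype(np.int32)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < params.min_area_px)
    labels = np.where(np.isin(labels, small[small > 0]), 0, labels)
    return _relabel_consecutive(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def cytoplasm_surface(stack: SBSImageStack, cycle: int | None = 0) -> np.ndarray:
    """Per-pixel median over the 4 SBS base channels.

    ``cycle`` selects one cycle (default the first); None takes the median
    over all cycles and channels jointly.
    """
    sbs = stack.sbs()
    if cycle is None:
        return np.median(sbs.reshape(-1, *sbs.shape[2:]), axis=0)
    return np.median(sbs[cycle], axis=0)


def segment_cells(
    nuclei: np.ndarray,
    stack: SBSImageStack,
    cycle: int | None = 0,
    mask_threshold: float | None = None,
) -> np.ndarray:
    """Grow cell bodies from nuclei by watershed on the SBS-median surface.

    Background is masked by a threshold on the surface (Otsu by default);
    nucleus pixels are always foreground, so every cell region is a superset
    of its seed nucleus and keeps its label. Watershed-unreached pixels stay 0.
    """
    nuclei = np.asarray(nuclei)
    if nuclei.shape != stack.pixels.shape[2:]:
        raise ValueError("nuclei labels and stack must share shape")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32)
    surface = cytoplasm_surface(stack, cycle=cycle)
    if surface.max() == surface.min():
        mask = nuclei > 0
    else:
        thr = mask_threshold if mask_threshold is not None else threshold_otsu(surface)
        mask = (surface > thr) | (nuclei > 0)
    cells = watershed(-surface, markers=nuclei.astype(np.int32), mask=mask)
    cells[nuclei > 0] = nuclei[nuclei > 0]
    return cells.astype(np.int32)


def measure_morphology(
    labels: np.ndarray,
    fov: FOVMetadata,
    intensity_images: dict | None = None,
) -> pd.DataFrame:
    """Per-label morphology in µm plus optional per-channel mean intensities.

    area_um2 = pixel count · pixel_size²; perimeter via the Crofton
    4-direction estimator · pixel_size; eccentricity from second central
    moments; solidity = area / convex-hull area. Labels with fewer than 3
    pixels are flagged degenerate and get eccentricity 0.
    """
    px = fov.pixel_size_um
    labels = np.asarray(labels, dtype=np.int32)
    H, W = labels.shape
    rows = []
    for rp in regionprops(labels):
        degenerate = rp.area < 3
        minr, minc, maxr, maxc = rp.bbox
        row = dict(
            label=int(rp.label),
            touches_border=bool(
                minr == 0 or minc == 0 or maxr == H or maxc == W
            ),
            area_um2=float(rp.area) * px**2,
            perimeter_um=float(rp.perimeter_crofton) * px,
            eccentricity=0.0 if degenerate else float(rp.eccentricity),
            solidity=float(rp.solidity),
            centroid_row_px=float(rp.centroid[0]),
            centroid_col_px=float(rp.centroid[1]),
            degenerate=bool(degenerate),
        )
        if intensity_images:
            for name, img in intensity_images.items():
                row[f"mean_{name}"] = float(
                    np.mean(np.asarray(img)[tuple(rp.coords.T)])
                )
        rows.append(row)
    cols = [
        "label", "touches_border", "area_um2", "perimeter_um", "eccentricity",
        "solidity", "centroid_row_px", "centroid_col_px", "degenerate",
    ]
    if intensity_images:
        cols += [f"mean_{n}" for n in intensity_images]
    return pd.DataFrame(rows, columns=cols)
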