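"""Cross-cycle registration by phase correlation of the DAPI channel.

Rigid translation only: the dominant inter-cycle motion on an automated stage
is a small translational shift. Each cycle's shift is estimated from its DAPI
frame against the reference cycle (cycle 1 by default) and applied to every
channel of that cycle. Integer shifts are applied exactly; subpixel shifts are
applied by spectral (Fourier) translation to avoid interpolation smoothing.

Sign convention: ``estimate_shift(reference, moving)`` returns (dy, dx) such
that translating ``moving`` by (dy, dx) superimposes it on ``reference``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .io import SBSImageStack


class RegistrationError(ValueError):
    pass


def estimate_shift(reference: np.ndarray, moving: np.ndarray, upsample: int = 1):
    """Phase-correlation shift estimate.

    Returns (dy, dx, peak) where applying (dy, dx) to ``moving`` aligns it to
    ``reference``. Exact for cyclic integer shifts at upsample=1; subpixel via
    local upsampling for upsample > 1.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise RegistrationError("images must share shape")
    if reference.max() == reference.min() or moving.max() == moving.min():
        raise RegistrationError("no structure to register (constant image)")
    shift, error, _ = phase_cross_correlation(
        reference, moving, upsample_factor=max(1, int(upsample)),
        normalization=None,
    )
    peak = 1.0 - float(error)
    return float(shift[0]), float(shift[1]), peak


def translate(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate with zero fill; integer shifts exact, subpixel spectral."""
    if dy == 0 and dx == 0:
        return np.asarray(image, dtype=float).copy()
    img = np.asarray(image, dtype=float)
    iy, ix = int(round(dy)), int(round(dx))
    if dy == iy and dx == ix:
        out = np.roll(img, (iy, ix), axis=(0, 1))
    else:
        out = np.fft.ifftn(
            ndi.fourier_shift(np.fft.fftn(img), (dy, dx))
        ).real
    _zero_border(out, dy, dx)
    return out


def _zero_border(img: np.ndarray, dy: float, dx: float) -> None:
    iy, ix = int(np.ceil(abs(dy))), int(np.ceil(abs(dx)))
    if dy > 0:
        img[:iy] = 0
    elif dy < 0 and iy:
        img[-iy:] = 0
    if dx > 0:
        img[:, :ix] = 0
    elif dx < 0 and ix:
        img[:, -ix:] = 0


def align_stack(
    stack: SBSImageStack,
    reference_cycle: int = 0,
    upsample: int = 1,
    max_shift: float = 50.0,
):
    """Align every cycle to the reference cycle using DAPI.

    Returns (aligned stack, shift table). A cycle whose estimated |shift|
    exceeds ``max_shift`` is flagged failed and left untranslated; downstream
    the consistency filter excludes failed cycles from its denominator and
    drops the spot from full-length calling.
    """
    n = stack.n_cycles
    ref = stack.dapi(reference_cycle)
    out = stack.pixels.copy()
    rows = []
    for c in range(n):
        if c == reference_cycle:
            dy = dx = 0.0
            peak = 1.0
            failed = False
        else:
            dy, dx, peak = estimate_shift(ref, stack.dapi(c), upsample=upsample)
            failed = max(abs(dy), abs(dx)) > max_shift
            if not failed and (dy or dx):
                for k in range(out.shape[1]):
                    out[c, k] = translate(stack.pixels[c, k], dy, dx)
        rows.append(
            dict(cycle=c + 1, dy_px=dy, dx_px=dx, peak_correlation=peak,
                 failed=failed)
        )
    aligned = SBSImageStack(
        fov=stack.fov, pixels=np.clip(out, 0, None), channels=stack.channels
    )
    shifts = pd.DataFrame(rows, columns=["cycle", "dy_px", "dx_px",
                                         "peak_correlation", "failed"])
    return aligned, shifts
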