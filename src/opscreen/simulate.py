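"""Synthetic optical-pooled-screen generator with full ground truth.

The simulator emulates the data a pooled CRISPR screen read out by in situ
sequencing (ISS) produces: low-magnification 12-cycle sequencing-by-synthesis
(SBS) stacks with DAPI plus four base channels, higher-magnification phenotype
images (nuclear FISH spots or immunofluorescence), per-FOV stage metadata, and
tables of every planted cell, spot, jitter shift and phenotype value so the
downstream pipeline can be verified against known truth.

Forward model, per spot and cycle c (1-based):

* on-channel signal amplitude ``signal_amplitude * decay_per_cycle**(c-1)``
* channel 4-vector = ``crosstalk @ one_hot(base_c) * amplitude``
* per-channel frame background ``background_start + (c-1)*background_growth``
* each cycle's whole frame is cyclically translated by an integer jitter
  (recorded in the ground truth) and i.i.d. Gaussian read noise is added.

Each cell carries exactly one sgRNA (the MOI < 0.1 idealization); an optional
doublet fraction plants two. Spot counts per cell are Poisson with mean
``reads_per_cell_mean``. Per-cell phenotype (integrated nFISH intensity) is
LogNormal(baseline) multiplied by the configured gene effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    BASES,
    Codebook,
    CodebookEntry,
    FOVMetadata,
    PhenotypeImage,
    SBSImageStack,
)

# 14-guide screen: 4 guides each against three ALT-pathway genes plus a
# non-targeting and a safe-targeting control. Barcodes are fixed 12-mers with
# pairwise Hamming distance >= 5.
_DEFAULT_BARCODES = [
    "GAGGAGCACTGC", "TAGTATCGAACT", "GCCTGCCTTGAG", "CAATAGCATGCC",
    "GTTGCACGCTCC", "GTCCGTCTCCTC", "CACACAGGTCTC", "GTGAGCGCGTTC",
    "GGTACAGCCTTT", "ACGGGTTAAATG", "CATGATTAGACA", "GATAGGGCACAT",
    "TAAAGCGTGGGC", "ACCGAGTTCTTG",
]


def default_codebook() -> Codebook:
    """The default 14-sgRNA screen codebook (FANCM/DDX39A/BLM + controls)."""
    entries = []
    i = 0
    for gene in ("FANCM", "DDX39A", "BLM"):
        for k in range(1, 5):
            entries.append(
                CodebookEntry(f"sg{gene}-{k}", _DEFAULT_BARCODES[i], gene, "targeting")
            )
            i += 1
    entries.append(
        CodebookEntry("sgCTL-1", _DEFAULT_BARCODES[i], "none", "non_targeting_control")
    )
    entries.append(
        CodebookEntry("sgSafe-1", _DEFAULT_BARCODES[i + 1], "none", "safe_targeting")
    )
    return Codebook(entries)


def default_crosstalk() -> np.ndarray:
    """Mild spectral mixing: diagonal 0.8, remaining 0.2 spread uniformly."""
    m = np.full((4, 4), 0.2 / 3)
    np.fill_diagonal(m, 0.8)
    return m


# Control cells average 1,144 A.U. integrated nFISH intensity; effects are
# multiplicative on that scale (FANCM-KO-like 2.90, BLM-KO-like 0.80).
_BASELINE_MEAN_AU = 1144.0
_DEFAULT_LOG_SD = 0.8


@dataclass
class SimConfig:
    """All knobs of the synthetic screen. Defaults are the study conditions."""

    seed: int = 0
    n_fovs_iss: int = 1
    fov_size_px: int = 256
    cells_per_fov: float = 30.0
    codebook: Codebook = field(default_factory=default_codebook)
    sgrna_proportions: dict | None = None  # sgrna_id -> weight; None = equimolar
    reads_per_cell_mean: float = 2.5
    n_cycles: int = 12
    signal_amplitude: float = 1000.0
    decay_per_cycle: float = 0.97
    background_start: float = 100.0
    background_growth_per_cycle: float = 3.0
    crosstalk: np.ndarray = field(default_factory=default_crosstalk)
    jitter_px_max: int = 3
    noise_sd: float = 100.0
    psf_sigma_px: float = 1.5
    min_spot_sep_px: float = 4.0
    poisson_noise: bool = False
    dapi_amplitude: float = 600.0
    dapi_background: float = 80.0
    cyto_level: float = 60.0
    doublet_fraction: float = 0.0
    # cell geometry (µm); nucleus size is U2OS-like
    nucleus_radius_um: float = 6.0
    nucleus_axis_jitter: float = 0.15
    cyto_scale: float = 1.8
    # magnifications / pixel sizes (µm per pixel; configuration, not claims)
    pixel_sizes_um: dict = field(
        default_factory=lambda: {"10X": 0.65, "20X": 0.325, "40X": 0.1625}
    )
    iss_magnification: str = "10X"
    pheno_magnification: str = "40X"
    pheno_fov_size_px: int = 256
    pheno_fov_overlap_um: float = 14.0
    render_phenotype: bool = True
    # phenotype model
    phenotype_effects: dict = field(
        default_factory=lambda: {"FANCM": 2.90, "BLM": 0.80}
    )
    phenotype_baseline_log_mean: float = (
        math.log(_BASELINE_MEAN_AU) - _DEFAULT_LOG_SD**2 / 2
    )
    phenotype_log_sd: float = _DEFAULT_LOG_SD
    nfish_spots_per_cell_mean: float = 6.0
    nfish_psf_sigma_px: float = 1.5
    nfish_min_sep_px: float = 7.0
    nfish_background: float = 50.0
    nfish_noise_sd: float = 2.0
    pheno_offset_um: tuple = (0.0, 0.0)  # planted systematic stage-metadata error

    def __post_init__(self):
        if not (0 < self.decay_per_cycle <= 1):
            raise ValueError("decay_per_cycle must be in (0, 1]")
        ct = np.asarray(self.crosstalk, dtype=float)
        if ct.shape != (4, 4):
            raise ValueError("crosstalk must be 4x4")
        if any(v <= 0 for v in self.phenotype_effects.values()):
            raise ValueError("phenotype effects must be > 0")
        self.crosstalk = ct

    def noiseless(self) -> "SimConfig":
        """A copy with noise, jitter and crosstalk switched off."""
        return replace(
            self,
            noise_sd=0.0,
            jitter_px_max=0,
            crosstalk=np.eye(4),
            nfish_noise_sd=0.0,
        )


@dataclass
class GroundTruth:
    """Planted truth: one row per cell, per spot, and per (fov, cycle) shift."""

    cells: pd.DataFrame
    spots: pd.DataFrame
    shifts: pd.DataFrame


@dataclass
class SimResult:
    iss_stacks: list
    pheno_images: list
    truth: GroundTruth
    config: SimConfig


def render_spot(image: np.ndarray, pos, amplitude: float, sigma: float) -> np.ndarray:
    """Add an isotropic Gaussian spot in place; returns the image.

    Total added intensity is amplitude * 2*pi*sigma**2 (to within 1% for
    sigma >= 1 px away from borders). ``pos`` is (row, col), may be fractional.
    """
    if amplitude == 0:
        return image
    r0, c0 = pos
    rad = max(1, int(math.ceil(4.5 * sigma)))
    rlo, rhi = int(math.floor(r0)) - rad, int(math.floor(r0)) + rad + 1
    clo, chi = int(math.floor(c0)) - rad, int(math.floor(c0)) + rad + 1
    rlo_c, rhi_c = max(rlo, 0), min(rhi, image.shape[0])
    clo_c, chi_c = max(clo, 0), min(chi, image.shape[1])
    if rlo_c >= rhi_c or clo_c >= chi_c:
        return image
    rr = np.arange(rlo_c, rhi_c)[:, None] - r0
    cc = np.arange(clo_c, chi_c)[None, :] - c0
    image[rlo_c:rhi_c, clo_c:chi_c] += amplitude * np.exp(
        -(rr**2 + cc**2) / (2 * sigma**2)
    )
    return image


def _ellipse_mask(shape, center, a_px, b_px, theta) -> np.ndarray:
    """Boolean mask of a rotated filled ellipse (semi-axes in pixels)."""
    r0, c0 = center
    rad = int(math.ceil(max(a_px, b_px))) + 1
    rlo, rhi = max(int(r0) - rad, 0), min(int(r0) + rad + 1, shape[0])
    clo, chi = max(int(c0) - rad, 0), min(int(c0) + rad + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if rlo >= rhi or clo >= chi:
        return mask
    rr = np.arange(rlo, rhi)[:, None] - r0
    cc = np.arange(clo, chi)[None, :] - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = rr * ct + cc * st
    v = -rr * st + cc * ct
    mask[rlo:rhi, clo:chi] = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return mask


def _ellipse_perimeter_um(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def _sample_positions_in_ellipse(rng, n, a_px, b_px, theta, min_sep):
    """Rejection-sample n points inside the ellipse with pairwise min_sep."""
    pts = []
    ct, st = math.cos(theta), math.sin(theta)
    for _ in range(400 * max(n, 1)):
        if len(pts) == n:
            break
        u = rng.uniform(-1, 1) * a_px
        v = rng.uniform(-1, 1) * b_px
        if (u / a_px) ** 2 + (v / b_px) ** 2 > 1:
            continue
        dr, dc = u * ct - v * st, u * st + v * ct
        if all((dr - p[0]) ** 2 + (dc - p[1]) ** 2 >= min_sep**2 for p in pts):
            pts.append((dr, dc))
    return pts


def _pick_sgrnas(rng, cfg: SimConfig, n: int):
    ids = [e.sgrna_id for e in cfg.codebook]
    if cfg.sgrna_proportions:
        w = np.array([cfg.sgrna_proportions.get(i, 0.0) for i in ids], dtype=float)
        w = w / w.sum()
    else:
        w = np.full(len(ids), 1.0 / len(ids))
    return rng.choice(ids, size=n, p=w)


def simulate_screen(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic screen with ground truth.

    Deterministic for a given config (all randomness flows from cfg.seed).
    """
    rng = np.random.default_rng(cfg.seed)
    px_iss = cfg.pixel_sizes_um[cfg.iss_magnification]
    H = W = cfg.fov_size_px
    fov_extent_um = W * px_iss

    # cell slot grid: non-overlapping cytoplasm footprints
    max_ax_um = cfg.nucleus_radius_um * (1 + cfg.nucleus_axis_jitter) * cfg.cyto_scale
    pitch = int(math.ceil(2 * max_ax_um / px_iss)) + 4
    n_slots_side = max(1, H // pitch)
    slot_centers = [
        ((i + 0.5) * pitch, (j + 0.5) * pitch)
        for i in range(n_slots_side)
        for j in range(n_slots_side)
        if (i + 0.5) * pitch < H - pitch / 2 + 1 and (j + 0.5) * pitch < W - pitch / 2 + 1
    ]

    # world layout: ISS FOVs in a row-major square-ish grid, centers spaced by
    # the FOV extent (no overlap); first FOV centered at the origin.
    ncols = int(math.ceil(math.sqrt(cfg.n_fovs_iss)))
    cell_rows, spot_rows, shift_rows = [], [], []
    iss_stacks = []
    cell_id = 0
    spot_id = 0
    barcode_of = {e.sgrna_id: e.barcode for e in cfg.codebook}
    gene_of = {e.sgrna_id: e.gene for e in cfg.codebook}

    for f in range(cfg.n_fovs_iss):
        gi, gj = divmod(f, ncols)
        stage_x = gj * fov_extent_um
        stage_y = gi * fov_extent_um
        fov = FOVMetadata(
            fov_id=f"iss-{f:03d}",
            well="A1",
            stage_x_um=stage_x,
            stage_y_um=stage_y,
            pixel_size_um=px_iss,
            magnification=cfg.iss_magnification,
            height_px=H,
            width_px=W,
        )

        n_cells = min(rng.poisson(cfg.cells_per_fov), len(slot_centers))
        chosen = rng.choice(len(slot_centers), size=n_cells, replace=False)
        sgrnas = _pick_sgrnas(rng, cfg, n_cells)

        dapi = np.full((H, W), cfg.dapi_background)
        cyto_mask = np.zeros((H, W), dtype=bool)
        fov_cells = []
        for s_idx, sg in zip(chosen, sgrnas):
            cell_id += 1
            base_r, base_c = slot_centers[s_idx]
            jit = pitch / 2 - max_ax_um / px_iss - 1
            r0 = base_r + rng.uniform(-max(jit, 0), max(jit, 0))
            c0 = base_c + rng.uniform(-max(jit, 0), max(jit, 0))
            ax_jit = rng.uniform(0, cfg.nucleus_axis_jitter)
            a_um = cfg.nucleus_radius_um * (1 + ax_jit)
            b_um = cfg.nucleus_radius_um / (1 + ax_jit)
            theta = rng.uniform(0, math.pi)
            nuc = _ellipse_mask((H, W), (r0, c0), a_um / px_iss, b_um / px_iss, theta)
            cyt = _ellipse_mask(
                (H, W),
                (r0, c0),
                a_um * cfg.cyto_scale / px_iss,
                b_um * cfg.cyto_scale / px_iss,
                theta,
            )
            dapi[nuc] = cfg.dapi_amplitude
            cyto_mask |= cyt

            is_doublet = rng.uniform() < cfg.doublet_fraction
            sg2 = ""
            if is_doublet:
                others = [i for i in barcode_of if i != sg]
                sg2 = rng.choice(others)

            n_spots = rng.poisson(cfg.reads_per_cell_mean)
            positions = _sample_positions_in_ellipse(
                rng,
                n_spots,
                0.92 * a_um * cfg.cyto_scale / px_iss,
                0.92 * b_um * cfg.cyto_scale / px_iss,
                theta,
                cfg.min_spot_sep_px,
            )
            cell_spots = []
            for dr, dc in positions:
                spot_id += 1
                src = sg if (not is_doublet or rng.uniform() < 0.5) else sg2
                cell_spots.append(
                    dict(
                        spot_id=spot_id,
                        cell_id=cell_id,
                        fov_id=fov.fov_id,
                        row_px=r0 + dr,
                        col_px=c0 + dc,
                        barcode=barcode_of[src],
                        sgrna_id=src,
                    )
                )
            spot_rows.extend(cell_spots)

            gx = stage_x + (c0 - (W - 1) / 2) * px_iss
            gy = stage_y + (r0 - (H - 1) / 2) * px_iss
            gene = gene_of[sg]
            eff = cfg.phenotype_effects.get(gene, 1.0)
            nfish_true = eff * float(
                rng.lognormal(cfg.phenotype_baseline_log_mean, cfg.phenotype_log_sd)
            )
            ecc = math.sqrt(1 - (b_um / a_um) ** 2)
            cell_rows.append(
                dict(
                    cell_id=cell_id,
                    fov_id=fov.fov_id,
                    row_px=r0,
                    col_px=c0,
                    global_x_um=gx,
                    global_y_um=gy,
                    sgrna_id=sg,
                    gene=gene,
                    barcode=barcode_of[sg],
                    second_sgrna_id=sg2,
                    is_doublet=is_doublet,
                    n_spots=len(cell_spots),
                    nfish_true=nfish_true,
                    nuc_a_um=a_um,
                    nuc_b_um=b_um,
                    theta=theta,
                    area_um2=math.pi * a_um * b_um,
                    perimeter_um=_ellipse_perimeter_um(a_um, b_um),
                    eccentricity=ecc,
                    solidity=1.0,
                )
            )
            fov_cells.append(cell_rows[-1])

        # render the 12-cycle stack
        base_order = {b: i for i, b in enumerate(BASES)}
        pixels = np.zeros((cfg.n_cycles, 5, H, W))
        fov_spots = [s for s in spot_rows if s["fov_id"] == fov.fov_id]
        for c in range(cfg.n_cycles):
            amp = cfg.signal_amplitude * cfg.decay_per_cycle**c
            bg = cfg.background_start + c * cfg.background_growth_per_cycle
            frame = np.full((4, H, W), bg)
            frame[:, cyto_mask] += cfg.cyto_level
            for s in fov_spots:
                weights = cfg.crosstalk[:, base_order[s["barcode"][c]]] * amp
                for k in range(4):
                    render_spot(
                        frame[k],
                        (s["row_px"], s["col_px"]),
                        weights[k],
                        cfg.psf_sigma_px,
                    )
            pixels[c, 0] = dapi
            pixels[c, 1:] = frame

            if cfg.jitter_px_max > 0 and c > 0:
                jy = int(rng.integers(-cfg.jitter_px_max, cfg.jitter_px_max + 1))
                jx = int(rng.integers(-cfg.jitter_px_max, cfg.jitter_px_max + 1))
            else:
                jy = jx = 0
            if jy or jx:
                pixels[c] = np.roll(pixels[c], (jy, jx), axis=(1, 2))
            shift_rows.append(
                dict(fov_id=fov.fov_id, cycle=c + 1, dy_px=jy, dx_px=jx)
            )
        if cfg.poisson_noise:
            pixels = rng.poisson(np.clip(pixels, 0, None)).astype(float)
        if cfg.noise_sd > 0:
            pixels = pixels + rng.normal(0, cfg.noise_sd, size=pixels.shape)
        pixels = np.clip(pixels, 0, None)
        iss_stacks.append(SBSImageStack(fov=fov, pixels=pixels))

    cells_df = pd.DataFrame(
        cell_rows,
        columns=[
            "cell_id", "fov_id", "row_px", "col_px", "global_x_um", "global_y_um",
            "sgrna_id", "gene", "barcode", "second_sgrna_id", "is_doublet",
            "n_spots", "nfish_true", "nuc_a_um", "nuc_b_um", "theta",
            "area_um2", "perimeter_um", "eccentricity", "solidity",
        ],
    )
    spots_df = pd.DataFrame(
        spot_rows,
        columns=["spot_id", "cell_id", "fov_id", "row_px", "col_px", "barcode",
                 "sgrna_id"],
    )
    shifts_df = pd.DataFrame(shift_rows, columns=["fov_id", "cycle", "dy_px", "dx_px"])

    pheno_images = []
    if cfg.render_phenotype:
        pheno_images = _render_phenotype_images(rng, cfg, cells_df)

    truth = GroundTruth(cells=cells_df, spots=spots_df, shifts=shifts_df)
    return SimResult(
        iss_stacks=iss_stacks, pheno_images=pheno_images, truth=truth, config=cfg
    )


def _render_phenotype_images(rng, cfg: SimConfig, cells_df: pd.DataFrame):
    """Re-render the same cells at the phenotype magnification.

    Phenotype FOVs tile the ISS world; their *recorded* stage coordinates carry
    the planted systematic offset ``pheno_offset_um`` (recorded = true - offset)
    so the matcher must recover it.
    """
    px = cfg.pixel_sizes_um[cfg.pheno_magnification]
    P = cfg.pheno_fov_size_px
    extent = P * px
    px_iss = cfg.pixel_sizes_um[cfg.iss_magnification]
    iss_extent = cfg.fov_size_px * px_iss
    ncols = int(math.ceil(math.sqrt(cfg.n_fovs_iss)))
    nrows = int(math.ceil(cfg.n_fovs_iss / ncols))
    # world bounding box (true coordinates)
    x_lo, y_lo = -iss_extent / 2, -iss_extent / 2
    x_hi = (ncols - 0.5) * iss_extent
    y_hi = (nrows - 0.5) * iss_extent
    step = max(extent - cfg.pheno_fov_overlap_um, extent / 2)
    kx = int(math.ceil((x_hi - x_lo - extent) / step)) + 1
    ky = int(math.ceil((y_hi - y_lo - extent) / step)) + 1
    off_x, off_y = cfg.pheno_offset_um

    images = []
    idx = 0
    for i in range(ky):
        for j in range(kx):
            cx = x_lo + extent / 2 + j * step
            cy = y_lo + extent / 2 + i * step
            sub = cells_df[
                (cells_df.global_x_um >= cx - extent / 2 - 15)
                & (cells_df.global_x_um < cx + extent / 2 + 15)
                & (cells_df.global_y_um >= cy - extent / 2 - 15)
                & (cells_df.global_y_um < cy + extent / 2 + 15)
            ]
            if sub.empty:
                continue
            fov = FOVMetadata(
                fov_id=f"ph-{idx:04d}",
                well="A1",
                stage_x_um=cx - off_x,
                stage_y_um=cy - off_y,
                pixel_size_um=px,
                magnification=cfg.pheno_magnification,
                height_px=P,
                width_px=P,
            )
            idx += 1
            dapi = np.full((P, P), cfg.dapi_background)
            sig = np.full((P, P), cfg.nfish_background)
            for cell in sub.itertuples(index=False):
                r0 = (cell.global_y_um - cy) / px + (P - 1) / 2
                c0 = (cell.global_x_um - cx) / px + (P - 1) / 2
                nuc = _ellipse_mask(
                    (P, P), (r0, c0), cell.nuc_a_um / px, cell.nuc_b_um / px,
                    cell.theta,
                )
                dapi[nuc] = cfg.dapi_amplitude
                n_sp = max(1, rng.poisson(cfg.nfish_spots_per_cell_mean))
                parts = rng.dirichlet(np.full(n_sp, 2.0)) * cell.nfish_true
                pts = _sample_positions_in_ellipse(
                    rng, n_sp,
                    0.75 * cell.nuc_a_um / px, 0.75 * cell.nuc_b_um / px,
                    cell.theta, cfg.nfish_min_sep_px,
                )
                parts = parts[: len(pts)]
                if len(pts) < n_sp and parts.sum() > 0:
                    parts = parts * cell.nfish_true / parts.sum()
                for (dr, dc), t in zip(pts, parts):
                    amp = t / (2 * math.pi * cfg.nfish_psf_sigma_px**2)
                    render_spot(sig, (r0 + dr, c0 + dc), amp, cfg.nfish_psf_sigma_px)
            if cfg.nfish_noise_sd > 0:
                dapi = dapi + rng.normal(0, cfg.nfish_noise_sd, dapi.shape)
                sig = sig + rng.normal(0, cfg.nfish_noise_sd, sig.shape)
            images.append(
                PhenotypeImage(fov=fov, dapi=np.clip(dapi, 0, None),
                               signal=np.clip(sig, 0, None))
            )
    return images


def simulate_match_world(
    n_cells: int = 400,
    offset_um=(8.0, -5.0),
    centroid_noise_um: float = 1.0,
    morph_rel_noise: float = 0.01,
    region_um: float = 600.0,
    min_sep_um: float = 12.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
):
    """Table-level two-magnification world for the cross-magnification matcher.

    Returns (iss_cells, pheno_cells, pairs): two GlobalCell tables whose
    phenotype coordinates carry the planted systematic metadata offset
    (pheno_observed = truth - offset), each with independent centroid noise and
    relative morphology noise, plus the true pairing. A fraction of phenotype
    cells can be turned into spatial outliers to exercise median robustness.
    """
    rng = np.random.default_rng(seed)
    # adherent cells cannot overlap: dart-throwing with a separation floor
    xs, ys = [], []
    for _ in range(500 * n_cells):
        if len(xs) == n_cells:
            break
        cx, cy = rng.uniform(0, region_um, 2)
        if all((cx - a) ** 2 + (cy - b) ** 2 >= min_sep_um**2
               for a, b in zip(xs, ys)):
            xs.append(cx)
            ys.append(cy)
    if len(xs) < n_cells:
        raise ValueError("region too small for n_cells at min_sep_um")
    x, y = np.array(xs), np.array(ys)
    r = rng.uniform(3.5, 6.0, n_cells)
    ax_jit = rng.uniform(0, 0.2, n_cells)
    a, b = r * (1 + ax_jit), r / (1 + ax_jit)
    area = np.pi * a * b
    perim = np.array([_ellipse_perimeter_um(ai, bi) for ai, bi in zip(a, b)])
    ecc = np.sqrt(1 - (b / a) ** 2)
    sol = np.full(n_cells, 0.98)

    def noisy(base_x, base_y, shift):
        return (
            base_x + shift[0] + rng.normal(0, centroid_noise_um, n_cells),
            base_y + shift[1] + rng.normal(0, centroid_noise_um, n_cells),
        )

    ix, iy = noisy(x, y, (0, 0))
    px_, py = noisy(x, y, (-offset_um[0], -offset_um[1]))
    n_out = int(round(outlier_fraction * n_cells))
    if n_out:
        which = rng.choice(n_cells, n_out, replace=False)
        px_[which] += rng.uniform(-25, 25, n_out)
        py[which] += rng.uniform(-25, 25, n_out)

    def morph_noise():
        return 1 + rng.normal(0, morph_rel_noise, n_cells)

    iss = pd.DataFrame(
        dict(
            dataset="iss", fov_id="iss-000", cell_label=np.arange(1, n_cells + 1),
            global_x_um=ix, global_y_um=iy,
            area_um2=area * morph_noise(), perimeter_um=perim * morph_noise(),
            eccentricity=np.clip(ecc * morph_noise(), 0, 0.999),
            solidity=np.clip(sol * morph_noise(), 0, 1),
        )
    )
    perm = rng.permutation(n_cells)
    pheno = pd.DataFrame(
        dict(
            dataset="phenotype", fov_id="ph-0000",
            cell_label=np.arange(1, n_cells + 1),
            global_x_um=px_[perm], global_y_um=py[perm],
            area_um2=(area * morph_noise())[perm],
            perimeter_um=(perim * morph_noise())[perm],
            eccentricity=np.clip((ecc * morph_noise())[perm], 0, 0.999),
            solidity=np.clip((sol * morph_noise())[perm], 0, 1),
        )
    )
    pairs = pd.DataFrame(
        dict(
            iss_label=np.arange(1, n_cells + 1)[perm],
            pheno_label=np.arange(1, n_cells + 1),
        )
    )
    return iss, pheno, pairs


def simulate_phenotype_table(
    n_per_sgrna: int,
    codebook: Codebook | None = None,
    effects: dict | None = None,
    baseline_log_mean: float | None = None,
    log_sd: float = _DEFAULT_LOG_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell phenotype values for a screen, bypassing image rendering.

    One row per cell with columns sgrna_id, gene, role, value: value is
    LogNormal(baseline_log_mean, log_sd) times the gene's multiplicative
    effect. Used for desk-scale statistical power / calibration runs.
    """
    cb = codebook or default_codebook()
    eff = effects if effects is not None else {"FANCM": 2.90, "BLM": 0.80}
    mu = (
        baseline_log_mean
        if baseline_log_mean is not None
        else math.log(_BASELINE_MEAN_AU) - log_sd**2 / 2
    )
    rng = np.random.default_rng(seed)
    rows = []
    for e in cb:
        vals = rng.lognormal(mu, log_sd, n_per_sgrna) * eff.get(e.gene, 1.0)
        for v in vals:
            rows.append((e.sgrna_id, e.gene, e.role, float(v)))
    return pd.DataFrame(rows, columns=["sgrna_id", "gene", "role", "value"])
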