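# Methods

## The measurement model

One field of view (FOV) of an in situ sequencing (ISS) acquisition is a
stack indexed (cycle, channel, row, col) with channels (DAPI, G, T, A, C) and
12 cycles by default. The simulator's forward model, which is also the model
the decoder assumes, is:

* Each cell carries exactly one sgRNA (the MOI < 0.1 idealization; a
  configurable doublet fraction plants a second one to exercise the
  dominant-barcode logic). Spot (amplicon) counts per cell are
  Poisson(`reads_per_cell_mean`, default 2.5).
* At cycle c (1-based) a spot whose barcode has base b contributes to the
  four base channels the vector `crosstalk @ one_hot(b) * A_c` with
  `A_c = signal_amplitude · decay_per_cycle^(c−1)`, rendered as an isotropic
  Gaussian of `psf_sigma_px`. Spectral crosstalk defaults to diagonal 0.8
  with the remaining 0.2 spread uniformly.
* Per-channel frame background is `background_start + (c−1)·growth`
  (chemistry background accumulates over cycles) and i.i.d. Gaussian read
  noise of `noise_sd` is added everywhere. Whole frames are cyclically
  translated per cycle by an integer stage jitter, recorded in the ground
  truth.
* The per-cell phenotype (integrated nFISH intensity) is
  LogNormal(µ, σ=0.8) · effect(gene), with µ chosen so control cells average
  1,144 A.U.; default effects are 2.90 for FANCM-like and 0.80 for BLM-like
  perturbations, i.e. the regime where one perturbation triples the signal
  and another produces only a ~20% decrease that needs cell numbers to
  detect. Each cell's total is split over discrete nuclear spots and
  re-rendered at the phenotype magnification (40X) with FOV stage metadata
  that can carry a planted systematic offset.

## What the simulator does and does not emulate

Emulated: cyclic channel switching, signal decay and background growth,
uniform spectral crosstalk, stage jitter, Gaussian read noise (optional
Poisson term), elliptical nuclei with morphology variation, cytoplasm
rings, two-magnification acquisition of the same physical cells with
overlap-tiled phenotype FOVs, stage-metadata error, control/targeting
codebook structure (14 guides: 4 each against three genes + non-targeting +
safe-targeting; fixed 12-mers with pairwise Hamming distance ≥ 5).

Not emulated: optical PSF physics and chromatic effects, rolling-circle
amplicon substructure, autofluorescence spectra, phasing/prephasing
chemistry errors, segmentation-hostile cell morphologies (crowded or
overlapping cells), uneven illumination. Passing tests therefore demonstrate
the correctness of the computational pipeline under its stated model, not
performance on any particular microscope's data.

Two generator conventions matter for interpretation. ISS spots within a cell
are placed with a minimum pairwise separation (4 px at 10X ≈ 2.6 µm),
emulating optically resolvable amplicons; without a separation floor,
coincident planted spots are indistinguishable from single detections and
"recall" stops being a detector property. nFISH spots are likewise separated
(7 px at 40X) and rendered at high SNR (noise sd 2 on a background of 50),
matching the discrete, clearly detectable spots the assay produces.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| `n_cycles` | 12 | – | barcode length = cycles read |
| `reads_per_cell_mean` | 2.5 | spots/cell | Poisson mean |
| `signal_amplitude` / `noise_sd` | 1000 / 100 | A.U. | default SNR 10; robustness runs use 5 |
| `decay_per_cycle` | 0.97 | – | signal loss per cycle |
| `background_start`, growth | 100, 3 | A.U. | per cycle |
| `jitter_px_max` | 3 | px | stage jitter bound (10 in registration stress runs) |
| pixel sizes | 0.65 / 0.325 / 0.1625 | µm/px | 10X / 20X / 40X; configuration, not claims |
| `nucleus_radius_um` | 6.0 | µm | U2OS-like; cytoplasm = nucleus × 1.8 |
| `min_distance_px` (detect) | 3 | px | peak separation in the SD image |
| `k_mad` (detect) | 5 | – | threshold = median + k·1.4826·MAD |
| `k_sigma` (consistency) | 3 | – | per-cycle windowed peak vs background + k·noise |
| `aperture_px` | 1 | px | 3×3 aperture, **mean** statistic |
| `morph_threshold` | 0.10 | – | per-feature relative difference |
| `min_cells` (stats) | 3000 | cells | report flag, not a hard filter |

## Numerical and design choices

**SD image.** Population SD (denominator = n_cycles), computed per SBS
channel then averaged over the four channels. Stated once and fixed so the
two-loop reference in the tests is exact.

**Aperture statistic.** The per-spot intensity is the *mean* over a 3×3
aperture (the max remains available). The max of i.i.d. noise is upward
biased and measurably raises the per-cycle miscall rate at moderate SNR
(85% vs 100% exact 12-mers at SNR 5 in a paired run); the mean acts as a
crude matched filter.

**Background subtraction before correction.** Crosstalk is multiplicative
on signal; camera background is additive. Each (cycle, channel) frame median
is subtracted from the raw tensor before the correction matrix is estimated
and applied. Without this, class-median columns mix background into the
mixing estimate (off-diagonals inflate from ~0.36 to ~0.55 at SNR 5) and
the inversion can lose margin relative to no correction.

**Correction-matrix estimation.** Two-pass: spots are provisionally classed
by raw argmax per cycle; column j of M is the channel-wise median vector of
class j, columns scaled to unit maximum. A class with fewer than 4 spots —
common in small screens, since a barcode set need not show every base at
every position — has its column imputed from the populated ones:
per-channel background from their off-diagonal entries plus the median
on-channel amplitude on the diagonal (exact under uniform crosstalk). Only
when no class is populated, or M is ill-conditioned (condition number
> 1e4), does the estimator fall back to a diagonal matrix of per-channel
global medians, flagged `fallback_used`. The whole-matrix diagonal fallback
is deliberately a last resort: when the base composition at a cycle is
skewed, a channel's global median contains signal and dividing by it
miscalls otherwise-clean data.

**Quality.** `q_c = 1 − second/first` on the non-negative-clamped corrected
intensities (0 when first = 0; the call itself uses the pre-clamp argmax);
spot quality is the min over cycles. Ties call the first channel in G,T,A,C
order and are flagged.

**Consistency filter.** A spot is kept only if, in every non-failed cycle,
its windowed (5×5) peak in some base channel exceeds that channel's frame
median + k·1.4826·MAD. Cycles whose registration failed (|shift| >
`max_shift`) are excluded from this denominator, but a failed cycle makes a
full-length read impossible, so such spots are dropped from calling. In the
quality/length-accuracy studies the filter is disabled (k_sigma = 0) on
purpose: it censors exactly the weak-read population whose behaviour those
curves describe; with it on, surviving reads are ~100% accurate and the
curves are degenerate.

**Segmentation.** The nuclei threshold is max(Otsu, median + 10·1.4826·MAD):
Otsu alone splits pure noise down the middle on empty phenotype tiles.
Cell labels equal their seed nucleus labels and every cell region contains
its nucleus; watershed-unreached pixels stay background. Perimeter uses the
Crofton 4-direction estimator; sub-3-pixel regions are flagged degenerate
(eccentricity stored as 0). Morphology is reported in µm so it is
magnification-invariant (≈0.2% for non-lattice-aligned disks across
10X/40X rasterization).

**nFISH quantification.** White top-hat (disk radius 8 px) removes diffuse
background. The top-hat of a noisy image has a positive pedestal (opening
under-estimates background), so its median is treated as the zero level for
both the detection threshold (pedestal + 5·noise) and integration. Each
spot's integrated value is the pedestal-subtracted top-hat summed over a
5-px disk around the peak, pixels owned by the nearest peak, masked below
pedestal + 1·noise. Integrating only the above-detection-threshold connected
component — the obvious alternative — truncates every spot's dim tail and
loses a capture fraction of 1 − threshold/amplitude (measured ≈50% at the
default SNR), which is why the disk scheme is used.

**Phenotype tiling.** 40X FOVs tile the world with 14 µm overlap and cells
touching a tile border are dropped: a sliced cell is a morphology outlier,
and the overlap guarantees each cell is whole in at least one tile.

**Offset estimation and matching.** The inter-acquisition offset is the
componentwise median of (ISS − phenotype) displacements over mutual nearest
neighbours within a 30 µm gate, iterated 3 times (a single pass is biased
toward zero whenever the offset is comparable to the inter-cell spacing).
For each ISS cell up to 3 nearest candidates within the 15 µm gate are
examined in distance order and the first passing morphology verification
(all four features within the 10% relative threshold, read per-feature)
is taken; accepted matches are made one-to-one greedily by increasing
residual. Morphology, not raw proximity, is the arbiter — the nearest
neighbour after centroid noise is occasionally the wrong cell, and
verification is what rejects it.

**Mann-Whitney U.** `U = Σ [x_i > y_j] + ½[x_i = y_j]`. Exact two-sided p by
full enumeration of all C(n+m, n) group assignments when `n_x·n_y ≤ 64`
(p = 2·min(tail), capped at 1), otherwise a normal approximation with tie
correction and a 0.5 continuity correction. Exhaustive comparison at the
8×8 switchover shows the two agree within 0.01 wherever the exact p < 0.25
and within 0.011 everywhere (the worst case sits at the distribution
centre). Controls are pooled (non-targeting + safe-targeting) by default;
tests are two-sided; `min_cells` = 3,000 marks under-powered rows
(`low_n`) without dropping them.

## Problem sizes

The test suite and acceptance script run on: a 9-FOV (~220-cell, ~570-read)
noiseless screen for exact decoding; 2-FOV screens for crosstalk (SNR 5),
detection and yield; a 6-FOV deliberately noisy screen (amplitude 350,
noise 100) for the quality/length-accuracy curves; a 500-cell two-
magnification table world for matching; 3,000 cells/sgRNA × 14 sgRNAs for
effect recovery; and 600 null replicates at n = 100/group for type-I
calibration. These sizes give each estimate enough events to be stable
across seeds while staying desk-scale.

## Known limitations

* The classical segmenter assumes well-separated, convex, DAPI-bright
  nuclei; crowded cultures need the pluggable deep-learning segmenter.
* Registration is rigid translation only; rotation, scaling and nonrigid
  distortion are out of scope.
* The median correction models linear, cycle-stationary crosstalk;
  phasing/prephasing chemistry effects are not corrected.
* nFISH integrated intensity is recovered up to a method-dependent capture
  fraction; it is a rank-faithful A.U. readout (rank correlation ≥ 0.9
  against planted truth at default SNR), not an absolute photon count.
* Levenshtein distances > 0 for codebook mapping are an extension hook; the
  screen design assumes exact 12-mer matching.
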