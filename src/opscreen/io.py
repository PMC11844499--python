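"""On-disk formats for OPS screens.

A field of view (FOV) lives in one directory of single-plane TIFFs named
``c{cycle:02d}_{channel}.tif`` (cycle is 1-based) plus a ``fov.json`` metadata
file. Codebooks and result tables are plain CSV. Pixel coordinates are 0-based
(row, col) with origin at the top-left; the stage coordinate in the metadata
refers to the FOV *center*, and stage y grows with the row index. Intensities
are stored as 16-bit unsigned integers on disk and converted to float64 on
load.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Canonical channel order of an SBS stack: DAPI plus the four base channels.
CHANNELS = ("DAPI", "G", "T", "A", "C")
#: Base channels in tensor order.
BASES = ("G", "T", "A", "C")
BARCODE_ALPHABET = frozenset("GCAT")
CODEBOOK_ROLES = ("targeting", "non_targeting_control", "safe_targeting")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented layout."""


@dataclass(frozen=True)
class FOVMetadata:
    """Stage/geometry metadata for one field of view."""

    fov_id: str
    well: str
    stage_x_um: float
    stage_y_um: float
    pixel_size_um: float
    magnification: str
    height_px: int
    width_px: int

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise FormatError(f"{self.fov_id}: pixel_size_um must be > 0")
        if self.height_px <= 0 or self.width_px <= 0:
            raise FormatError(f"{self.fov_id}: image dimensions must be > 0")

    def to_dict(self) -> dict:
        return {
            "fov_id": self.fov_id,
            "well": self.well,
            "stage_x_um": self.stage_x_um,
            "stage_y_um": self.stage_y_um,
            "pixel_size_um": self.pixel_size_um,
            "magnification": self.magnification,
            "height_px": self.height_px,
            "width_px": self.width_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FOVMetadata":
        return cls(
            fov_id=str(d["fov_id"]),
            well=str(d.get("well", "A1")),
            stage_x_um=float(d["stage_x_um"]),
            stage_y_um=float(d["stage_y_um"]),
            pixel_size_um=float(d["pixel_size_um"]),
            magnification=str(d["magnification"]),
            height_px=int(d["height_px"]),
            width_px=int(d["width_px"]),
        )


@dataclass
class SBSImageStack:
    """One FOV's cyclic SBS images, indexed (cycle, channel, row, col).

    Channel axis follows :data:`CHANNELS`; cycles are ascending from cycle 1.
    """

    fov: FOVMetadata
    pixels: np.ndarray  # (n_cycles, n_channels, H, W) float64, finite, >= 0
    channels: tuple = CHANNELS

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise FormatError("stack pixels must be 4-D (cycle, channel, row, col)")
        if self.pixels.shape[1] != len(self.channels):
            raise FormatError("channel axis does not match channel labels")
        if not np.isfinite(self.pixels).all():
            raise FormatError("stack contains non-finite intensities")
        if (self.pixels < 0).any():
            raise FormatError("stack contains negative intensities")

    @property
    def n_cycles(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self):
        return self.pixels.shape

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def dapi(self, cycle: int = 0) -> np.ndarray:
        return self.pixels[cycle, self.channel_index("DAPI")]

    def sbs(self) -> np.ndarray:
        """The four base channels, shape (n_cycles, 4, H, W), order G,T,A,C."""
        idx = [self.channels.index(b) for b in BASES]
        return self.pixels[:, idx]


@dataclass(frozen=True)
class CodebookEntry:
    sgrna_id: str
    barcode: str
    gene: str
    role: str


@dataclass
class Codebook:
    """Barcode prefix -> sgRNA/gene lookup with control designations."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        lengths = {len(e.barcode) for e in self.entries}
        if len(lengths) > 1:
            raise FormatError("codebook barcodes have mixed lengths")
        for e in self.entries:
            if set(e.barcode) - BARCODE_ALPHABET:
                raise FormatError(f"bad barcode {e.barcode!r}: alphabet is GCAT")
            if e.barcode in seen:
                raise FormatError(f"duplicate barcode {e.barcode!r}")
            if e.role not in CODEBOOK_ROLES:
                raise FormatError(f"unknown role {e.role!r}")
            seen.add(e.barcode)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0].barcode) if self.entries else 0

    def barcodes(self) -> list:
        return [e.barcode for e in self.entries]

    def control_ids(self) -> set:
        return {e.sgrna_id for e in self.entries if e.role != "targeting"}

    def entry_for_sgrna(self, sgrna_id: str) -> CodebookEntry:
        for e in self.entries:
            if e.sgrna_id == sgrna_id:
                return e
        raise KeyError(sgrna_id)

    def prefix_map(self, read_length: int) -> dict:
        """barcode[:read_length] -> entry; raises if truncation collides."""
        out = {}
        for e in self.entries:
            p = e.barcode[:read_length]
            if p in out:
                raise FormatError(
                    f"codebook ambiguous at length {read_length}: prefix {p!r}"
                )
            out[p] = e
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sgrna_id, e.barcode, e.gene, e.role) for e in self.entries],
            columns=["sgrna_id", "barcode", "gene", "role"],
        )


@dataclass
class PhenotypeImage:
    """One phenotype FOV: a DAPI plane plus one signal plane (IF or nFISH)."""

    fov: FOVMetadata
    dapi: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.dapi = np.asarray(self.dapi, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.dapi.shape != self.signal.shape:
            raise FormatError("DAPI and signal planes must share shape")


def write_phenotype_image(img: PhenotypeImage, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, plane in (("DAPI", img.dapi), ("signal", img.signal)):
        px = np.clip(np.round(plane), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(out / f"{name}.tif", px)
    (out / "fov.json").write_text(json.dumps(img.fov.to_dict(), indent=1))
    return out


def read_phenotype_image(in_dir) -> PhenotypeImage:
    d = Path(in_dir)
    fov = FOVMetadata.from_dict(json.loads((d / "fov.json").read_text()))
    dapi = np.asarray(tifffile.imread(d / "DAPI.tif"), dtype=np.float64)
    signal = np.asarray(tifffile.imread(d / "signal.tif"), dtype=np.float64)
    return PhenotypeImage(fov=fov, dapi=dapi, signal=signal)


_TIFF_RE = re.compile(r"^c(\d{2})_([A-Za-z]+)\.tif$")


def write_image_stack(stack: SBSImageStack, out_dir) -> Path:
    """Write a stack as per-(cycle, channel) uint16 TIFFs plus fov.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = np.clip(np.round(stack.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    for c in range(stack.n_cycles):
        for k, ch in enumerate(stack.channels):
            tifffile.imwrite(out / f"c{c + 1:02d}_{ch}.tif", px[c, k])
    (out / "fov.json").write_text(json.dumps(stack.fov.to_dict(), indent=1))
    return out


def read_image_stack(stack_dir) -> SBSImageStack:
    """Read a FOV directory back into an :class:`SBSImageStack`.

    Cycles are sorted ascending; channels are returned in canonical order.
    A missing (cycle, channel) file or a shape mismatch is an error.
    """
    d = Path(stack_dir)
    meta_path = d / "fov.json"
    if not meta_path.exists():
        raise FormatError(f"{d}: missing fov.json")
    fov = FOVMetadata.from_dict(json.loads(meta_path.read_text()))

    found = {}
    for p in d.iterdir():
        m = _TIFF_RE.match(p.name)
        if not m:
            continue
        cyc, ch = int(m.group(1)), m.group(2)
        if ch not in CHANNELS:
            raise FormatError(f"bad layout: unknown channel label {ch!r} in {p.name}")
        found[(cyc, ch)] = p
    if not found:
        raise FormatError(f"{d}: no stack TIFFs found")
    cycles = sorted({c for c, _ in found})
    planes = []
    shape = None
    for cyc in cycles:
        row = []
        for ch in CHANNELS:
            p = found.get((cyc, ch))
            if p is None:
                raise FormatError(
                    f"inconsistent stack: missing cycle {cyc} channel {ch}"
                )
            img = tifffile.imread(p)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError("inconsistent stack: shape mismatch across planes")
            row.append(np.asarray(img, dtype=np.float64))
        planes.append(row)
    return SBSImageStack(fov=fov, pixels=np.array(planes))


def read_codebook(path) -> Codebook:
    """Read a CSV codebook with header sgrna_id,barcode,gene,role."""
    df = pd.read_csv(path, dtype=str)
    required = ["sgrna_id", "barcode", "gene", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"codebook {path}: missing columns {missing}")
    entries = [
        CodebookEntry(r.sgrna_id, r.barcode, r.gene, r.role)
        for r in df.itertuples(index=False)
    ]
    return Codebook(entries)


def write_codebook(cb: Codebook, path) -> None:
    cb.to_frame().to_csv(path, index=False)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with header."""
    try:
        table.to_csv(path, index=False)
    except OSError as e:
        raise OSError(f"writing table to {path}: {e}") from e


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except OSError as e:
        raise OSError(f"reading table from {path}: {e}") from e


def validate_fov_dir(stack_dir) -> dict:
    """Validate a FOV directory; returns a small summary dict."""
    stack = read_image_stack(stack_dir)
    return {
        "fov_id": stack.fov.fov_id,
        "n_cycles": stack.n_cycles,
        "shape": list(stack.shape),
        "magnification": stack.fov.magnification,
    }
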