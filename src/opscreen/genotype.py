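"""Per-cell read aggregation, dominant-barcode selection, codebook mapping.

Reads are grouped by the cell body they overlap; the two most frequent
(truncated) barcodes per cell are kept with their counts, and the top barcode
is mapped to the codebook — by exact match (Levenshtein distance 0) by
default, with an optional small-distance extension. All tie rules are total
orders so the genotype table is deterministic.
"""

from __future__ import annotations

import edlib
import numpy as np
import pandas as pd

from .io import Codebook


def aggregate_reads(
    reads: pd.DataFrame,
    read_length: int = 12,
    quality_min: float = 0.0,
) -> pd.DataFrame:
    """Count truncated barcodes per cell.

    Reads with spot_quality < quality_min are discarded; barcodes are
    truncated to ``read_length``. Returns columns cell_label, barcode, count.
    """
    if not 1 <= read_length:
        raise ValueError("read_length must be >= 1")
    df = reads[
        (reads["barcode"].astype(str).str.len() > 0)
        & (reads["cell_label"] > 0)
        & (reads["spot_quality"] >= quality_min)
    ].copy()
    if df.empty:
        return pd.DataFrame(columns=["cell_label", "barcode", "count"])
    df["barcode"] = df["barcode"].str[:read_length]
    out = (
        df.groupby(["cell_label", "barcode"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out.sort_values(["cell_label", "count", "barcode"],
                           ascending=[True, False, True], ignore_index=True)


def dominant_barcodes(counts: dict):
    """Top-2 barcodes by count; ties broken lexicographically (flagged).

    Returns (top, top_count, second, second_count, ambiguous); an empty map
    yields (None, 0, None, 0, False).
    """
    if not counts:
        return None, 0, None, 0, False
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top, top_count = ranked[0]
    second, second_count = (ranked[1] if len(ranked) > 1 else (None, 0))
    ambiguous = len(ranked) > 1 and ranked[1][1] == top_count
    return top, top_count, second, second_count, ambiguous


def map_to_codebook(
    barcode: str,
    codebook: Codebook,
    read_length: int = 12,
    max_distance: int = 0,
) -> str:
    """Map a (truncated) barcode to an sgRNA id, or "unmapped".

    At max_distance 0 this is exact prefix lookup. For max_distance > 0 the
    unique codebook prefix within that Levenshtein distance wins; distance
    ties map to "unmapped". A codebook whose prefixes collide at
    ``read_length`` is an error, not a silent merge.
    """
    prefixes = codebook.prefix_map(read_length)
    if max_distance == 0:
        e = prefixes.get(barcode)
        return e.sgrna_id if e else "unmapped"
    best, best_d, tie = None, max_distance + 1, False
    for p, e in prefixes.items():
        d = edlib.align(barcode, p, task="distance")["editDistance"]
        if d < best_d:
            best, best_d, tie = e, d, False
        elif d == best_d:
            tie = True
    if best is None or tie:
        return "unmapped"
    return best.sgrna_id


def genotype_cells(
    reads: pd.DataFrame,
    total_cells: int | list,
    codebook: Codebook,
    read_length: int = 12,
    quality_min: float = 0.0,
    max_distance: int = 0,
):
    """Genotype every cell and compute screen-level summary statistics.

    ``total_cells`` is either the number of segmented cells or an explicit
    list of cell labels (labels without reads still get a row). Summary:
    fraction_cells_with_reads = cells with >= 1 read / total cells;
    reads_per_cell_mean over all cells; fraction_reads_mapped = mapped reads
    / total reads (0 with a flag when there are no reads).
    """
    labels = (
        list(range(1, total_cells + 1))
        if isinstance(total_cells, (int, np.integer))
        else sorted(int(x) for x in total_cells)
    )
    counts = aggregate_reads(reads, read_length=read_length,
                             quality_min=quality_min)
    by_cell = {
        int(lbl): dict(zip(grp["barcode"], grp["count"]))
        for lbl, grp in counts.groupby("cell_label")
    }
    gene_of = {e.sgrna_id: e.gene for e in codebook}
    rows = []
    n_mapped_reads = 0
    for lbl in labels:
        cmap = by_cell.get(lbl, {})
        top, tc, second, sc, amb = dominant_barcodes(cmap)
        if top is None:
            sg = "unmapped"
        else:
            sg = map_to_codebook(top, codebook, read_length=read_length,
                                 max_distance=max_distance)
        mapped = sg != "unmapped"
        if mapped:
            n_mapped_reads += tc
        rows.append(
            dict(
                cell_label=lbl,
                n_reads=int(sum(cmap.values())),
                top_barcode=top or "",
                top_count=int(tc),
                second_barcode=second or "",
                second_count=int(sc),
                mapped_sgrna_id=sg,
                gene=gene_of.get(sg, ""),
                ambiguous=bool(amb),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["cell_label", "n_reads", "top_barcode", "top_count",
                 "second_barcode", "second_count", "mapped_sgrna_id", "gene",
                 "ambiguous"],
    )
    total_reads = int(counts["count"].sum()) if len(counts) else 0
    n_cells = len(labels)
    # mapped fraction over individual reads: a read counts as mapped when its
    # (truncated) barcode maps to the codebook
    if total_reads:
        mapped_mask = counts["barcode"].map(
            lambda b: map_to_codebook(b, codebook, read_length=read_length,
                                      max_distance=max_distance) != "unmapped"
        )
        frac_mapped = float(counts.loc[mapped_mask, "count"].sum()) / total_reads
        undefined = False
    else:
        frac_mapped = 0.0
        undefined = True
    summary = dict(
        n_cells=n_cells,
        fraction_cells_with_reads=(
            float((table["n_reads"] > 0).sum()) / n_cells if n_cells else 0.0
        ),
        reads_per_cell_mean=(
            float(table["n_reads"].mean()) if n_cells else 0.0
        ),
        fraction_reads_mapped=frac_mapped,
        fraction_reads_mapped_undefined=undefined,
    )
    return table, summary
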