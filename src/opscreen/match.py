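"""Cross-magnification cell matching via global stage coordinates.

Low-magnification ISS cells and higher-magnification phenotype cells are
placed in a common micrometre coordinate system from the stage coordinates
recorded per FOV (the stage coordinate is the FOV centre). A systematic
offset between the two acquisitions is estimated as the componentwise median
displacement over mutual-nearest-neighbour pairs, then candidate matches are
verified by morphology: a match is accepted only when area, perimeter,
eccentricity and solidity each differ by at most the relative threshold
(10% by default). Accepted matches are one-to-one, assigned greedily in order
of increasing residual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import FOVMetadata

MORPH_FEATURES = ("area_um2", "perimeter_um", "eccentricity", "solidity")


def to_global(centroid_px, fov: FOVMetadata):
    """Pixel centroid (row, col) -> global (x_um, y_um).

    The stage coordinate is the FOV centre; x grows with col, y grows with
    row (y-axis orientation is a convention shared with the simulator).
    """
    row, col = centroid_px
    x = fov.stage_x_um + (col - (fov.width_px - 1) / 2) * fov.pixel_size_um
    y = fov.stage_y_um + (row - (fov.height_px - 1) / 2) * fov.pixel_size_um
    return float(x), float(y)


def global_cell_table(
    morphology: pd.DataFrame, fov: FOVMetadata, dataset: str
) -> pd.DataFrame:
    """Attach global coordinates to a per-FOV morphology table."""
    out = morphology.copy()
    xy = [
        to_global((r.centroid_row_px, r.centroid_col_px), fov)
        for r in morphology.itertuples(index=False)
    ]
    out["global_x_um"] = [p[0] for p in xy]
    out["global_y_um"] = [p[1] for p in xy]
    out["dataset"] = dataset
    out["fov_id"] = fov.fov_id
    out = out.rename(columns={"label": "cell_label"})
    return out


def estimate_offset(
    iss_cells: pd.DataFrame,
    pheno_cells: pd.DataFrame,
    gate_um: float = 30.0,
    min_pairs: int = 10,
    n_iter: int = 3,
):
    """Systematic (dx, dy) between acquisitions from mutual nearest neighbours.

    offset = componentwise median of (iss - pheno) over mutual-NN pairs
    within the coarse gate; adding it to the phenotype coordinates moves them
    onto the ISS frame. The estimate is refined iteratively (the offset is
    applied and the mutual-NN pairing recomputed) because a first-pass median
    is biased toward zero when the offset is comparable to the inter-cell
    spacing. Too few candidate pairs -> (0, 0) with a warning flag.
    Returns (dx_um, dy_um, ok).
    """
    ixy = iss_cells[["global_x_um", "global_y_um"]].to_numpy()
    pxy0 = pheno_cells[["global_x_um", "global_y_um"]].to_numpy()
    if len(ixy) == 0 or len(pxy0) == 0:
        return 0.0, 0.0, False
    dx = dy = 0.0
    ok = False
    ti = cKDTree(ixy)
    for _ in range(max(1, n_iter)):
        pxy = pxy0 + [dx, dy]
        tp = cKDTree(pxy)
        d_ip, nn_ip = tp.query(ixy, distance_upper_bound=gate_um)
        d_pi, nn_pi = ti.query(pxy, distance_upper_bound=gate_um)
        pairs = [
            (i, int(nn_ip[i]))
            for i in range(len(ixy))
            if np.isfinite(d_ip[i]) and nn_ip[i] < len(pxy)
            and nn_pi[int(nn_ip[i])] == i
        ]
        if len(pairs) < min_pairs:
            return (dx, dy, ok) if ok else (0.0, 0.0, False)
        disp = np.array([ixy[i] - pxy0[j] for i, j in pairs])
        dx, dy = (float(v) for v in np.median(disp, axis=0))
        ok = True
    return dx, dy, True


def match_cells(
    iss_cells: pd.DataFrame,
    pheno_cells: pd.DataFrame,
    gate_um: float = 15.0,
    morph_threshold: float = 0.10,
    offset: tuple | None = None,
    offset_gate_um: float = 30.0,
    n_candidates: int = 3,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Match ISS cells to phenotype cells; verify by morphology.

    If ``offset`` is None it is estimated first and applied to the phenotype
    coordinates. For each ISS cell the ``n_candidates`` nearest phenotype
    cells within ``gate_um`` are examined in order of distance and the first
    that passes morphology verification is the candidate: each feature must
    satisfy |f_iss - f_ph| / max(f_iss, f_ph, eps) <= morph_threshold
    (morphology, not raw proximity, is the arbiter of correspondence).
    Accepted matches are made one-to-one greedily by increasing residual.
    """
    if offset is None:
        dx, dy, _ = estimate_offset(iss_cells, pheno_cells,
                                    gate_um=offset_gate_um)
    else:
        dx, dy = offset
    ixy = iss_cells[["global_x_um", "global_y_um"]].to_numpy()
    pxy = pheno_cells[["global_x_um", "global_y_um"]].to_numpy() + [dx, dy]
    rows = []
    if len(ixy) and len(pxy):
        k = min(max(1, n_candidates), len(pxy))
        tree = cKDTree(pxy)
        dist, nn = tree.query(ixy, k=k, distance_upper_bound=gate_um)
        dist = np.atleast_2d(dist.T).T
        nn = np.atleast_2d(nn.T).T
        for i in range(len(ixy)):
            best = None
            for c in range(k):
                if not np.isfinite(dist[i, c]) or nn[i, c] >= len(pxy):
                    break
                j = int(nn[i, c])
                rel = {}
                ok = True
                for f in MORPH_FEATURES:
                    a = float(iss_cells.iloc[i][f])
                    b = float(pheno_cells.iloc[j][f])
                    rd = abs(a - b) / max(a, b, eps)
                    rel[f"rel_{f}"] = rd
                    ok = ok and rd <= morph_threshold
                if best is None:
                    best = (j, float(dist[i, c]), rel, ok)
                if ok:
                    best = (j, float(dist[i, c]), rel, ok)
                    break
            if best is None:
                continue
            j, d, rel, ok = best
            rows.append(
                dict(
                    iss_fov=iss_cells.iloc[i].get("fov_id", ""),
                    iss_label=int(iss_cells.iloc[i]["cell_label"]),
                    pheno_fov=pheno_cells.iloc[j].get("fov_id", ""),
                    pheno_label=int(pheno_cells.iloc[j]["cell_label"]),
                    _i=i, _j=j,
                    residual_um=d,
                    **rel,
                    accepted=bool(ok),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["iss_fov", "iss_label", "pheno_fov", "pheno_label", "_i",
                 "_j", "residual_um"]
        + [f"rel_{f}" for f in MORPH_FEATURES]
        + ["accepted"],
    )
    # greedy one-to-one on accepted candidates, by increasing residual
    if len(df):
        used_i, used_j = set(), set()
        keep = np.zeros(len(df), dtype=bool)
        order = df.sort_values("residual_um").index
        for idx in order:
            if not df.loc[idx, "accepted"]:
                continue
            i, j = df.loc[idx, "_i"], df.loc[idx, "_j"]
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            keep[df.index.get_loc(idx)] = True
        df["accepted"] = keep
    df = df.drop(columns=["_i", "_j"])
    df.attrs["offset_um"] = (dx, dy)
    return df
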