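"""Per-sgRNA screen statistics.

Each non-control sgRNA's per-cell phenotype distribution is compared against
the pooled control cells with the two-sided Mann-Whitney U test (exact by
enumeration for small samples, normal approximation with tie and continuity
corrections otherwise) and Bonferroni correction across the non-control
sgRNAs. Fold changes are ratios of means; ECDFs support distribution plots.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd


def mann_whitney_u(x, y, exact_max_pairs: int = 64):
    """Two-sided Mann-Whitney U test.

    U = sum over pairs of [x_i > y_j] + 1/2 [x_i = y_j]. The p-value is exact
    (full enumeration of all C(n+m, n) group assignments of the pooled
    values) when n_x * n_y <= exact_max_pairs, else a normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    u = _u_statistic(x, y)
    n, m = len(x), len(y)
    if n * m <= exact_max_pairs:
        p = _exact_p(x, y, u)
    else:
        p = _normal_p(x, y, u)
    return float(u), float(min(p, 1.0))


def _u_statistic(x, y):
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_p(x, y, u_obs):
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = range(len(pooled))
    total = comb(len(pooled), n)
    us = []
    for pick in combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(pick)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    # two-sided: double the smaller tail (point mass counted in both)
    p_lo = (us <= u_obs + 1e-12).sum() / total
    p_hi = (us >= u_obs - 1e-12).sum() / total
    return min(1.0, 2.0 * min(p_lo, p_hi))


def _normal_p(x, y, u_obs):
    n, m = len(x), len(y)
    N = n + m
    mu = n * m / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))


def bonferroni(p_raw: float, n_tests: int) -> float:
    return min(1.0, p_raw * n_tests)


def compare_sgrnas(
    cells: pd.DataFrame,
    control_ids,
    value_col: str = "value",
    min_cells: int = 3000,
    exact_max_pairs: int = 64,
) -> pd.DataFrame:
    """Test every non-control sgRNA against the pooled control cells.

    ``cells`` has one row per cell with columns sgrna_id, gene (optional) and
    the phenotype value. Controls are pooled; n_tests = number of non-control
    sgRNAs; p_bonferroni = min(1, p_raw * n_tests); fold_change =
    mean(sgRNA) / mean(control). sgRNAs with fewer than ``min_cells`` cells
    are flagged low_n but still reported.
    """
    control_ids = set(control_ids)
    ctl = cells.loc[cells["sgrna_id"].isin(control_ids), value_col].to_numpy()
    if len(ctl) == 0:
        raise ValueError("no control cells")
    test_ids = [s for s in cells["sgrna_id"].unique() if s not in control_ids]
    n_tests = len(test_ids)
    ctl_mean = float(ctl.mean())
    rows = []
    for sg in sorted(test_ids):
        sub = cells[cells["sgrna_id"] == sg]
        vals = sub[value_col].to_numpy()
        u, p = mann_whitney_u(vals, ctl, exact_max_pairs=exact_max_pairs)
        rows.append(
            dict(
                sgrna_id=sg,
                gene=(sub["gene"].iloc[0] if "gene" in sub else ""),
                n_cells=len(vals),
                mean_intensity=float(vals.mean()),
                median_intensity=float(np.median(vals)),
                fold_change_vs_control=(
                    float(vals.mean()) / ctl_mean if ctl_mean != 0 else np.nan
                ),
                U=u,
                p_raw=p,
                p_bonferroni=bonferroni(p, n_tests),
                n_tests=n_tests,
                low_n=len(vals) < min_cells,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["sgrna_id", "gene", "n_cells", "mean_intensity",
                 "median_intensity", "fold_change_vs_control", "U", "p_raw",
                 "p_bonferroni", "n_tests", "low_n"],
    )
    out.attrs["control_mean"] = ctl_mean
    out.attrs["n_control_cells"] = len(ctl)
    return out


def ecdf(values) -> pd.DataFrame:
    """Empirical CDF as a step table (right-continuous).

    Returns columns value, ecdf with one row per distinct value;
    ecdf(max) = 1 and ecdf of anything below min is 0.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    uniq, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts) / len(v)
    return pd.DataFrame(dict(value=uniq, ecdf=cum))


def ecdf_at(table: pd.DataFrame, q: float) -> float:
    """Evaluate a step-table ECDF at q."""
    mask = table["value"].to_numpy() <= q
    return float(table["ecdf"].to_numpy()[mask][-1]) if mask.any() else 0.0
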