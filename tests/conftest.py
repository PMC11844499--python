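import numpy as np
import pytest

from opscreen.simulate import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def noiseless_screen():
    """Small noiseless, jitter-free, identity-crosstalk screen (ISS only)."""
    cfg = SimConfig(seed=11, n_fovs_iss=2, render_phenotype=False).noiseless()
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def noisy_screen():
    """Default-condition screen (crosstalk, jitter, read noise; ISS only)."""
    cfg = SimConfig(seed=12, n_fovs_iss=2, render_phenotype=False)
    return simulate_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def match_spots_to_truth(spots_df, truth_spots, max_dist=2.0):
    """Greedy nearest-neighbour matching of detections to planted spots."""
    from scipy.spatial import cKDTree

    gt_xy = truth_spots[["row_px", "col_px"]].to_numpy()
    det_xy = spots_df[["row", "col"]].to_numpy()
    if len(det_xy) == 0 or len(gt_xy) == 0:
        return []
    tree = cKDTree(gt_xy)
    d, idx = tree.query(det_xy)
    pairs = []
    used = set()
    for order in np.argsort(d):
        if d[order] <= max_dist and idx[order] not in used:
            used.add(idx[order])
            pairs.append((order, int(idx[order])))
    return pairs
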