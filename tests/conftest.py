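import numpy as np
import pytest

import hypoxiquant as hq

#: Published single-section ICCs (k = 1..5 rows) for whole-tumor, epithelial
#: and stromal hypoxic percentage on three image-analysis platforms; used to
#: check that each column is internally consistent with the Spearman-Brown
#: step-up from its k=1 entry.
PUBLISHED_ICC_TABLE = {
    "developer": {
        "hp_wt": [0.728, 0.842, 0.889, 0.914, 0.930],
        "hp_epi": [0.736, 0.848, 0.893, 0.918, 0.933],
        "hp_str": [0.713, 0.832, 0.882, 0.909, 0.925],
    },
    "genie": {
        "hp_wt": [0.678, 0.808, 0.863, 0.894, 0.913],
        "hp_epi": [0.702, 0.825, 0.876, 0.904, 0.922],
        "hp_str": [0.567, 0.724, 0.797, 0.840, 0.868],
    },
    "tissue_studio": {
        "hp_wt": [0.325, 0.490, 0.591, 0.658, 0.706],
        "hp_epi": [0.308, 0.471, 0.572, 0.640, 0.690],
        "hp_str": [0.059, 0.112, 0.159, 0.201, 0.240],
    },
}


@pytest.fixture(scope="session")
def published_icc_table():
    return PUBLISHED_ICC_TABLE


@pytest.fixture(scope="session")
def small_tile():
    """One small synthetic tile + ground truth, shared across tests."""
    cfg = hq.TissueSynthConfig(
        seed=7, width_um=192, height_um=144,
        n_epithelial=50, n_stromal=35, n_inflammatory=10, n_glands=2,
    )
    return hq.generate_tissue_tile(cfg)


def make_nucleus(nid, rows, cols):
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    return hq.NucleusSegment(
        id=nid, rows=rows, cols=cols,
        centroid=(float(rows.mean()), float(cols.mean())),
        area_um2=float(len(rows)),
    )


def disk_coords(cy, cx, r, shape):
    from skimage.draw import disk

    return disk((cy, cx), r, shape=shape)
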