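import warnings

import numpy as np
import pandas as pd
import pytest

from agelung import atlas, presets, sim

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_atlas():
    """A compact 4-type atlas with strong markers, shared across tests."""
    cfg = sim.SimConfig(
        seed=2,
        n_genes=600,
        n_celltypes=4,
        cells_per_mouse=60,
        empty_droplets_per_mouse=50,
        n_markers_per_type=15,
        marker_log2fc=4.0,
    )
    matrix, annotation, truth = sim.simulate_atlas(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def small_cells(small_atlas):
    """Real-cell submatrix and annotation of the small atlas."""
    _, matrix, annotation, _ = small_atlas
    cells = annotation[annotation["is_cell"]].reset_index(drop=True)
    return matrix.subset_barcodes(list(cells["barcode"])), cells


@pytest.fixture(scope="session")
def small_markers(small_atlas, small_cells):
    cell_matrix, cells = small_cells
    return atlas.find_markers(cell_matrix, cells["cell_type"].to_numpy())


@pytest.fixture(scope="session")
def ambient_atlas():
    """Ambient-dominant fixture: 30 abundant genes feeding the empty pool."""
    cfg = presets.ambient_cohort(seed=3)
    matrix, annotation, truth = sim.simulate_atlas(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def mouse_ages(cells: pd.DataFrame) -> pd.Series:
    return cells.groupby("mouse_id")["age"].first()
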