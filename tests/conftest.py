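import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cropmap.screen_data import GuideEntry, GuideLibrary, ScreenMatrix, compute_qc_metrics
from cropmap.simulate import SimConfig, simulate_screen


def make_matrix(counts, genes=None, barcodes=None) -> ScreenMatrix:
    """Small dense-counts helper for hand-built examples."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = pd.Index(genes if genes is not None else [f"g{i+1}" for i in range(n_genes)])
    barcodes = barcodes if barcodes is not None else [f"c{i+1}" for i in range(n_cells)]
    m = ScreenMatrix(
        counts=sp.csr_matrix(counts), genes=genes,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
    )
    return compute_qc_metrics(m)


@pytest.fixture
def pilot_library() -> GuideLibrary:
    """Six hepatic-fate targets x 3 guides + 4 NT controls (22 guides)."""
    genes = ["Hnf4a", "Onecut1", "Hdac3", "Esrp2", "Cebpd", "Hmga2"]
    entries = [GuideEntry(f"{g}-{i}", g, False) for g in genes for i in (1, 2, 3)]
    entries += [GuideEntry(f"NT-{i}", None, True) for i in (1, 2, 3, 4)]
    return GuideLibrary(entries)


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen shared by downstream-stage tests."""
    up = {"TF2": 1.5, "TF3": 1.5, "TF4": 1.5, "TF5": 1.5}
    down = {"TF6": -1.5, "TF7": -1.5, "TF8": -1.5, "TF9": -1.5}
    cfg = SimConfig(
        n_cells_per_guide=60,
        n_genes=600,
        n_tfs=10,
        regulon_size=(8, 12),
        # two perturbation programs: four activators of one regulon block,
        # four repressors of another
        targets={
            **{f"Act{i}": dict(up) for i in range(1, 5)},
            **{f"Rep{i}": dict(down) for i in range(1, 5)},
        },
        n_guides_per_target=2,
        n_nt=3,
        escape_rate=0.0,
        seed=42,
    )
    return cfg, simulate_screen(cfg)
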