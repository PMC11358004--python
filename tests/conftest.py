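import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import xenospot as xs
from xenospot.io import SpotDataset


@pytest.fixture(scope="session")
def profiles():
    return xs.simulate_reference_profiles(xs.ProfileSimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_dataset():
    """One seeded xenograft dataset with its ground truth."""
    return xs.simulate_xenograft_dataset(xs.XenoSimConfig(seed=11))


@pytest.fixture(scope="session")
def table1():
    return xs.load_table1_fixture()


def make_tiny_dataset(counts, species, barcodes=None, positions=None):
    """Hand-built SpotDataset from a dense genes x spots array."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    barcodes = barcodes or [f"BC{j}" for j in range(n_spots)]
    prefix = {"human": "GRCh38_", "pig": "Sscrofa11-1_"}
    features = pd.DataFrame(
        {
            "feature_id": [f"{prefix[s]}G{i}" for i, s in enumerate(species)],
            "feature_name": [f"G{i}" for i in range(n_genes)],
            "species": list(species),
        }
    )
    if positions is None:
        positions = pd.DataFrame(
            {
                "in_tissue": 1,
                "array_row": 0,
                "array_col": np.arange(n_spots),
                "x_px": np.arange(n_spots) * 100.0,
                "y_px": 0.0,
            },
            index=pd.Index(barcodes, name="barcode"),
        )
    return SpotDataset(
        counts=sp.csr_matrix(counts), features=features, barcodes=list(barcodes),
        positions=positions,
    ).validate()


@pytest.fixture
def tiny_dataset():
    # 2 human genes + 1 pig gene over 3 spots
    return make_tiny_dataset(
        [[3, 0, 1], [2, 0, 4], [10, 0, 2]], ["human", "human", "pig"]
    )
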