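import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from apaxis.containers import CountMatrix, NormalizedMatrix
from apaxis.synthetic import StripeSpec, default_panel, embed_ground_truth, simulate_embryo


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_world(panel):
    """A small simulated embryo shared by read-only tests."""
    cm, truth = simulate_embryo(600, 150, panel, seed=7)
    emb = embed_ground_truth(truth, "arc", noise_sd=0.5, seed=7)
    return cm, truth, emb


def make_count_matrix(arr, gene_prefix="g", bc_prefix="n"):
    arr = np.asarray(arr)
    genes = pd.Index([f"{gene_prefix}{i}" for i in range(arr.shape[0])])
    bcs = pd.Index([f"{bc_prefix}{j}" for j in range(arr.shape[1])])
    return CountMatrix(genes, bcs, sp.csr_matrix(arr))


def make_normalized(arr, positions=None, gene_prefix="g", bc_prefix="n"):
    arr = np.asarray(arr, dtype=float)
    genes = pd.Index([f"{gene_prefix}{i}" for i in range(arr.shape[0])])
    bcs = pd.Index([f"{bc_prefix}{j}" for j in range(arr.shape[1])])
    nm = NormalizedMatrix(genes, bcs, sp.csr_matrix(arr))
    if positions is None:
        return nm
    pos = pd.DataFrame(
        {
            "nucleus_id": bcs.to_numpy(),
            "position": np.asarray(positions, dtype=float),
            "distance": 0.0,
            "on_extension": False,
        }
    )
    pos.attrs["anterior_terminus"] = float(np.min(positions))
    pos.attrs["posterior_terminus"] = float(np.max(positions))
    return nm, pos
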