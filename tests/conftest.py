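import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import dbk


@pytest.fixture(scope="session")
def truth():
    """Well-separated 5-type ground truth used across tests."""
    return dbk.generate_ground_truth(2000, 5, 10, seed=1)


@pytest.fixture(scope="session")
def clean_cells(truth):
    """Artifact-free simulated sample with true labels."""
    return dbk.simulate_cells(
        truth,
        2000,
        [0.2, 0.2, 0.2, 0.2, 0.2],
        dbk.ProtocolEffect(),
        depth_mean=5000,
        seed=7,
    )


@pytest.fixture(scope="session")
def norm_cells(clean_cells):
    return dbk.lognormalize(clean_cells)


@pytest.fixture(scope="session")
def reference(truth):
    ref_cells = dbk.simulate_cells(
        truth,
        1000,
        [0.2, 0.2, 0.2, 0.2, 0.2],
        dbk.ProtocolEffect(),
        depth_mean=5000,
        seed=11,
        sample="ref",
    )
    ref_cells.obs["label"] = ref_cells.obs["true_type"]
    return dbk.build_reference([ref_cells])


def make_adata(counts, gene_names=None, cell_names=None, **obs_cols):
    """Small dense-count AnnData helper for hand-built toys."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_names = gene_names or [f"g{i}" for i in range(n_genes)]
    cell_names = cell_names or [f"c{i}" for i in range(n_cells)]
    obs = pd.DataFrame(index=cell_names)
    for k, v in obs_cols.items():
        obs[k] = v
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene_id"))
    var["mito"] = [g.lower().startswith("mt-") for g in gene_names]
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
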