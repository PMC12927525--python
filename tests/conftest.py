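import numpy as np
import pandas as pd
import pytest
import anndata as ad
import scipy.sparse as sp

from doubletnull import synth


def make_adata(counts, gene_names=None, barcodes=None, mito=None, clusters=None):
    """Small helper: cells x genes AnnData from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_names = gene_names or [f"g{j}" for j in range(g)]
    barcodes = barcodes or [f"cell{i}" for i in range(n)]
    var = pd.DataFrame(index=gene_names)
    var["mito"] = mito if mito is not None else [False] * g
    obs = pd.DataFrame(index=barcodes)
    if clusters is not None:
        obs["cluster"] = clusters
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_doublet_dataset():
    """A compact synthetic dataset with an injected count-sum doublet cluster."""
    cfg = synth.benchmark_config(
        7, scenario="doublet", n_clusters=4, cells_per_cluster=150,
        n_genes=400, hybrid_cells=60, markers_per_cluster=30,
    )
    return synth.generate_dataset(cfg)
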