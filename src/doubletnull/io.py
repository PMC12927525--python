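"""Reading and writing the 10x-convention MatrixMarket triplet.

``matrix.mtx`` (genes x cells), ``features.tsv``, ``barcodes.tsv`` — plain
or gzipped — plus an optional ``clusters.tsv`` (barcode TAB label).
In-memory orientation is cells x genes (AnnData).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_10x", "read_labels"]


def _find(dir_path: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dir_path, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a barcode TAB cluster-label table into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "cluster"], dtype=str)
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise ValueError(f"duplicate barcode in label table: {dup!r}")
    return df.set_index("barcode")["cluster"]


def read_10x(
    dir_path: str | os.PathLike,
    mito_prefix: str = "mt-",
) -> tuple[ad.AnnData, pd.Series | None]:
    """Read matrix.mtx + features.tsv + barcodes.tsv (+ clusters.tsv).

    Returns a cells x genes AnnData with integer sparse ``X``,
    ``var['mito']`` set from the (case-insensitive) gene-name prefix, and
    the cluster labels if a clusters.tsv is present (also copied into
    ``obs['cluster']``).
    """
    dir_path = str(dir_path)
    M = scipy.io.mmread(_find(dir_path, "matrix.mtx"))  # genes x cells
    features = pd.read_csv(_find(dir_path, "features.tsv"), sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(_find(dir_path, "barcodes.tsv"), sep="\t", header=None, dtype=str)[0]
    if M.shape[0] != len(features):
        raise ValueError(
            f"matrix.mtx has {M.shape[0]} gene rows but features.tsv lists {len(features)} genes"
        )
    if M.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix.mtx has {M.shape[1]} cell columns but barcodes.tsv lists {len(barcodes)} barcodes"
        )
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise ValueError(f"duplicate barcode in barcodes.tsv: {dup!r}")
    gene_ids = features[0]
    if gene_ids.duplicated().any():
        dup = gene_ids[gene_ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id in features.tsv: {dup!r}")
    X = sp.csr_matrix(M.T).astype(np.int64)
    var = pd.DataFrame(index=pd.Index(gene_ids, name=None))
    name_col = features[1] if features.shape[1] > 1 else gene_ids
    var["mito"] = name_col.str.lower().str.startswith(mito_prefix.lower()).to_numpy()
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index(barcodes.to_list())), var=var)

    labels = None
    try:
        lpath = _find(dir_path, "clusters.tsv")
    except FileNotFoundError:
        lpath = None
    if lpath is not None:
        labels = read_labels(lpath)
        missing = adata.obs_names.difference(labels.index)
        if len(missing):
            raise ValueError(
                f"clusters.tsv is missing {len(missing)} barcodes (e.g. {missing[0]!r})"
            )
        labels = labels.reindex(adata.obs_names)
        adata.obs["cluster"] = labels.to_numpy()
    return adata, labels
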