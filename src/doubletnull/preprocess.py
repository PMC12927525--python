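"""QC filtering and log-normalization of UMI count matrices.

The QC rule removes cells with an abnormally high (>2500) or low (<200)
number of detected features or with mitochondrial content above 5%; the
inequalities are strict, so boundary cells are retained.  "Detected
feature" means a gene with count > 0.  Normalization scales each cell to
10,000 transcripts and takes the natural log of 1 + scaled count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["QCThresholds", "qc_filter", "normalize_log10k", "scale_genes"]


@dataclass
class QCThresholds:
    min_features: int = 200
    max_features: int = 2500
    max_mito_fraction: float = 0.05

    def validate(self) -> None:
        if not (0 <= self.min_features < self.max_features):
            raise ValueError(
                f"need 0 <= min_features < max_features, got {self.min_features}, {self.max_features}"
            )
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError(f"max_mito_fraction must be in [0, 1], got {self.max_mito_fraction}")


def _per_cell_stats(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    X = sp.csr_matrix(adata.X)
    n_features = X.getnnz(axis=1)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(adata.var["mito"], dtype=bool)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return n_features, mito_frac


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the feature-count and mitochondrial-fraction filters.

    Returns the retained cells and a per-cell QC report
    (``cell_id, n_features, mito_fraction, kept, reason``).  A cell is
    removed only when it violates a *strict* inequality, so cells sitting
    exactly on a threshold are kept.  Raises if the matrix lacks
    mitochondrial flags or if no cell survives.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    thresholds.validate()
    if "mito" not in adata.var:
        raise ValueError("count matrix has no 'mito' gene flags; cannot apply the mito filter")
    n_features, mito_frac = _per_cell_stats(adata)

    low = n_features < thresholds.min_features
    high = n_features > thresholds.max_features
    mito_bad = mito_frac > thresholds.max_mito_fraction
    keep = ~(low | high | mito_bad)

    reasons = []
    for lo, hi, mb in zip(low, high, mito_bad):
        r = [tag for flag, tag in ((lo, "low_features"), (hi, "high_features"), (mb, "high_mito")) if flag]
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "n_features": n_features,
            "mito_fraction": mito_frac,
            "kept": keep,
            "reason": reasons,
        }
    )
    if not keep.any():
        raise ValueError("empty after QC: every cell failed the filters")
    return adata[keep].copy(), report


def normalize_log10k(adata: ad.AnnData, scale_total: float = 10_000.0) -> ad.AnnData:
    """Depth-normalize to ``scale_total`` transcripts per cell, then log1p.

    value(c, g) = ln(1 + count(c, g) / total(c) * scale_total).  The
    sparsity pattern is preserved and for every cell
    sum_g(exp(value) - 1) == scale_total to floating tolerance.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    X = X.multiply((scale_total / totals)[:, None]).tocsr()
    X.data = np.log1p(X.data)
    out = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["scale_total"] = float(scale_total)
    return out


def scale_genes(norm: ad.AnnData, max_value: float = 10.0) -> np.ndarray:
    """Per-gene z-scaling of the log-normalized layer (dense output).

    Provided for completeness with the conventional toolkit pipeline; the
    doublet-null distances are computed on the *log-normalized* layer, not
    on this one, because the unlog/mean/relog mixing is defined there.
    """
    X = np.asarray(sp.csr_matrix(norm.X).todense(), dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Z = np.where(sd > 0, (X - mu) / sd, 0.0)
    return np.clip(Z, -max_value, max_value)
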