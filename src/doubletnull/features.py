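"""Highly variable gene selection (variance-stabilizing ranking).

Reimplements the standard "vst" ranking: fit a loess trend of
log10(variance) on log10(mean) across genes (span 0.3), standardize each
gene's raw counts by the trend-predicted standard deviation, clip the
standardized values at sqrt(n_cells), and rank genes by the variance of
the clipped values.  The local regression uses statsmodels' lowess
(locally linear); agreement with other loess implementations is not exact
by design, but the ranking is checked against a brute-force oracle in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["HVGResult", "select_hvg", "standardized_variance"]


@dataclass
class HVGResult:
    genes: list[str]
    standardized_variance: np.ndarray  # for the selected genes, same order
    n_hvg: int
    all_standardized_variance: pd.Series  # every input gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "standardized_variance": self.standardized_variance,
                "rank": np.arange(1, len(self.genes) + 1),
            }
        )


def standardized_variance(counts: np.ndarray | sp.spmatrix, span: float = 0.3) -> np.ndarray:
    """Per-gene standardized variance of a cells x genes raw count matrix.

    Genes with zero empirical variance get standardized variance 0.
    """
    X = sp.csc_matrix(counts, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 cells to estimate variance, got {n}")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    # constant genes can pick up ~1e-16 relative float error; snap them to 0
    var[var < 1e-10 * np.maximum(mean**2, 1e-300)] = 0.0
    var = np.maximum(var, 0.0)

    out = np.zeros(X.shape[1])
    fit_mask = (mean > 0) & (var > 0)
    if not fit_mask.any():
        return out
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    if np.unique(lx).size < 2:
        # degenerate trend: expected variance = observed variance
        pred_var = var[fit_mask]
    else:
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
        pred_var = 10.0**fitted
    sd_exp = np.sqrt(pred_var)

    clip = np.sqrt(n)
    idx = np.flatnonzero(fit_mask)
    for j, g in enumerate(idx):
        col = np.zeros(n)
        sl = slice(X.indptr[g], X.indptr[g + 1])
        col[X.indices[sl]] = X.data[sl]
        z = np.minimum((col - mean[g]) / sd_exp[j], clip)
        out[g] = z.var(ddof=1)
    return out


def select_hvg(counts: ad.AnnData, n_hvg: int = 2000, span: float = 0.3) -> HVGResult:
    """Rank genes by standardized variance and return the top ``n_hvg``.

    Ties are broken by ascending gene index.  If fewer than ``n_hvg`` genes
    have nonzero variance, the available ones are returned with a warning.
    """
    sv = standardized_variance(counts.X, span=span)
    order = np.lexsort((np.arange(sv.size), -sv))
    eligible = order[sv[order] > 0]
    if eligible.size < n_hvg:
        warnings.warn(
            f"only {eligible.size} genes have nonzero variance; returning fewer than n_hvg={n_hvg}"
        )
    top = eligible[:n_hvg]
    genes = [counts.var_names[i] for i in top]
    return HVGResult(
        genes=genes,
        standardized_variance=sv[top],
        n_hvg=n_hvg,
        all_standardized_variance=pd.Series(sv, index=counts.var_names),
    )
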