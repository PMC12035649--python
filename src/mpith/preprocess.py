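"""Quality-control filters and the variance-stabilising NMF input transform.

Cells are kept when they detect more than ``min_features`` genes and carry
fewer than ``max_counts`` total counts (strict inequalities); genes when
detected in at least ``min_cells`` cells; samples when they contain at
least ``min_malignant_cells`` malignant cells.  The NMF input is
``log2(1 + CPM/10)`` per cell, mean-centred per gene, with negative values
clipped to zero so the matrix stays non-negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = [
    "EmptySampleError",
    "qc_filter_cells",
    "qc_filter_genes",
    "qc_filter_samples",
    "normalize_for_nmf",
]

NMF_LAYER = "nmf_input"


class EmptySampleError(ValueError):
    """Raised when a QC filter removes every cell, or a cohort every sample."""


def _counts(adata: AnnData) -> sparse.csr_matrix:
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    return X.tocsr()


def qc_filter_cells(
    adata: AnnData, min_features: int = 300, max_counts: int = 7500
) -> AnnData:
    """Keep cells with > ``min_features`` detected genes and < ``max_counts``
    total counts.  Cell order is preserved; values are untouched."""
    X = _counts(adata)
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    keep = (n_features > min_features) & (total < max_counts)
    if not keep.any():
        raise EmptySampleError(
            f"sample {adata.uns.get('sample_id', '?')}: all cells removed by QC"
        )
    return adata[keep].copy()


def qc_filter_genes(adata: AnnData, min_cells: int = 100) -> AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    X = _counts(adata)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells >= min_cells
    if not keep.any():
        warnings.warn(
            f"sample {adata.uns.get('sample_id', '?')}: gene filter removed all genes"
        )
    return adata[:, keep].copy()


def qc_filter_samples(
    cohort: list[AnnData], min_malignant_cells: int = 200
) -> list[AnnData]:
    """Drop samples with fewer than ``min_malignant_cells`` cells flagged
    malignant in ``obs['malignant']``."""
    for m in cohort:
        if "malignant" not in m.obs:
            raise KeyError(
                f"sample {m.uns.get('sample_id', '?')} lacks obs['malignant']"
            )
    kept = [
        m for m in cohort if int(m.obs["malignant"].sum()) >= min_malignant_cells
    ]
    if not kept:
        raise EmptySampleError("no sample passes the malignant-cell threshold")
    return kept


def lognorm(adata: AnnData, target_scale: float = 1e5) -> np.ndarray:
    """log2(1 + CPM/10) per cell, dense cells x genes array.

    ``target_scale`` = 1e5 corresponds to counts-per-million divided by 10.
    Raises on cells with zero total counts, naming the first offender.
    """
    X = _counts(adata).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise EmptySampleError(
            f"cell {adata.obs_names[zero[0]]!r} has zero total counts; "
            "cannot normalise"
        )
    dense = X.toarray() / total[:, None] * target_scale
    return np.log2(1.0 + dense)


def normalize_for_nmf(adata: AnnData, target_scale: float = 1e5) -> AnnData:
    """Fill ``layers['nmf_input']`` with the non-negative NMF input.

    log2(1 + CPM/10), per-gene mean-centred across cells, negatives clipped
    to 0.  Returns the same AnnData for chaining.
    """
    logged = lognorm(adata, target_scale=target_scale)
    centred = logged - logged.mean(axis=0, keepdims=True)
    adata.layers[NMF_LAYER] = np.maximum(centred, 0.0)
    return adata
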