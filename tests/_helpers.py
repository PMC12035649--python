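"""Shared test helpers: hand-built programs and small expression matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from mpith.nmf import NMFProgram


def make_program(
    sample_id: str,
    rank_k: int,
    factor_index: int,
    genes,
    weights=None,
) -> NMFProgram:
    """An NMFProgram with descending synthetic weights unless given."""
    genes = tuple(genes)
    if weights is None:
        weights = {g: float(len(genes) - i) for i, g in enumerate(genes)}
    return NMFProgram(
        sample_id=sample_id,
        rank_k=rank_k,
        factor_index=factor_index,
        genes=genes,
        weights=weights,
    )


def gene_block(start: int, n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(start, start + n)]


def counts_adata(counts: np.ndarray, sample_id: str = "S") -> AnnData:
    """AnnData from a cells x genes integer array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(
            {"sample_id": sample_id, "malignant": True},
            index=[f"{sample_id}_c{i:03d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=[f"g{i:04d}" for i in range(n_genes)]),
    )
    adata.uns["sample_id"] = sample_id
    return adata
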