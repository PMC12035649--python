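"""Per-sample NMF and extraction of top-gene expression programs.

Each tumour sample's non-negative normalised matrix (genes x cells) is
factorised at every rank K in a range (default 4..9).  Every factor yields
one *program*: the ``genes_per_program`` genes (default 50) with the
largest basis coefficients in that factor, so a K-range of {4..9} yields
4+5+...+9 = 39 programs per sample regardless of data content.

The solver is scikit-learn's coordinate-descent NMF with non-negative
double-SVD (``nndsvd``) initialisation, max 500 iterations and tolerance
1e-4; the deterministic initialisation makes gene lists reproducible for a
fixed seed.  Ties in top-gene selection break lexicographically on gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from anndata import AnnData
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from mpith.preprocess import NMF_LAYER

__all__ = ["NMFProgram", "factorize", "extract_programs", "DEFAULT_K_RANGE"]

DEFAULT_K_RANGE: tuple[int, ...] = (4, 5, 6, 7, 8, 9)


@dataclass(frozen=True)
class NMFProgram:
    """One factor of one per-sample factorisation.

    ``genes`` are ordered by non-increasing basis coefficient (ties broken
    by gene id); ``weights`` maps each listed gene to its coefficient.
    """

    sample_id: str
    rank_k: int
    factor_index: int
    genes: tuple[str, ...]
    weights: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("program genes must be distinct")
        w = [self.weights[g] for g in self.genes]
        if any(x < 0 for x in w):
            raise ValueError("NMF weights must be non-negative")
        if any(w[i] < w[i + 1] for i in range(len(w) - 1)):
            raise ValueError("weights must be non-increasing along genes")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sample_id, self.rank_k, self.factor_index)

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


def _nmf_matrix(m: AnnData) -> np.ndarray:
    if NMF_LAYER not in m.layers:
        raise ValueError("normalised layer missing; run normalize_for_nmf first")
    # genes x cells orientation: basis columns weight genes
    return np.asarray(m.layers[NMF_LAYER]).T


def factorize(
    m: AnnData,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Factorise the sample's normalised genes x cells matrix at rank ``k``.

    Returns ``(basis, loadings, frobenius_error)`` with ``basis`` of shape
    (genes, k) and ``loadings`` (k, cells), both non-negative.
    """
    X = _nmf_matrix(m)
    if k < 1 or k > min(X.shape):
        raise ValueError(f"rank k={k} outside [1, {min(X.shape)}]")
    model = NMF(
        n_components=k,
        init="nndsvd",
        solver="cd",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # stopping at the iteration cap is the intended behaviour
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        basis = model.fit_transform(X)
    return basis, model.components_, float(model.reconstruction_err_)


def _top_genes(
    gene_ids: np.ndarray, coeffs: np.ndarray, n: int
) -> tuple[tuple[str, ...], dict[str, float]]:
    # sort by coefficient descending, ties by gene id ascending
    order = np.lexsort((gene_ids, -coeffs))[:n]
    genes = tuple(gene_ids[order])
    return genes, {g: float(coeffs[i]) for g, i in zip(genes, order)}


def extract_programs(
    m: AnnData,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    genes_per_program: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> list[NMFProgram]:
    """All programs of one sample over the rank range.

    Exactly ``sum(k_range)`` programs are returned, ordered by (K, factor
    index).  Program (K, j) lists the ``genes_per_program`` genes with the
    largest basis coefficient in factor j of the rank-K factorisation.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if genes_per_program > m.n_vars:
        raise ValueError(
            f"genes_per_program={genes_per_program} exceeds {m.n_vars} genes"
        )
    sample_id = str(m.uns.get("sample_id", "sample"))
    gene_ids = np.asarray(m.var_names, dtype=object)
    programs: list[NMFProgram] = []
    for k in ks:
        basis, _, _ = factorize(m, k, seed=seed, max_iter=max_iter, tol=tol)
        for j in range(k):
            genes, weights = _top_genes(gene_ids, basis[:, j], genes_per_program)
            programs.append(
                NMFProgram(
                    sample_id=sample_id,
                    rank_k=k,
                    factor_index=j,
                    genes=genes,
                    weights=weights,
                )
            )
    return programs
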