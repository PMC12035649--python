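"""Per-cell MP scoring and arg-max assignment.

Signature scores follow the bin-matched control scheme standard in
single-cell work: genes are binned by average log-normalised expression;
each signature gene contributes its centred expression minus the mean
centred expression of control genes drawn from its own bin.  This removes
the depth/complexity component of the raw signature mean.  Cells are
assigned to the arg-max MP; an MP is only scored in a sample when at least
25 of its 50 genes are present, and is only retained as a label when it
tops at least 5% of the sample's cells — cells of dropped MPs are labelled
"unresolved".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

from mpith.preprocess import lognorm

__all__ = [
    "CellAssignment",
    "signature_score",
    "score_cells",
    "assign_cells",
    "mp_module_scores",
    "mp_correlation_matrix",
]

UNRESOLVED = "unresolved"


@dataclass
class CellAssignment:
    """Per-sample assignment result.

    ``labels`` maps every cell to an MP id or ``"unresolved"``; every
    retained MP labels at least ``min_prevalence`` of the sample's cells.
    ``prevalence`` records the post-drop label fractions for auditing.
    """

    sample_id: str
    scores: pd.DataFrame
    labels: pd.Series
    retained_mps: tuple[str, ...]
    prevalence: pd.Series

    def __post_init__(self) -> None:
        allowed = set(self.retained_mps) | {UNRESOLVED}
        bad = set(self.labels.unique()) - allowed
        if bad:
            raise ValueError(f"labels outside retained MPs: {sorted(bad)}")


def _expression_bins(avg: np.ndarray, gene_ids: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index per gene: equal-size bins of the average-expression ranking.

    Ties break on gene id so the binning is invariant to gene order.
    """
    order = np.lexsort((gene_ids, avg))
    bins = np.empty(len(avg), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def signature_score(
    m: AnnData,
    genes: Iterable[str],
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Bin-matched control score of a gene signature, per cell.

    score(cell) = mean over present signature genes of centred
    log-normalised expression, minus the mean over signature genes of their
    control genes' centred expression.  Controls are ``n_ctrl`` genes drawn
    (without replacement, seeded) from the signature gene's
    average-expression bin; when the bin holds at most ``n_ctrl`` genes the
    whole bin is used deterministically.  Signature genes absent from the
    matrix are ignored; an all-absent signature is an error.
    """
    gene_ids = np.asarray(m.var_names, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    sig = sorted(set(genes) & set(gene_ids))
    if not sig:
        raise ValueError("no signature gene present in the matrix")

    logged = lognorm(m)
    centred = logged - logged.mean(axis=0, keepdims=True)
    avg = logged.mean(axis=0)
    bins = _expression_bins(avg, gene_ids, n_bins)
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }
    # genes within a bin in a canonical order so draws are input-order-free
    for b, idx in bin_members.items():
        bin_members[b] = idx[np.argsort(gene_ids[idx])]

    rng = np.random.default_rng(seed)
    sig_idx = np.array([pos[g] for g in sig])
    ctrl_means = np.zeros((m.n_obs, len(sig)))
    for j, g in enumerate(sig):
        members = bin_members[bins[pos[g]]]
        if len(members) <= n_ctrl:
            ctrl = members
        else:
            ctrl = rng.choice(members, size=n_ctrl, replace=False)
        ctrl_means[:, j] = centred[:, ctrl].mean(axis=1)
    score = centred[:, sig_idx].mean(axis=1) - ctrl_means.mean(axis=1)
    return pd.Series(score, index=m.obs_names, name="score")


def score_cells(
    m: AnnData,
    mps: Sequence,
    min_genes_conserved: int = 25,
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell x MP score matrix; MPs with < ``min_genes_conserved`` of their
    genes present in the matrix are excluded (reported via a warning and
    ``df.attrs['excluded_mps']``)."""
    if not mps:
        raise ValueError("no meta-programs supplied")
    present = set(m.var_names)
    cols: dict[str, pd.Series] = {}
    excluded: list[str] = []
    for mp in mps:
        n_present = len(set(mp.genes) & present)
        if n_present < min_genes_conserved:
            excluded.append(mp.mp_id)
            continue
        cols[mp.mp_id] = signature_score(
            m, mp.genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
        )
    if excluded:
        warnings.warn(
            f"sample {m.uns.get('sample_id', '?')}: MPs excluded for "
            f"insufficient gene conservation: {excluded}"
        )
    if not cols:
        raise ValueError("every MP fails the gene-conservation rule in this sample")
    df = pd.DataFrame(cols)
    df.attrs["excluded_mps"] = excluded
    return df


def assign_cells(
    scores: pd.DataFrame,
    min_prevalence: float = 0.05,
    sample_id: str = "sample",
) -> CellAssignment:
    """Arg-max MP label per cell with the sample-prevalence rule.

    Each cell provisionally takes the highest-scoring MP (ties: first MP in
    column order).  MPs topping fewer than ``min_prevalence`` of cells are
    dropped and their cells labelled unresolved; prevalence is re-checked
    once after dropping (a single pass — dropping never changes the labels
    of retained MPs, so the audit trail records any residual sub-threshold
    fraction instead of iterating).
    """
    if scores.empty:
        raise ValueError("empty score matrix")
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    n_cells = len(scores)
    arg = scores.to_numpy().argmax(axis=1)
    provisional = pd.Series(
        [scores.columns[j] for j in arg], index=scores.index, name="mp_label"
    )
    counts = provisional.value_counts()
    threshold = min_prevalence * n_cells - 1e-9
    retained = tuple(c for c in scores.columns if counts.get(c, 0) >= threshold)
    labels = provisional.where(provisional.isin(retained), UNRESOLVED)
    prevalence = labels.value_counts() / n_cells
    return CellAssignment(
        sample_id=sample_id,
        scores=scores,
        labels=labels,
        retained_mps=retained,
        prevalence=prevalence,
    )


def mp_module_scores(
    m: AnnData,
    mps: Sequence,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Continuous per-cell module score for every MP (cell x MP).

    Same bin-matched control scheme as :func:`signature_score`, with the
    coarser 24-bin default used for downstream correlations.
    """
    cols = {
        mp.mp_id: signature_score(m, mp.genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for mp in mps
    }
    return pd.DataFrame(cols)


def mp_correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """MP x MP Pearson correlation of per-cell scores.

    Symmetric with unit diagonal; zero-variance columns yield NaN entries
    and a warning rather than a silent zero.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 cells")
    X = scores.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        flat = [c for c, s in zip(scores.columns, sd) if s == 0]
        warnings.warn(f"zero-variance score columns: {flat}; entries set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return pd.DataFrame(corr, index=scores.columns, columns=scores.columns)
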