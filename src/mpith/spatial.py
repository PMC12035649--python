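"""Spot-grid geometry, tumour neighbourhood scores and MP/TME correlations.

A slide is modelled as a square lattice of spots.  Every tumour spot is
scored against each meta-program and labelled with the arg-max MP; the
*tumour neighbourhood score* of a cell type (or of any per-spot signature)
at a tumour spot is the sum of that column over the spots adjacent to it.
Correlating MP scores with neighbourhood scores across all tumour spots of
one or more slides quantifies which cell types surround which tumour state.

The neighbourhood is the 8-spot Moore neighbourhood of the square lattice
(row +/- 1, col +/- 1).  Spots on edges and corners keep their truncated
neighbourhood; no padding or renormalisation is applied.  A 6-neighbour
hexagonal mode (Visium-style array coordinates, where adjacent columns
differ by 2) is available via ``hex_mode=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

__all__ = [
    "SpotGrid",
    "CorrelationResult",
    "neighbourhood",
    "neighbourhood_score",
    "neighbourhood_score_table",
    "assign_spot_mp",
    "mp_tme_correlation",
]

_MOORE_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
# Visium array coordinates: odd rows are offset, neighbours differ by 2 in col
_HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))

_WEIGHT_SUM_TOL = 1e-9


@dataclass
class SpotGrid:
    """One spatial slide.

    Parameters
    ----------
    spots
        DataFrame indexed by spot id with integer columns ``row``, ``col``
        and boolean column ``is_tumour``.  (row, col) pairs must be unique.
    weights
        Per-spot cell-type deconvolution weights (spots x cell types),
        non-negative with per-spot sums <= 1.
    spot_scores
        Optional per-spot signature scores (spots x signatures), e.g. MP
        module scores filled in by :func:`assign_spot_mp`.
    mp_labels
        Optional per-spot MP label for tumour spots ("unresolved" allowed);
        non-tumour spots are absent or NaN.
    expression
        Optional spots x genes count matrix (AnnData) used to score MPs.
    """

    spots: pd.DataFrame
    weights: pd.DataFrame
    spot_scores: pd.DataFrame | None = None
    mp_labels: pd.Series | None = None
    expression: AnnData | None = None
    slide_id: str = "slide"
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"row", "col", "is_tumour"}
        if not required.issubset(self.spots.columns):
            raise ValueError(f"spots table needs columns {sorted(required)}")
        pos = list(zip(self.spots["row"].astype(int), self.spots["col"].astype(int)))
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate (row, col) spot positions")
        if not self.weights.index.equals(self.spots.index):
            self.weights = self.weights.reindex(self.spots.index)
        w = self.weights.to_numpy(dtype=float)
        if np.any(w < 0):
            raise ValueError("cell-type weights must be non-negative")
        if np.any(w.sum(axis=1) > 1.0 + _WEIGHT_SUM_TOL):
            raise ValueError("per-spot cell-type weights must sum to <= 1")
        self._pos = dict(zip(pos, self.spots.index))

    @property
    def tumour_spots(self) -> pd.Index:
        return self.spots.index[self.spots["is_tumour"].astype(bool)]

    def position_of(self, spot_id) -> tuple[int, int]:
        row = self.spots.loc[spot_id]
        return int(row["row"]), int(row["col"])


def neighbourhood(grid: SpotGrid, spot_id, hex_mode: bool = False) -> list:
    """Spot ids adjacent to ``spot_id`` (the spot itself excluded).

    Square lattice: the 8 Moore neighbours; interior spots have exactly 8,
    edges 5, corners 3.  ``hex_mode`` uses the 6 hexagonal neighbours of
    Visium array coordinates instead.
    """
    if spot_id not in self_index(grid):
        raise KeyError(f"unknown spot {spot_id!r}")
    r, c = grid.position_of(spot_id)
    offsets = _HEX_OFFSETS if hex_mode else _MOORE_OFFSETS
    out = []
    for dr, dc in offsets:
        hit = grid._pos.get((r + dr, c + dc))
        if hit is not None:
            out.append(hit)
    return out


def self_index(grid: SpotGrid) -> pd.Index:
    return grid.spots.index


def _column_series(grid: SpotGrid, column: str) -> pd.Series:
    if column in grid.weights.columns:
        return grid.weights[column]
    if grid.spot_scores is not None and column in grid.spot_scores.columns:
        return grid.spot_scores[column]
    raise KeyError(f"column {column!r} found in neither weights nor spot scores")


def neighbourhood_score(
    grid: SpotGrid, spot_id, column: str, hex_mode: bool = False
) -> float:
    """Sum of ``column`` (a cell-type weight or signature score) over the
    spots adjacent to tumour spot ``spot_id``."""
    if not bool(grid.spots.loc[spot_id, "is_tumour"]):
        raise ValueError(f"spot {spot_id!r} is not a tumour spot")
    values = _column_series(grid, column)
    neigh = neighbourhood(grid, spot_id, hex_mode=hex_mode)
    if not neigh:
        return 0.0
    return float(values.loc[neigh].sum())


def neighbourhood_score_table(
    grid: SpotGrid,
    columns: Sequence[str] | None = None,
    hex_mode: bool = False,
) -> pd.DataFrame:
    """Neighbourhood scores for every tumour spot (rows) x column.

    ``columns`` defaults to all cell-type weight columns.
    """
    if columns is None:
        columns = list(grid.weights.columns)
    tumour = grid.tumour_spots
    data = np.zeros((len(tumour), len(columns)))
    series = {c: _column_series(grid, c) for c in columns}
    for i, s in enumerate(tumour):
        neigh = neighbourhood(grid, s, hex_mode=hex_mode)
        for j, c in enumerate(columns):
            data[i, j] = series[c].loc[neigh].sum() if neigh else 0.0
    return pd.DataFrame(data, index=tumour, columns=list(columns))


def assign_spot_mp(
    grid: SpotGrid,
    mps: Sequence,
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SpotGrid:
    """Score each spot against every MP and label tumour spots arg-max.

    MP scores are bin-matched control signature scores computed on the
    grid's expression matrix (see :func:`mpith.assign.signature_score`).
    Ties go to the first MP in input order.  Tumour spots with no scoreable
    MP (no MP genes present) are labelled ``"unresolved"`` with a warning.
    Non-tumour spots receive scores but no label.
    """
    from mpith.assign import signature_score

    if grid.expression is None:
        raise ValueError("grid carries no expression matrix to score")
    cols = {}
    for mp in mps:
        mp_id = getattr(mp, "mp_id", None) or getattr(mp, "program_id")
        genes = set(mp.genes) & set(grid.expression.var_names)
        if not genes:
            warnings.warn(f"MP {mp_id} has no genes in the slide; skipped")
            continue
        cols[mp_id] = signature_score(
            grid.expression, mp.genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
        )
    tumour = grid.tumour_spots
    if not cols:
        warnings.warn("no MP scoreable on this slide; all tumour spots unresolved")
        scores = pd.DataFrame(index=grid.spots.index)
        labels = pd.Series("unresolved", index=tumour, name="mp_label")
    else:
        scores = pd.DataFrame(cols)
        # first-column tie break comes from argmax on the input order
        arg = scores.loc[tumour].to_numpy().argmax(axis=1)
        labels = pd.Series(
            [scores.columns[j] for j in arg], index=tumour, name="mp_label"
        )
    return SpotGrid(
        spots=grid.spots,
        weights=grid.weights,
        spot_scores=scores,
        mp_labels=labels,
        expression=grid.expression,
        slide_id=grid.slide_id,
    )


@dataclass
class CorrelationResult:
    """Pooled and per-slide Pearson correlations between MP scores at tumour
    spots and neighbourhood scores of TME columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    per_slide: Mapping[str, pd.DataFrame]
    n_spots: int


def mp_tme_correlation(
    grids: Iterable[SpotGrid],
    mp_columns: Sequence[str] | None = None,
    target_columns: Sequence[str] | None = None,
    hex_mode: bool = False,
) -> CorrelationResult:
    """Pearson correlation of MP score vs neighbourhood score, pooled
    across slides.

    For every (MP, target) pair the MP score at each tumour spot is paired
    with the target's neighbourhood score at that spot; pairs are pooled
    over all slides (no per-slide standardisation) and the Pearson r and
    two-sided p-value computed.  Per-slide matrices are also returned.
    Zero-variance series yield NaN with a warning rather than a silent 0.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no slides supplied")
    if mp_columns is None:
        if grids[0].spot_scores is None:
            raise ValueError("slides carry no spot scores; run assign_spot_mp first")
        mp_columns = list(grids[0].spot_scores.columns)
    if target_columns is None:
        target_columns = list(grids[0].weights.columns)

    pooled_x: dict[str, list[np.ndarray]] = {m: [] for m in mp_columns}
    pooled_y: dict[str, list[np.ndarray]] = {t: [] for t in target_columns}
    per_slide: dict[str, pd.DataFrame] = {}
    total = 0
    for grid in grids:
        tumour = grid.tumour_spots
        total += len(tumour)
        ntab = neighbourhood_score_table(grid, target_columns, hex_mode=hex_mode)
        smat = grid.spot_scores.loc[tumour, mp_columns]
        r_slide = pd.DataFrame(index=mp_columns, columns=target_columns, dtype=float)
        for m in mp_columns:
            x = smat[m].to_numpy(dtype=float)
            pooled_x[m].append(x)
            for t in target_columns:
                y = ntab[t].to_numpy(dtype=float)
                r_slide.loc[m, t] = _pearson(x, y)[0]
        for t in target_columns:
            pooled_y[t].append(ntab[t].to_numpy(dtype=float))
        per_slide[grid.slide_id] = r_slide

    if total < 3:
        raise ValueError("need at least 3 pooled tumour spots")
    r = pd.DataFrame(index=mp_columns, columns=target_columns, dtype=float)
    p = pd.DataFrame(index=mp_columns, columns=target_columns, dtype=float)
    for m in mp_columns:
        x = np.concatenate(pooled_x[m])
        for t in target_columns:
            y = np.concatenate(pooled_y[t])
            r.loc[m, t], p.loc[m, t] = _pearson(x, y)
    return CorrelationResult(r=r, p=p, per_slide=per_slide, n_spots=total)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3:
        return float("nan"), float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance series in correlation; returning NaN")
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
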