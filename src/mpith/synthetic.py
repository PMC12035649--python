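"""Synthetic multi-sample cohorts and spatial slides with planted truth.

The generator states a simple, fully seeded world:

* **Cohorts** — each sample is a genes x cells negative-binomial count
  matrix.  A *planted program* is a fixed gene set; each cell is
  independently active for each program carried by its sample
  (Bernoulli ``activity_rate``), and the NB mean of the program's genes is
  multiplied by ``effect_size`` in active cells.  Shared programs are
  carried by every sample; private programs by one sample only.  The
  default world is 8 samples x 300 cells, 600 genes, three disjoint shared
  50-gene programs with effect size 8 and activity rate 0.2 — strong,
  recurrent co-expression modules on overdispersed droplet-like noise.

* **Slides** — a square lattice of spots.  Each planted MP has a smooth
  spatial activity field in [0, 1] (box-smoothed white noise, so
  neighbouring spots have correlated activity).  Per-spot cell-type
  weights are a Dirichlet draw whose concentration for an associated cell
  type is shifted by ``slope x activity``; spot expression is NB with MP
  genes boosted by the local activity on tumour spots.

Identical configs and seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.ndimage import uniform_filter

from mpith.spatial import SpotGrid

__all__ = [
    "PlantedProgram",
    "CohortConfig",
    "SpatialConfig",
    "simulate_cohort",
    "simulate_spatial",
    "default_cohort_config",
    "default_spatial_config",
    "gene_universe",
]


def gene_universe(n_genes: int) -> list[str]:
    """Canonical gene ids g0000, g0001, ... used by the generator."""
    return [f"g{i:04d}" for i in range(n_genes)]


@dataclass(frozen=True)
class PlantedProgram:
    """A planted co-expression program: a gene set that is jointly boosted
    in cells (or spots) where the program is active.

    ``effect_size`` multiplies the NB mean of every program gene in active
    cells; ``activity_rate`` is the fraction of cells active for it.
    """

    program_id: str
    genes: tuple[str, ...]
    activity_rate: float = 0.2
    effect_size: float = 8.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"program {self.program_id}: empty gene set")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"program {self.program_id}: duplicate genes")
        if not 0 < self.activity_rate <= 1:
            raise ValueError(f"program {self.program_id}: activity_rate must be in (0, 1]")
        if self.effect_size <= 0:
            raise ValueError(f"program {self.program_id}: effect_size must be > 0")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass(frozen=True)
class CohortConfig:
    """World description for :func:`simulate_cohort`.

    Counts are NB with mean ``baseline_mean`` per gene and size parameter
    ``dispersion`` (variance = mu + mu^2 / dispersion).  Shared programs
    are planted in every sample; ``private_programs`` maps sample id to
    programs planted only there.
    """

    n_samples: int = 8
    n_genes: int = 600
    cells_per_sample: int = 300
    shared_programs: tuple[PlantedProgram, ...] = ()
    private_programs: Mapping[str, tuple[PlantedProgram, ...]] = field(
        default_factory=dict
    )
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.cells_per_sample < 1:
            raise ValueError("n_samples, n_genes and cells_per_sample must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        universe = set(gene_universe(self.n_genes))
        seen: set[str] = set()
        for p in self.shared_programs:
            if seen & p.gene_set:
                raise ValueError(
                    f"shared program {p.program_id} overlaps another shared program"
                )
            seen |= p.gene_set
        all_programs = list(self.shared_programs)
        for progs in self.private_programs.values():
            all_programs.extend(progs)
        planted = set().union(*(p.gene_set for p in all_programs)) if all_programs else set()
        if not planted <= universe:
            raise ValueError("planted genes must lie inside the gene universe")
        ids = [p.program_id for p in all_programs]
        if len(set(ids)) != len(ids):
            raise ValueError("program ids must be unique")
        unknown = set(self.private_programs) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"private_programs keys not in cohort: {sorted(unknown)}")


def default_cohort_config(
    seed: int = 0,
    n_samples: int = 8,
    n_genes: int = 600,
    cells_per_sample: int = 300,
    n_shared: int = 3,
    program_size: int = 50,
    effect_size: float = 8.0,
    activity_rate: float = 0.2,
    baseline_mean: float = 1.0,
    dispersion: float = 2.0,
) -> CohortConfig:
    """The stated default world: disjoint shared programs occupying the
    first ``n_shared * program_size`` genes of the universe."""
    genes = gene_universe(n_genes)
    if n_shared * program_size > n_genes:
        raise ValueError("gene universe too small for the requested programs")
    shared = tuple(
        PlantedProgram(
            program_id=f"P{i + 1}",
            genes=tuple(genes[i * program_size : (i + 1) * program_size]),
            activity_rate=activity_rate,
            effect_size=effect_size,
        )
        for i in range(n_shared)
    )
    return CohortConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        cells_per_sample=cells_per_sample,
        shared_programs=shared,
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with size (shape) theta: var = mu + mu^2/theta
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_cohort(config: CohortConfig) -> tuple[list[AnnData], pd.DataFrame]:
    """Simulate one cohort; returns (samples, ground-truth table).

    Each sample is an AnnData with raw counts in ``X`` (cells x genes,
    CSR), ``obs['sample_id']`` and ``obs['malignant']`` (all True), and
    ``uns['sample_id']``.  The ground-truth table has one row per cell and
    one boolean column per planted program id.
    """
    config.validate()
    genes = gene_universe(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    children = np.random.SeedSequence(config.seed).spawn(config.n_samples)

    all_program_ids: list[str] = [p.program_id for p in config.shared_programs]
    for sid in config.sample_ids:
        for p in config.private_programs.get(sid, ()):
            all_program_ids.append(p.program_id)

    samples: list[AnnData] = []
    truth_rows: list[pd.DataFrame] = []
    for i, sid in enumerate(config.sample_ids):
        rng = np.random.default_rng(children[i])
        programs = list(config.shared_programs) + list(
            config.private_programs.get(sid, ())
        )
        n_cells = config.cells_per_sample
        active = np.zeros((n_cells, len(programs)), dtype=bool)
        for j, p in enumerate(programs):
            active[:, j] = rng.random(n_cells) < p.activity_rate
        mult = np.ones((n_cells, config.n_genes))
        for j, p in enumerate(programs):
            idx = [gene_pos[g] for g in p.genes]
            mult[np.ix_(active[:, j], idx)] *= p.effect_size
        mean = config.baseline_mean * mult
        counts = _nb_draw(rng, mean, config.dispersion)

        cell_ids = [f"{sid}_c{j:04d}" for j in range(n_cells)]
        obs = pd.DataFrame(
            {"sample_id": sid, "malignant": True}, index=pd.Index(cell_ids, name="cell_id")
        )
        adata = AnnData(
            X=sparse.csr_matrix(counts),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
        )
        adata.uns["sample_id"] = sid
        samples.append(adata)

        tr = pd.DataFrame(
            {pid: False for pid in all_program_ids},
            index=pd.Index(cell_ids, name="cell_id"),
        )
        for j, p in enumerate(programs):
            tr[p.program_id] = active[:, j]
        tr.insert(0, "sample_id", sid)
        truth_rows.append(tr)

    truth = pd.concat(truth_rows)
    return samples, truth


@dataclass(frozen=True)
class SpatialConfig:
    """World description for :func:`simulate_spatial`.

    ``association`` lists (mp_id, cell_type, slope) triples: the Dirichlet
    concentration of that cell type at a spot is ``base_concentration +
    slope * activity(mp, spot)``.  ``tumour_region`` may be a
    ``(row, col) -> bool`` predicate; by default spots at least
    ``tumour_margin`` away from every border are tumour.
    """

    n_rows: int = 40
    n_cols: int = 40
    cell_types: tuple[str, ...] = (
        "fibroblast",
        "t_cell",
        "b_cell",
        "macrophage",
        "endothelial",
    )
    mp_programs: tuple[PlantedProgram, ...] = ()
    association: tuple[tuple[str, str, float], ...] = ()
    tumour_region: Callable[[int, int], bool] | None = None
    tumour_margin: int = 4
    n_genes: int = 300
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    base_concentration: float = 2.0
    seed: int = 0

    def is_tumour(self, row: int, col: int) -> bool:
        if self.tumour_region is not None:
            return bool(self.tumour_region(row, col))
        m = self.tumour_margin
        return m <= row < self.n_rows - m and m <= col < self.n_cols - m

    def validate(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3x3 (needs an interior spot)")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell types must be unique")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be > 0")
        mp_ids = {p.program_id for p in self.mp_programs}
        universe = set(gene_universe(self.n_genes))
        for p in self.mp_programs:
            if not p.gene_set <= universe:
                raise ValueError(f"MP {p.program_id} genes outside the universe")
        for mp_id, ct, slope in self.association:
            if mp_id not in mp_ids:
                raise ValueError(f"association references unknown MP {mp_id!r}")
            if ct not in self.cell_types:
                raise ValueError(f"association references unknown cell type {ct!r}")
            if not np.isfinite(slope):
                raise ValueError("association slope must be finite")


def default_spatial_config(
    seed: int = 0,
    n_rows: int = 40,
    n_cols: int = 40,
    n_mps: int = 2,
    program_size: int = 50,
    slope: float = 6.0,
    n_genes: int = 300,
    effect_size: float = 8.0,
) -> SpatialConfig:
    """Default slide: two planted MPs on a 40x40 grid, the first positively
    associated with fibroblasts (Dirichlet slope 6), the second null."""
    genes = gene_universe(n_genes)
    mps = tuple(
        PlantedProgram(
            program_id=f"MP{i + 1}",
            genes=tuple(genes[i * program_size : (i + 1) * program_size]),
            effect_size=effect_size,
            activity_rate=1.0,
        )
        for i in range(n_mps)
    )
    return SpatialConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        mp_programs=mps,
        association=(("MP1", "fibroblast", slope),),
        n_genes=n_genes,
        seed=seed,
    )


def simulate_spatial(config: SpatialConfig) -> tuple[SpotGrid, pd.DataFrame]:
    """Simulate one slide; returns (grid, ground truth).

    Ground truth has one row per spot with its position, tumour flag and
    the planted activity of every MP (smooth field in [0, 1]).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    nr, nc = config.n_rows, config.n_cols
    genes = gene_universe(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # smooth activity field per MP: box-filtered white noise, min-max scaled
    activity: dict[str, np.ndarray] = {}
    for p in config.mp_programs:
        raw = rng.random((nr, nc))
        smooth = uniform_filter(raw, size=3, mode="nearest")
        lo, hi = smooth.min(), smooth.max()
        activity[p.program_id] = (smooth - lo) / (hi - lo) if hi > lo else smooth * 0.0

    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    spot_ids = [f"s{r:03d}_{c:03d}" for r, c in zip(rows, cols)]
    is_tumour = np.array([config.is_tumour(r, c) for r, c in zip(rows, cols)])

    # Dirichlet weights with association-shifted concentrations
    alphas = np.full((len(spot_ids), len(config.cell_types)), config.base_concentration)
    ct_pos = {c: i for i, c in enumerate(config.cell_types)}
    for mp_id, ct, slope in config.association:
        alphas[:, ct_pos[ct]] += slope * activity[mp_id][rows, cols]
    alphas = np.maximum(alphas, 1e-3)
    gam = rng.gamma(shape=alphas)
    weights = gam / gam.sum(axis=1, keepdims=True)

    # expression: MP genes boosted proportionally to local activity on tumour spots
    mean = np.full((len(spot_ids), config.n_genes), config.baseline_mean)
    for p in config.mp_programs:
        act = activity[p.program_id][rows, cols] * is_tumour
        idx = [gene_pos[g] for g in p.genes]
        mean[:, idx] *= 1.0 + (p.effect_size - 1.0) * act[:, None]
    counts = _nb_draw(rng, mean, config.dispersion)

    index = pd.Index(spot_ids, name="spot_id")
    spots = pd.DataFrame({"row": rows, "col": cols, "is_tumour": is_tumour}, index=index)
    wdf = pd.DataFrame(weights, index=index, columns=list(config.cell_types))
    expr = AnnData(
        X=sparse.csr_matrix(counts),
        obs=spots.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    grid = SpotGrid(spots=spots, weights=wdf, expression=expr, slide_id=f"slide{config.seed}")

    truth = spots.copy()
    for p in config.mp_programs:
        truth[f"activity_{p.program_id}"] = activity[p.program_id][rows, cols]
    return grid, truth
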