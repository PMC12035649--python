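"""Readers and writers for the pipeline's on-disk formats.

Samples travel as Matrix Market triplets (genes x cells ``matrix.mtx``)
with ``genes.tsv`` / ``barcodes.tsv`` sidecars plus an ``obs.tsv`` holding
per-cell metadata (sample id, malignant flag).  Programs and MP membership
are TSVs; gene signatures are GMT; spatial slides are a spots TSV (id,
row, col, tumour flag, one column per cell-type weight) with an optional
expression triplet.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from mpith.cluster import MetaProgram
from mpith.nmf import NMFProgram
from mpith.spatial import SpotGrid

__all__ = [
    "write_sample",
    "read_sample",
    "write_gmt",
    "read_gmt",
    "programs_to_table",
    "programs_from_table",
    "write_programs",
    "read_programs",
    "write_spot_grid",
    "read_spot_grid",
    "mps_to_gmt",
]


# ---------------------------------------------------------------- samples


def write_sample(adata: AnnData, outdir: str | Path) -> Path:
    """Write a sample as matrix.mtx (genes x cells) + genes/barcodes/obs TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(outdir / "obs.tsv", sep="\t")
    return outdir


def read_sample(indir: str | Path, sample_id: str | None = None) -> AnnData:
    """Read a sample written by :func:`write_sample`."""
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs_path = indir / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    else:
        obs = pd.DataFrame(index=barcodes)
    adata = AnnData(
        X=X,
        obs=obs.loc[barcodes],
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if sample_id is None and "sample_id" in adata.obs:
        sample_id = str(adata.obs["sample_id"].iloc[0])
    adata.uns["sample_id"] = sample_id or indir.name
    return adata


# -------------------------------------------------------------------- GMT


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *list(genes)]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


def mps_to_gmt(mps: Sequence[MetaProgram], path: str | Path) -> Path:
    return write_gmt({mp.mp_id: mp.genes for mp in mps}, path)


# --------------------------------------------------------------- programs


def programs_to_table(programs: Sequence[NMFProgram]) -> pd.DataFrame:
    rows = []
    for p in programs:
        for rank, g in enumerate(p.genes):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "rank_k": p.rank_k,
                    "factor_index": p.factor_index,
                    "gene": g,
                    "weight": p.weights[g],
                    "gene_rank": rank,
                }
            )
    return pd.DataFrame(rows)


def programs_from_table(df: pd.DataFrame) -> list[NMFProgram]:
    programs = []
    for (sid, k, j), grp in df.groupby(
        ["sample_id", "rank_k", "factor_index"], sort=True
    ):
        grp = grp.sort_values("gene_rank")
        genes = tuple(grp["gene"].astype(str))
        weights = dict(zip(genes, grp["weight"].astype(float)))
        programs.append(
            NMFProgram(
                sample_id=str(sid),
                rank_k=int(k),
                factor_index=int(j),
                genes=genes,
                weights=weights,
            )
        )
    return programs


def write_programs(programs: Sequence[NMFProgram], path: str | Path) -> Path:
    path = Path(path)
    programs_to_table(programs).to_csv(path, sep="\t", index=False)
    return path


def read_programs(path: str | Path) -> list[NMFProgram]:
    return programs_from_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------- spatial


def write_spot_grid(grid: SpotGrid, outdir: str | Path) -> Path:
    """Write spots+weights TSV, optional scores TSV and expression triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = grid.spots.join(grid.weights)
    table.to_csv(outdir / "spots.tsv", sep="\t")
    meta = {"slide_id": grid.slide_id, "cell_types": list(grid.weights.columns)}
    (outdir / "slide.json").write_text(json.dumps(meta, indent=1))
    if grid.spot_scores is not None:
        grid.spot_scores.to_csv(outdir / "spot_scores.tsv", sep="\t")
    if grid.mp_labels is not None:
        grid.mp_labels.to_frame().to_csv(outdir / "mp_labels.tsv", sep="\t")
    if grid.expression is not None:
        write_sample(grid.expression, outdir / "expression")
    return outdir


def read_spot_grid(indir: str | Path) -> SpotGrid:
    indir = Path(indir)
    table = pd.read_csv(indir / "spots.tsv", sep="\t", index_col=0)
    meta = json.loads((indir / "slide.json").read_text())
    cell_types = meta["cell_types"]
    spots = table[["row", "col", "is_tumour"]].copy()
    spots["is_tumour"] = spots["is_tumour"].astype(bool)
    weights = table[cell_types]
    scores = None
    if (indir / "spot_scores.tsv").exists():
        scores = pd.read_csv(indir / "spot_scores.tsv", sep="\t", index_col=0)
    labels = None
    if (indir / "mp_labels.tsv").exists():
        labels = pd.read_csv(indir / "mp_labels.tsv", sep="\t", index_col=0)[
            "mp_label"
        ]
    expression = None
    if (indir / "expression").exists():
        expression = read_sample(indir / "expression")
    return SpotGrid(
        spots=spots,
        weights=weights,
        spot_scores=scores,
        mp_labels=labels,
        expression=expression,
        slide_id=meta.get("slide_id", indir.name),
    )
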