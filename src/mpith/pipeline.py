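"""End-to-end orchestration: simulate -> QC -> programs -> robust ->
cluster -> assign -> spatial score -> correlate, with one JSON config, a
line-delimited JSON log and a manifest of artifact hashes.

Per-stage seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence`` spawn keys, so a rerun with the same config
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from mpith import io as mio
from mpith.assign import assign_cells, mp_module_scores, score_cells
from mpith.cluster import cluster_all
from mpith.nmf import extract_programs
from mpith.preprocess import (
    normalize_for_nmf,
    qc_filter_cells,
    qc_filter_genes,
    qc_filter_samples,
)
from mpith.robust import ProgramSet, frac_to_count, select_robust
from mpith.spatial import assign_spot_mp, mp_tme_correlation, neighbourhood_score_table
from mpith.synthetic import (
    CohortConfig,
    PlantedProgram,
    SpatialConfig,
    default_cohort_config,
    default_spatial_config,
    simulate_cohort,
    simulate_spatial,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def _program_to_dict(p: PlantedProgram) -> dict:
    return {
        "program_id": p.program_id,
        "genes": list(p.genes),
        "activity_rate": p.activity_rate,
        "effect_size": p.effect_size,
    }


def _program_from_dict(d: dict) -> PlantedProgram:
    return PlantedProgram(
        program_id=d["program_id"],
        genes=tuple(d["genes"]),
        activity_rate=float(d.get("activity_rate", 0.2)),
        effect_size=float(d.get("effect_size", 8.0)),
    )


def cohort_config_to_dict(c: CohortConfig) -> dict:
    d = dataclasses.asdict(c)
    d["shared_programs"] = [_program_to_dict(p) for p in c.shared_programs]
    d["private_programs"] = {
        sid: [_program_to_dict(p) for p in progs]
        for sid, progs in c.private_programs.items()
    }
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["shared_programs"] = tuple(
        _program_from_dict(p) for p in d.get("shared_programs", [])
    )
    d["private_programs"] = {
        sid: tuple(_program_from_dict(p) for p in progs)
        for sid, progs in d.get("private_programs", {}).items()
    }
    return CohortConfig(**d)


def spatial_config_to_dict(c: SpatialConfig) -> dict:
    if c.tumour_region is not None:
        raise ValueError("callable tumour_region is not JSON-serialisable; use tumour_margin")
    d = dataclasses.asdict(c)
    d.pop("tumour_region")
    d["mp_programs"] = [_program_to_dict(p) for p in c.mp_programs]
    d["association"] = [list(t) for t in c.association]
    return d


def spatial_config_from_dict(d: dict) -> SpatialConfig:
    d = dict(d)
    d["mp_programs"] = tuple(_program_from_dict(p) for p in d.get("mp_programs", []))
    d["association"] = tuple(
        (str(m), str(ct), float(s)) for m, ct, s in d.get("association", [])
    )
    d["cell_types"] = tuple(d.get("cell_types", SpatialConfig.cell_types))
    return SpatialConfig(**d)


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run.

    Defaults reproduce the reference workflow: rank range 4..9, top-50
    programs, robustness overlaps 70%/20%/30% of 50 (35/10/15 genes),
    founder rule 8 genes in > 5 cases, accretion at 10 genes, 50-gene MPs,
    conservation >= 25 genes, prevalence >= 5%.
    """

    cohort: CohortConfig = field(default_factory=default_cohort_config)
    spatial: SpatialConfig = field(default_factory=default_spatial_config)
    k_min: int = 4
    k_max: int = 9
    genes_per_program: int = 50
    min_features: int = 300
    max_counts: int = 7500
    min_cells_per_gene: int = 100
    min_malignant_cells: int = 200
    intra_frac: float = 0.70
    inter_frac: float = 0.20
    dedup_frac: float = 0.30
    founder_min_overlap: int = 8
    founder_min_cases: int = 5
    accrete_min_overlap: int = 10
    mp_size: int = 50
    min_genes_conserved: int = 25
    min_prevalence: float = 0.05
    n_bins: int = 30
    n_ctrl: int = 100
    module_bins: int = 24
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = cohort_config_to_dict(self.cohort)
        d["spatial"] = spatial_config_to_dict(self.spatial)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = cohort_config_from_dict(d["cohort"])
        if "spatial" in d:
            d["spatial"] = spatial_config_from_dict(d["spatial"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def __call__(self, stage: str, **kw: Any) -> None:
        rec = {"stage": stage, **kw}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on the configured synthetic world; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "log.jsonl")
    artifacts: list[Path] = []
    t0 = time.time()

    def track(p: Path) -> None:
        if p.is_dir():
            artifacts.extend(sorted(q for q in p.rglob("*") if q.is_file()))
        else:
            artifacts.append(p)

    # 1. simulate ---------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, 0))
    samples, truth = simulate_cohort(cohort_cfg)
    truth_path = outdir / "cohort_truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    track(truth_path)
    for s in samples:
        track(mio.write_sample(s, outdir / "samples" / s.uns["sample_id"]))
    log("simulate_cohort", n_samples=len(samples), seed=cohort_cfg.seed)

    # 2. QC + normalisation ----------------------------------------------
    qcd = []
    for s in samples:
        s = qc_filter_cells(s, config.min_features, config.max_counts)
        s = qc_filter_genes(s, config.min_cells_per_gene)
        qcd.append(s)
    qcd = qc_filter_samples(qcd, config.min_malignant_cells)
    for s in qcd:
        normalize_for_nmf(s)
    log("qc", kept_samples=[s.uns["sample_id"] for s in qcd],
        cells=[int(s.n_obs) for s in qcd], genes=[int(s.n_vars) for s in qcd])

    # 3. per-sample NMF programs -----------------------------------------
    nmf_seed = stage_seed(config.seed, 1)
    programs = []
    for s in qcd:
        programs.extend(
            extract_programs(
                s,
                k_range=range(config.k_min, config.k_max + 1),
                genes_per_program=config.genes_per_program,
                seed=nmf_seed,
            )
        )
    prog_path = mio.write_programs(programs, outdir / "programs.tsv")
    track(prog_path)
    log("nmf_programs", n_programs=len(programs), seed=nmf_seed)

    # 4. robustness filter -----------------------------------------------
    size = config.genes_per_program
    robust = select_robust(
        ProgramSet(programs),
        intra_min_overlap=frac_to_count(config.intra_frac, size),
        inter_min_overlap=frac_to_count(config.inter_frac, size),
        dedup_max_overlap=frac_to_count(config.dedup_frac, size),
    )
    robust_path = mio.write_programs(list(robust), outdir / "robust_programs.tsv")
    track(robust_path)
    log("robust_filter", n_robust=len(robust))

    # 5. meta-program clustering -----------------------------------------
    mps, unassigned, audit = cluster_all(
        robust,
        founder_min_overlap=config.founder_min_overlap,
        min_cases=config.founder_min_cases,
        accrete_min_overlap=config.accrete_min_overlap,
        size=config.mp_size,
    )
    gmt_path = mio.mps_to_gmt(mps, outdir / "meta_programs.gmt")
    track(gmt_path)
    audit_path = outdir / "cluster_audit.tsv"
    audit.to_csv(audit_path, sep="\t", index=False)
    track(audit_path)
    membership = pd.DataFrame(
        [
            {"mp_id": mp.mp_id, "sample_id": m.sample_id, "rank_k": m.rank_k,
             "factor_index": m.factor_index}
            for mp in mps
            for m in mp.members
        ]
    )
    memb_path = outdir / "mp_members.tsv"
    membership.to_csv(memb_path, sep="\t", index=False)
    track(memb_path)
    log("mp_cluster", n_mps=len(mps), n_unassigned=len(unassigned))

    # 6. per-cell assignment ---------------------------------------------
    assign_seed = stage_seed(config.seed, 2)
    label_frames = []
    if mps:
        for s in qcd:
            sid = s.uns["sample_id"]
            scores = score_cells(
                s, mps,
                min_genes_conserved=config.min_genes_conserved,
                n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=assign_seed,
            )
            ca = assign_cells(scores, config.min_prevalence, sample_id=sid)
            module = mp_module_scores(
                s, mps, n_bins=config.module_bins, n_ctrl=config.n_ctrl,
                seed=assign_seed,
            )
            sdir = outdir / "assignment" / sid
            sdir.mkdir(parents=True, exist_ok=True)
            scores.to_csv(sdir / "scores.tsv", sep="\t")
            module.to_csv(sdir / "module_scores.tsv", sep="\t")
            lab = ca.labels.to_frame()
            lab.insert(0, "sample_id", sid)
            lab.to_csv(sdir / "labels.tsv", sep="\t")
            track(sdir)
            label_frames.append(lab)
        log("cell_assign", seed=assign_seed,
            n_labelled=int(sum(len(f) for f in label_frames)))
    else:
        log("cell_assign", skipped="no meta-programs emitted")

    # 7. spatial -----------------------------------------------------------
    spatial_cfg = dataclasses.replace(config.spatial, seed=stage_seed(config.seed, 3))
    grid, spatial_truth = simulate_spatial(spatial_cfg)
    st_path = outdir / "spatial_truth.tsv"
    spatial_truth.to_csv(st_path, sep="\t")
    track(st_path)
    # fall back to the planted spatial signatures if clustering emitted none
    spot_mps = mps if mps else list(spatial_cfg.mp_programs)
    grid = assign_spot_mp(
        grid, spot_mps, n_bins=config.n_bins, n_ctrl=config.n_ctrl,
        seed=stage_seed(config.seed, 4),
    )
    ntab = neighbourhood_score_table(grid)
    corr = mp_tme_correlation([grid])
    sdir = mio.write_spot_grid(grid, outdir / "spatial")
    track(sdir)
    ntab_path = outdir / "neighbourhood_scores.tsv"
    ntab.to_csv(ntab_path, sep="\t")
    track(ntab_path)
    corr_path = outdir / "mp_tme_correlation.tsv"
    corr.r.to_csv(corr_path, sep="\t")
    track(corr_path)
    corr_p_path = outdir / "mp_tme_correlation_pvalues.tsv"
    corr.p.to_csv(corr_p_path, sep="\t")
    track(corr_p_path)
    log("spatial", n_tumour_spots=int(corr.n_spots))

    # manifest -------------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "runtime_s": round(time.time() - t0, 2),
        "n_meta_programs": len(mps),
        "files": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log("done", n_files=len(manifest["files"]))
    return manifest


def assign_spot_mp_from_sets(grid, gene_sets: dict, n_bins=30, n_ctrl=100, seed=0):
    """assign_spot_mp over plain gene sets (used when no MP objects exist)."""
    from types import SimpleNamespace

    mps = [SimpleNamespace(mp_id=k, genes=tuple(v)) for k, v in gene_sets.items()]
    return assign_spot_mp(grid, mps, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
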