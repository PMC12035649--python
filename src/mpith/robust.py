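"""Robustness filtering of per-sample NMF programs.

A program is *robust* when it (1) recurs within its own sample — at least
70% gene overlap (35/50 genes) with a program of a different rank K in the
same sample; (2) recurs across samples — at least 20% overlap (10/50) with
some program of another sample; and (3) survives within-sample
de-duplication — among the survivors of (1)-(2), same-sample programs
overlapping a retained program by more than 30% (15/50 genes) are dropped,
processing candidates in order of decreasing maximal inter-sample overlap
(the more cross-sample-supported program survives).

Thresholds are expressed as gene counts against the fixed program size
(default 50); helper :func:`frac_to_count` converts fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from mpith.nmf import NMFProgram

__all__ = [
    "ProgramSet",
    "overlap",
    "passes_intra_sample",
    "passes_inter_sample",
    "deduplicate_within_sample",
    "select_robust",
    "frac_to_count",
]


def frac_to_count(frac: float, program_size: int = 50) -> int:
    """Gene-count threshold for a fractional overlap of ``program_size``."""
    return int(math.ceil(frac * program_size - 1e-9))


@dataclass
class ProgramSet:
    """A pool of NMF programs with a per-sample index.

    Duplicate (sample_id, rank_k, factor_index) keys are rejected.
    ``universe`` records the candidate pool a filtered set was drawn from,
    so the recurrence criteria stay anchored to the original pool when a
    filter output is filtered again (this is what makes
    :func:`select_robust` idempotent).
    """

    programs: list[NMFProgram]
    universe: "ProgramSet | None" = field(default=None, repr=False, compare=False)
    index: dict[str, list[NMFProgram]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        keys = [p.key for p in self.programs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sample, K, factor) program keys")
        self.index = {}
        for p in self.programs:
            self.index.setdefault(p.sample_id, []).append(p)

    def __len__(self) -> int:
        return len(self.programs)

    def __iter__(self):
        return iter(self.programs)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.index)

    def by_sample(self, sample_id: str) -> list[NMFProgram]:
        return self.index.get(sample_id, [])


def overlap(a: NMFProgram, b: NMFProgram) -> int:
    """Number of genes shared by two programs (symmetric)."""
    if not a.genes or not b.genes:
        raise ValueError("overlap of empty program")
    return len(a.gene_set & b.gene_set)


def passes_intra_sample(
    p: NMFProgram, pool: ProgramSet, min_overlap: int = 35
) -> bool:
    """True iff some same-sample program of a *different* rank K overlaps
    ``p`` by at least ``min_overlap`` genes."""
    return any(
        q.rank_k != p.rank_k and overlap(p, q) >= min_overlap
        for q in pool.by_sample(p.sample_id)
        if q.key != p.key
    )


def passes_inter_sample(
    p: NMFProgram, pool: ProgramSet, min_overlap: int = 10
) -> bool:
    """True iff some program of *another* sample overlaps ``p`` by at least
    ``min_overlap`` genes.  Undefined (error) on a single-sample pool."""
    if len(pool.sample_ids) < 2:
        raise ValueError("inter-sample criterion undefined on a single-sample pool")
    return any(
        overlap(p, q) >= min_overlap
        for sid in pool.sample_ids
        if sid != p.sample_id
        for q in pool.by_sample(sid)
    )


def _max_inter_overlap(p: NMFProgram, programs: Sequence[NMFProgram]) -> int:
    other = [q for q in programs if q.sample_id != p.sample_id]
    return max((overlap(p, q) for q in other), default=0)


def deduplicate_within_sample(
    kept: Sequence[NMFProgram], max_overlap: int = 15
) -> list[NMFProgram]:
    """Greedy within-sample de-duplication.

    Candidates are processed in order of decreasing maximal inter-sample
    overlap (tie: lower rank K, then factor index); a candidate overlapping
    an already-retained same-sample program by more than ``max_overlap``
    genes is dropped.  Output preserves the input order.
    """
    kept = list(kept)
    support = {p.key: _max_inter_overlap(p, kept) for p in kept}
    retained: dict[str, list[NMFProgram]] = {}
    retained_keys: set[tuple] = set()
    order = sorted(kept, key=lambda p: (-support[p.key], p.rank_k, p.factor_index))
    for p in order:
        prior = retained.setdefault(p.sample_id, [])
        if all(overlap(p, q) <= max_overlap for q in prior):
            prior.append(p)
            retained_keys.add(p.key)
    return [p for p in kept if p.key in retained_keys]


def select_robust(
    pool: ProgramSet,
    intra_min_overlap: int = 35,
    inter_min_overlap: int = 10,
    dedup_max_overlap: int = 15,
) -> ProgramSet:
    """Apply the three robustness criteria; output is a subset of the pool.

    Recurrence criteria (1)-(2) are evaluated against the pool's original
    candidate universe, so re-filtering a filtered set changes nothing.
    """
    universe = pool.universe if pool.universe is not None else pool
    kept = [
        p
        for p in pool
        if passes_intra_sample(p, universe, intra_min_overlap)
        and passes_inter_sample(p, universe, inter_min_overlap)
    ]
    final = deduplicate_within_sample(kept, dedup_max_overlap)
    return ProgramSet(final, universe=universe)


def audit_table(
    pool: ProgramSet,
    intra_min_overlap: int = 35,
    inter_min_overlap: int = 10,
    dedup_max_overlap: int = 15,
) -> pd.DataFrame:
    """Per-program pass/fail audit of each criterion (for the TSV output)."""
    universe = pool.universe if pool.universe is not None else pool
    rows = []
    kept = []
    for p in pool:
        c1 = passes_intra_sample(p, universe, intra_min_overlap)
        c2 = passes_inter_sample(p, universe, inter_min_overlap)
        if c1 and c2:
            kept.append(p)
        rows.append(
            {
                "sample_id": p.sample_id,
                "rank_k": p.rank_k,
                "factor_index": p.factor_index,
                "intra_sample": c1,
                "inter_sample": c2,
            }
        )
    survivors = {p.key for p in deduplicate_within_sample(kept, dedup_max_overlap)}
    df = pd.DataFrame(rows)
    df["dedup"] = [
        (p.key in survivors) if (r["intra_sample"] and r["inter_sample"]) else False
        for p, (_, r) in zip(pool, df.iterrows())
    ]
    df["robust"] = df["intra_sample"] & df["inter_sample"] & df["dedup"]
    return df
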