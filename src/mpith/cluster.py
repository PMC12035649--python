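"""Founder clustering of robust programs into 50-gene meta-programs.

Robust programs are clustered by gene-set similarity.  A *founder* is the
program supported by the most other programs at >= 8 shared genes (a
cluster forms only when more than 5 such supporters exist).  The cluster
seeds with the founder and its highest-overlap partner; the meta-program
(MP) gene list is completed to 50 genes by ranking genes on (number of
member programs containing the gene, mean NMF weight, gene id).  Remaining
programs overlapping the current MP by >= 10 genes are accreted one at a
time (largest overlap first), recomputing the MP after every admission.
Founding and accretion repeat until no founder remains; leftovers are
reported as unassigned, never forced into a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from mpith.nmf import NMFProgram
from mpith.robust import ProgramSet, overlap

__all__ = [
    "MetaProgram",
    "jaccard",
    "find_founder",
    "complete_mp",
    "build_cluster",
    "cluster_all",
]


@dataclass(frozen=True)
class MetaProgram:
    """A consensus signature of exactly ``size`` genes (default 50) with
    the member programs that produced it."""

    mp_id: str
    genes: tuple[str, ...]
    members: tuple[NMFProgram, ...]
    founder: NMFProgram

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("MP genes must be distinct")
        if not self.members:
            raise ValueError("MP must have at least one member")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |A n B| / |A u B| of two gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard of an empty gene set is undefined")
    return len(a & b) / len(a | b)


def _order_key(p: NMFProgram) -> tuple:
    return (p.sample_id, p.rank_k, p.factor_index)


def find_founder(
    pool: ProgramSet, founder_min_overlap: int = 8, min_cases: int = 5
) -> NMFProgram | None:
    """The best-supported cluster founder, or None.

    A candidate needs more than ``min_cases`` other programs overlapping it
    by >= ``founder_min_overlap`` genes; the candidate with the most
    supporters wins (ties: larger mean supporter overlap, then sample/rank
    order).
    """
    if len(pool) == 0:
        return None
    best: tuple | None = None
    best_p: NMFProgram | None = None
    for p in pool:
        ovs = [
            overlap(p, q)
            for q in pool
            if q.key != p.key and overlap(p, q) >= founder_min_overlap
        ]
        if len(ovs) <= min_cases:
            continue
        key = (-len(ovs), -sum(ovs) / len(ovs)) + _order_key(p)
        if best is None or key < best:
            best, best_p = key, p
    return best_p


def complete_mp(members: Sequence[NMFProgram], size: int = 50) -> tuple[str, ...]:
    """Consensus gene list of a member set, completed to ``size`` genes.

    Genes rank by (#members containing the gene desc, mean NMF weight over
    those members desc, gene id asc).
    """
    if not members:
        raise ValueError("complete_mp needs at least one member")
    freq: dict[str, int] = {}
    wsum: dict[str, float] = {}
    for m in members:
        for g in m.genes:
            freq[g] = freq.get(g, 0) + 1
            wsum[g] = wsum.get(g, 0.0) + m.weights[g]
    if len(freq) < size:
        raise ValueError(
            f"member union has {len(freq)} genes; cannot complete to {size} "
            f"(short by {size - len(freq)})"
        )
    ranked = sorted(freq, key=lambda g: (-freq[g], -wsum[g] / freq[g], g))
    return tuple(ranked[:size])


def build_cluster(
    founder: NMFProgram,
    pool: ProgramSet,
    accrete_min_overlap: int = 10,
    founder_min_overlap: int = 8,
    size: int = 50,
    mp_id: str = "MP",
) -> tuple[MetaProgram, ProgramSet, list[dict]]:
    """Grow one cluster from ``founder``; returns (MP, remaining pool, audit).

    Seeds with the founder and its highest-overlap partner, then repeatedly
    admits the remaining program with the largest overlap (>= threshold)
    against the *current* MP genes, recomputing the MP after each admission.
    The audit lists each admission with the overlap at admission time.
    """
    if founder.key not in {p.key for p in pool}:
        raise ValueError("founder not in pool")
    others = [p for p in pool if p.key != founder.key]
    if not others:
        raise ValueError("founder has no potential partner in the pool")
    partner = min(
        others, key=lambda q: (-overlap(founder, q),) + _order_key(q)
    )
    if overlap(founder, partner) < founder_min_overlap:
        raise ValueError("founder has no partner with sufficient overlap")
    members: list[NMFProgram] = [founder, partner]
    audit = [
        {"member": founder.key, "overlap_at_admission": len(founder.genes)},
        {"member": partner.key, "overlap_at_admission": overlap(founder, partner)},
    ]
    mp_genes = complete_mp(members, size=size)
    member_keys = {m.key for m in members}
    remaining = [p for p in pool if p.key not in member_keys]
    while True:
        mp_set = set(mp_genes)
        scored = [(len(p.gene_set & mp_set), p) for p in remaining]
        eligible = [(ov, p) for ov, p in scored if ov >= accrete_min_overlap]
        if not eligible:
            break
        ov, nxt = min(eligible, key=lambda t: (-t[0],) + _order_key(t[1]))
        members.append(nxt)
        audit.append({"member": nxt.key, "overlap_at_admission": ov})
        remaining = [p for p in remaining if p.key != nxt.key]
        mp_genes = complete_mp(members, size=size)
    mp = MetaProgram(
        mp_id=mp_id, genes=mp_genes, members=tuple(members), founder=founder
    )
    return mp, ProgramSet(remaining), audit


def cluster_all(
    pool: ProgramSet,
    founder_min_overlap: int = 8,
    min_cases: int = 5,
    accrete_min_overlap: int = 10,
    size: int = 50,
) -> tuple[list[MetaProgram], list[NMFProgram], pd.DataFrame]:
    """Cluster a robust pool into meta-programs.

    Repeats founder selection and cluster growth until no founder remains.
    Every program ends up in exactly one MP or in the unassigned list; MPs
    are numbered MP1, MP2, ... in creation order, each with exactly
    ``size`` genes.
    """
    remaining = pool
    mps: list[MetaProgram] = []
    audit_rows: list[dict] = []
    while True:
        founder = find_founder(remaining, founder_min_overlap, min_cases)
        if founder is None:
            break
        mp_id = f"MP{len(mps) + 1}"
        mp, remaining, audit = build_cluster(
            founder,
            remaining,
            accrete_min_overlap=accrete_min_overlap,
            founder_min_overlap=founder_min_overlap,
            size=size,
            mp_id=mp_id,
        )
        mps.append(mp)
        for row in audit:
            audit_rows.append({"mp_id": mp_id, **row})
    audit_df = pd.DataFrame(
        audit_rows, columns=["mp_id", "member", "overlap_at_admission"]
    )
    return mps, list(remaining), audit_df
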