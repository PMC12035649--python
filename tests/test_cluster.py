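"""Founder selection, MP completion, accretion, and full clustering,
checked against brute-force oracles and planted program families."""

import itertools

import numpy as np
import pytest

from mpith.cluster import (
    build_cluster,
    cluster_all,
    complete_mp,
    find_founder,
    jaccard,
)
from mpith.robust import ProgramSet
from _helpers import gene_block, make_program


def _jaccard_oracle(a, b):
    inter = sum(1 for g in set(a) if g in set(b))
    union = len(set(list(a) + list(b)))
    return inter / union


class TestJaccard:
    def test_identical_sets(self):
        g = gene_block(0, 50)
        assert jaccard(g, g) == 1.0

    def test_disjoint_sets(self):
        assert jaccard(gene_block(0, 50), gene_block(100, 50)) == 0.0

    def test_half_shared(self):
        a = gene_block(0, 50)
        b = gene_block(25, 50)
        assert jaccard(a, b) == pytest.approx(25 / 75)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            jaccard([], gene_block(0, 5))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        universe = gene_block(0, 200)
        for _ in range(1000):
            a = list(rng.choice(universe, size=rng.integers(1, 60), replace=False))
            b = list(rng.choice(universe, size=rng.integers(1, 60), replace=False))
            assert jaccard(a, b) == _jaccard_oracle(a, b)


def _star_pool(n_supporters=6, overlap_n=10):
    """One hub overlapping n_supporters programs by overlap_n genes each;
    supporters are mutually disjoint outside the hub."""
    hub_genes = gene_block(0, 50)
    programs = [make_program("S0", 4, 0, hub_genes)]
    for i in range(n_supporters):
        genes = hub_genes[:overlap_n] + gene_block(1000 + i * 100, 50 - overlap_n)
        programs.append(make_program(f"S{i + 1}", 4, 0, genes))
    return ProgramSet(programs)


class TestFindFounder:
    def test_disjoint_pool_has_no_founder(self):
        pool = ProgramSet(
            [make_program(f"S{i}", 4, 0, gene_block(i * 100, 50)) for i in range(8)]
        )
        assert find_founder(pool) is None

    def test_star_topology_returns_the_hub(self):
        pool = _star_pool(n_supporters=6)
        founder = find_founder(pool)
        assert founder is not None and founder.sample_id == "S0"

    def test_five_supporters_is_not_enough(self):
        # "exceeded five cases" is strict: 5 supporters do not found
        assert find_founder(_star_pool(n_supporters=5)) is None

    def test_more_supporters_wins(self):
        hub_a = gene_block(0, 50)
        hub_b = gene_block(2000, 50)
        programs = [
            make_program("A0", 4, 0, hub_a),
            make_program("B0", 4, 0, hub_b),
        ]
        for i in range(7):  # A has 7 supporters
            genes = hub_a[:10] + gene_block(3000 + i * 100, 40)
            programs.append(make_program(f"A{i + 1}", 4, 0, genes))
        for i in range(6):  # B has 6
            genes = hub_b[:10] + gene_block(5000 + i * 100, 40)
            programs.append(make_program(f"B{i + 1}", 4, 0, genes))
        founder = find_founder(ProgramSet(programs))
        assert founder.sample_id == "A0"


class TestCompleteMP:
    def test_single_member_returns_its_own_genes(self):
        p = make_program("S1", 4, 0, gene_block(0, 50))
        assert set(complete_mp([p])) == set(p.genes)

    def test_shared_genes_always_included(self):
        a, b = gene_block(0, 50), gene_block(20, 50)  # share 30 genes
        members = [make_program("S1", 4, 0, a), make_program("S2", 4, 0, b)]
        mp = complete_mp(members)
        assert set(gene_block(20, 30)) <= set(mp)

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(1)
        universe = gene_block(0, 150)
        members = []
        for i in range(3):
            genes = list(rng.choice(universe, size=50, replace=False))
            weights = {g: float(w) for g, w in zip(genes, sorted(rng.random(50))[::-1])}
            members.append(make_program(f"S{i}", 4, 0, genes, weights))
        mp = complete_mp(members, size=50)

        genes = sorted({g for m in members for g in m.genes})
        freq = {g: sum(g in m.gene_set for m in members) for g in genes}
        meanw = {
            g: np.mean([m.weights[g] for m in members if g in m.gene_set])
            for g in genes
        }
        expected = sorted(genes, key=lambda g: (-freq[g], -meanw[g], g))[:50]
        assert list(mp) == expected

    def test_union_too_small_is_an_error(self):
        p = make_program("S1", 4, 0, gene_block(0, 10))
        with pytest.raises(ValueError, match="short by"):
            complete_mp([p], size=50)


class TestBuildCluster:
    def test_degenerate_pool_of_copies(self):
        g = gene_block(0, 50)
        pool = ProgramSet([make_program(f"S{i}", 4, 0, g) for i in range(6)])
        founder = pool.programs[0]
        mp, remaining, audit = build_cluster(founder, pool)
        assert set(mp.genes) == set(g)
        assert len(mp.members) == 6
        assert len(remaining) == 0

    def test_nine_gene_overlap_never_admitted(self):
        g = gene_block(0, 50)
        pool_programs = [make_program(f"S{i}", 4, 0, g) for i in range(3)]
        outsider = make_program(
            "S9", 4, 0, g[:9] + gene_block(1000, 41)
        )
        pool = ProgramSet(pool_programs + [outsider])
        mp, remaining, _ = build_cluster(pool.programs[0], pool)
        assert outsider.key not in {m.key for m in mp.members}
        assert outsider.key in {p.key for p in remaining}

    def test_admission_overlaps_logged_and_at_least_threshold(self, meta_programs):
        mps, _, audit = meta_programs
        accreted = audit.groupby("mp_id").apply(lambda d: d.iloc[2:], include_groups=False)
        if len(accreted):
            assert (accreted["overlap_at_admission"] >= 10).all()


class TestClusterAll:
    def _family_pool(self, n_families=3, members_per_family=7, noise=0):
        # 7 members -> 6 supporters per program, satisfying the strict
        # "more than five cases" founder rule
        rng = np.random.default_rng(7)
        programs = []
        for f in range(n_families):
            core = gene_block(f * 200, 50)
            for m in range(members_per_family):
                genes = list(core)
                drop = rng.choice(50, size=5, replace=False)
                for d in sorted(drop, reverse=True):
                    genes[d] = f"g{9000 + f * 100 + m * 10 + d:05d}"
                programs.append(make_program(f"S{m}", 4 + (m % 3), f, genes))
        for i in range(noise):
            programs.append(
                make_program(f"N{i}", 4, 0, gene_block(5000 + i * 100, 50))
            )
        return ProgramSet(programs)

    def test_recovers_three_planted_families(self):
        pool = self._family_pool()
        mps, unassigned, _ = cluster_all(pool)
        assert len(mps) == 3
        matched = set()
        for f in range(3):
            core = set(gene_block(f * 200, 50))
            best = max(mps, key=lambda mp: len(core & mp.gene_set))
            assert len(core & best.gene_set) >= 35
            matched.add(best.mp_id)
        assert len(matched) == 3

    def test_isolated_pool_yields_no_mps(self):
        pool = ProgramSet(
            [make_program(f"S{i}", 4, 0, gene_block(i * 100, 50)) for i in range(6)]
        )
        mps, unassigned, _ = cluster_all(pool)
        assert mps == [] and len(unassigned) == 6

    def test_every_mp_has_exactly_50_genes(self, meta_programs):
        mps, _, _ = meta_programs
        assert mps and all(len(mp.genes) == 50 for mp in mps)

    def test_partition_of_the_pool(self, robust_pool, meta_programs):
        mps, unassigned, _ = meta_programs
        member_keys = [m.key for mp in mps for m in mp.members]
        assert len(member_keys) == len(set(member_keys))  # disjoint members
        all_keys = set(member_keys) | {p.key for p in unassigned}
        assert all_keys == {p.key for p in robust_pool}

    def test_planted_programs_become_distinct_mps(self, cohort_world, meta_programs):
        cfg, _, _ = cohort_world
        mps, _, _ = meta_programs
        assert len(mps) >= 3
        best_ids = set()
        for plant in cfg.shared_programs:
            target = set(plant.genes)
            score, best = max((len(target & mp.gene_set), mp.mp_id) for mp in mps)
            assert score >= 35
            best_ids.add(best)
        assert len(best_ids) == 3
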