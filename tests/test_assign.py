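"""Bin-matched control scoring, conservation and prevalence rules, and the
MP correlation matrix, cross-checked against scanpy's scoring family."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpith.assign import (
    assign_cells,
    mp_correlation_matrix,
    mp_module_scores,
    score_cells,
    signature_score,
)
from mpith.cluster import MetaProgram
from _helpers import counts_adata, gene_block, make_program


def _mp(mp_id, genes):
    member = make_program(mp_id, 4, 0, genes)
    return MetaProgram(mp_id=mp_id, genes=tuple(genes), members=(member,), founder=member)


@pytest.fixture(scope="module")
def planted_sample(cohort_world):
    _, samples, truth = cohort_world
    s = samples[0]
    return s, truth.loc[s.obs_names]


class TestSignatureScore:
    def test_full_signature_with_full_bin_controls_cancels(self):
        rng = np.random.default_rng(0)
        adata = counts_adata(rng.poisson(3.0, size=(20, 60)) + 1)
        scores = signature_score(
            adata, list(adata.var_names), n_bins=5, n_ctrl=10_000, seed=0
        )
        assert np.abs(scores.to_numpy()).max() < 1e-10

    def test_constant_matrix_scores_zero(self):
        adata = counts_adata(np.full((10, 30), 4, dtype=int))
        scores = signature_score(adata, gene_block(0, 10), seed=0)
        assert np.abs(scores.to_numpy()).max() == 0

    def test_active_cells_outscore_inactive(self, planted_sample):
        s, truth = planted_sample
        genes = gene_block(0, 50)  # plant P1 occupies the first 50 genes
        scores = signature_score(s, genes, seed=0)
        active = truth["P1"].to_numpy()
        p = stats.mannwhitneyu(
            scores[active], scores[~active], alternative="greater"
        ).pvalue
        assert p < 1e-6

    def test_absent_signature_is_an_error(self):
        adata = counts_adata(np.ones((5, 10), dtype=int))
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(adata, ["nope1", "nope2"])

    def test_invariant_to_gene_and_cell_order(self):
        rng = np.random.default_rng(1)
        adata = counts_adata(rng.poisson(2.0, size=(15, 40)) + 1)
        sig = gene_block(3, 8)
        base = signature_score(adata, sig, n_bins=4, seed=5)
        perm_g = rng.permutation(adata.n_vars)
        perm_c = rng.permutation(adata.n_obs)
        shuffled = adata[perm_c, perm_g].copy()
        shuffled.uns["sample_id"] = "S"
        other = signature_score(shuffled, sig, n_bins=4, seed=5)
        pd.testing.assert_series_equal(base.loc[other.index], other)

    def test_seed_determinism(self, planted_sample):
        s, _ = planted_sample
        a = signature_score(s, gene_block(0, 50), seed=3)
        b = signature_score(s, gene_block(0, 50), seed=3)
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_agrees_with_scanpy_scoring(self, planted_sample):
        """Independent cross-check: scanpy's bin-matched score_genes ranks
        cells the same way on a planted signature."""
        sc = pytest.importorskip("scanpy")
        from mpith.preprocess import lognorm

        s, _ = planted_sample
        ours = signature_score(s, gene_block(0, 50), seed=0)
        ref = s.copy()
        ref.X = lognorm(ref)
        sc.tl.score_genes(
            ref, gene_block(0, 50), ctrl_size=100, n_bins=30, score_name="sc",
            random_state=0,
        )
        rho = stats.spearmanr(ours.to_numpy(), ref.obs["sc"].to_numpy()).statistic
        assert rho > 0.9


class TestScoreCells:
    def test_conservation_boundary(self):
        rng = np.random.default_rng(2)
        adata = counts_adata(rng.poisson(3.0, size=(30, 100)) + 1)
        # matrix genes are g0000..g0099; build MPs with 20 vs 25 present
        mp_out = _mp("MP_out", gene_block(0, 20) + [f"x{i}" for i in range(30)])
        mp_in = _mp("MP_in", gene_block(0, 25) + [f"x{i}" for i in range(25)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = score_cells(adata, [mp_out, mp_in], min_genes_conserved=25)
        assert list(scores.columns) == ["MP_in"]
        assert scores.attrs["excluded_mps"] == ["MP_out"]

    def test_all_mps_present_gives_one_column_each(self, planted_sample):
        s, _ = planted_sample
        mps = [_mp(f"MP{i}", gene_block(i * 50, 50)) for i in range(3)]
        scores = score_cells(s, mps)
        assert list(scores.columns) == ["MP0", "MP1", "MP2"]

    def test_all_mps_failing_is_an_error(self):
        adata = counts_adata(np.ones((5, 30), dtype=int))
        with pytest.raises(ValueError, match="conservation"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score_cells(adata, [_mp("MP1", [f"x{i}" for i in range(50)])])


class TestAssignCells:
    def _scores(self, top_counts: dict, n_cells=100):
        """Score matrix where each MP tops exactly top_counts[mp] cells."""
        mps = list(top_counts)
        data = np.zeros((n_cells, len(mps)))
        start = 0
        for j, mp in enumerate(mps):
            data[start : start + top_counts[mp], j] = 1.0
            start += top_counts[mp]
        return pd.DataFrame(data, columns=mps,
                            index=[f"c{i:03d}" for i in range(n_cells)])

    def test_rare_mp_cells_become_unresolved(self):
        scores = self._scores({"MP1": 96, "MP2": 4})
        ca = assign_cells(scores)
        assert ca.retained_mps == ("MP1",)
        assert (ca.labels == "unresolved").sum() == 4

    def test_single_dominant_mp_labels_everything(self):
        scores = self._scores({"MP1": 100})
        ca = assign_cells(scores)
        assert (ca.labels == "MP1").all()

    def test_five_percent_boundary_is_inclusive(self):
        scores = self._scores({"MP1": 95, "MP2": 5})
        ca = assign_cells(scores)
        assert "MP2" in ca.retained_mps
        assert (ca.labels == "MP2").sum() == 5

    def test_ties_go_to_first_column(self):
        scores = pd.DataFrame(
            np.ones((10, 2)), columns=["A", "B"], index=[f"c{i}" for i in range(10)]
        )
        ca = assign_cells(scores)
        assert (ca.labels == "A").all()

    def test_retained_prevalence_invariant(self, planted_sample, cohort_world):
        cfg, _, _ = cohort_world
        s, _ = planted_sample
        mps = [_mp(f"MP{i}", gene_block(i * 50, 50)) for i in range(3)]
        ca = assign_cells(score_cells(s, mps), min_prevalence=0.05)
        n = len(ca.labels)
        for mp in ca.retained_mps:
            assert (ca.labels == mp).sum() >= 0.05 * n - 1e-9


class TestModuleScores:
    def test_columns_equal_individual_signature_scores(self, planted_sample):
        s, _ = planted_sample
        mps = [_mp(f"MP{i}", gene_block(i * 50, 50)) for i in range(2)]
        module = mp_module_scores(s, mps, n_bins=24, seed=1)
        for mp in mps:
            single = signature_score(s, mp.genes, n_bins=24, seed=1)
            assert (module[mp.mp_id].to_numpy() == single.to_numpy()).all()

    def test_matching_mp_scores_highest_in_active_cells(self, planted_sample):
        s, truth = planted_sample
        mps = [_mp(f"MP{i}", gene_block(i * 50, 50)) for i in range(3)]
        module = mp_module_scores(s, mps, seed=0)
        # cells active only for plant P1
        only_p1 = truth["P1"] & ~truth["P2"] & ~truth["P3"]
        sub = module.loc[only_p1.to_numpy()]
        contrast = sub["MP0"] - sub[["MP1", "MP2"]].max(axis=1)
        assert contrast.median() > 0


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(3).normal(size=20)
        df = pd.DataFrame({"a": x, "b": x})
        corr = mp_correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        x = np.linspace(0, 1, 15)
        corr = mp_correlation_matrix(pd.DataFrame({"a": x, "b": -x}))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        corr = mp_correlation_matrix(df)
        for i in "abcd":
            for j in "abcd":
                x, y = df[i] - df[i].mean(), df[j] - df[j].mean()
                expected = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
                assert corr.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_flagged_not_silent(self):
        df = pd.DataFrame(
            {"a": np.arange(10.0), "flat": np.ones(10)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = mp_correlation_matrix(df)
        assert np.isnan(corr.loc["a", "flat"])
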