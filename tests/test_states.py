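"""QC, normalization, clustering, markers and differential expression."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from perturbatlas import states
from perturbatlas.enrichment import bh_adjust


class TestQCFilter:
    def test_high_mito_removed(self):
        counts = np.array([[10, 10, 3], [10, 10, 1]])  # gene 3 is mito
        kept = states.qc_filter(counts, [False, False, True])
        # cell 0: 3/23 = 13% mito -> removed; cell 1: 1/21 ~ 4.8% -> kept
        assert list(kept) == [1]

    def test_identical_cells_all_kept(self):
        counts = np.tile([5, 5, 0], (10, 1))
        kept = states.qc_filter(counts, [False, False, True])
        assert len(kept) == 10

    def test_gene_count_band(self, rng):
        base = rng.poisson(5, size=(50, 30))
        outlier = np.zeros((1, 30), dtype=int)
        outlier[0, 0] = 1  # detects one gene, far below mean - 2 SD
        counts = np.vstack([base, outlier])
        kept = states.qc_filter(counts, [False] * 30)
        assert 50 not in kept


class TestNormalize:
    def test_single_gene_cell(self):
        counts = np.array([[7, 0, 0]])
        norm = states.normalize_log1p(counts, scale=1e4).toarray()
        assert norm[0, 0] == pytest.approx(np.log1p(1e4))
        assert norm[0, 1] == 0

    def test_depth_invariance(self, rng):
        counts = rng.poisson(3, size=(4, 6)) + 1
        doubled = counts.copy()
        doubled[2] *= 2
        a = states.normalize_log1p(counts).toarray()
        b = states.normalize_log1p(doubled).toarray()
        np.testing.assert_allclose(a[2], b[2], rtol=1e-12)

    def test_matches_direct_formula(self, rng):
        counts = rng.poisson(4, size=(5, 4)) + 1
        norm = states.normalize_log1p(counts, scale=100).toarray()
        expected = np.log1p(counts / counts.sum(1, keepdims=True) * 100)
        np.testing.assert_allclose(norm, expected, rtol=1e-12)

    def test_zero_cell_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            states.normalize_log1p(np.array([[1, 2], [0, 0]]),
                                   cell_names=["a", "b"])


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        X = np.full((10, 20), 3.0)
        genes = [f"g{i}" for i in range(20)]
        score = states.score_module(X, genes, ["g1", "g2"], seed=0)
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_elevated_set_scores_positive(self, rng):
        X = rng.normal(1, 0.1, size=(20, 30))
        genes = [f"g{i}" for i in range(30)]
        X[5, [0, 1, 2]] *= 2  # set genes scaled x2 in cell 5
        score = states.score_module(X, genes, ["g0", "g1", "g2"], seed=0)
        assert score[5] > 0
        assert score[5] > np.delete(score, 5).max()

    def test_absent_set_errors(self):
        X = np.ones((3, 3))
        with pytest.raises(ValueError):
            states.score_module(X, ["a", "b", "c"], ["zz"], seed=0)


def test_assign_phase_rules():
    assert states.assign_phase(0.5, 0.1) == "S"
    assert states.assign_phase(-0.2, -0.1) == "G1"
    assert states.assign_phase(0.1, 0.4) == "G2M"
    assert states.assign_phase(0.0, 0.0) == "G1"


class TestRegressOut:
    def test_linear_gene_residual_zero(self):
        cov = np.arange(10.0)
        Y = np.column_stack([2 * cov + 1, cov ** 2])
        resid = states.regress_out(Y, cov)
        np.testing.assert_allclose(resid[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        Y = rng.normal(size=(50, 8))
        C = rng.normal(size=(50, 2))
        resid = states.regress_out(Y, C)
        for j in range(8):
            for k in range(2):
                r = np.corrcoef(resid[:, j], C[:, k])[0, 1]
                assert abs(r) < 1e-8

    def test_matches_normal_equations(self, rng):
        Y = rng.normal(size=(20, 3))
        C = rng.normal(size=(20, 2))
        X = np.column_stack([np.ones(20), C])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        expected = Y - X @ beta
        np.testing.assert_allclose(states.regress_out(Y, C), expected,
                                   atol=1e-10)

    def test_collinear_errors(self):
        cov = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            states.regress_out(np.ones((10, 2)), cov)


class TestSelectHVG:
    def test_planted_high_dispersion_gene_first(self, rng):
        X = rng.normal(1, 0.1, size=(100, 20)).clip(0)
        X[:, 7] = rng.normal(1, 2.0, size=100).clip(0)  # same mean, high var
        genes = [f"g{i}" for i in range(20)]
        assert states.select_hvg(X, genes, n=5)[0] == "g7"

    def test_constant_gene_never_selected(self, rng):
        X = rng.normal(1, 0.5, size=(30, 5)).clip(0.01)
        X[:, 2] = 1.0
        genes = list("abcde")
        assert "c" not in states.select_hvg(X, genes, n=5)

    def test_n_larger_than_genes(self, rng):
        X = rng.normal(1, 0.5, size=(30, 4)).clip(0.01)
        genes = list("abcd")
        assert len(states.select_hvg(X, genes, n=100)) == 4


class TestClustering:
    def _planted(self, rng, n_per=60, sep=6.0):
        X = rng.normal(0, 1, size=(2 * n_per, 30))
        X[n_per:, :10] += sep
        truth = np.repeat([0, 1], n_per)
        return np.abs(X), truth

    def test_recovers_two_planted_states(self, rng):
        X, truth = self._planted(rng)
        genes = [f"g{i}" for i in range(30)]
        labels = states.cluster_states(X, genes, genes, dims=5, seed=0)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_seed_invariance_on_separated_data(self, rng):
        X, _ = self._planted(rng)
        genes = [f"g{i}" for i in range(30)]
        a = states.cluster_states(X, genes, genes, dims=5, seed=1)
        b = states.cluster_states(X, genes, genes, dims=5, seed=42)
        assert adjusted_rand_score(a, b) == 1.0

    def test_dims_validation(self, rng):
        X = rng.normal(size=(10, 5))
        genes = list("abcde")
        with pytest.raises(ValueError, match="dims"):
            states.cluster_states(X, genes, genes, dims=5)


class TestWilcoxon:
    def test_agrees_with_exact_enumeration(self, rng):
        # enumerate the permutation null of the rank-sum statistic
        for _ in range(10):
            nx, ny = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            pooled = rng.normal(size=nx + ny)
            while len(np.unique(pooled)) < nx + ny:
                pooled = rng.normal(size=nx + ny)
            x, y = pooled[:nx], pooled[nx:]
            p = states.wilcoxon_test(x, y)
            ranks = sps.rankdata(pooled)
            obs = ranks[:nx].sum()
            n_tot = nx + ny
            mean = nx * (n_tot + 1) / 2
            stat_obs = abs(obs - mean)
            count = sum(
                abs(ranks[list(combo)].sum() - mean) >= stat_obs - 1e-9
                for combo in itertools.combinations(range(n_tot), nx)
            )
            expected = count / len(list(itertools.combinations(range(n_tot), nx)))
            assert p == pytest.approx(expected, abs=1e-9)

    def test_degenerate_returns_one(self):
        assert states.wilcoxon_test([1, 1, 1], [1, 1]) == 1.0


class TestFindMarkers:
    def test_planted_marker_detected(self, rng):
        n = 200
        X = rng.normal(1, 0.3, size=(n, 15)).clip(0)
        labels = np.repeat([0, 1], n // 2)
        X[labels == 0, 3] += 3.0  # exclusive state-0 marker
        genes = [f"g{i}" for i in range(15)]
        mk = states.find_markers(X, genes, labels)
        top = mk[(mk.state == 0)].sort_values("p_adj").iloc[0]
        assert top.gene == "g3" and top.p_adj < 0.05 and top.log2fc > 0.25

    def test_permuted_labels_control_fdr(self, rng):
        X = rng.normal(1, 0.3, size=(100, 40)).clip(0)
        labels = rng.integers(0, 2, size=100)
        mk = states.find_markers(X, genes := [f"g{i}" for i in range(40)],
                                 labels)
        assert (mk.p_adj < 0.05).mean() <= 0.05

    def test_constant_gene_p_one(self, rng):
        X = rng.normal(1, 0.3, size=(30, 3)).clip(0)
        X[:, 1] = 2.0
        mk = states.find_markers(X, ["a", "b", "c"],
                                 np.repeat([0, 1], 15))
        assert (mk.loc[mk.gene == "b", "p"] == 1.0).all()

    def test_small_state_skipped(self, rng):
        X = rng.normal(1, 0.3, size=(20, 3)).clip(0)
        labels = np.array([0] * 18 + [1] * 2)
        mk = states.find_markers(X, ["a", "b", "c"], labels)
        assert set(mk.state) == {0}


class TestIndependentFiltering:
    def _planted(self, rng, n_true=30, n_null=300):
        n_cells = 40
        ga = np.zeros(2 * n_cells, dtype=bool)
        ga[:n_cells] = True
        gb = ~ga
        # true DE genes at high mean; null genes at low mean
        counts = np.zeros((2 * n_cells, n_true + n_null))
        counts[:, :n_true] = rng.poisson(20, size=(2 * n_cells, n_true))
        counts[ga, :n_true] += rng.poisson(15, size=(n_cells, n_true))
        counts[:, n_true:] = rng.poisson(0.3, size=(2 * n_cells, n_null))
        norm = states.normalize_log1p(counts + (counts.sum(1, keepdims=True) == 0))
        genes = [f"g{i}" for i in range(n_true + n_null)]
        return counts, norm, ga, gb, genes

    def test_threshold_maximizes_significant_count(self, rng):
        counts, norm, ga, gb, genes = self._planted(rng)
        res = states.de_independent_filtering(counts, norm, ga, gb, genes)
        assert res.chosen_filter_threshold > 0
        # exhaustive recount over the grid (independent recomputation)
        mean_counts = res.table["mean_count"].to_numpy()
        pvals = res.table["p"].to_numpy()
        recount = []
        for thr in res.grid:
            m = mean_counts >= thr
            recount.append(int((bh_adjust(pvals[m]) < 0.05).sum())
                           if m.sum() else 0)
        assert res.n_significant == max(recount)
        assert res.chosen_filter_threshold == res.grid[int(np.argmax(recount))]
        # filtering must not lose significant genes vs no filtering
        assert res.n_significant >= recount[0]

    def test_identical_groups_few_significant(self, rng):
        counts = rng.poisson(5, size=(60, 50)) + 1
        norm = states.normalize_log1p(counts)
        ga = np.zeros(60, dtype=bool)
        ga[:30] = True
        res = states.de_independent_filtering(counts, norm, ga, ~ga,
                                              [f"g{i}" for i in range(50)])
        assert res.n_significant <= max(2, int(0.05 * 50))

    def test_single_threshold_grid(self, rng):
        counts = rng.poisson(5, size=(10, 6)) + 1
        norm = states.normalize_log1p(counts)
        ga = np.zeros(10, dtype=bool)
        ga[:5] = True
        res = states.de_independent_filtering(counts, norm, ga, ~ga,
                                              list("abcdef"), n_grid=1)
        assert res.chosen_filter_threshold == res.grid[0]


def test_count_de_thresholds():
    import pandas as pd

    tab = pd.DataFrame({"log2fc": [1.2], "p": [0.01]})
    assert states.count_de(tab) == (1, 0)
    tab = pd.DataFrame({"log2fc": [-0.9], "p": [0.001]})
    assert states.count_de(tab) == (0, 0)
    assert states.count_de(pd.DataFrame(columns=["log2fc", "p"])) == (0, 0)


class TestCloneDE:
    def test_small_genotype_excluded(self, rng):
        X = rng.normal(1, 0.2, size=(150, 10)).clip(0)
        genos = np.array(["gA"] * 150)
        clones = rng.choice(["c1", "c2"], size=150)
        out = states.clone_de(X, [f"g{i}" for i in range(10)], genos, clones)
        assert len(out) == 0  # 150 <= 200 cells

    def test_identical_clones_report_no_degs(self, rng):
        n = 240
        X = rng.normal(1, 0.2, size=(n, 12)).clip(0)
        genos = np.array(["gA"] * n)
        clones = np.repeat(["c1", "c2", "c3"], n // 3)
        out = states.clone_de(X, [f"g{i}" for i in range(12)], genos, clones)
        assert len(out) == 3
        assert (out["n_deg"] == 0).mean() >= 0.95 or out["n_deg"].sum() <= 1

    def test_planted_clone_effect_detected(self, rng):
        n = 240
        X = rng.normal(1, 0.2, size=(n, 12)).clip(0)
        genos = np.array(["gA"] * n)
        clones = np.repeat(["c1", "c2", "c3"], n // 3)
        X[clones == "c1", 5] *= 4
        out = states.clone_de(X, [f"g{i}" for i in range(12)], genos, clones)
        assert out.loc[out.clone == "c1", "n_deg"].iloc[0] >= 1


class TestSignatureRank:
    def test_top_ranked_set_scores_one(self):
        X = np.array([[9.0, 8.0, 1.0, 0.5, 0.1]])
        genes = list("abcde")
        score = states.score_signature_rank(X, genes, ["a", "b"], r_max=4)
        assert score[0] == pytest.approx(1.0)

    def test_set_beyond_rmax_scores_zero(self):
        X = np.array([np.arange(30.0)[::-1]])
        genes = [f"g{i}" for i in range(30)]
        score = states.score_signature_rank(X, genes, ["g29"], r_max=5)
        assert score[0] == 0.0
        # multi-gene sets beyond r_max land at the formula's floor-adjacent
        # value (n-1)/(2*r_max)
        score2 = states.score_signature_rank(X, genes, ["g28", "g29"], r_max=5)
        assert score2[0] == pytest.approx(1 / 10)

    def test_matches_rank_formula(self, rng):
        X = rng.normal(size=(3, 30))
        genes = [f"g{i}" for i in range(30)]
        gene_set = ["g3", "g11", "g17", "g22", "g29"]
        r_max = 20
        score = states.score_signature_rank(X, genes, gene_set, r_max=r_max)
        for c in range(3):
            ranks = sps.rankdata(-X[c])
            ranks = np.minimum(ranks, r_max + 1)
            idx = [genes.index(g) for g in gene_set]
            U = ranks[idx].sum() - len(idx) * (len(idx) + 1) / 2
            expected = max(0.0, 1 - U / (len(idx) * r_max))
            assert score[c] == pytest.approx(expected, abs=1e-12)
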