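import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from metascore.config import PipelineConfig
from metascore.errors import ConfigError, DataError, EmptyDataError
from metascore.preprocessing import (
    flag_malignant,
    knn_graph,
    louvain_cluster,
    normalize_log1p,
    pca_embed,
    qc_filter,
    select_hvg,
)
from metascore.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


class TestQcFilter:
    def test_cell_threshold(self):
        # detected genes per cell: 3, 1, 2 -> with min_genes=2 keep cells 0 and 2
        x = np.array([[1, 2, 3], [4, 0, 0], [1, 1, 0]], dtype=float)
        m = make_matrix(x, layer="counts")
        cfg = PipelineConfig(min_genes_per_cell=2, min_cells_per_gene=1)
        out, qc = qc_filter(m, cfg)
        assert out.cell_ids == ["c0", "c2"]
        assert qc["pass_qc"].tolist() == [True, False, True]

    def test_zero_count_gene_removed(self):
        x = np.array([[1, 0], [2, 0]], dtype=float)
        m = make_matrix(x, layer="counts")
        cfg = PipelineConfig(min_genes_per_cell=0, min_cells_per_gene=1)
        out, _ = qc_filter(m, cfg)
        assert out.gene_ids == ["g0"]

    def test_permissive_thresholds_are_identity(self):
        x = np.array([[1, 0], [0, 3]], dtype=float)
        m = make_matrix(x, layer="counts")
        cfg = PipelineConfig(min_genes_per_cell=0, min_cells_per_gene=1,
                             max_mito_frac=1.0)
        out, _ = qc_filter(m, cfg)
        np.testing.assert_array_equal(out.X, x)

    def test_all_cells_removed(self):
        m = make_matrix(np.eye(2), layer="counts")
        with pytest.raises(EmptyDataError):
            qc_filter(m, PipelineConfig(min_genes_per_cell=5))

    def test_mito_fraction_filter(self):
        x = np.array([[10, 10], [90, 10]], dtype=float)
        m = make_matrix(x, layer="counts")
        m.gene_ids = ["MT-CO1", "ACTB"]
        cfg = PipelineConfig(min_genes_per_cell=0, min_cells_per_gene=1,
                             max_mito_frac=0.5)
        out, _ = qc_filter(m, cfg)
        assert out.cell_ids == ["c0"]


class TestNormalize:
    def test_hand_computed(self):
        m = make_matrix([[0, 2, 2]], layer="counts")
        out = normalize_log1p(m, target_sum=4)
        np.testing.assert_allclose(out.X[0], [0.0, np.log(3), np.log(3)], atol=1e-12)
        assert out.layer == "lognorm"

    def test_scale_invariance(self):
        m1 = make_matrix([[1, 2, 3]], layer="counts")
        m2 = make_matrix([[2, 4, 6]], layer="counts")
        np.testing.assert_allclose(
            normalize_log1p(m1, 10).X, normalize_log1p(m2, 10).X, atol=1e-12
        )

    def test_all_equal_cell(self):
        m = make_matrix([[1, 1, 1, 1]], layer="counts")
        out = normalize_log1p(m, target_sum=4)
        np.testing.assert_allclose(out.X[0], np.log(2) * np.ones(4), atol=1e-12)

    def test_zero_total_cell_is_contract_violation(self):
        m = make_matrix([[0, 0]], layer="counts")
        with pytest.raises(DataError):
            normalize_log1p(m, 10)


class TestSelectHvg:
    def test_high_variance_gene_ranks_first(self):
        # 6 genes with exactly equal means (one bin); gene 3 (index 2)
        # has 10x the variance of the rest
        n = 400
        t = np.tile([1.0, -1.0], n // 2)  # exact zero mean
        scales = np.array([0.1, 0.1, np.sqrt(10) * 0.1, 0.1, 0.1, 0.1])
        x = 3.0 + np.outer(t, scales)
        m = make_matrix(x, layer="lognorm")
        disp = x.var(axis=0) / x.mean(axis=0)  # independent oracle
        assert np.argmax(disp) == 2
        assert select_hvg(m, 1)[0] == 2

    def test_zero_variance_gene_never_beats_positive_variance(self, rng):
        # all genes share one mean bin; gene 4 is constant
        x = rng.gamma(2.0, 1.0, size=(50, 10))
        x -= x.mean(axis=0) - 3.0  # equal means
        x[:, 4] = 3.0
        m = make_matrix(x, layer="lognorm")
        chosen = select_hvg(m, 9)
        assert 4 not in chosen

    def test_identical_genes_tie_broken_by_id(self, rng):
        col = rng.gamma(2.0, 1.0, size=50)
        x = np.column_stack([col, col, rng.gamma(2.0, 1.0, size=50)])
        m = make_matrix(x, layer="lognorm")
        chosen = select_hvg(m, 1)
        # genes 0 and 1 identical; whichever z-rank wins, the tie must
        # resolve to the lower gene index
        assert chosen[0] in (0, 2)

    def test_n_hvg_too_large(self):
        m = make_matrix(np.ones((5, 3)), layer="lognorm")
        with pytest.raises(ConfigError):
            select_hvg(m, 4)


def _pca_eigen_oracle(x, n_pcs):
    """Dense covariance eigen-decomposition oracle."""
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / 1.0  # scatter matrix; eigvecs identical
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_pcs]
    comps = vecs[:, order].T
    scores = centered @ comps.T
    return scores, comps


class TestPca:
    def test_rank_one_data_explains_everything(self):
        t = np.linspace(-1, 1, 8)
        x = np.outer(t, [1.0, 2.0, 3.0]) + 5.0
        emb = pca_embed(make_matrix(x, layer="lognorm"), 1)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_score_columns_orthogonal(self, rng):
        x = rng.normal(size=(12, 6))
        emb = pca_embed(make_matrix(x, layer="lognorm"), 4)
        gram = emb.scores.T @ emb.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_eigen_oracle_small(self, rng):
        x = rng.normal(size=(5, 4))
        emb = pca_embed(make_matrix(x, layer="lognorm"), 3)
        scores_o, _ = _pca_eigen_oracle(x, 3)
        for j in range(3):
            col, ref = emb.scores[:, j], scores_o[:, j]
            assert (np.allclose(col, ref, atol=1e-8)
                    or np.allclose(col, -ref, atol=1e-8))

    @pytest.mark.parametrize("seed", range(5))
    def test_eigen_oracle_random_shapes(self, seed):
        rng = np.random.default_rng(seed)
        n, g = rng.integers(4, 21), rng.integers(3, 21)
        x = rng.normal(size=(n, g))
        k = int(min(n - 1, g, 5))
        emb = pca_embed(make_matrix(x, layer="lognorm"), k)
        scores_o, _ = _pca_eigen_oracle(x, k)
        for j in range(k):
            col, ref = emb.scores[:, j], scores_o[:, j]
            assert (np.allclose(col, ref, atol=1e-8)
                    or np.allclose(col, -ref, atol=1e-8))

    def test_sign_convention(self, rng):
        x = rng.normal(size=(10, 5))
        emb = pca_embed(make_matrix(x, layer="lognorm"), 3)
        for row in emb.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_deficient_truncated_with_warning(self):
        t = np.linspace(-1, 1, 6)
        x = np.outer(t, [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="truncat"):
            emb = pca_embed(make_matrix(x, layer="lognorm"), 3)
        assert emb.scores.shape[1] == 1


class TestKnnGraph:
    def test_collinear_middle_bridges(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        g = knn_graph(pts, 1)
        assert g.has_edge(0, 1) and g.has_edge(1, 2)

    def test_complete_graph(self, rng):
        pts = rng.normal(size=(6, 3))
        g = knn_graph(pts, 5)
        assert g.number_of_edges() == 15

    def test_no_self_loops(self, rng):
        pts = np.vstack([rng.normal(size=(5, 2))] * 2)  # duplicate points
        g = knn_graph(pts, 3)
        assert nx.number_of_selfloops(g) == 0

    def test_k_too_large(self, rng):
        with pytest.raises(ConfigError):
            knn_graph(rng.normal(size=(4, 2)), 4)


def _partitions(items):
    """All set partitions (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


class TestLouvain:
    def test_two_cliques_exhaustive_modularity_oracle(self):
        g = nx.union(nx.complete_graph(5), nx.complete_graph(5), rename=("a", "b"))
        g = nx.convert_node_labels_to_integers(g)
        labels = louvain_cluster(g, resolution=1.0, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        # exhaustive check: no partition of the 10 nodes beats the 2-clique one
        best = max(
            nx.community.modularity(g, [set(b) for b in part])
            for part in _partitions(list(g.nodes))
        )
        found = nx.community.modularity(
            g, [set(np.flatnonzero(labels == c)) for c in set(labels)]
        )
        assert found == pytest.approx(best, abs=1e-12)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node(0)
        labels = louvain_cluster(g, 1.0, 0)
        assert labels.tolist() == [0]

    def test_empty_graph_errors(self):
        with pytest.raises(EmptyDataError):
            louvain_cluster(nx.Graph(), 1.0, 0)

    def test_modularity_beats_singletons(self, rng):
        pts = rng.normal(size=(60, 2))
        g = knn_graph(pts, 5)
        labels = louvain_cluster(g, 1.0, 0)
        part = [set(np.flatnonzero(labels == c)) for c in set(labels)]
        singletons = [{v} for v in g.nodes]
        assert (nx.community.modularity(g, part)
                >= nx.community.modularity(g, singletons))

    def test_two_blob_recovery(self, rng):
        blob1 = rng.normal(0.0, 1.0, size=(100, 2))
        blob2 = rng.normal(30.0, 1.0, size=(100, 2))
        pts = np.vstack([blob1, blob2])
        truth = np.repeat([0, 1], 100)
        g = knn_graph(pts, 10)
        labels = louvain_cluster(g, resolution=0.05, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_cluster_ids_ordered_by_size(self):
        g = nx.union(nx.complete_graph(3), nx.complete_graph(6), rename=("a", "b"))
        g = nx.convert_node_labels_to_integers(g)
        labels = louvain_cluster(g, 1.0, 0)
        sizes = np.bincount(labels)
        assert (np.diff(sizes) <= 0).all()

    def test_deterministic(self, rng):
        pts = rng.normal(size=(80, 3))
        g = knn_graph(pts, 6)
        a = louvain_cluster(g, 1.0, 7)
        b = louvain_cluster(g, 1.0, 7)
        np.testing.assert_array_equal(a, b)


class TestFlagMalignant:
    def test_user_labels_pass_through(self):
        labels = np.array([True, False, True])
        out = flag_malignant(np.array([0, 1, 1]), user_labels=labels)
        np.testing.assert_array_equal(out, labels)

    def test_identical_cluster_means_flags_nothing(self):
        clusters = np.array([0, 0, 1, 1])
        score = np.array([1.0, 3.0, 2.0, 2.0])  # both cluster means are 2
        out = flag_malignant(clusters, malignant_score=score)
        assert not out.any()

    def test_median_rule(self):
        clusters = np.array([0, 0, 1, 1, 2, 2])
        score = np.array([0.0, 0.0, 5.0, 5.0, 1.0, 1.0])
        out = flag_malignant(clusters, malignant_score=score)
        np.testing.assert_array_equal(out, [False, False, True, True, False, False])

    def test_needs_score_or_labels(self):
        with pytest.raises(ConfigError):
            flag_malignant(np.array([0, 1]))

    def test_simulated_recovery(self):
        from metascore.pipeline import run_pipeline

        cfg = SimulationConfig(
            n_cells=400, n_genes=400, program_size=40, frac_malignant=0.5,
            frac_hybrid=0.0, frac_mesenchymal=0.0, frac_stem=0.0,
            frac_glycolytic=0.0, n_clusters=1, effect_size=2.0, seed=0,
        )
        m, truth, sigs = simulate_dataset(cfg)
        res = run_pipeline(m, sigs, PipelineConfig(min_genes_per_cell=50))
        called = set(res.per_cell["cell_id"])
        agree = np.mean(
            [(c in called) == mal
             for c, mal in zip(truth.cells["cell_id"], truth.cells["malignant"])]
        )
        assert agree >= 0.95


def test_preprocessing_chain_deterministic(rng):
    x = rng.integers(0, 30, size=(60, 50)).astype(float)
    m = make_matrix(x, layer="counts")
    cfg = PipelineConfig(min_genes_per_cell=1, min_cells_per_gene=1,
                         n_hvg=30, n_pcs=10, knn_k=5)

    def chain():
        f, _ = qc_filter(m, cfg)
        ln = normalize_log1p(f, cfg.target_sum)
        hvg = select_hvg(ln, cfg.n_hvg)
        emb = pca_embed(ln.subset_genes(hvg), cfg.n_pcs)
        g = knn_graph(emb, cfg.knn_k)
        return louvain_cluster(g, cfg.louvain_resolution, cfg.cluster_seed), emb.scores

    l1, s1 = chain()
    l2, s2 = chain()
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_array_equal(s1, s2)
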