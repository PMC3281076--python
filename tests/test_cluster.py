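import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from circuc.cluster import (
    colocalize,
    correlation_clusters,
    hier_cluster_samples,
    pairwise_r_pvalue,
    pearson_matrix,
)
from circuc.datatypes import ExprMatrix, GenomicLocus, ValidationError
from circuc.synth import SimulationDesign, sample_table, simulate_feature_matrix


def _expr(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExprMatrix(pd.DataFrame(values, index=features, columns=samples))


class TestSampleClustering:
    def test_separated_groups_recovered_exactly(self):
        design = SimulationDesign(n_features=100, n_de=40, log2_fc_range=(3.0, 4.0),
                                  noise_sd_range=(0.3, 0.3), corr_blocks=(), seed=2)
        expr, _ = simulate_feature_matrix(design)
        meta = sample_table(design)
        result = hier_cluster_samples(expr, meta)
        assert result.misclassified == 0

    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        X[:, 3] = X[:, 0]  # duplicate column
        result = hier_cluster_samples(_expr(X))
        assert result.linkage_matrix[0, 2] == 0.0  # first merge at height 0
        assert set(result.linkage_matrix[0, :2]) == {0.0, 3.0}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        result = hier_cluster_samples(_expr(rng.normal(size=(20, 12))))
        heights = result.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)


class TestPearson:
    def test_matches_per_pair_brute_force(self):
        rng = np.random.default_rng(5)
        m = _expr(rng.normal(size=(10, 40)))
        corr = pearson_matrix(m).to_numpy()
        X = m.values
        for i in range(10):
            for j in range(10):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr[i, j] == pytest.approx(expected, abs=1e-10)

    def test_r_pvalue_range_for_r06_n40(self):
        p = pairwise_r_pvalue(0.6, 40)
        assert 1e-5 < p < 1e-4


class TestCorrelationClusters:
    def test_duplicated_feature_lands_in_same_cluster(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 30))
        X[5] = X[0]
        cset = correlation_clusters(_expr(X), r_threshold=0.6)
        pair = [c for c in cset.clusters if {"f0", "f5"} <= set(c)]
        assert pair, f"expected f0/f5 clustered together, got {cset.clusters}"

    def test_every_cluster_satisfies_min_pairwise_r(self):
        design = SimulationDesign(n_features=40, n_de=0,
                                  corr_blocks=((8, 0.75), (8, 0.75)), seed=9)
        expr, _ = simulate_feature_matrix(design)
        cset = correlation_clusters(expr, r_threshold=0.6)
        for members in cset.clusters:
            sub = cset.correlation_matrix.loc[members, members].to_numpy()
            off = sub[~np.eye(len(members), dtype=bool)]
            assert off.min() > 0.6
        assert (cset.stats["min_pairwise_r"] > 0.6).all()

    def test_independent_noise_rarely_forms_clusters(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            cset = correlation_clusters(_expr(rng.normal(size=(10, 40))),
                                        r_threshold=0.6)
            hits += bool(cset.clusters)
        assert hits <= 5

    def test_planted_blocks_recovered(self):
        # 4 latent blocks at rho=0.75 plus independent singletons; the
        # extracted partition matches the planted one (ARI > 0.9 over 20 runs)
        aris = []
        for s in range(20):
            design = SimulationDesign(
                n_features=40, n_de=0,
                corr_blocks=((8, 0.75), (8, 0.75), (6, 0.75), (6, 0.75)),
                seed=500 + s)
            expr, truth = simulate_feature_matrix(design)
            cset = correlation_clusters(expr, r_threshold=0.6)
            predicted = {}
            for k, members in enumerate(cset.clusters):
                for f in members:
                    predicted[f] = k
            next_label = len(cset.clusters)
            for f in cset.unassigned:
                predicted[f] = next_label
                next_label += 1
            features = truth["feature_id"].tolist()
            true_labels = truth["block_id"].to_numpy().copy()
            singles = true_labels == -1  # each singleton is its own class
            true_labels[singles] = np.arange(singles.sum()) + true_labels.max() + 1
            aris.append(adjusted_rand_score(
                true_labels, np.array([predicted[f] for f in features])))
        assert np.mean(aris) > 0.9

    def test_constant_feature_moved_to_unassigned(self):
        X = np.vstack([np.full(20, 3.0), np.random.default_rng(0).normal(size=(3, 20))])
        cset = correlation_clusters(_expr(X), r_threshold=0.6)
        assert "f0" in cset.unassigned

    def test_membership_invariant_to_sample_order(self):
        design = SimulationDesign(n_features=30, n_de=0,
                                  corr_blocks=((6, 0.8),), seed=12)
        expr, _ = simulate_feature_matrix(design)
        cset_a = correlation_clusters(expr, r_threshold=0.6)
        perm = np.random.default_rng(1).permutation(expr.shape[1])
        cset_b = correlation_clusters(ExprMatrix(expr.data.iloc[:, perm]),
                                      r_threshold=0.6)
        assert cset_a.clusters == cset_b.clusters


class TestColocalize:
    def test_gap_arithmetic_and_chromosome_partition(self):
        loci = [
            GenomicLocus("a", "chr1", 100, 200),
            GenomicLocus("b", "chr1", 500, 600),
            GenomicLocus("c", "chr2", 100, 200),
            GenomicLocus("d", "chr1", 150, 250),
        ]
        pairs = colocalize(loci, max_gap_bp=1000)
        table = {(r.feature_a, r.feature_b): r.gap_bp for r in pairs.itertuples()}
        assert table[("a", "b")] == 300
        assert table[("a", "d")] == 0  # overlap
        assert not any("c" in k for k in table)  # different chromosome

    def test_gap_threshold_respected(self):
        loci = [GenomicLocus("a", "chr1", 0, 10), GenomicLocus("b", "chr1", 500, 510)]
        assert colocalize(loci, max_gap_bp=100).empty
        assert len(colocalize(loci, max_gap_bp=490)) == 1
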