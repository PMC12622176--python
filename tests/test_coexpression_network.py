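import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from psymap import (GeneSet, SignedLouvain, SyntheticSpec, binarized_degree,
                    cluster_maps, gce_matrix, gen_expression, gen_parcel_atlas,
                    louvain_signed, set_average_map, signed_modularity)
from psymap.coexpression_network import CoexpressionMatrix
from psymap.errors import ZeroVarianceError

# ---------------------------------------------------------------- oracles


def reference_modularity(W, labels, gamma):
    """Independent double-loop implementation of Q+/v+ - Q-/v-."""
    n = len(W)
    q = 0.0
    for Wx, sign in ((np.clip(W, 0, None), 1), (np.clip(-W, 0, None), -1)):
        v = Wx.sum()
        if v == 0:
            continue
        k = Wx.sum(axis=1)
        s = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    s += Wx[i, j] - gamma * k[i] * k[j] / v
        q += sign * s / v
    return q


def all_partitions(n):
    """Every set partition of n items as restricted-growth label vectors."""
    def grow(prefix, m):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for c in range(m + 1):
            yield from grow(prefix + [c], max(m, c + 1))
    yield from grow([0], 1)


def brute_force_best(W, gamma):
    best_q, best_labels = -np.inf, None
    for labels in all_partitions(len(W)):
        q = reference_modularity(W, labels, gamma)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return best_q, best_labels


def random_signed_matrix(n, rng):
    W = rng.uniform(-1, 1, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


# ------------------------------------------------------------------ tests


class TestGceMatrix:
    def test_identical_columns_give_unit_correlation(self, atlas60):
        spec = SyntheticSpec(n_parcels=60, n_genes=6, n_clusters=2,
                             noise_sd=0.0, seed=1)
        E, labels = gen_expression(atlas60, spec)
        C = gce_matrix(E, E.gene_set())
        same = labels[:, None] == labels[None, :]
        assert np.allclose(C.values[same], 1.0, atol=1e-9)
        # cross-cluster entries all equal the (single) profile correlation
        cross = C.values[~same]
        assert np.allclose(cross, cross[0], atol=1e-9)
        assert np.all(np.abs(cross) < 1 - 1e-9)

    def test_symmetric_with_unit_diagonal(self, clustered_expression):
        E, _ = clustered_expression
        C = gce_matrix(E, E.gene_set())
        assert np.allclose(C.values, C.values.T, atol=1e-12)
        assert np.allclose(np.diag(C.values), 1.0)
        assert np.all(np.abs(C.values) <= 1.0)

    def test_zero_variance_gene_raises(self, atlas60, clustered_expression):
        E, _ = clustered_expression
        values = E.values.copy()
        values[~E.missing_mask, 0] = 5.0
        from psymap.expression_maps import ExpressionMatrix
        bad = ExpressionMatrix(atlas=E.atlas, genes=E.genes, values=values,
                               missing_mask=E.missing_mask)
        with pytest.raises(ZeroVarianceError, match=E.genes[0]):
            gce_matrix(bad, bad.gene_set())


class TestBinarizedDegree:
    def test_worked_example(self):
        C = CoexpressionMatrix(("A", "B", "C"),
                               np.array([[1, .5, .2], [.5, 1, .35], [.2, .35, 1]]))
        assert binarized_degree(C, 0.3).tolist() == [1, 2, 1]

    def test_signed_rule_ignores_negative_edges(self):
        vals = np.full((4, 4), -0.9)
        np.fill_diagonal(vals, 1.0)
        C = CoexpressionMatrix(tuple("ABCD"), vals)
        assert binarized_degree(C, 0.3).tolist() == [0, 0, 0, 0]
        assert binarized_degree(C, 0.3, absolute=True).tolist() == [3, 3, 3, 3]

    def test_threshold_extremes_and_monotonicity(self):
        rng = np.random.default_rng(0)
        vals = random_signed_matrix(6, rng)
        np.fill_diagonal(vals, 1.0)
        C = CoexpressionMatrix(tuple("ABCDEF"), vals)
        assert binarized_degree(C, -0.999).tolist() == [5] * 6
        degs = [binarized_degree(C, t).sum() for t in (-0.5, 0.0, 0.3, 0.7)]
        assert degs == sorted(degs, reverse=True)


class TestSignedModularity:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        W = random_signed_matrix(n, rng)
        labels = rng.integers(0, 3, size=n)
        for gamma in (0.5, 1.0):
            assert signed_modularity(W, labels, gamma) == pytest.approx(
                reference_modularity(W, labels, gamma), abs=1e-12)


class TestSignedLouvain:
    def test_uniform_positive_weights_give_one_community(self):
        W = np.full((6, 6), 0.4)
        np.fill_diagonal(W, 0.0)
        est = SignedLouvain(gamma=0.5, n_restarts=10, random_state=0).fit(W)
        assert est.n_communities_ == 1
        q_bf, _ = brute_force_best(W, 0.5)
        assert est.modularity_ == pytest.approx(q_bf, abs=1e-12)

    def test_two_signed_blocks_recovered_exactly(self):
        W = np.full((8, 8), -0.5)
        W[:4, :4] = 0.8
        W[4:, 4:] = 0.8
        np.fill_diagonal(W, 0.0)
        est = SignedLouvain(gamma=0.5, n_restarts=10, random_state=1).fit(W)
        assert est.n_communities_ == 2
        assert len(set(est.labels_[:4])) == 1 and len(set(est.labels_[4:])) == 1
        q_bf, _ = brute_force_best(W, 0.5)
        assert est.modularity_ == pytest.approx(q_bf, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_attains_exhaustive_optimum_on_small_random_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        W = random_signed_matrix(int(rng.integers(4, 7)), rng)
        est = SignedLouvain(gamma=0.5, n_restarts=50, random_state=seed).fit(W)
        q_bf, _ = brute_force_best(W, 0.5)
        assert est.modularity_ == pytest.approx(q_bf, abs=1e-9)

    def test_beats_or_matches_trivial_partition(self):
        rng = np.random.default_rng(7)
        W = random_signed_matrix(12, rng)
        est = SignedLouvain(n_restarts=20, random_state=0).fit(W)
        assert est.modularity_ >= signed_modularity(W, np.zeros(12), 0.5) - 1e-12

    def test_deterministic_and_sklearn_compatible(self):
        rng = np.random.default_rng(3)
        W = random_signed_matrix(15, rng)
        a = SignedLouvain(n_restarts=25, random_state=4).fit_predict(W)
        b = SignedLouvain(n_restarts=25, random_state=4).fit_predict(W)
        assert np.array_equal(a, b)
        est = SignedLouvain(gamma=0.7)
        assert est.get_params()["gamma"] == 0.7
        est.set_params(gamma=0.3)
        assert est.gamma == 0.3

    def test_all_zero_matrix_single_community(self):
        est = SignedLouvain().fit(np.zeros((5, 5)))
        assert est.n_communities_ == 1 and est.modularity_ == 0.0

    def test_planted_clusters_recovered(self, clustered_expression):
        E, labels = clustered_expression
        C = gce_matrix(E, E.gene_set())
        part = louvain_signed(C, gamma=0.5, seed=0, n_restarts=30)
        assert adjusted_rand_score(labels, part.labels()) == 1.0
        assert min(part.communities.values()) == 1  # ids contiguous from 1


class TestClusterMaps:
    def test_single_community_equals_set_average(self, clustered_expression):
        E, _ = clustered_expression
        from psymap.coexpression_network import Partition
        part = Partition(genes=E.genes, communities={g: 1 for g in E.genes},
                         modularity=0.0, gamma=0.5, seed=0, n_restarts=1)
        maps = cluster_maps(E, part)
        expect = set_average_map(E, GeneSet("all", E.genes))
        assert len(maps) == 1
        assert np.allclose(maps[0].values, expect.values, equal_nan=True)

    def test_singleton_community_is_gene_map(self, clustered_expression):
        E, _ = clustered_expression
        from psymap.coexpression_network import Partition
        comms = {g: 1 for g in E.genes}
        comms[E.genes[0]] = 2
        part = Partition(genes=E.genes, communities=comms, modularity=0.0,
                         gamma=0.5, seed=0, n_restarts=1)
        maps = cluster_maps(E, part)
        # named by descending size: Cluster 1 is the big one
        assert maps[0].name == "Cluster 1"
        assert np.allclose(maps[1].values, E.column(E.genes[0]), equal_nan=True)

    def test_detected_maps_match_distinct_planted_profiles(self, clustered_expression):
        E, labels = clustered_expression
        C = gce_matrix(E, E.gene_set())
        part = louvain_signed(C, seed=0, n_restarts=30)
        maps = cluster_maps(E, part)
        ok = ~E.missing_mask
        matches = []
        for c in sorted(set(labels)):
            planted = E.values[:, labels == c].mean(axis=1)
            rs = [np.corrcoef(planted[ok], m.values[ok])[0, 1] for m in maps]
            assert max(rs) > 0.9
            matches.append(int(np.argmax(rs)))
        assert len(set(matches)) == len(matches)
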