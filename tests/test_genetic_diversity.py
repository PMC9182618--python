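"""Mahalanobis D2, pooled dispersion, Tocher / hierarchical clustering, PCA."""

import numpy as np
import pandas as pd
import pytest

from metvar import (
    SimulationConfig,
    anova_rcbd,
    cluster_distance_summary,
    cluster_hierarchical,
    cluster_tocher,
    d2_matrix,
    mahalanobis_d2,
    pca_traits,
    pooled_error_covariance,
    simulate_met,
)
from metvar.genetic_diversity import D2Matrix, tocher_threshold
from metvar.trial_data import TraitSpec


def _d2_from_values(vals: np.ndarray, labels) -> D2Matrix:
    df = pd.DataFrame(vals, index=labels, columns=labels)
    return D2Matrix(genotypes=list(labels), values=df,
                    dispersion=pd.DataFrame(np.eye(1)))


def _two_cloud_means(rng, n=20, sep=40.0):
    """Two well-separated genotype clouds in 3-trait space."""
    half = n // 2
    a = rng.normal(0, 1, size=(half, 3))
    b = rng.normal(0, 1, size=(n - half, 3)) + sep
    means = pd.DataFrame(np.vstack([a, b]), columns=["t1", "t2", "t3"],
                         index=[f"G{i + 1}" for i in range(n)])
    labels = np.array([0] * half + [1] * (n - half))
    return means, labels


def _tetra_cloud_means(sep=40.0):
    """Two compact, internally equidistant clouds (tetrahedron vertices).

    Within-cloud D2 is identical for every pair (the edge of a regular
    tetrahedron), so Tocher's default threshold — the maximum
    nearest-neighbour D2 — admits every cloud member while the huge
    between-cloud distance (separation ratio >> 25) keeps the clouds apart.
    """
    tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float)
    pts = np.vstack([tetra, tetra + sep])
    means = pd.DataFrame(pts, columns=["t1", "t2", "t3"],
                         index=[f"G{i + 1}" for i in range(8)])
    labels = np.array([0] * 4 + [1] * 4)
    return means, labels


class TestPooledErrorCovariance:
    def test_single_trait_reduces_to_pooled_mse(self):
        ds, _ = simulate_met(SimulationConfig(n_genotypes=6, n_replicates=3,
                                              seed=13))
        W = pooled_error_covariance(ds)
        mses = [anova_rcbd(ds, "Y", loc).mse for loc in ds.locations]
        # equal error df per location, so the pool is the plain average
        assert W.loc["Y", "Y"] == pytest.approx(np.mean(mses), rel=1e-10)

    def test_independent_traits_near_diagonal(self):
        offs = []
        diags = []
        for seed in range(200):
            cfg = SimulationConfig(
                n_genotypes=8, n_replicates=3, locations=("L1",),
                traits=(TraitSpec("A"), TraitSpec("B")), mu=(0, 0),
                sigma_g=np.zeros((2, 2)), sigma_e=np.diag([2.0, 8.0]),
                sigma_gl=(0, 0), sigma_rep=(0, 0), seed=seed)
            ds, _ = simulate_met(cfg)
            W = pooled_error_covariance(ds)
            offs.append(W.loc["A", "B"])
            diags.append((W.loc["A", "A"], W.loc["B", "B"]))
        assert np.mean(offs) == pytest.approx(0.0, abs=0.15)
        d = np.mean(diags, axis=0)
        assert d[0] == pytest.approx(2.0, rel=0.1)
        assert d[1] == pytest.approx(8.0, rel=0.1)

    def test_duplicated_trait_flags_singular(self):
        ds, _ = simulate_met(SimulationConfig(n_genotypes=5, n_replicates=3,
                                              seed=2))
        df = ds.data.assign(Y2=ds.data["Y"])
        ds2 = ds.with_data(df)
        ds2.traits = (TraitSpec("Y"), TraitSpec("Y2"))
        with pytest.raises(np.linalg.LinAlgError):
            d2_matrix(ds2)
        d2 = d2_matrix(ds2, allow_pseudo_inverse=True)
        assert d2.singular_dispersion


class TestMahalanobisD2:
    def test_identical_vectors_zero(self):
        assert mahalanobis_d2([1, 2], [1, 2], np.eye(2)) == 0

    def test_identity_dispersion_reduces_to_euclidean(self):
        assert mahalanobis_d2([3, 4], [0, 0], np.eye(2)) == pytest.approx(25)

    def test_matches_linear_solver_oracle(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        W = A @ A.T + 4 * np.eye(4)
        d = a - b
        expected = float(d @ np.linalg.lstsq(W, d, rcond=None)[0])
        assert mahalanobis_d2(a, b, W) == pytest.approx(expected, rel=1e-8)

    def test_affine_invariance(self, rng):
        means = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"),
                             index=[f"G{i}" for i in range(6)])
        A = rng.normal(size=(3, 3))
        W = A @ A.T + np.eye(3)
        d2 = d2_matrix(means, dispersion=pd.DataFrame(W, index=list("abc"),
                                                      columns=list("abc")))
        for _ in range(5):
            M = rng.normal(size=(3, 3))
            M += 3 * np.eye(3)  # keep well-conditioned
            means_t = pd.DataFrame(means.to_numpy() @ M.T, index=means.index,
                                   columns=means.columns)
            Wt = pd.DataFrame(M @ W @ M.T, index=list("abc"), columns=list("abc"))
            d2_t = d2_matrix(means_t, dispersion=Wt)
            np.testing.assert_allclose(d2_t.values.to_numpy(),
                                       d2.values.to_numpy(), rtol=1e-8,
                                       atol=1e-8)

    def test_matrix_invariants(self, rng):
        means = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        d2 = d2_matrix(means, dispersion=pd.DataFrame(np.eye(2),
                                                      index=["a", "b"],
                                                      columns=["a", "b"]))
        v = d2.values.to_numpy()
        assert np.allclose(np.diag(v), 0)
        assert (v >= 0).all()
        assert np.allclose(v, v.T)


class TestClusterTocher:
    def test_identical_genotypes_single_cluster(self):
        vals = np.zeros((5, 5))
        ca = cluster_tocher(_d2_from_values(vals, [f"G{i}" for i in range(5)]))
        assert ca.n_clusters == 1
        assert sum(ca.percentages) == pytest.approx(100)

    def test_two_cloud_recovery(self):
        means, labels = _tetra_cloud_means()
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        ca = cluster_tocher(d2_matrix(means, dispersion=W))
        assert ca.n_clusters == 2
        member = ca.membership()
        got = np.array([member[g] for g in means.index])
        assert all(got[:4] == got[0]) and all(got[4:] == got[4])
        assert got[0] != got[4]

    def test_percentages_sum_and_partition(self, rng):
        ds, _ = simulate_met(SimulationConfig(seed=6))
        ca = cluster_tocher(d2_matrix(ds))
        assert sum(ca.percentages) == pytest.approx(100)
        assert sorted(g for c in ca.clusters for g in c) == sorted(ds.genotypes)
        # percentage arithmetic: count / 45 * 100
        for c, pct in zip(ca.clusters, ca.percentages):
            assert pct == pytest.approx(100 * len(c) / 45)

    def test_threshold_convention(self, rng):
        vals = np.array([[0, 1.0, 9], [1, 0, 8], [9, 8, 0]])
        d2 = _d2_from_values(vals, ["A", "B", "C"])
        # min off-diag per row: 1, 1, 8 -> threshold 8
        assert tocher_threshold(d2) == pytest.approx(8)


class TestClusterHierarchical:
    def test_k_equals_n_gives_singletons(self, rng):
        means, _ = _two_cloud_means(rng, n=8)
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        ca = cluster_hierarchical(d2_matrix(means, dispersion=W), k=8)
        assert ca.n_clusters == 8
        assert all(len(c) == 1 for c in ca.clusters)

    def test_k_one_single_cluster(self, rng):
        means, _ = _two_cloud_means(rng, n=6)
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        ca = cluster_hierarchical(d2_matrix(means, dispersion=W), k=1)
        assert ca.n_clusters == 1 and len(ca.clusters[0]) == 6

    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    def test_two_cloud_recovery(self, rng, linkage):
        means, labels = _two_cloud_means(rng)
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        ca = cluster_hierarchical(d2_matrix(means, dispersion=W),
                                  linkage=linkage, k=2)
        member = ca.membership()
        got = np.array([member[g] for g in means.index])
        assert all(got[:10] == got[0]) and all(got[10:] == got[10])
        assert got[0] != got[10]

    def test_newick_serialization_has_all_leaves(self, rng):
        means, _ = _two_cloud_means(rng, n=6)
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        ca = cluster_hierarchical(d2_matrix(means, dispersion=W), k=2)
        assert ca.newick.endswith(";")
        for g in means.index:
            assert g in ca.newick

    def test_invalid_k_rejected(self, rng):
        means, _ = _two_cloud_means(rng, n=4)
        W = pd.DataFrame(np.eye(3), index=means.columns, columns=means.columns)
        with pytest.raises(ValueError):
            cluster_hierarchical(d2_matrix(means, dispersion=W), k=9)


class TestClusterDistanceSummary:
    def test_hand_three_genotype_case(self):
        vals = np.array([[0, 2.0, 4], [2, 0, 6], [4, 6, 0]])
        d2 = _d2_from_values(vals, ["A", "B", "C"])
        ca = cluster_tocher(d2, threshold=3.0)
        tab = cluster_distance_summary(d2, ca)
        assert ca.clusters == [["A", "B"], ["C"]]
        assert tab.loc["I", "I"] == pytest.approx(2)      # intra {A,B}
        assert tab.loc["II", "II"] == 0                   # singleton
        assert tab.loc["I", "II"] == pytest.approx(5)     # mean(4, 6)

    def test_consistent_with_enumeration_oracle(self, rng):
        n = 12
        sym = rng.uniform(1, 10, size=(n, n))
        vals = (sym + sym.T) / 2
        np.fill_diagonal(vals, 0)
        labels = [f"G{i}" for i in range(n)]
        d2 = _d2_from_values(vals, labels)
        ca = cluster_tocher(d2)
        tab = cluster_distance_summary(d2, ca)
        for ci, cluster in enumerate(ca.clusters):
            pairs = [vals[labels.index(a), labels.index(b)]
                     for ai, a in enumerate(cluster) for b in cluster[ai + 1:]]
            expected = np.mean(pairs) if pairs else 0.0
            assert tab.iloc[ci, ci] == pytest.approx(expected)

    def test_bad_partition_rejected(self):
        vals = np.zeros((3, 3))
        d2 = _d2_from_values(vals, ["A", "B", "C"])
        ca = cluster_tocher(d2)
        ca.clusters = [["A", "B"]]  # drop C
        with pytest.raises(ValueError):
            cluster_distance_summary(d2, ca)


class TestPcaTraits:
    def test_perfectly_correlated_pair_loads_on_pc1(self, rng):
        x = rng.normal(size=30)
        means = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_traits(means, mode="correlation")
        assert res.percent_variance[0] == pytest.approx(100, abs=1e-8)

    def test_percent_variance_sums_to_100(self, rng):
        means = pd.DataFrame(rng.normal(size=(20, 5)))
        for mode in ("correlation", "covariance"):
            res = pca_traits(means, mode=mode)
            assert res.percent_variance.sum() == pytest.approx(100, abs=1e-6)
            assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_scores_reconstruct_centered_data(self, rng):
        means = pd.DataFrame(rng.normal(size=(15, 4)))
        res = pca_traits(means, mode="covariance")
        rebuilt = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = means.to_numpy() - means.to_numpy().mean(axis=0)
        np.testing.assert_allclose(rebuilt, centered, atol=1e-8)

    def test_uncorrelated_equal_variance_traits_share_variance(self):
        shares = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            means = pd.DataFrame(rng.normal(size=(40, 3)))
            shares.append(pca_traits(means).percent_variance)
        mean_shares = np.mean(shares, axis=0)
        # sampling spread orders components, but each should be near 1/3
        assert mean_shares[0] < 50 and mean_shares[-1] > 20

    def test_constant_trait_rejected_in_correlation_mode(self, rng):
        means = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            pca_traits(means, mode="correlation")

    def test_covariance_mode_dominated_by_large_scale_trait(self, rng):
        means = pd.DataFrame({
            "small": rng.normal(0, 1, size=40),
            "big": rng.normal(0, 100, size=40),
        })
        res = pca_traits(means, mode="covariance")
        assert res.percent_variance[0] > 99
        assert abs(res.loadings.loc["big", "PC1"]) > 0.99
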