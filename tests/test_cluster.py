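"""Clustering, cluster-number selection, Hopkins, VAT and the SOM."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from exonml import (
    fuzzy_cmeans,
    hcpc,
    hopkins,
    kmeans_multi,
    order_clusters_by_abundance,
    run_pca,
    select_k,
    som_fit,
    vat,
)
from exonml.features import FeatureMatrix, scale_matrix
from exonml.som import InsufficientObservationsError


def scaled(df):
    return scale_matrix(FeatureMatrix(data=pd.DataFrame(df)))


class TestKMeansMulti:
    def test_k_bounds_enforced(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            kmeans_multi(X, 1)
        with pytest.raises(ValueError):
            kmeans_multi(X, len(X))

    def test_best_of_restarts_no_worse_than_single_starts(self, blobs):
        X, _ = blobs
        best = kmeans_multi(X, 3, n_starts=50, seed=0)
        for s in range(5):
            single = kmeans_multi(X, 3, n_starts=1, seed=100 + s)
            assert best.total_wss <= single.total_wss + 1e-9

    def test_recovers_blobs_and_is_order_invariant(self, blobs):
        X, truth = blobs
        a = kmeans_multi(X, 3, seed=1)
        assert adjusted_rand_score(truth, a.labels) == 1.0
        perm = np.random.default_rng(0).permutation(len(X))
        b = kmeans_multi(X.iloc[perm], 3, seed=7)
        assert adjusted_rand_score(truth[perm], b.labels) == 1.0

    def test_wss_matches_label_center_distances(self, blobs):
        X, _ = blobs
        a = kmeans_multi(X, 3, seed=2)
        manual = 0.0
        M = X.to_numpy()
        for c in range(1, 4):
            mask = (a.labels == c).to_numpy()
            manual += ((M[mask] - a.centers.loc[c].to_numpy()) ** 2).sum()
        assert a.total_wss == pytest.approx(manual, rel=1e-6)

    def test_abundance_ordering_relabels_consistently(self, table4_raw):
        a = kmeans_multi(table4_raw, 3, seed=1)
        abundance = table4_raw[["alc1", "alc2", "cont1", "cont2"]].mean(axis=1)
        ordered = order_clusters_by_abundance(a, abundance)
        means = abundance.groupby(ordered).mean()
        assert means.is_monotonic_increasing


class TestSelectK:
    def test_three_blobs_unanimous(self, blobs):
        X, _ = blobs
        ks = select_k(X, kmax=8, n_starts=20, gap_B=30, seed=0)
        assert ks.elbow_k == 3
        assert ks.silhouette_k == 3
        assert ks.gap_k == 3
        assert ks.consensus_k == 3

    def test_wss_curve_non_increasing(self, blobs):
        X, _ = blobs
        ks = select_k(X, kmax=8, n_starts=20, gap_B=10, seed=0)
        assert (np.diff(ks.table["wss"].to_numpy()) <= 1e-6).all()

    def test_kmax_bounds(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            select_k(X, kmax=1)
        with pytest.raises(ValueError):
            select_k(X.head(5), kmax=5)


class TestHCPC:
    def test_two_blob_recovery_with_automatic_k(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.5, (25, 3)), rng.normal(8, 0.5, (25, 3))])
        truth = np.repeat([0, 1], 25)
        p = run_pca(scaled(X))
        a = hcpc(p)
        assert a.k == 2
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_k_equal_n_gives_singletons_with_zero_wss(self):
        rng = np.random.default_rng(2)
        p = run_pca(scaled(rng.normal(size=(8, 3))))
        a = hcpc(p, k=8)
        assert a.total_wss == pytest.approx(0.0)
        assert a.labels.nunique() == 8

    def test_consolidation_never_increases_wss(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(40, 4))
        p = run_pca(scaled(S))
        from scipy.cluster.hierarchy import fcluster, linkage

        for k in (2, 3, 5):
            a = hcpc(p, k=k)
            Zl = linkage(p.scores.to_numpy(), method="ward")
            lab0 = fcluster(Zl, t=k, criterion="maxclust")
            M = p.scores.to_numpy()
            wss0 = sum(((M[lab0 == c] - M[lab0 == c].mean(axis=0)) ** 2).sum() for c in np.unique(lab0))
            assert a.total_wss <= wss0 + 1e-9

    def test_too_few_observations_rejected(self):
        fm = scaled(np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 3.0], [2.0, 2.0, 1.0]]))
        p = run_pca(fm)
        # 3 observations is the minimum; 2 rows cannot even reach PCA
        assert hcpc(p, k=2).k == 2


class TestFuzzyCMeans:
    def test_membership_rows_sum_to_one(self, blobs):
        X, _ = blobs
        a = fuzzy_cmeans(X, 3, seed=0)
        assert np.allclose(a.membership.sum(axis=1), 1.0, atol=1e-6)
        assert a.converged

    def test_equidistant_point_gets_half_membership(self):
        # symmetric configuration around the midpoint observation
        X = pd.DataFrame({"x": [-5.0, -5.0, -5.1, 5.0, 5.0, 5.1, 0.0], "y": 0.0})
        a = fuzzy_cmeans(X, 2, seed=1)
        mid = a.membership.iloc[-1].to_numpy()
        assert mid == pytest.approx([0.5, 0.5], abs=0.01)

    def test_fuzzifier_bound(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            fuzzy_cmeans(X, 3, fuzzifier=1.0)

    def test_raw_mirna_matrix_replicates_kmeans_partition(self, table4_raw):
        km = kmeans_multi(table4_raw, 3, seed=1)
        fc = fuzzy_cmeans(table4_raw, 3, seed=1)
        assert adjusted_rand_score(km.labels, fc.labels) == 1.0


class TestHopkins:
    def test_uniform_data_near_half(self):
        rng = np.random.default_rng(0)
        U = pd.DataFrame(rng.uniform(size=(200, 4)))
        h = hopkins(U, repeats=100, seed=1, ranges=(np.zeros(4), np.ones(4)))
        assert 0.45 <= h.H <= 0.55

    def test_tight_clusters_score_low(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1e-3, (20, 3)), rng.normal(5, 1e-3, (20, 3))])
        h = hopkins(pd.DataFrame(X), repeats=50, seed=0)
        assert h.H < 0.1

    def test_sample_size_bound(self):
        X = pd.DataFrame(np.eye(5))
        with pytest.raises(ValueError):
            hopkins(X, m=5)

    def test_recomputable_from_stored_sums(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        h = hopkins(X, repeats=40, seed=3)
        assert h.per_repeat.shape == (40,)
        assert h.H == pytest.approx(h.per_repeat.mean())
        pooled = h.sum_real / (h.sum_real + h.sum_uniform)
        assert pooled == pytest.approx(h.H, abs=0.1)

    def test_scalar_affine_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        h1 = hopkins(pd.DataFrame(X), repeats=30, seed=5)
        h2 = hopkins(pd.DataFrame(3.5 * X + 2.0), repeats=30, seed=5)
        assert h1.H == pytest.approx(h2.H, abs=1e-12)


class TestVat:
    def test_ordering_is_a_permutation(self, blobs):
        X, _ = blobs
        v = vat(X)
        assert sorted(v.ordering) == list(range(len(X)))

    def test_ordered_matrix_is_consistent_permutation(self, blobs):
        X, _ = blobs
        from scipy.spatial.distance import pdist, squareform

        v = vat(X)
        D = squareform(pdist(X.to_numpy()))
        assert np.allclose(v.ordered_dissimilarity, D[np.ix_(v.ordering, v.ordering)])

    def test_two_observations(self):
        v = vat(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))
        assert v.ordered_dissimilarity.shape == (2, 2)
        assert v.ordered_dissimilarity[0, 1] == pytest.approx(np.sqrt(2))

    def test_planted_blocks_appear_on_diagonal(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.3, (15, 3)), rng.normal(6, 0.3, (15, 3))])
        v = vat(pd.DataFrame(X))
        O = v.ordered_dissimilarity
        within = (O[:15, :15].sum() + O[15:, 15:].sum()) / (2 * 15 * 14)
        between = O[:15, 15:].mean()
        assert within < between


class TestSom:
    def test_mirna_matrix_refused_on_study_grid(self, table4_scaled):
        with pytest.raises(InsufficientObservationsError, match="insufficient"):
            som_fit(table4_scaled, grid=(15, 10))

    def test_training_curve_decreases(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.5, (100, 4)), rng.normal(5, 0.5, (100, 4))])
        res = som_fit(scaled(X), epochs=2000, learning_rate=0.05, seed=0)
        assert res.training_curve.iloc[-1] <= res.training_curve.iloc[0]
        assert res.node_assignments.between(0, np.prod(res.grid) - 1).all()

    def test_codebook_partition_recovers_planted_clusters(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.5, (250, 4)), rng.normal(6, 0.5, (250, 4))])
        truth = np.repeat([0, 1], 250)
        res = som_fit(scaled(X), epochs=4000, learning_rate=0.05, n_partitions=2, seed=1)
        assert adjusted_rand_score(truth, res.partition) > 0.9
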