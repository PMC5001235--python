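"""Dissimilarity transform, classical MDS, K-means, silhouettes, gene sets."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from dcorstrat import stratify, synthetic, variant_io
from dcorstrat.dcor import DistanceCorrelationMatrix
from dcorstrat.stratify import (
    classical_mds,
    group_specific_genes,
    kmeans_cluster,
    silhouette_profile,
    to_dissimilarity,
)
from dcorstrat.variant_io import SMGProfile

from conftest import cluster_cohort


def dcm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    return DistanceCorrelationMatrix(values=values, patient_ids=ids)


class TestToDissimilarity:
    def test_elementwise_complement(self):
        D = dcm([[1.0, 0.25, 0.0], [0.25, 1.0, 1.0], [0.0, 1.0, 1.0]])
        S = to_dissimilarity(D)
        assert S.values[0, 1] == pytest.approx(0.75)
        assert S.values[0, 2] == pytest.approx(1.0)
        assert S.values[1, 2] == pytest.approx(0.0)
        np.testing.assert_array_equal(np.diag(S.values), 0.0)

    def test_out_of_range_entries_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            to_dissimilarity(dcm([[1.0, 1.4], [1.4, 1.0]]))


class TestClassicalMDS:
    def test_collinear_points_recovered_in_one_dimension(self):
        S = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        emb = classical_mds(S, k=3)
        # one positive axis suffices for an exactly 1-D configuration
        coords = emb.coordinates
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec, S, atol=1e-9)

    def test_all_zero_dissimilarity_embeds_at_origin(self):
        emb = classical_mds(np.zeros((4, 4)), k=3)
        np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-12)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_euclidean_round_trip(self, dim):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(12, dim))
        S = squareform(pdist(pts))
        emb = classical_mds(S, k=dim)
        rec = squareform(pdist(emb.coordinates))
        np.testing.assert_allclose(rec, S, atol=1e-9)

    def test_agrees_with_pcoa_oracle(self):
        """Torgerson scaling cross-checked against scikit-bio's principal
        coordinates analysis on the same dissimilarity."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        S = squareform(pdist(pts))
        ours = squareform(pdist(classical_mds(S, k=3).coordinates))
        theirs = squareform(pdist(pcoa(S, number_of_dimensions=3).samples.values))
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(9, 4))
        emb = classical_mds(squareform(pdist(pts)), k=3)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)

    def test_asymmetric_input_rejected(self):
        S = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(S)


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.05, size=(20, 2)), rng.normal(50, 0.05, size=(20, 2))]
        )
        truth = np.array([0] * 20 + [1] * 20)
        assign = kmeans_cluster(X, K=2, replicates=10, seed=1)
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_single_cluster_within_ss_is_total_ss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        assign = kmeans_cluster(X, K=1, replicates=3, seed=0)
        total = float(np.sum((X - X.mean(axis=0)) ** 2))
        assert assign.within_ss == pytest.approx(total)

    def test_k_equals_n_gives_zero_within_ss(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        assign = kmeans_cluster(X, K=6, replicates=3, seed=0)
        assert assign.within_ss == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(np.zeros((3, 2)), K=4)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        a = kmeans_cluster(X, K=3, replicates=10, seed=5)
        b = kmeans_cluster(X, K=3, replicates=10, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_patient_reordering_invariant_up_to_label_permutation(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(0, 0.1, size=(10, 2)), rng.normal(10, 0.1, size=(10, 2))]
        )
        perm = rng.permutation(20)
        a = kmeans_cluster(X, K=2, replicates=10, seed=0)
        b = kmeans_cluster(X[perm], K=2, replicates=10, seed=0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


class TestSilhouette:
    def test_perfectly_separated_coincident_pairs(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        assign = kmeans_cluster(X, K=2, replicates=2, seed=0)
        values, mean = silhouette_profile(X, assign)
        assert mean == pytest.approx(1.0)

    def test_random_labels_on_one_blob_score_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        means = []
        for seed in range(5):
            labels = np.random.default_rng(seed).integers(1, 3, size=60)
            assign = stratify.ClusterAssignment(
                patient_ids=[str(i) for i in range(60)],
                labels=labels, K=2, within_ss=np.nan, seed=seed, replicates=0,
            )
            _, mean = silhouette_profile(X, assign)
            means.append(mean)
        assert abs(np.mean(means)) < 0.15

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [0.2], [9.0]])
        assign = stratify.ClusterAssignment(
            patient_ids=["a", "b", "c", "d"],
            labels=np.array([1, 1, 1, 2]), K=2, within_ss=np.nan, seed=0, replicates=0,
        )
        values, _ = silhouette_profile(X, assign)
        assert values[3] == 0.0

    def test_single_cluster_rejected(self):
        X = np.zeros((4, 2))
        assign = stratify.ClusterAssignment(
            patient_ids=list("abcd"), labels=np.ones(4, dtype=int),
            K=1, within_ss=0.0, seed=0, replicates=0,
        )
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette_profile(X, assign)


class TestGroupGeneSets:
    @staticmethod
    def _assign(labels):
        return stratify.ClusterAssignment(
            patient_ids=[f"P{i}" for i in range(len(labels))],
            labels=np.asarray(labels), K=len(set(labels)),
            within_ss=np.nan, seed=0, replicates=0,
        )

    def test_set_algebra_example(self):
        profiles = {
            "P0": SMGProfile("P0", frozenset(["g1", "g2"])),
            "P1": SMGProfile("P1", frozenset(["g2", "g3"])),
        }
        sets = group_specific_genes(self._assign([1, 2]), profiles)
        assert sets.specific[1] == {"g1"}
        assert sets.specific[2] == {"g3"}
        assert sets.shared == {"g2"}

    def test_identical_unions_have_no_specific_genes(self):
        profiles = {
            "P0": SMGProfile("P0", frozenset(["g1"])),
            "P1": SMGProfile("P1", frozenset(["g1"])),
        }
        sets = group_specific_genes(self._assign([1, 2]), profiles)
        assert sets.specific[1] == sets.specific[2] == frozenset()

    def test_matches_exhaustive_membership_enumeration(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        profiles = {
            f"P{i}": SMGProfile(f"P{i}", frozenset(rng.choice(genes, 5, replace=False)))
            for i in range(9)
        }
        labels = [1, 2, 3] * 3
        sets = group_specific_genes(self._assign(labels), profiles)
        for g in genes:
            present_in = {
                label
                for pid, label in zip(profiles, labels)
                if g in profiles[pid].genes
            }
            for k in (1, 2, 3):
                assert (g in sets.specific[k]) == (present_in == {k})
        # specific sets are pairwise disjoint and within their union
        for k in (1, 2, 3):
            assert sets.specific[k] <= sets.unions[k]
            for k2 in (1, 2, 3):
                if k != k2:
                    assert not (sets.specific[k] & sets.specific[k2])


def test_planted_group_membership_stable_between_k3_and_k5(strong_cohort):
    """Raising the cluster count from 3 to 5 refines rather than reshuffles
    the partition: the two extra centroids subdivide some groups, but at
    least one planted functional group keeps its K=3 membership essentially
    intact (best-matching-cluster Jaccard > 0.8)."""
    a3, profiles = cluster_cohort(strong_cohort, K=3, seed=0)
    a5, _ = cluster_cohort(strong_cohort, K=5, seed=0, profiles=profiles)
    stabilities = []
    for g in range(3):
        truth_g = {p for p, grp in strong_cohort.truth.group_of.items() if grp == g}
        members3 = set(
            max(
                (a3.members(k) for k in range(1, 4)),
                key=lambda m: len(set(m) & truth_g),
            )
        )
        best = max(
            len(set(a5.members(k)) & members3) / len(set(a5.members(k)) | members3)
            for k in range(1, 6)
        )
        stabilities.append(best)
    assert max(stabilities) > 0.8
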