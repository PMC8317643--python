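import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from restforge.clustering import (
    PopulationClustering,
    ahc_linkage,
    cut_top,
    denormalize_population,
    normalize_population,
    percentile_constrain,
)
from restforge.params import make_base_params


@pytest.fixture()
def base_vec():
    return make_base_params().to_vector()


def _raw_from_norm(norm, base_vec):
    raw = np.zeros_like(norm)
    nz = base_vec != 0
    raw[:, nz] = base_vec[nz] * np.exp2(norm[:, nz])
    return raw


@pytest.fixture()
def two_blobs(rng, base_vec):
    nz = base_vec != 0
    n1, n2 = 60, 40
    norm = np.zeros((n1 + n2, 28))
    norm[:n1, nz] = rng.normal(0, 0.1, (n1, nz.sum()))
    norm[n1:, nz] = rng.normal(0, 0.1, (n2, nz.sum()))
    norm[n1:, 9] += 6.0  # separate along one parameter axis
    labels = np.r_[np.zeros(n1, dtype=int), np.ones(n2, dtype=int)]
    return _raw_from_norm(norm, base_vec), labels, norm


class TestNormalization:
    def test_base_population_maps_to_zero(self, base_vec):
        pm = normalize_population(np.tile(base_vec, (5, 1)))
        assert np.all(pm.values == 0.0)

    def test_doubling_gives_one(self, base_vec):
        row = base_vec.copy()
        nz = row != 0
        row[nz] *= 2.0
        pm = normalize_population(row[None, :])
        assert np.allclose(pm.values[0, nz], 1.0)

    def test_roundtrip(self, two_blobs):
        raw, _, _ = two_blobs
        pm = normalize_population(raw)
        assert np.allclose(denormalize_population(pm), raw, rtol=1e-12)

    def test_nonpositive_rejected(self, base_vec):
        bad = np.tile(base_vec, (2, 1))
        bad[0, 9] = -1.0
        with pytest.raises(ValueError):
            normalize_population(bad)


class TestLinkage:
    def test_two_blob_recovery_and_cophenetic(self, two_blobs):
        raw, labels, _ = two_blobs
        pc = PopulationClustering(k=2).fit(raw)
        assert adjusted_rand_score(labels, pc.labels_) == 1.0
        assert pc.cophenetic_ > 0.95
        assert tuple(pc.cluster_sizes_) == (60, 40)

    def test_duplicate_only_matrix_flags_undefined_cophenetic(self, base_vec):
        tree = ahc_linkage(normalize_population(np.tile(base_vec, (6, 1))))
        assert tree.cophenetic is None

    def test_merge_heights_nondecreasing(self, two_blobs):
        raw, _, _ = two_blobs
        tree = ahc_linkage(normalize_population(raw))
        heights = tree.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_row_permutation_invariance(self, two_blobs, rng):
        raw, labels, _ = two_blobs
        perm = rng.permutation(raw.shape[0])
        a = PopulationClustering(k=2).fit(raw).labels_
        b = PopulationClustering(k=2).fit(raw[perm]).labels_
        assert adjusted_rand_score(a[perm], b) == 1.0


class TestCut:
    def test_outlier_split(self, base_vec):
        norm = np.zeros((21, 28))
        nz = base_vec != 0
        norm[20, nz] = 8.0
        raw = _raw_from_norm(norm, base_vec)
        pm = normalize_population(raw)
        cut = cut_top(ahc_linkage(pm), 2)
        assert tuple(cut.sizes) == (20, 1)

    def test_k_equals_n(self, two_blobs):
        raw, _, _ = two_blobs
        pm = normalize_population(raw[:8])
        cut = cut_top(ahc_linkage(pm), 8)
        assert np.all(cut.sizes == 1)

    def test_sizes_sum_and_coarsening(self, two_blobs):
        raw, _, _ = two_blobs
        tree = ahc_linkage(normalize_population(raw))
        c2 = cut_top(tree, 2)
        c4 = cut_top(tree, 4)
        assert c2.sizes.sum() == c4.sizes.sum() == raw.shape[0]
        # top-2 is a coarsening of top-4: each top-4 cluster maps into one top-2 cluster
        for k4 in range(4):
            members = c4.labels == k4
            assert len(np.unique(c2.labels[members])) == 1

    def test_centroids_near_blob_centers(self, two_blobs):
        raw, labels, norm = two_blobs
        tree = ahc_linkage(normalize_population(raw))
        cut = cut_top(tree, 2)
        got = normalize_population(cut.centroids[1].to_vector()[None, :]).values[0]
        true_center = norm[labels == 1].mean(axis=0)
        sigma_bound = 3 * 0.1 / np.sqrt((labels == 1).sum())
        assert np.max(np.abs(got - true_center)) < max(3 * sigma_bound, 0.1)


class TestPercentileConstraint:
    def test_p100_is_identity(self, two_blobs):
        raw, _, _ = two_blobs
        pm = normalize_population(raw)
        out = percentile_constrain(pm, 100.0)
        assert np.array_equal(out.values, pm.values)

    def test_single_row_retained(self, base_vec):
        pm = normalize_population(base_vec[None, :])
        assert percentile_constrain(pm, 95.0).n == 1

    def test_planted_outliers_removed(self, base_vec, rng):
        nz = base_vec != 0
        norm = np.zeros((105, 28))
        norm[:, nz] = rng.normal(0, 0.2, (105, nz.sum()))
        norm[:5, nz] = 10.0  # extreme rows
        pm = normalize_population(_raw_from_norm(norm, base_vec))
        kept = percentile_constrain(pm, 95.0)
        assert not np.any(kept.row_index < 5)

    def test_invalid_p(self, base_vec):
        pm = normalize_population(np.tile(base_vec, (4, 1)))
        with pytest.raises(ValueError):
            percentile_constrain(pm, 40.0)
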