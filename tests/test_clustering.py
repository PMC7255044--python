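import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clusterflim import (
    DecayCube,
    accumulate_fls,
    build_features,
    cluster_flim,
    euclidean_distance,
    kmeans_partition,
    match_fls_to_reference,
    poisson_refine,
    render_false_color,
)
from clusterflim.clustering import DEFAULT_PALETTE, MASK_COLOR
from clusterflim.synthetic import block_layout, simulate_image


class TestBuildFeatures:
    def test_dim_pixels_masked_at_threshold(self):
        counts = np.zeros((1, 2, 4), dtype=int)
        counts[0, 0] = [3, 3, 2, 1]  # 9 photons: below a 10-count threshold
        counts[0, 1] = [4, 3, 2, 1]  # 10 photons: kept
        fm = build_features(DecayCube(counts), b=4, min_counts=10)
        assert fm.mask.tolist() == [[False, True]]
        assert fm.n_pixels == 1

    def test_rows_normalized_to_unit_area(self, small_cube):
        fm = build_features(small_cube, b=8, min_counts=1)
        assert np.allclose(fm.features.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance_of_features(self):
        counts = np.zeros((1, 2, 3), dtype=int)
        counts[0, 0] = [1, 2, 1]
        counts[0, 1] = [10, 20, 10]
        fm = build_features(DecayCube(counts), b=3, min_counts=1)
        assert np.allclose(fm.features[0], fm.features[1])

    def test_all_masked_raises_helpful_error(self, small_cube):
        with pytest.raises(ValueError, match="min_counts"):
            build_features(small_cube, b=8, min_counts=10**9)


class TestEuclideanDistance:
    def test_identity_and_pythagorean(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        x, c = rng.uniform(size=8), rng.uniform(size=8)
        assert euclidean_distance(x, c) == pytest.approx(euclidean_distance(c, x))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1.0], [1.0, 2.0])


def _brute_force_sse(points: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster SSE over all assignments."""
    best = np.inf
    n = len(points)
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        sse = 0.0
        a = np.asarray(assign)
        for c in range(k):
            grp = points[a == c]
            sse += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestKmeansPartition:
    def test_k1_center_is_mean_and_inertia_is_scatter(self, rng):
        X = rng.normal(size=(20, 3))
        labels, centers, inertia = kmeans_partition(X, 1, seed=0)
        assert np.allclose(centers[0], X.mean(axis=0))
        assert inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_well_separated_1d_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, _, inertia = kmeans_partition(X, 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert inertia == pytest.approx(_brute_force_sse(X, 2))

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_optimum_on_small_inputs(self, trial):
        # oracle: exhaustive enumeration of all 2-partitions of <= 8 points
        rng = np.random.default_rng(100 + trial)
        X = rng.uniform(size=(7, 2))
        _, _, inertia = kmeans_partition(X, 2, seed=1, restarts=20)
        assert inertia == pytest.approx(_brute_force_sse(X, 2), rel=1e-9)

    def test_contract_on_labels(self, rng):
        X = rng.normal(size=(30, 4))
        labels, _, _ = kmeans_partition(X, 3, seed=0)
        assert len(labels) == 30
        assert set(labels) == {0, 1, 2}

    def test_k_larger_than_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_partition(rng.normal(size=(3, 2)), 4)


class TestAccumulateFls:
    def test_single_cluster_equals_total_histogram(self, small_cube):
        mask = small_cube.pixel_totals() >= 1
        labels = np.zeros(int(mask.sum()), dtype=int)
        fls = accumulate_fls(small_cube, labels, mask, k=1)
        assert np.array_equal(fls[0], small_cube.counts[mask].sum(axis=0))

    def test_exact_photon_conservation(self, small_cube, rng):
        mask = small_cube.pixel_totals() >= 3
        labels = rng.integers(0, 3, size=int(mask.sum()))
        fls = accumulate_fls(small_cube, labels, mask, k=3)
        assert fls.sum() == small_cube.counts[mask].sum()


class TestClusterFlim:
    def test_k1_single_cluster_full_fraction(self, two_species_image):
        cube, _, _ = two_species_image
        result = cluster_flim(cube, k=1, b=32, min_counts=10, seed=0)
        assert result.k == 1
        assert result.fractions.tolist() == [1.0]
        assert (result.labels >= 0).all()

    def test_recovers_two_species_blocks(self, two_species_image):
        cube, truth, _ = two_species_image
        result = cluster_flim(cube, k=2, b=32, min_counts=10, seed=0)
        keep = result.labels >= 0
        agreement = max(
            (result.labels[keep] == truth[keep]).mean(),
            (result.labels[keep] == 1 - truth[keep]).mean(),
        )
        assert agreement > 0.99

    def test_seed_stability_high_counts(self, two_species_image):
        cube, _, _ = two_species_image
        r1 = cluster_flim(cube, k=2, b=32, seed=1)
        r2 = cluster_flim(cube, k=2, b=32, seed=99)
        keep = r1.labels >= 0
        ari = adjusted_rand_score(r1.labels[keep], r2.labels[keep])
        assert ari >= 0.99

    def test_exact_photon_conservation_of_fls(self, two_species_image):
        cube, _, _ = two_species_image
        result = cluster_flim(cube, k=2, b=32, seed=0)
        unmasked_total = cube.counts[result.labels >= 0].sum()
        assert result.fls.sum() == unmasked_total
        assert result.member_counts.sum() == (result.labels >= 0).sum()
        assert result.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_labels(self, two_species_image):
        # multiplying every histogram by an integer factor leaves the
        # partition unchanged (features are shape-only)
        cube, _, _ = two_species_image
        scaled = DecayCube(cube.counts * 10, cube.channel_width)
        r1 = cluster_flim(cube, k=2, b=32, seed=5)
        r2 = cluster_flim(scaled, k=2, b=32, seed=5)
        keep = r1.labels >= 0
        assert adjusted_rand_score(r1.labels[keep], r2.labels[keep]) == pytest.approx(1.0)

    def test_clusters_ordered_by_ascending_lifetime(self, two_species_image):
        cube, _, _ = two_species_image
        result = cluster_flim(cube, k=2, b=32, seed=0)
        assert result.mean_lifetimes_ns[0] <= result.mean_lifetimes_ns[1]


class TestPoissonRefine:
    def test_fixed_point_of_pure_partition(self, two_species_image):
        cube, truth, _ = two_species_image
        mask = cube.pixel_totals() >= 10
        X = cube.counts[mask].astype(float)
        labels, converged = poisson_refine(X, truth[mask].astype(int), 2)
        assert converged
        # starting from the exact partition, reassignment must stay near it
        assert (labels == truth[mask]).mean() > 0.99


class TestRenderFalseColor:
    def test_all_masked_renders_white(self):
        from clusterflim.clustering import ClusterResult

        result = ClusterResult(
            labels=np.full((4, 4), -1),
            centers=np.zeros((2, 3)),
            fls=np.zeros((2, 8), dtype=int),
            member_counts=np.zeros(2, dtype=int),
            fractions=np.full(2, np.nan),
            channel_width=19.97,
            mean_lifetimes_ns=np.zeros(2),
        )
        img = render_false_color(result)
        assert np.allclose(img, np.array(MASK_COLOR))

    def test_k_clusters_plus_mask_colors(self, two_species_image):
        cube, _, _ = two_species_image
        result = cluster_flim(cube, k=2, b=32, seed=0)
        result.labels[0, 0] = -1  # force at least one masked pixel
        img = render_false_color(result)
        colors = {tuple(c) for c in img.reshape(-1, 3)}
        assert colors == {MASK_COLOR, DEFAULT_PALETTE[0], DEFAULT_PALETTE[1]}


def test_cross_image_cluster_matching_recovers_permutation(two_species_image):
    cube, _, _ = two_species_image
    ref = cluster_flim(cube, k=2, b=32, seed=0)
    other = cluster_flim(cube, k=2, b=32, seed=3)
    perm = match_fls_to_reference(other, ref)
    assert sorted(perm.tolist()) == [0, 1]
    # same image, so matched identities must agree pixel-wise
    remapped = np.where(other.labels >= 0, perm[other.labels], -1)
    assert np.array_equal(remapped, ref.labels)
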