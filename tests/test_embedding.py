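import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from vtatrace.embedding import (
    AggregatedDistanceMatrix,
    aggregate_distances,
    cluster_regions,
    compare_datasets,
    embed_ensemble,
    mixing_score,
    normalized_pairwise_distance,
    zscore_regions,
)
from vtatrace.quantify import FractionMatrix, fraction_matrix
from vtatrace.synthetic import (
    GeneratorConfig,
    default_archetype_loadings,
    generate_cohort,
    generate_two_dataset_scenario,
)


def _fm(values, brains=None, regions=None):
    brains = brains or [f"b{i}" for i in range(values.shape[0])]
    regions = regions or [f"r{i}" for i in range(values.shape[1])]
    return FractionMatrix(
        values=pd.DataFrame(values, index=brains, columns=regions)
    )


class TestZScore:
    def test_hand_computed_values(self):
        """Counts 1..4 across four brains standardize to +/-1.162, +/-0.387."""
        fm = _fm(np.array([[1.0], [2.0], [3.0], [4.0]]))
        z = zscore_regions(fm)
        np.testing.assert_allclose(
            z.values.loc["r0"].to_numpy(),
            [-1.161895, -0.387298, 0.387298, 1.161895],
            atol=1e-6,
        )

    def test_constant_row_zeroed_with_warning(self):
        fm = _fm(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0], [5.0, 4.0]]))
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_regions(fm)
        assert (z.values.loc["r0"] == 0).all()
        assert z.constant_regions == ["r0"]

    def test_rows_standardized(self, cohort4, catalog):
        z = zscore_regions(fraction_matrix(cohort4, catalog))
        keep = [r for r in z.region_names if r not in z.constant_regions]
        means = z.values.loc[keep].mean(axis=1)
        sds = z.values.loc[keep].std(axis=1, ddof=1)
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_requires_two_brains(self):
        with pytest.raises(ValueError):
            zscore_regions(_fm(np.array([[1.0, 2.0]])))


class TestNormalizedDistance:
    def test_two_points_self_normalize(self):
        d = normalized_pairwise_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == 1.0 and d[1, 0] == 1.0
        assert d[0, 0] == 0.0

    def test_three_collinear_points(self):
        d = normalized_pairwise_distance(
            np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        )
        expected = np.array([[0, 0.5, 1.0], [0.5, 0, 0.5], [1.0, 0.5, 0]])
        np.testing.assert_allclose(d, expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(57, 2))
        d = normalized_pairwise_distance(pts)
        # O(n^2) reference: explicit loops, then divide by max
        n = len(pts)
        ref = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                ref[i, j] = np.hypot(*(pts[i] - pts[j]))
        ref /= ref.max()
        np.testing.assert_allclose(d, ref, atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            normalized_pairwise_distance(np.zeros((3, 2)))


class TestAggregation:
    def test_identical_matrices_average_to_themselves(self):
        m = normalized_pairwise_distance(np.array([[0.0, 0], [1, 0], [0, 2]]))
        agg = aggregate_distances([m] * 20)
        np.testing.assert_allclose(agg.values.to_numpy(), m)
        assert agg.n_embeddings == 20

    def test_mean_of_zero_and_m_is_half_m(self):
        m = normalized_pairwise_distance(np.array([[0.0, 0], [1, 0], [0, 2]]))
        agg = aggregate_distances([np.zeros_like(m), m])
        np.testing.assert_allclose(agg.values.to_numpy(), m / 2)

    def test_invariants_validated(self):
        bad = pd.DataFrame(np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            AggregatedDistanceMatrix(bad, 1, [0]).validate()
        with pytest.raises(ValueError, match="shape"):
            aggregate_distances([np.zeros((2, 2)), np.zeros((3, 3))])


@pytest.fixture(scope="module")
def planted(catalog):
    """Low-noise z-scored cohort with the three planted projection archetypes."""
    cfg = GeneratorConfig(n_brains=8, noise_scale=0.05, seed=21)
    cohort = generate_cohort(cfg, catalog)
    return zscore_regions(fraction_matrix(cohort, catalog))


@pytest.fixture(scope="module")
def scenario_config():
    return GeneratorConfig(n_brains=12, seed=5)


class TestEnsembleAndClustering:
    def test_ensemble_shape_and_determinism(self, planted):
        embs = embed_ensemble(planted.values.to_numpy(), n_embeddings=3,
                              seeds=[5, 6, 7])
        assert len(embs) == 3
        assert all(e.shape == (57, 2) for e in embs)
        again = embed_ensemble(planted.values.to_numpy(), n_embeddings=1,
                               seeds=[5])
        np.testing.assert_allclose(embs[0], again[0])

    def test_duplicate_seeds_rejected(self, planted):
        with pytest.raises(ValueError, match="distinct"):
            embed_ensemble(planted.values.to_numpy(), n_embeddings=2,
                           seeds=[1, 1])

    def test_neighborhood_larger_than_points_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_ensemble(np.zeros((5, 3)), n_embeddings=1, n_neighbors=10)

    def test_planted_archetypes_recovered(self, planted, catalog):
        """Full stage recovers the three planted clusters (ARI >= 0.9)."""
        embs = embed_ensemble(planted.values.to_numpy(), n_embeddings=20)
        mats = [normalized_pairwise_distance(e) for e in embs]
        agg = aggregate_distances(mats, region_names=planted.region_names)
        assignment = cluster_regions(agg)
        assert assignment.k == 3
        loadings = default_archetype_loadings(catalog)
        truth = [int(np.argmax(loadings[r])) for r in assignment.labels.index]
        assert adjusted_rand_score(truth, assignment.labels.to_numpy()) >= 0.9

    def test_within_archetype_distances_smaller(self, planted, catalog):
        """In every embedding, planted groups are tighter than the whole cloud."""
        embs = embed_ensemble(planted.values.to_numpy(), n_embeddings=5,
                              seeds=range(50, 55))
        loadings = default_archetype_loadings(catalog)
        truth = np.array(
            [int(np.argmax(loadings[r])) for r in planted.region_names]
        )
        for pts in embs:
            d = normalized_pairwise_distance(pts)
            same = truth[:, None] == truth[None, :]
            off_diag = ~np.eye(len(truth), dtype=bool)
            within = d[same & off_diag].mean()
            between = d[~same].mean()
            assert within < between

    def test_k_one_returns_single_cluster(self, planted):
        embs = embed_ensemble(planted.values.to_numpy(), n_embeddings=2,
                              seeds=[0, 1])
        agg = aggregate_distances(
            [normalized_pairwise_distance(e) for e in embs],
            region_names=planted.region_names,
        )
        assignment = cluster_regions(agg, k=1)
        assert assignment.k == 1
        assert (assignment.labels == 0).all()

    def test_k_larger_than_regions_rejected(self, planted):
        embs = embed_ensemble(planted.values.to_numpy(), n_embeddings=1,
                              seeds=[0])
        agg = aggregate_distances(
            [normalized_pairwise_distance(e) for e in embs],
            region_names=planted.region_names,
        )
        with pytest.raises(ValueError):
            cluster_regions(agg, k=58)


class TestMixingScore:
    def test_separated_clouds_score_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(100, 0.1, size=(20, 2))
        pts = np.vstack([a, b])
        labels = ["a"] * 20 + ["b"] * 20
        score, chance = mixing_score(pts, labels)
        assert score == 1.0
        assert chance == pytest.approx(19 / 39 * 0.5 * 2, abs=1e-9)

    def test_permuted_labels_score_near_chance(self):
        """Under label exchangeability the score matches the analytic chance."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(60, 2))
        base = np.array(["a"] * 30 + ["b"] * 30)
        scores = []
        for _ in range(100):
            scores.append(mixing_score(pts, rng.permutation(base))[0])
        chance = mixing_score(pts, base)[1]
        assert np.mean(scores) == pytest.approx(chance, abs=0.02)

    def test_knn_at_least_group_size_rejected(self):
        pts = np.arange(12, dtype=float).reshape(6, 2)
        with pytest.raises(ValueError):
            mixing_score(pts, ["a"] * 3 + ["b"] * 3, k_nn=3)

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            mixing_score(np.zeros((10, 2)), ["a"] * 10)


class TestCompareDatasets:
    def test_shared_composition_mixes(self, scenario_config, catalog):
        a, b = generate_two_dataset_scenario(True, scenario_config, catalog)
        report = compare_datasets(
            a, b, catalog, subset="long_range",
            n_embeddings=10, n_permutations=100, seed=1,
        )
        assert report["mixing_score"] < report["chance"] + 0.15
        assert report["permutation_p"] > 0.05

    def test_disjoint_composition_segregates(self, scenario_config, catalog):
        a, b = generate_two_dataset_scenario(False, scenario_config, catalog)
        report = compare_datasets(
            a, b, catalog, subset="excluded",
            n_embeddings=10, n_permutations=100, seed=1,
        )
        assert report["mixing_score"] > 0.9
        assert report["permutation_p"] < 0.05

    def test_identical_cohorts_mix(self, scenario_config, catalog):
        a, _ = generate_two_dataset_scenario(True, scenario_config, catalog)
        report = compare_datasets(
            a, a, catalog, subset="questionable",
            n_embeddings=5, n_permutations=100, seed=2,
        )
        assert report["permutation_p"] > 0.05

    def test_unknown_subset_rejected(self, scenario_config, catalog):
        a, b = generate_two_dataset_scenario(True, scenario_config, catalog)
        with pytest.raises(ValueError):
            compare_datasets(a, b, catalog, subset="everything")
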