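"""K-Means behaviour, silhouette conventions, thresholds and outlier clusters."""

import itertools

import numpy as np
import pytest

from modscreen import PhenotypeTable
from modscreen.clustering import (ClusterModel, ThresholdSpec,
                                  compute_thresholds, embed_2d,
                                  identify_outliers, kmeans, silhouette)
from conftest import make_strain_expression


def exhaustive_two_partition_wss(points: np.ndarray) -> float:
    """Minimum WSS over every 2-partition, by brute-force enumeration."""
    n = len(points)
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in group A
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        for group in (points[mask], points[~mask]):
            if len(group) == 0:
                break
        else:
            wss = sum(((grp - grp.mean(axis=0)) ** 2).sum()
                      for grp in (points[mask], points[~mask]))
            best = min(best, wss)
    return best


class TestKMeans:
    def test_k_equals_n_gives_zero_wss(self, rng):
        data = make_strain_expression(rng.normal(size=(6, 4)))
        model = kmeans(data, k=6, seed=0)
        assert model.wss == pytest.approx(0.0, abs=1e-12)
        assert sorted(model.sizes) == [1] * 6

    def test_two_point_masses_recovered(self, rng):
        a = rng.normal(0, 0.05, (8, 3))
        b = rng.normal(10, 0.05, (7, 3)) + 10
        data = make_strain_expression(np.vstack([a, b]))
        model = kmeans(data, k=2, seed=3)
        labels = model.labels
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_model_invariants(self, rng):
        data = make_strain_expression(rng.normal(size=(20, 5)))
        model = kmeans(data, k=4, seed=1)
        assert model.sizes.sum() == 20 and np.all(model.sizes >= 1)
        X = data.values
        for j in range(model.k):
            members = X[model.labels == j + 1]
            np.testing.assert_allclose(model.centroids[j], members.mean(axis=0),
                                       atol=1e-9)
        d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
        own = d2[np.arange(20), model.labels - 1]
        assert np.all(own <= d2.min(axis=1) + 1e-9)

    def test_matches_exhaustive_optimum_on_small_1d_instances(self, rng):
        """Best-of-10-restarts equals the brute-force optimum >= 95/100."""
        hits = 0
        for trial in range(100):
            n = int(rng.integers(4, 9))
            pts = rng.normal(0, 1, (n, 1)) * rng.uniform(0.5, 3)
            data = make_strain_expression(pts)
            model = kmeans(data, k=2, seed=trial, n_restarts=10)
            best = exhaustive_two_partition_wss(pts)
            if model.wss <= best + 1e-9:
                hits += 1
            assert model.wss >= best - 1e-9  # never beats the true optimum
        assert hits >= 95

    def test_wss_trace_non_increasing(self, rng):
        data = make_strain_expression(rng.normal(size=(40, 6)))
        model = kmeans(data, k=5, seed=2)
        trace = np.array(model.wss_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_deterministic_given_seed(self, rng):
        data = make_strain_expression(rng.normal(size=(30, 4)))
        m1 = kmeans(data, k=3, seed=7)
        m2 = kmeans(data, k=3, seed=7)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        assert m1.wss == m2.wss

    def test_k_larger_than_n_rejected(self, rng):
        data = make_strain_expression(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            kmeans(data, k=4, seed=0)


class TestSilhouette:
    def test_separated_singletons_get_zero(self):
        data = make_strain_expression([[0.0, 0.0], [1e6, 1e6]])
        model = kmeans(data, k=2, seed=0)
        widths, mean = silhouette(data, model)
        assert widths == pytest.approx([0.0, 0.0])
        assert mean == 0.0

    def test_tight_separated_blobs_near_one(self, rng):
        a = rng.normal(0, 0.01, (10, 3))
        b = rng.normal(0, 0.01, (10, 3)) + 50
        data = make_strain_expression(np.vstack([a, b]))
        model = kmeans(data, k=2, seed=0)
        _, mean = silhouette(data, model)
        assert mean > 0.9

    def test_unstructured_data_near_zero(self, rng):
        data = make_strain_expression(rng.normal(size=(60, 8)))
        model = kmeans(data, k=2, seed=0)
        _, mean = silhouette(data, model)
        assert abs(mean) < 0.25

    def test_k1_rejected(self, rng):
        data = make_strain_expression(rng.normal(size=(5, 2)))
        model = kmeans(data, k=1, seed=0)
        with pytest.raises(ValueError):
            silhouette(data, model)


class TestEmbed2D:
    def test_2d_input_preserves_distances(self, rng):
        X = rng.normal(size=(10, 2))
        coords = embed_2d(make_strain_expression(X))
        orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        new = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(new, orig, atol=1e-9)

    def test_rank1_second_coordinate_zero(self):
        base = np.arange(6, dtype=float)
        X = np.column_stack([base, 2 * base, -base])
        coords = embed_2d(make_strain_expression(X))
        np.testing.assert_allclose(coords[:, 1], 0.0, atol=1e-9)

    def test_scores_match_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 4))
        coords = embed_2d(make_strain_expression(X))
        Xc = X - X.mean(axis=0)
        vals, vecs = np.linalg.eigh(np.cov(Xc.T))
        order = np.argsort(vals)[::-1]
        expected = Xc @ vecs[:, order[:2]]
        for j in range(2):  # eigenvector sign is arbitrary
            assert (np.allclose(coords[:, j], expected[:, j], atol=1e-9)
                    or np.allclose(coords[:, j], -expected[:, j], atol=1e-9))


class TestThresholds:
    def test_published_values(self):
        """partition 3273.628, upper 24,075.48, lower 17,528.23."""
        pheno = PhenotypeTable([1, 2, 3], np.array([27349.11, 14254.6, 20000.0]))
        spec = compute_thresholds(pheno)
        assert spec.partition == pytest.approx((27349.11 - 14254.6) / 4)
        assert f"{spec.partition:.3f}" == "3273.628"
        assert f"{spec.upper:.2f}" == "24075.48"
        assert f"{spec.lower:.2f}" == "17528.23"

    def test_degenerate_equal_sizes(self):
        pheno = PhenotypeTable([1, 2], np.array([5.0, 5.0]))
        spec = compute_thresholds(pheno)
        assert spec.partition == 0 and spec.upper == spec.lower == 5.0

    def test_simple_range(self):
        pheno = PhenotypeTable([1, 2], np.array([4.0, 0.1]))
        spec = compute_thresholds(pheno)
        assert spec.partition == pytest.approx(0.975)
        assert spec.upper == pytest.approx(3.025)
        assert spec.lower == pytest.approx(1.075)

    def test_invariant_to_order_and_interior_duplication(self, rng):
        sizes = rng.uniform(10, 30, 15)
        pheno = PhenotypeTable(list(range(1, 16)), sizes)
        spec = compute_thresholds(pheno)
        perm = rng.permutation(15)
        shuffled = PhenotypeTable([int(i + 100) for i in perm], sizes[perm])
        spec2 = compute_thresholds(shuffled)
        assert (spec.partition, spec.upper, spec.lower) == (
            spec2.partition, spec2.upper, spec2.lower)
        interior = float(np.sort(sizes)[7])
        dup = PhenotypeTable(list(range(1, 17)), np.append(sizes, interior))
        spec3 = compute_thresholds(dup)
        assert (spec.partition, spec.upper, spec.lower) == (
            spec3.partition, spec3.upper, spec3.lower)

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds(PhenotypeTable([1], np.array([2.0])))


def _model_from_labels(strain_ids, labels):
    labels = np.asarray(labels)
    k = labels.max()
    return ClusterModel(k=int(k), strain_ids=list(strain_ids), labels=labels,
                        centroids=np.zeros((k, 1)),
                        sizes=np.bincount(labels - 1, minlength=k),
                        wss=0.0, seed=0, n_iter=1)


class TestIdentifyOutliers:
    def test_simple_example(self):
        sizes = [25, 26, 25.5, 15, 16, 20, 21]
        pheno = PhenotypeTable(list(range(1, 8)), np.array(sizes, dtype=float))
        model = _model_from_labels(range(1, 8), [1, 1, 1, 2, 2, 3, 3])
        spec = ThresholdSpec(min_size=15, max_size=25)  # upper 22.5, lower 17.5
        out = identify_outliers(model, pheno, spec)
        assert out.high_cluster == 1 and out.low_cluster == 2
        assert out.counts_above == {1: 3, 2: 0, 3: 0}
        assert out.counts_below == {1: 0, 2: 2, 3: 0}

    def test_threshold_boundary_is_strict(self):
        pheno = PhenotypeTable([1, 2, 3, 4], np.array([23.0, 24.0, 10.0, 9.0]))
        model = _model_from_labels([1, 2, 3, 4], [1, 1, 2, 2])
        spec = ThresholdSpec(min_size=11, max_size=27)  # upper 23, lower 15
        out = identify_outliers(model, pheno, spec)
        # strain 1 sits exactly at the upper threshold: not counted
        assert out.counts_above[1] == 1

    def test_tie_fails_loudly(self):
        pheno = PhenotypeTable([1, 2, 3, 4], np.array([30.0, 30.0, 1.0, 1.0]))
        model = _model_from_labels([1, 2, 3, 4], [1, 2, 1, 2])
        spec = ThresholdSpec(min_size=1, max_size=30)
        with pytest.raises(ValueError, match="tied"):
            identify_outliers(model, pheno, spec)

    def test_no_outliers_fails(self):
        pheno = PhenotypeTable([1, 2], np.array([20.0, 21.0]))
        model = _model_from_labels([1, 2], [1, 2])
        spec = ThresholdSpec(min_size=0, max_size=100)
        with pytest.raises(ValueError, match="no outlier cluster"):
            identify_outliers(model, pheno, spec)

    def test_counts_match_naive_double_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            sizes = rng.uniform(0, 100, n)
            labels = rng.integers(1, 5, n)
            labels[:4] = [1, 2, 3, 4]  # every cluster populated
            pheno = PhenotypeTable(list(range(1, n + 1)), sizes)
            model = _model_from_labels(range(1, n + 1), labels)
            spec = ThresholdSpec(min_size=float(sizes.min()),
                                 max_size=float(sizes.max()))
            above = {c: 0 for c in range(1, 5)}
            below = {c: 0 for c in range(1, 5)}
            for s, lab in zip(range(1, n + 1), labels):  # naive oracle
                v = sizes[s - 1]
                if v > spec.upper:
                    above[int(lab)] += 1
                if v < spec.lower:
                    below[int(lab)] += 1
            try:
                out = identify_outliers(model, pheno, spec)
            except ValueError:
                continue  # tie or empty side: oracle agrees it is ambiguous
            assert out.counts_above == above
            assert out.counts_below == below
            assert above[out.high_cluster] == max(above.values())
            assert below[out.low_cluster] == max(below.values())
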