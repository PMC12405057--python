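"""Adaptive hierarchical clustering: Lance-Williams oracle equivalence,
inconsistency definition checks (including against scipy), adaptive-cut
semantics, quality-index oracles, threshold search, and profiling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from beevein.clustering import (
    ClusterResult,
    adaptive_cut,
    cluster_features,
    cluster_quality,
    inconsistency,
    optimize_threshold,
    profile_clusters,
    standardize,
    ward_linkage,
)
from beevein.features import FEATURE_NAMES


# ---------------------------------------------------------------- oracles
def brute_force_ward(x: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive O(n^3) Ward agglomeration via the Lance-Williams recurrence,
    written independently of scipy.  Returns (set_a, set_b, height) merges;
    ties broken by the smallest (i, j) index pair."""
    n = len(x)
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((x[i] - x[j]) ** 2).sum())
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((clusters[i], clusters[j], np.sqrt(best)))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            d2[(k, new)] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        for k in (i, j):
            del clusters[k], sizes[k]
        d2 = {key: v for key, v in d2.items() if i not in key and j not in key}
    return merges


def brute_force_inconsistency(z: np.ndarray, depth: int) -> np.ndarray:
    """Definition-level recomputation of the coefficient."""
    n = len(z) + 1

    def collect(i, d):
        out = [z[i, 2]]
        if d > 1:
            for c in (int(z[i, 0]), int(z[i, 1])):
                if c >= n:
                    out += collect(c - n, d - 1)
        return out

    coeffs = []
    for i in range(len(z)):
        h = collect(i, depth)
        if len(h) < 2 or np.std(h, ddof=1) == 0:
            coeffs.append(0.0)
        else:
            coeffs.append((z[i, 2] - np.mean(h)) / np.std(h, ddof=1))
    return np.array(coeffs)


def brute_force_quality(x: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Silhouette / DBI / CH straight from their definitions."""
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    labs = np.unique(labels)
    # silhouette
    sil = []
    for i in range(len(x)):
        same = [j for j in range(len(x)) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same]) if same else 0.0
        bs = []
        for lab in labs:
            if lab == labels[i]:
                continue
            other = [j for j in range(len(x)) if labels[j] == lab]
            bs.append(np.mean([np.linalg.norm(x[i] - x[j]) for j in other]))
        b = min(bs)
        sil.append(0.0 if not same else (b - a) / max(a, b))
    # DBI
    cents = {lab: x[labels == lab].mean(axis=0) for lab in labs}
    s = {
        lab: np.mean([np.linalg.norm(p - cents[lab]) for p in x[labels == lab]])
        for lab in labs
    }
    dbi = np.mean(
        [
            max(
                (s[a] + s[b]) / np.linalg.norm(cents[a] - cents[b])
                for b in labs
                if b != a
            )
            for a in labs
        ]
    )
    # CH
    mean = x.mean(axis=0)
    ssb = sum(len(x[labels == lab]) * np.linalg.norm(cents[lab] - mean) ** 2 for lab in labs)
    ssw = sum(
        np.linalg.norm(p - cents[lab]) ** 2 for lab in labs for p in x[labels == lab]
    )
    k, n = len(labs), len(x)
    ch = (ssb / (k - 1)) / (ssw / (n - k))
    return float(np.mean(sil)), float(dbi), float(ch)


# ----------------------------------------------------------------- tests
class TestWardLinkage:
    def test_one_dimensional_example(self):
        z = ward_linkage(np.array([0.0, 1.0, 10.0]))
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(np.sqrt(361 / 3))

    def test_identical_points_merge_at_zero(self):
        z = ward_linkage(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert z[0, 2] == pytest.approx(0.0)

    def test_heights_monotone_and_sizes_consistent(self):
        rng = np.random.default_rng(1)
        z = ward_linkage(rng.random((30, 4)))
        assert (np.diff(z[:, 2]) >= -1e-12).all()
        assert z[-1, 3] == 30

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0], [np.nan]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_merge_sets_and_heights(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((7, 3))
        z = ward_linkage(x)
        oracle = brute_force_ward(x)
        n = len(x)
        members: list[frozenset] = [frozenset([i]) for i in range(n)]
        for row, (oa, ob, oh) in zip(z, oracle):
            a, b = members[int(row[0])], members[int(row[1])]
            assert {a, b} == {oa, ob}
            assert row[2] == pytest.approx(oh, abs=1e-9)
            members.append(a | b)


class TestInconsistency:
    def test_equal_heights_zero_coefficients(self):
        x = np.array([0.0, 2.0, 8.0, 10.0])  # symmetric: two equal first merges
        z = ward_linkage(x)
        records = inconsistency(z, depth=2)
        assert records[0].coefficient == 0.0
        assert records[1].coefficient == 0.0

    def test_hand_computed_neighborhood(self):
        # heights {2, 2, 4} with the merge itself at 4
        z = np.array(
            [
                [0.0, 1.0, 2.0, 2.0],
                [2.0, 3.0, 2.0, 2.0],
                [4.0, 5.0, 4.0, 4.0],
            ]
        )
        rec = inconsistency(z, depth=2)[2]
        assert rec.mean == pytest.approx(8 / 3)
        assert rec.coefficient == pytest.approx((4 - 8 / 3) / np.std([2, 2, 4], ddof=1))
        assert rec.coefficient == pytest.approx(np.sqrt(4 / 3))

    def test_bottom_merge_convention(self):
        z = ward_linkage(np.array([0.0, 1.0, 10.0]))
        assert inconsistency(z, depth=2)[0].coefficient == 0.0

    def test_invalid_depth(self):
        z = ward_linkage(np.array([0.0, 1.0, 10.0]))
        with pytest.raises(ValueError):
            inconsistency(z, depth=0)

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_matches_scipy_and_brute_force(self, depth):
        rng = np.random.default_rng(7)
        z = ward_linkage(rng.random((20, 5)))
        mine = np.array([r.coefficient for r in inconsistency(z, depth)])
        assert mine == pytest.approx(brute_force_inconsistency(z, depth), abs=1e-12)
        assert mine == pytest.approx(sch.inconsistent(z, depth)[:, 3], abs=1e-10)


class TestAdaptiveCut:
    def test_threshold_above_max_one_cluster(self):
        z = ward_linkage(np.random.default_rng(0).random((12, 2)))
        assert len(np.unique(adaptive_cut(z, threshold=1e9))) == 1
        assert len(np.unique(adaptive_cut(z, threshold=1e9, criterion="height"))) == 1

    def test_negative_threshold_all_singletons(self):
        x = np.random.default_rng(0).random((10, 2))
        z = ward_linkage(x)
        assert len(np.unique(adaptive_cut(z, threshold=-1.0, criterion="height"))) == 10

    def test_two_blobs_recovered(self):
        x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        z = ward_linkage(x)
        labels = adaptive_cut(z, threshold=1.0)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    @pytest.mark.parametrize("threshold", [0.5, 1.0, 1.15, 2.0])
    def test_matches_scipy_fcluster_inconsistent(self, threshold):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        z = ward_linkage(rng.random((25, 4)))
        mine = adaptive_cut(z, threshold=threshold, depth=2)
        ref = sch.fcluster(z, t=threshold, criterion="inconsistent", depth=2)
        assert adjusted_rand_score(mine, ref) == 1.0

    @pytest.mark.parametrize("threshold", [0.3, 0.8, 1.5])
    def test_height_criterion_matches_scipy_distance(self, threshold):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        z = ward_linkage(rng.random((25, 4)))
        mine = adaptive_cut(z, threshold=threshold, criterion="height")
        ref = sch.fcluster(z, t=threshold, criterion="distance")
        assert adjusted_rand_score(mine, ref) == 1.0

    def test_non_finite_threshold_rejected(self):
        z = ward_linkage(np.array([0.0, 1.0, 10.0]))
        with pytest.raises(ValueError):
            adaptive_cut(z, threshold=np.inf)


class TestClusterQuality:
    def test_two_pair_fixture(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        s, d, c = cluster_quality(x, np.array([0, 0, 1, 1]))
        assert s == pytest.approx(0.8997, abs=1e-4)
        assert d == pytest.approx(0.1)
        assert c == pytest.approx(200.0)

    def test_degenerate_labelings_rejected(self):
        x = np.random.default_rng(0).random((6, 2))
        with pytest.raises(ValueError):
            cluster_quality(x, np.zeros(6, dtype=int))
        with pytest.raises(ValueError):
            cluster_quality(x, np.arange(6))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_definitions(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((8, 3))
        labels = rng.integers(0, 3, 8)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        s, d, c = cluster_quality(x, labels)
        so, do, co = brute_force_quality(x, labels)
        assert s == pytest.approx(so, abs=1e-9)
        assert d == pytest.approx(do, abs=1e-9)
        assert c == pytest.approx(co, abs=1e-9)


class TestOptimizeThreshold:
    def test_single_threshold_returned(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        best, table = optimize_threshold(x, [1.0], n_folds=2, seed=0)
        assert best == 1.0
        assert list(table.columns) == ["threshold", "silhouette", "dbi", "ch"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold(np.random.default_rng(0).random((20, 2)), [])

    def test_table_has_one_row_per_threshold(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.2, (12, 2)), rng.normal(4, 0.2, (12, 2))])
        _, table = optimize_threshold(x, [0.5, 1.0, 2.0], n_folds=2, seed=0)
        assert len(table) == 3


class TestClusterFeatures:
    def test_three_gaussian_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        x = np.vstack(
            [rng.normal(c, 0.3, (30, 5)) for c in (0.0, 4.0, 9.0)]
        )
        truth = np.repeat([0, 1, 2], 30)
        res = cluster_features(x, seed=5)
        assert isinstance(res, ClusterResult)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.silhouette > 0.5

    def test_silhouette_trend_rises_then_falls(self, regime_features):
        """Across the height grid the fold-averaged silhouette rises to a
        peak and falls at the extremes (unimodal trend, coarse check)."""
        table, _ = regime_features
        x = table.drop(columns=["image_id"]).to_numpy()
        res = cluster_features(x, seed=11)
        sil = res.metrics_table["silhouette"].to_numpy()
        peak = int(np.argmax(sil))
        assert 0 < peak < len(sil) - 1
        assert sil[peak] > sil[0] and sil[peak] > sil[-1]


class TestProfileClusters:
    @staticmethod
    def _table(densities):
        data = np.zeros((len(densities), 45))
        data[:, 0] = densities
        return pd.DataFrame(data, columns=list(FEATURE_NAMES))

    def test_single_cluster_one_row(self):
        table = self._table([0.1, 0.2, 0.3])
        summary, extras = profile_clusters(table, np.zeros(3, dtype=int))
        assert len(summary) == 1
        assert summary.loc[0, "size"] == 3
        assert extras == {}

    def test_density_mean_and_population_sd(self):
        table = self._table([0.1, 0.2])
        summary, _ = profile_clusters(table, np.zeros(2, dtype=int))
        assert summary.loc[0, "density_mean"] == pytest.approx(0.15)
        assert summary.loc[0, "density_sd"] == pytest.approx(0.05)

    def test_perfect_recovery_diagonal_contingency(self):
        table = self._table([0.1, 0.1, 0.5, 0.5])
        labels = np.array([0, 0, 1, 1])
        manifest = pd.DataFrame({"regime_label": ["a", "a", "b", "b"]})
        _, extras = profile_clusters(table, labels, manifest)
        assert extras["ari"] == 1.0
        cont = extras["contingency"]
        assert cont.loc[0, "a"] == 2 and cont.loc[1, "b"] == 2
        assert cont.loc[0, "b"] == 0 and cont.loc[1, "a"] == 0


def test_standardize_unit_variance_and_zero_variance_passthrough():
    rng = np.random.default_rng(0)
    x = rng.random((50, 3))
    x[:, 2] = 7.0
    z = standardize(x)
    assert np.allclose(z[:, :2].std(axis=0), 1.0)
    assert np.allclose(z[:, 2], 0.0)
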