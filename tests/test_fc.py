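"""Sliding-window FC, edge series, edge clustering and the high-order network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnrfc import cohort as coh
from dnrfc import fc
from dnrfc.errors import ConfigurationError, DimensionError


def _subject(series, sid="s0", label=coh.NON_DNR):
    return coh.SubjectSeries(sid, label, series)


class TestCountWindows:
    @pytest.mark.parametrize("t,w,s,expected", [(115, 90, 1, 26), (10, 10, 1, 1), (12, 10, 2, 2)])
    def test_examples(self, t, w, s, expected):
        assert fc.count_windows(t, fc.WindowSpec(w, s)) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(t=st.integers(2, 200), w=st.integers(2, 200), s=st.integers(1, 10))
    def test_matches_window_enumeration(self, t, w, s):
        """K equals the number of full windows [j*s, j*s+w) fitting in t points."""
        spec = fc.WindowSpec(w, s)
        if w > t:
            with pytest.raises(DimensionError):
                fc.count_windows(t, spec)
            return
        enumerated = sum(1 for j in range(t) if j * s + w <= t)
        assert fc.count_windows(t, spec) == enumerated
        slices = fc.window_slices(t, spec)
        assert len(slices) == enumerated
        assert all(sl.stop - sl.start == w and sl.stop <= t for sl in slices)


class TestLowOrderFC:
    def test_copied_roi_gives_unit_correlation(self, rng):
        x = rng.normal(size=(1, 30))
        series = np.vstack([x, x, rng.normal(size=(1, 30))])
        d = fc.low_order_fc(_subject(series), fc.WindowSpec(10, 5))
        assert np.allclose(d.matrices[:, 0, 1], 1.0)

    def test_negated_roi_gives_minus_one(self, rng):
        x = rng.normal(size=30)
        series = np.vstack([x, -x])
        d = fc.low_order_fc(_subject(series), fc.WindowSpec(10, 5))
        assert np.allclose(d.matrices[:, 0, 1], -1.0)

    def test_matches_direct_pearson_formula(self, rng):
        """Every entry equals the covariance / sd product computed by hand."""
        series = rng.normal(size=(4, 20))
        spec = fc.WindowSpec(10, 5)
        d = fc.low_order_fc(_subject(series), spec)
        for j, sl in enumerate(fc.window_slices(20, spec)):
            win = series[:, sl]
            for p in range(4):
                for q in range(4):
                    xp = win[p] - win[p].mean()
                    xq = win[q] - win[q].mean()
                    expected = (xp @ xq) / np.sqrt((xp @ xp) * (xq @ xq))
                    assert abs(d.matrices[j, p, q] - expected) < 1e-12

    def test_full_window_equals_static_fc(self, rng):
        """w = t yields K = 1 and the static full-series correlation matrix."""
        series = rng.normal(size=(5, 40))
        d = fc.low_order_fc(_subject(series), fc.WindowSpec(40, 3))
        assert d.matrices.shape[0] == 1
        np.testing.assert_allclose(d.matrices[0], np.corrcoef(series), atol=1e-12)

    def test_constant_roi_raises_with_context(self):
        series = np.vstack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="ROI 0.*window 0"):
            fc.low_order_fc(_subject(series, sid="subX"), fc.WindowSpec(10, 5))

    def test_symmetry_and_range(self, small_dynamic_fc):
        for d in small_dynamic_fc:
            for m in d.matrices:
                assert np.max(np.abs(m - m.T)) < 1e-12
                assert np.all(m <= 1.0) and np.all(m >= -1.0)
                np.testing.assert_allclose(np.diag(m), 1.0)


class TestAverageLowOrder:
    def test_average_is_elementwise_mean(self, small_dynamic_fc):
        d = small_dynamic_fc[0]
        np.testing.assert_allclose(
            fc.average_low_order(d), d.matrices.sum(axis=0) / d.matrices.shape[0],
            atol=1e-15,
        )


class TestEdgeSeries:
    def test_edge_count_for_90_rois(self, rng):
        series = rng.normal(size=(90, 12))
        d = fc.low_order_fc(_subject(series), fc.WindowSpec(6, 2))
        es = fc.edge_series(d)
        assert es.series.shape[0] == 90 * 89 // 2 == 4005

    def test_three_roi_edge_ordering(self, rng):
        series = rng.normal(size=(3, 12))
        es = fc.edge_series(fc.low_order_fc(_subject(series), fc.WindowSpec(6, 2)))
        assert es.edge_index == [(0, 1), (0, 2), (1, 2)]

    def test_rows_match_matrix_entries(self, small_dynamic_fc):
        d = small_dynamic_fc[0]
        es = fc.edge_series(d)
        for row, (p, q) in zip(es.series, es.edge_index):
            np.testing.assert_array_equal(row, d.matrices[:, p, q])

    def test_single_window_rejected(self, rng):
        d = fc.low_order_fc(_subject(rng.normal(size=(3, 10))), fc.WindowSpec(10, 1))
        with pytest.raises(ConfigurationError):
            fc.edge_series(d)

    def test_nonstationary_edges_vary_more_across_windows(self, rng):
        """Piecewise covariance change shows up as edge-series variance."""
        half = 60
        z = rng.normal(size=(2, 2 * half))
        stationary = np.vstack([z[0], 0.8 * z[0] + 0.6 * z[1]])
        flip = np.concatenate([np.ones(half), -np.ones(half)])
        nonstationary = np.vstack([z[0], (0.8 * z[0] + 0.6 * z[1]) * flip])
        spec = fc.WindowSpec(20, 5)
        var_s = fc.edge_series(fc.low_order_fc(_subject(stationary), spec)).series.var(axis=1)
        var_n = fc.edge_series(fc.low_order_fc(_subject(nonstationary), spec)).series.var(axis=1)
        assert var_n[0] > 5 * var_s[0]


class TestEdgeClustering:
    def _bundled_edges(self):
        """6 edges in 2 well-separated bundles of constant profiles."""
        k = 8
        series = np.vstack([
            np.tile(np.linspace(0.8, 0.9, k), (3, 1)) + 1e-3 * np.arange(3)[:, None],
            np.tile(np.linspace(-0.5, -0.6, k), (3, 1)) + 1e-3 * np.arange(3)[:, None],
        ])
        return fc.EdgeSeriesSet("s0", fc.edge_pairs(4), series)

    def test_two_bundles_separated_exactly(self):
        es = self._bundled_edges()
        clustering = fc.fit_edge_clustering([es], n_clusters=2, seed=0)
        a = clustering.assignment
        assert len(set(a[:3])) == 1 and len(set(a[3:])) == 1 and a[0] != a[3]
        # oracle: exhaustive 2-partitions — the bundle split minimizes
        # within-cluster sum of squares
        best = None
        for mask in range(1, 2 ** 6 - 1):
            groups = [[i for i in range(6) if (mask >> i) & 1],
                      [i for i in range(6) if not (mask >> i) & 1]]
            wss = sum(
                np.sum((es.series[g] - es.series[g].mean(axis=0)) ** 2)
                for g in groups if g
            )
            if best is None or wss < best[0]:
                best = (wss, groups)
        assert sorted(map(sorted, best[1])) == [[0, 1, 2], [3, 4, 5]]

    def test_n_clusters_equal_edge_count_is_identity(self):
        es = self._bundled_edges()
        clustering = fc.fit_edge_clustering([es], n_clusters=6, seed=0)
        assert sorted(clustering.assignment.tolist()) == list(range(6))

    def test_deterministic_under_seed(self, small_dynamic_fc):
        train = [fc.edge_series(d) for d in small_dynamic_fc[:4]]
        a = fc.fit_edge_clustering(train, n_clusters=5, seed=3)
        b = fc.fit_edge_clustering(train, n_clusters=5, seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.fitted_on == [d.subject_id for d in small_dynamic_fc[:4]]

    def test_too_many_clusters_rejected(self, small_dynamic_fc):
        train = [fc.edge_series(small_dynamic_fc[0])]
        with pytest.raises(ConfigurationError):
            fc.fit_edge_clustering(train, n_clusters=10**6)

    def test_every_cluster_nonempty(self, small_dynamic_fc):
        train = [fc.edge_series(d) for d in small_dynamic_fc[:4]]
        clustering = fc.fit_edge_clustering(train, n_clusters=8, seed=0)
        assert np.unique(clustering.assignment).size == 8


class TestHighOrderFC:
    def test_matches_brute_force_pearson_on_mean_series(self, small_dynamic_fc):
        es = fc.edge_series(small_dynamic_fc[0])
        clustering = fc.fit_edge_clustering([es], n_clusters=4, seed=0)
        high = fc.high_order_fc(es, clustering)
        means = fc.cluster_mean_series(es, clustering)
        for c in range(4):
            for d in range(4):
                a = means[c] - means[c].mean()
                b = means[d] - means[d].mean()
                expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert abs(high.matrix[c, d] - expected) < 1e-12

    def test_identical_mean_series_give_unit_offdiagonal(self):
        series = np.vstack([np.linspace(0, 1, 6)] * 3)  # both clusters average to the same ramp
        es = fc.EdgeSeriesSet("s0", fc.edge_pairs(3), series)
        cl = fc.EdgeClustering(2, np.array([0, 0, 1]), es.edge_index, ["s0"], 0)
        high = fc.high_order_fc(es, cl)
        assert abs(high.matrix[0, 1] - 1.0) < 1e-12

    def test_orthogonal_mean_series_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # zero-mean, dot(a, b) = 0
        es = fc.EdgeSeriesSet("s0", [(0, 1), (0, 2)], np.vstack([a, b]))
        cl = fc.EdgeClustering(2, np.array([0, 1]), es.edge_index, ["s0"], 0)
        high = fc.high_order_fc(es, cl)
        assert abs(high.matrix[0, 1]) < 1e-12

    def test_constant_cluster_mean_warns_and_zeroes(self):
        series = np.vstack([np.ones(5), np.linspace(0, 1, 5)])
        es = fc.EdgeSeriesSet("s0", [(0, 1), (0, 2)], series)
        cl = fc.EdgeClustering(2, np.array([0, 1]), es.edge_index, ["s0"], 0)
        with pytest.warns(UserWarning, match="constant"):
            high = fc.high_order_fc(es, cl)
        assert high.matrix[0, 1] == 0.0 and high.matrix[1, 0] == 0.0
        assert high.matrix[0, 0] == 1.0

    def test_full_high_order_refuses_study_scale(self, rng):
        es = fc.EdgeSeriesSet("s0", fc.edge_pairs(40), rng.normal(size=(780, 5)))
        with pytest.raises(ConfigurationError):
            fc.full_high_order_fc(es)

    def test_full_high_order_small_case(self, rng):
        series = rng.normal(size=(3, 7))
        es = fc.EdgeSeriesSet("s0", fc.edge_pairs(3), series)
        np.testing.assert_allclose(fc.full_high_order_fc(es), np.corrcoef(series), atol=1e-12)


def test_clustering_serialization_roundtrip(tmp_path, small_dynamic_fc):
    train = [fc.edge_series(d) for d in small_dynamic_fc[:3]]
    clustering = fc.fit_edge_clustering(train, n_clusters=4, seed=1)
    csv_path = fc.save_edge_clustering(clustering, tmp_path)
    import json

    lines = csv_path.read_text().splitlines()
    assert lines[0] == "p,q,cluster" and len(lines) == 1 + len(clustering.edge_index)
    meta = json.loads((tmp_path / "edge_clusters.json").read_text())
    assert meta["n_clusters"] == 4 and meta["seed"] == 1
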