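"""Cluster statistics against brute-force oracles."""

import numpy as np
import pytest

from fclsim.cluster_analysis import (
    Dwell,
    InsufficientDataError,
    cluster_area_from_points,
    compute_tc,
    counted_cluster_number,
    dwelling_times,
    find_clusters,
    mean_cluster_size,
    mean_dwell,
    membrane_bound_clathrin_count,
    pattern_statistics,
)


def brute_force_components(n, edges):
    """Transitive-closure oracle for connected components."""
    comp = {i: {i} for i in range(n)}
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            union = comp[i] | comp[j]
            for k in union:
                if comp[k] != union:
                    comp[k] = union
                    changed = True
            comp[i] = comp[j] = union
    return {frozenset(c) for c in comp.values()}


class TestFindClusters:
    def test_no_bonds_empty(self):
        assert find_clusters(np.empty((0, 4), int), np.zeros(10, bool)) == []

    def test_chain_with_one_ap2(self):
        edges = np.array([[0, 0, 1, 0], [1, 1, 2, 0]])
        ap2 = np.zeros(3, bool)
        ap2[0] = True
        recs = find_clusters(edges, ap2)
        assert len(recs) == 1
        assert recs[0].n_clathrin == 3 and recs[0].n_ap2 == 1
        assert recs[0].is_membrane_bound

    def test_ap2_monomer_is_singleton_cluster(self):
        recs = find_clusters(np.empty((0, 4), int), np.array([False, True]))
        assert len(recs) == 1 and recs[0].n_clathrin == 1

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            m = int(rng.integers(0, n * 2))
            edges = rng.integers(0, n, size=(m, 2))
            edges = edges[edges[:, 0] != edges[:, 1]]
            rows = np.column_stack(
                [edges[:, 0], np.zeros(len(edges), int), edges[:, 1], np.zeros(len(edges), int)]
            )
            ap2 = rng.random(n) < 0.3
            recs = find_clusters(rows, ap2)
            got = {frozenset(r.member_ids) for r in recs}
            oracle = {
                c
                for c in brute_force_components(n, [tuple(e) for e in edges])
                if len(c) > 1 or any(ap2[i] for i in c)
            }
            assert got == oracle


class TestMembraneBoundCount:
    def test_recount_by_traversal(self):
        rng = np.random.default_rng(5)
        n = 30
        edges = rng.integers(0, n, size=(25, 2))
        edges = edges[edges[:, 0] != edges[:, 1]]
        rows = np.column_stack(
            [edges[:, 0], np.zeros(len(edges), int), edges[:, 1], np.zeros(len(edges), int)]
        )
        ap2 = rng.random(n) < 0.25
        recs = find_clusters(rows, ap2)
        count = membrane_bound_clathrin_count(recs)
        # independent recount: clathrins connected (transitively) to an AP-2
        comps = brute_force_components(n, [tuple(e) for e in edges])
        expected = sum(
            len(c) for c in comps if any(ap2[i] for i in c) and (len(c) > 1 or True)
        )
        assert count == expected
        assert count <= n


class TestClusterArea:
    def test_single_point_disc(self):
        a = cluster_area_from_points(np.array([[0.0, 0.0]]), 12.5)
        assert a == pytest.approx(np.pi * 0.0125**2, rel=1e-3)

    def test_triangle_against_shoelace_oracle(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        r = 12.5
        a = cluster_area_from_points(pts, r)
        # shoelace + perimeter strip + full disc (Minkowski sum of a convex
        # polygon with a disc)
        shoelace = 0.5 * abs(50 * 50)
        perimeter = 50 + 50 + np.sqrt(2) * 50
        expected = (shoelace + perimeter * r + np.pi * r**2) / 1e6
        assert a == pytest.approx(expected, rel=1e-3)

    def test_monotone_under_member_addition(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 100, size=(6, 2))
        for k in range(1, 6):
            a1 = cluster_area_from_points(pts[:k], 12.5)
            a2 = cluster_area_from_points(pts[: k + 1], 12.5)
            assert a2 >= a1 - 1e-12


class TestTc:
    def test_constant_series_first_frame(self):
        assert compute_tc([5, 5, 5], [0.0, 1.0, 2.0]) == 0.0

    def test_linear_ramp(self):
        times = np.linspace(0, 30, 301)  # 0.1-unit spacing
        series = 100 * times / 30.0
        # first strictly above 90 is t = 27.1 on this grid
        assert compute_tc(series, times) == pytest.approx(27.1)

    def test_all_zero_undefined(self):
        assert compute_tc([0, 0, 0], [0.0, 1.0, 2.0]) is None


class TestPatternStatistics:
    def test_constant_series(self):
        freqs, mode = pattern_statistics([3, 3, 3, 3])
        assert mode == 3 and freqs == {3: 1.0}

    def test_histogram_mode(self):
        series = [1] * 10 + [2] * 30 + [3] * 5
        freqs, mode = pattern_statistics(series)
        assert mode == 2
        assert freqs[2] == pytest.approx(30 / 45)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_tie_breaks_to_smaller(self):
        _freqs, mode = pattern_statistics([2, 2, 1, 1])
        assert mode == 1

    def test_empty_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            pattern_statistics([])


class TestMeanClusterSize:
    def _rec(self, n, area):
        from fclsim.cluster_analysis import ClusterRecord

        return ClusterRecord(
            member_ids=tuple(range(n)),
            n_clathrin=n,
            n_ap2=1,
            area=area,
            is_membrane_bound=True,
            is_large=n > 10,
        )

    def test_single_and_mean(self):
        assert mean_cluster_size([self._rec(12, 0.05)]) == pytest.approx(0.05)
        recs = [self._rec(12, 0.02), self._rec(15, 0.04)]
        assert mean_cluster_size(recs) == pytest.approx(0.03)

    def test_small_clusters_not_counted(self):
        recs = [self._rec(5, 0.01)]
        assert counted_cluster_number(recs) == 0
        with pytest.raises(InsufficientDataError):
            mean_cluster_size(recs)


class TestDwellingTimes:
    def test_single_run_censored(self):
        times = np.arange(0, 6e8, 6e7)  # minutes in us
        d = dwelling_times(np.ones(10, int), times)
        assert len(d) == 1
        assert d[0].censored
        assert d[0].duration == pytest.approx(10.0)  # 10 x 1 min frames

    def test_run_length_encoding(self):
        spacing = 0.1 * 6e7  # 0.1 min
        series = [1, 1, 2, 2, 2, 1]
        times = np.arange(6) * spacing
        d2 = dwelling_times(series, times, pattern=2)
        assert len(d2) == 1 and not d2[0].censored
        assert d2[0].duration == pytest.approx(0.3)

    def test_durations_sum_to_window(self):
        rng = np.random.default_rng(7)
        series = rng.integers(0, 3, size=200)
        spacing = 3e3
        times = np.arange(200) * spacing
        d = dwelling_times(series, times)
        total = sum(x.duration for x in d)
        assert total == pytest.approx(200 * spacing / 6e7)

    def test_mean_dwell_excludes_censored(self):
        d = [
            Dwell(2, 1.0, True),
            Dwell(2, 0.4, False),
            Dwell(2, 0.6, False),
        ]
        assert mean_dwell(d) == pytest.approx(0.5)
        assert mean_dwell(d, include_censored=True) == pytest.approx(2.0 / 3)
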