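"""Core T-LoCoH machinery checked against brute-force oracles:
hand-evaluated TSD distances, exhaustive neighbour sorts, an independent
convex-hull area computation, and prefix-union isopleth invariants."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from bioprobe.locoh import (
    Fix,
    LocohParams,
    Track,
    build_hull,
    build_isopleths,
    edge_area_diagnostic,
    fraction_time_selected,
    knn_tsd,
    max_observed_speed,
    occupancy_time,
    occupancy_time_idx,
    tsd_distance,
    utilization_distribution,
    _build_all_hulls,
    _knn_indices,
    _sorted_hulls,
)
from conftest import T0, make_track, random_track


def fix(x, y, minutes=0.0, animal="a"):
    return Fix(animal, T0 + pd.Timedelta(minutes=minutes), x, y)


# ---------------------------------------------------------------------------
# time-scaled distance


class TestTsdDistance:
    def test_s_zero_is_euclidean(self):
        assert tsd_distance(fix(0, 0), fix(3, 4, minutes=500), 0.0) == 5.0

    def test_zero_time_axis(self):
        assert tsd_distance(fix(0, 0), fix(3, 4), 0.05, v_max=2.0) == 5.0

    def test_hand_evaluated_time_axis(self):
        # dz = s * v_max * dt = 0.05 * 1 * 100 = 5 -> sqrt(9+16+25)
        a = fix(0, 0, minutes=0.0)
        b = fix(3, 4, minutes=100 / 60)
        assert tsd_distance(a, b, 0.05, v_max=1.0) == pytest.approx(
            math.sqrt(50), rel=1e-12)

    def test_symmetric_and_dominates_euclidean(self, rng):
        for _ in range(50):
            a = fix(*rng.uniform(0, 1000, 2), minutes=rng.uniform(0, 600))
            b = fix(*rng.uniform(0, 1000, 2), minutes=rng.uniform(0, 600))
            d_ab = tsd_distance(a, b, 0.03, v_max=1.5)
            assert d_ab == pytest.approx(
                tsd_distance(b, a, 0.03, v_max=1.5), rel=1e-12)
            assert d_ab >= tsd_distance(a, b, 0.0) - 1e-12

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Fix("a", T0, float("nan"), 0.0)
        with pytest.raises(ValueError):
            Fix("a", T0, 0.0, float("inf"))

    def test_v_max_required_when_s_positive(self):
        with pytest.raises(ValueError):
            tsd_distance(fix(0, 0), fix(1, 1, minutes=5), 0.03)


class TestMaxObservedSpeed:
    def test_single_segment(self):
        tr = make_track([0, 100], [0, 0], minutes=[0, 50 / 60])
        assert max_observed_speed(tr) == pytest.approx(2.0)

    def test_all_coincident_is_degenerate_zero(self):
        tr = make_track([5, 5, 5], [1, 1, 1])
        assert max_observed_speed(tr) == 0.0

    def test_matches_exhaustive_segment_maximum(self, rng):
        tr = random_track(rng, n=20)
        segs = [
            math.hypot(tr.x[i + 1] - tr.x[i], tr.y[i + 1] - tr.y[i])
            / (tr.t_seconds[i + 1] - tr.t_seconds[i])
            for i in range(19)
        ]
        assert max_observed_speed(tr) == pytest.approx(max(segs), rel=1e-12)

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError):
            max_observed_speed(make_track([0], [0]))


# ---------------------------------------------------------------------------
# neighbour selection


def brute_force_knn(track, focal_i, k, s, v_max):
    """Independent oracle: full sort on scalar tsd_distance + tie-break."""
    f = track[focal_i]
    cand = [
        (tsd_distance(f, track[j], s, v_max), track.t_seconds[j], j)
        for j in range(len(track)) if j != focal_i
    ]
    cand.sort()
    return [j for _, _, j in cand[:k]]


class TestKnnTsd:
    def test_collinear_nearest(self):
        tr = make_track([0, 1, 2, 3], [0, 0, 0, 0])
        nbrs = knn_tsd(tr, 0, LocohParams(k=1, s=0.0))
        assert nbrs[0].x == 1.0

    def test_temporally_closer_candidate_wins(self):
        # two candidates 100 m from the focal; one is 1 h closer in time
        tr = Track("a",
                   [T0, T0 + pd.Timedelta(hours=1),
                    T0 + pd.Timedelta(hours=2)],
                   [100.0, 0.0, -100.0], [0.0, 0.0, 0.0])
        focal_i = 1
        nbrs = knn_tsd(tr, focal_i, LocohParams(k=1, s=0.05, v_max=1.0))
        d_each = [tsd_distance(tr[focal_i], tr[j], 0.05, 1.0)
                  for j in (0, 2)]
        assert d_each[0] == pytest.approx(d_each[1])  # spatially tied
        tr2 = Track("a",
                    [T0, T0 + pd.Timedelta(hours=1),
                     T0 + pd.Timedelta(hours=3)],
                    [100.0, 0.0, -100.0], [0.0, 0.0, 0.0])
        nbrs2 = knn_tsd(tr2, 1, LocohParams(k=1, s=0.05, v_max=1.0))
        assert nbrs2[0].x == 100.0  # 1 h away beats 2 h away

    @pytest.mark.parametrize("s", [0.0, 0.03, 0.5])
    def test_matches_exhaustive_sort(self, rng, s):
        tr = random_track(rng, n=50)
        v = max_observed_speed(tr)
        nn = _knn_indices(tr, 10, s, v)
        for i in (0, 7, 25, 49):
            assert list(nn[i]) == brute_force_knn(tr, i, 10, s, v)

    def test_k_too_large_rejected(self):
        tr = random_track(np.random.default_rng(0), n=5)
        with pytest.raises(ValueError):
            knn_tsd(tr, 0, LocohParams(k=5, s=0.0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_knn_oracle_property(seed):
    """Vectorised kNN equals the exhaustive sort on random instances."""
    r = np.random.default_rng(seed)
    n = int(r.integers(8, 40))
    tr = random_track(r, n=n)
    k = int(r.integers(1, min(7, n - 1)))
    s = float(r.choice([0.0, 0.01, 0.1]))
    v = max_observed_speed(tr)
    nn = _knn_indices(tr, k, s, v)
    i = int(r.integers(0, n))
    assert list(nn[i]) == brute_force_knn(tr, i, k, s, v)


# ---------------------------------------------------------------------------
# hulls


class TestBuildHull:
    def test_right_triangle_area(self):
        tr = make_track([0, 1000, 0], [0, 0, 1000])
        h = build_hull(0, [1, 2], tr, LocohParams(k=2, s=0.0))
        assert h.area_km2 == pytest.approx(0.5)
        assert h.n_enclosed == 3

    def test_degenerate_identical_points_kept(self):
        tr = make_track([5, 5, 5], [5, 5, 5])
        h = build_hull(0, [1, 2], tr, LocohParams(k=2, s=0.0))
        assert h.area_km2 == 0.0
        assert h.n_enclosed == 3  # all coincident points enclosed

    def test_area_matches_independent_convex_hull(self, rng):
        tr = random_track(rng, n=10)
        h = build_hull(0, list(range(1, 10)), tr, LocohParams(k=9, s=0.0))
        oracle = ConvexHull(np.column_stack([tr.x, tr.y]))
        assert h.area_km2 * 1e6 == pytest.approx(oracle.volume, rel=1e-9)

    def test_hull_is_convex_and_contains_members(self, rng):
        tr = random_track(rng, n=30)
        hulls = _build_all_hulls(tr, LocohParams(k=6, s=0.0))
        for h in hulls[:10]:
            assert h.geom.equals(h.geom.convex_hull)
            pts = shapely.points(tr.x[h.member_idx], tr.y[h.member_idx])
            assert shapely.covers(h.geom, pts).all()

    def test_empty_neighbours_rejected(self):
        tr = make_track([0, 1], [0, 1])
        with pytest.raises(ValueError):
            build_hull(0, [], tr, LocohParams(k=1, s=0.0))


class TestOccupancyTime:
    def test_single_fix_contributes_nominal_interval(self):
        tr = make_track([0, 5000, 10000], [0, 0, 0])
        assert occupancy_time_idx(np.array([1]), tr) == pytest.approx(0.3)

    def test_run_of_five_18min_fixes(self):
        tr = make_track(np.arange(6) * 10.0, np.zeros(6))
        assert occupancy_time_idx(np.arange(5), tr) == pytest.approx(1.2)

    def test_two_disjoint_runs_are_additive(self):
        minutes = [0, 15, 30, 100, 300, 330, 360, 700]
        tr = make_track(np.arange(8) * 1000.0, np.zeros(8),
                        minutes=minutes)
        # run {0,1,2} spans 30 min; fix 3 is outside; run {4,5,6} spans 60
        occ = occupancy_time_idx(np.array([0, 1, 2, 4, 5, 6]), tr)
        assert occ == pytest.approx(1.5)

    def test_hull_interface_and_empty_error(self):
        tr = make_track([0, 10, 20], [0, 0, 0])
        h = build_hull(0, [1, 2], tr, LocohParams(k=2, s=0.0))
        assert occupancy_time(h, tr) == h.occupancy_h
        with pytest.raises(ValueError):
            occupancy_time_idx(np.array([], dtype=int), tr)


# ---------------------------------------------------------------------------
# isopleths


def oracle_isopleth_counts(hulls, track):
    """Brute-force prefix coverage: union geometries step by step and
    count covered fixes with an independent shapely query per prefix."""
    pts = shapely.points(track.x, track.y)
    counts = []
    union = None
    for h in _sorted_hulls(hulls):
        union = h.geom if union is None else union.union(h.geom)
        counts.append(int(shapely.covers(union, pts).sum()))
    return counts


class TestBuildIsopleths:
    def test_identical_hulls_give_identical_quantiles(self):
        tr = make_track([0, 1000, 0, 500], [0, 0, 1000, 400])
        params = LocohParams(k=3, s=0.0)
        hulls = [build_hull(i, [j for j in range(4) if j != i], tr, params)
                 for i in range(4)]
        isos = build_isopleths(hulls, 4, (0.25, 0.5, 0.95))
        areas = {iso.area_km2 for iso in isos}
        assert len(areas) == 1
        assert all(isos[0].geom.equals(iso.geom) for iso in isos)

    def test_coverage_and_minimality_small_instances(self, rng):
        for _ in range(5):
            tr = random_track(rng, n=40)
            hulls = _build_all_hulls(tr, LocohParams(k=4, s=0.0))
            counts = oracle_isopleth_counts(hulls, tr)
            isos = build_isopleths(hulls, 40)
            for iso in isos:
                need = math.ceil(iso.level * 40 - 1e-9)
                assert iso.n_fixes >= need
                j = counts.index(iso.n_fixes)
                # dropping the final merged hull violates coverage
                if j > 0:
                    assert counts[j - 1] < need

    def test_nesting_and_monotone_area(self, rng):
        tr = random_track(rng, n=80)
        _, isos = utilization_distribution(tr, LocohParams(k=5, s=0.0))
        for small, big in zip(isos, isos[1:]):
            assert small.area_km2 <= big.area_km2 + 1e-12
            assert small.n_fixes <= big.n_fixes
            assert small.geom.difference(big.geom).area < 1e-6

    def test_empty_hull_list_rejected(self):
        with pytest.raises(ValueError):
            build_isopleths([], 10)


# ---------------------------------------------------------------------------
# time selection and diagnostics


class TestFractionTimeSelected:
    def test_zero_when_s_zero(self, rng):
        tr = random_track(rng, n=30)
        assert fraction_time_selected(tr, LocohParams(k=5, s=0.0)) == 0.0

    def test_nondecreasing_on_s_grid(self, rng):
        tr = random_track(rng, n=60)
        fracs = [fraction_time_selected(tr, LocohParams(k=8, s=s))
                 for s in (0.0, 0.005, 0.02, 0.1, 1.0)]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_large_s_plateau_selects_temporal_neighbours(self, rng):
        tr = random_track(rng, n=40)
        v = max_observed_speed(tr)
        big = fraction_time_selected(tr, LocohParams(k=4, s=1e4, v_max=v))
        bigger = fraction_time_selected(tr, LocohParams(k=4, s=1e6, v_max=v))
        assert big == bigger  # plateau reached
        nn = _knn_indices(tr, 4, 1e6, v)
        # interior focal: neighbours are the temporally adjacent fixes
        assert set(nn[20]) == {18, 19, 21, 22}


class TestEdgeAreaDiagnostic:
    def test_single_k_equals_direct_call(self, rng):
        tr = random_track(rng, n=50)
        table = edge_area_diagnostic(tr, [6])
        _, isos = utilization_distribution(tr, LocohParams(k=6, s=0.0))
        for iso in isos:
            row = table[(table.k == 6) & (table.level == iso.level)]
            assert row["area_km2"].iloc[0] == pytest.approx(iso.area_km2)

    def test_95_area_nondecreasing_in_k_on_uniform_points(self, rng):
        tr = random_track(rng, n=120)
        table = edge_area_diagnostic(tr, [4, 8, 16])
        a95 = table[table.level == 0.95].sort_values("k")["area_km2"]
        assert a95.is_monotonic_increasing

    def test_edge_to_area_falls_as_hulls_coalesce(self):
        g = np.arange(10) * 500.0
        X, Y = np.meshgrid(g, g)
        tr = make_track(X.ravel(), Y.ravel())
        table = edge_area_diagnostic(tr, [4, 24])
        r = table[table.level == 0.95].sort_values("k")["edge_area_ratio"]
        assert r.iloc[-1] < r.iloc[0]
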