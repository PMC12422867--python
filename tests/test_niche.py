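"""Checklist co-occurrence, vagrancy filtering, thinning, thresholding and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybriddiag.niche import (
    EARTH_RADIUS_KM,
    SuitabilitySurface,
    binarize_and_overlap,
    build_absence_set,
    filter_localities,
    find_cooccurrences,
    fit_gaussian_envelope,
    thin_grid,
    youden_threshold,
)
from hybriddiag.simulate import ChecklistTable


def make_table(rows):
    """rows: (checklist_id, locality_id, lon, lat, date, species-tuple)."""
    df = pd.DataFrame(
        [(c, l, lon, lat, pd.Timestamp(d), True, sp) for c, l, lon, lat, d, sp in rows],
        columns=["checklist_id", "locality_id", "lon", "lat", "date", "complete", "species"],
    )
    return ChecklistTable(records=df)


class TestCooccurrences:
    def test_no_shared_checklists(self):
        t = make_table(
            [
                ("c1", "L1", -98, 27, "2020-05-01", ("a",)),
                ("c2", "L2", -98, 30, "2020-05-02", ("b",)),
            ]
        )
        res = find_cooccurrences(t, "a", "b")
        assert (res.n_checklists, res.n_localities) == (0, 0)
        assert res.per_year.empty

    def test_hand_counted_events(self):
        t = make_table(
            [
                ("c1", "L1", -98, 27, "2020-05-01", ("a", "b")),
                ("c2", "L1", -98, 27, "2021-05-01", ("a", "b")),
                ("c3", "L2", -98, 30, "2021-06-01", ("a", "b")),
                ("c4", "L3", -99, 28, "2021-06-01", ("a",)),
            ]
        )
        res = find_cooccurrences(t, "a", "b")
        assert (res.n_checklists, res.n_localities) == (3, 2)
        assert dict(res.per_year) == {2020: 1, 2021: 2}

    def test_incomplete_checklists_ignored(self):
        t = make_table([("c1", "L1", -98, 27, "2020-05-01", ("a", "b"))])
        t.records.loc[0, "complete"] = False
        assert find_cooccurrences(t, "a", "b").n_checklists == 0


class TestFilterLocalities:
    def test_two_years_in_window_retains(self):
        rows = [("c1", "L1", -98, 27, "2019-04-01", ("a",)),
                ("c2", "L1", -98, 27, "2021-04-01", ("a",))]
        rows += [(f"x{i}", "L1", -98, 27, "2018-01-01", ()) for i in range(20)]
        res = filter_localities(make_table(rows), "a")
        assert res.retained_localities == ["L1"]

    def test_half_detection_rate_retains_single_year(self):
        rows = [(f"c{i}", "L1", -98, 27, "2020-04-01", ("a",)) for i in range(5)]
        rows += [(f"x{i}", "L1", -98, 27, "2020-05-01", ()) for i in range(5)]
        res = filter_localities(make_table(rows), "a")
        assert res.retained_localities == ["L1"]
        assert res.removed.empty

    def test_single_rare_record_removed(self):
        rows = [("c1", "L1", -98, 27, "2020-04-01", ("a",))]
        rows += [(f"x{i}", "L1", -98, 27, "2020-05-01", ()) for i in range(19)]
        res = filter_localities(make_table(rows), "a")
        assert res.retained.empty
        assert list(res.removed["locality_id"]) == ["L1"]
        assert res.removed.iloc[0]["failed_min_years"]
        assert res.removed.iloc[0]["failed_min_rate"]

    def test_rate_criterion_uses_all_time_denominator(self):
        # 2 detections in one window year; 4 all-time checklists -> rate 0.5
        rows = [
            ("c1", "L1", -98, 27, "2020-04-01", ("a",)),
            ("c2", "L1", -98, 27, "2020-06-01", ("a",)),
            ("x1", "L1", -98, 27, "2005-01-01", ()),
            ("x2", "L1", -98, 27, "2006-01-01", ()),
        ]
        res = filter_localities(make_table(rows), "a")
        assert res.retained_localities == ["L1"]

    def test_detections_outside_window_do_not_satisfy_year_criterion(self):
        rows = [("c1", "L1", -98, 27, "2016-04-01", ("a",)),
                ("c2", "L1", -98, 27, "2017-04-01", ("a",))]
        rows += [(f"x{i}", "L1", -98, 27, "2020-01-01", ()) for i in range(10)]
        res = filter_localities(make_table(rows), "a")
        assert res.retained.empty

    def test_monotone_in_detections(self):
        # adding detections can only keep or grow the retained set
        base_rows = [("c1", "L1", -98, 27, "2020-04-01", ("a",))]
        base_rows += [(f"x{i}", "L1", -98, 27, "2020-05-01", ()) for i in range(10)]
        more_rows = base_rows + [("c2", "L1", -98, 27, "2022-04-01", ("a",))]
        before = set(filter_localities(make_table(base_rows), "a").retained_localities)
        after = set(filter_localities(make_table(more_rows), "a").retained_localities)
        assert before <= after


class TestThinGrid:
    def test_two_points_one_cell_one_survivor(self):
        pts = pd.DataFrame({"lon": [-98.0, -98.001], "lat": [27.0, 27.001]})
        out = thin_grid(pts, cell_km=10, seed=0)
        assert len(out) == 1

    def test_distinct_cells_identity(self):
        pts = pd.DataFrame({"lon": [-98.0, -97.0, -96.0], "lat": [27.0, 29.0, 31.0]})
        out = thin_grid(pts, cell_km=10, seed=0)
        assert len(out) == 3

    def test_pigeonhole_bound_on_dense_points(self, rng):
        # ~5x5 cells of 10 km -> at most 25 survivors
        km_per_deg = 2 * np.pi * EARTH_RADIUS_KM / 360.0
        dlat = 50 / km_per_deg
        lats = rng.uniform(27.0, 27.0 + dlat, 1000)
        dlon = 50 / (km_per_deg * np.cos(np.radians(27.0)))
        lons = rng.uniform(-98.0, -98.0 + dlon, 1000)
        out = thin_grid(pd.DataFrame({"lon": lons, "lat": lats}), cell_km=10, seed=1)
        assert len(out) <= 36  # 5x5 plus boundary-straddling cells

    def test_idempotent_and_seed_reproducible(self, rng):
        pts = pd.DataFrame({"lon": rng.uniform(-99, -98, 200), "lat": rng.uniform(27, 28, 200)})
        once = thin_grid(pts, cell_km=10, seed=5)
        twice = thin_grid(once, cell_km=10, seed=11, center_lat=float(pts["lat"].mean()))
        assert once.equals(twice)
        assert once.equals(thin_grid(pts, cell_km=10, seed=5))


class TestAbsenceSet:
    def _rows(self, loc, years, species_years=()):
        rows = []
        for i, y in enumerate(years):
            sp = ("a",) if y in species_years else ()
            rows.append((f"{loc}_{i}", loc, -98.0, 27.0, f"{y}-06-01", sp))
        return rows

    def test_fully_surveyed_never_detected_is_absence(self):
        t = make_table(self._rows("L1", [2019, 2020, 2021, 2022, 2023]))
        out = build_absence_set(t, "a")
        assert list(out["locality_id"]) == ["L1"]

    def test_missing_survey_year_excluded(self):
        t = make_table(self._rows("L1", [2019, 2020, 2022, 2023]))  # no 2021
        assert build_absence_set(t, "a").empty

    def test_any_detection_excluded(self):
        t = make_table(self._rows("L1", [2019, 2020, 2021, 2022, 2023], species_years=[2020]))
        assert build_absence_set(t, "a").empty

    def test_empty_year_set_rejected(self):
        t = make_table(self._rows("L1", [2019]))
        with pytest.raises(ValueError):
            build_absence_set(t, "a", years=[])


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    best = None
    best_j = -np.inf
    for thr in candidates:
        pred = scores > thr
        j = (pred & labels).sum() / labels.sum() + ((~pred) & (~labels)).sum() / (~labels).sum()
        if j > best_j + 1e-12:
            best_j, best = j, thr
    return best, best_j


class TestYoudenThreshold:
    def test_perfect_separation(self):
        thr = youden_threshold([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert 0.2 < thr < 0.8
        # the lowest maximizing midpoint is returned
        assert thr == pytest.approx(0.5)

    def test_overlapping_toy_set_matches_exhaustive_search(self):
        scores = [0.1, 0.3, 0.35, 0.4, 0.5, 0.6, 0.62, 0.9]
        labels = [False, False, True, False, True, False, True, True]
        expected, _ = brute_force_youden(scores, labels)
        assert youden_threshold(scores, labels) == pytest.approx(expected)

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.5, 0.5, 0.5], [True, False, True])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [True, True])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 3)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any() or len(np.unique(scores)) < 2:
            return
        expected, expected_j = brute_force_youden(scores, labels)
        got = youden_threshold(scores, labels)
        pred = scores > got
        got_j = (pred & labels).sum() / labels.sum() + ((~pred) & (~labels)).sum() / (~labels).sum()
        assert got_j == pytest.approx(expected_j)
        assert got == pytest.approx(expected)


def surface_with_cells(cells, extent=(-99.0, -98.0, 27.0, 28.0), n=10):
    lon_edges = np.linspace(extent[0], extent[1], n + 1)
    lat_edges = np.linspace(extent[2], extent[3], n + 1)
    vals = np.zeros((n, n))
    for i, j in cells:
        vals[i, j] = 1.0
    return SuitabilitySurface(vals, lon_edges, lat_edges)


class TestOverlap:
    def test_disjoint_regions_zero_area(self):
        a = surface_with_cells([(0, 0)])
        b = surface_with_cells([(5, 5)])
        res = binarize_and_overlap(a, b, 0.5, 0.5)
        assert res.area_km2 == 0.0
        assert res.centroid is None
        assert res.to_geojson()["features"] == []

    def test_single_shared_10km_cell(self):
        # build a grid whose cells are ~10 km x 10 km at the extent center
        km_per_deg = 2 * np.pi * EARTH_RADIUS_KM / 360.0
        lat0 = 27.0
        dlat = 10.0 / km_per_deg
        dlon = 10.0 / (km_per_deg * np.cos(np.radians(lat0 + dlat / 2)))
        lon_edges = np.array([-98.0, -98.0 + dlon])
        lat_edges = np.array([lat0, lat0 + dlat])
        surf = SuitabilitySurface(np.ones((1, 1)), lon_edges, lat_edges)
        res = binarize_and_overlap(surf, surf, 0.5, 0.5)
        assert res.area_km2 == pytest.approx(100.0, rel=1e-3)
        assert res.centroid[0] == pytest.approx(-98.0 + dlon / 2)
        assert res.centroid[1] == pytest.approx(lat0 + dlat / 2)

    def test_two_equal_cells_centroid_is_midpoint(self):
        # same latitude band -> equal areas -> centroid at the midpoint
        a = surface_with_cells([(3, 2), (3, 6)])
        res = binarize_and_overlap(a, a, 0.5, 0.5)
        lon_c, lat_c = a.cell_centers()
        assert res.centroid[0] == pytest.approx(0.5 * (lon_c[2] + lon_c[6]))
        assert res.centroid[1] == pytest.approx(lat_c[3])

    def test_overlap_bounded_by_each_species_area(self):
        a = surface_with_cells([(i, j) for i in range(4) for j in range(4)])
        b = surface_with_cells([(i, j) for i in range(2, 8) for j in range(2, 8)])
        res = binarize_and_overlap(a, b, 0.5, 0.5)
        areas = a.cell_areas_km2()
        area_a = areas[a.values > 0.5].sum()
        area_b = areas[b.values > 0.5].sum()
        assert 0 < res.area_km2 <= min(area_a, area_b)

    def test_symmetric_in_species_order(self):
        a = surface_with_cells([(1, 1), (2, 2)])
        b = surface_with_cells([(2, 2), (3, 3)])
        r1 = binarize_and_overlap(a, b, 0.5, 0.5)
        r2 = binarize_and_overlap(b, a, 0.5, 0.5)
        assert r1.area_km2 == r2.area_km2
        assert r1.centroid == r2.centroid

    def test_grid_mismatch_rejected(self):
        a = surface_with_cells([(0, 0)], n=10)
        b = surface_with_cells([(0, 0)], n=5)
        with pytest.raises(ValueError):
            binarize_and_overlap(a, b, 0.5, 0.5)

    def test_centroid_inside_bounding_box_of_overlap(self, rng):
        cells = {(int(rng.integers(0, 10)), int(rng.integers(0, 10))) for _ in range(20)}
        a = surface_with_cells(sorted(cells))
        res = binarize_and_overlap(a, a, 0.5, 0.5)
        lon_c, lat_c = a.cell_centers()
        lons = [lon_c[j] for i, j in cells]
        lats = [lat_c[i] for i, j in cells]
        assert min(lons) <= res.centroid[0] <= max(lons)
        assert min(lats) <= res.centroid[1] <= max(lats)


class TestEnvelopeModel:
    def test_surface_peaks_near_presence_cloud(self, rng):
        pts = pd.DataFrame(
            {"lon": rng.normal(-98, 0.5, 100), "lat": rng.normal(27.5, 0.5, 100)}
        )
        surf = fit_gaussian_envelope(pts, SuitabilitySurface.empty(cell_deg=0.5))
        at_center = surf.sample([-98.0], [27.5])[0]
        at_corner = surf.sample([-104.5], [34.5])[0]
        assert at_center > 0.5 > at_corner

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_envelope(np.array([[-98.0, 27.0]]))
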