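"""Centerline detection: endpoints, cost field, Dijkstra, extraction."""

import itertools

import numpy as np
import pytest

from ductcpr.centerline import (
    CenterlineParams,
    CostField,
    REGION_DUCT,
    REGION_OUTSIDE,
    REGION_PANCREAS,
    _smooth_polyline,
    build_cost_field,
    centerline_distance,
    detect_endpoints,
    dijkstra_path,
    directed_mean_distance,
    extract_centerline,
    medial_axis_voxels,
)
from ductcpr.grid import SegmentationMask
from ductcpr.path import CenterlinePath, SOURCE_DUCT
from ductcpr.segmentation import segment_classical

from conftest import rod_mask


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

class TestEndpoints:
    def test_straight_rod_endpoints_are_extremes(self):
        mask = rod_mask(length=50)
        head, tail = detect_endpoints(mask)
        assert head[0] == 51 and tail[0] == 2  # head at max-x by convention
        assert {head[0], tail[0]} == {2, 51}

    def test_single_voxel_mask_degenerates_with_warning(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        with pytest.warns(UserWarning, match="degenerate"):
            head, tail = detect_endpoints(SegmentationMask(data, (1, 1, 1)))
        assert head == tail == (2, 2, 2)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            detect_endpoints(SegmentationMask(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_c_shape_matches_exhaustive_all_pairs_bfs(self):
        nx = pytest.importorskip("networkx")
        # C-shaped tube in one slab, < 500 voxels
        data = np.zeros((24, 24, 2), dtype=bool)
        ii, jj = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
        r = np.hypot(ii - 11.5, jj - 11.5)
        ring = (r >= 7) & (r <= 10)
        opening = (jj > 11.5) & (np.abs(ii - 11.5) < 5)  # cut a mouth into the C
        data[:, :, 0] = ring & ~opening
        assert 0 < data.sum() <= 500
        mask = SegmentationMask(data, (1, 1, 1))

        g = nx.Graph()
        voxels = [tuple(v) for v in np.argwhere(data)]
        for v in voxels:
            g.add_node(v)
        for v in voxels:
            for d in itertools.product((-1, 0, 1), repeat=3):
                if d == (0, 0, 0):
                    continue
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in g:
                    g.add_edge(v, w)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        best = max(
            (dist, a, b)
            for a, row in lengths.items()
            for b, dist in row.items()
        )
        head, tail = detect_endpoints(mask)
        assert lengths[head][tail] == best[0]


# ---------------------------------------------------------------------------
# cost field
# ---------------------------------------------------------------------------

class TestCostField:
    def _cylinder(self, radius=5, height=20):
        data = np.zeros((2 * radius + 5, 2 * radius + 5, height), dtype=bool)
        c = radius + 2
        ii, jj = np.meshgrid(np.arange(data.shape[0]), np.arange(data.shape[1]),
                             indexing="ij")
        data[(np.hypot(ii - c, jj - c) <= radius), :] = True
        return SegmentationMask(data, (1, 1, 1)), c

    def test_cylinder_min_cost_is_the_axis(self):
        mask, c = self._cylinder()
        field = build_cost_field(mask)
        for k in range(3, 17):  # interior slices
            sl = np.where(mask.data[:, :, k], field.cost[:, :, k], np.inf)
            i, j = np.unravel_index(np.argmin(sl), sl.shape)
            assert (i, j) == (c, c)

    def test_costs_strictly_positive_and_finite(self):
        mask, _ = self._cylinder()
        field = build_cost_field(mask)
        assert np.all(field.cost > 0)
        assert np.all(np.isfinite(field.cost))

    def test_region_cost_ordering(self, curved_phantom):
        _, vol, truth = curved_phantom
        field = build_cost_field(truth.pancreas_mask, truth.duct_mask)
        duct_max = field.cost[field.region == REGION_DUCT].max()
        panc_min = field.cost[field.region == REGION_PANCREAS].min()
        out_min = field.cost[field.region == REGION_OUTSIDE].min()
        assert duct_max < panc_min < out_min

    def test_empty_duct_has_no_duct_region(self, curved_phantom):
        _, _, truth = curved_phantom
        field = build_cost_field(truth.pancreas_mask, None)
        assert not np.any(field.region == REGION_DUCT)

    def test_empty_pancreas_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_cost_field(SegmentationMask(np.zeros((4, 4, 4)), (1, 1, 1)))


# ---------------------------------------------------------------------------
# Dijkstra vs oracles
# ---------------------------------------------------------------------------

def _edges_26(shape, spacing):
    idx = np.arange(np.prod(shape)).reshape(shape)
    edges = []
    for v in np.ndindex(shape):
        for d in itertools.product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            w = tuple(v[a] + d[a] for a in range(3))
            if all(0 <= w[a] < shape[a] for a in range(3)):
                step = np.sqrt(sum((d[a] * spacing[a]) ** 2 for a in range(3)))
                edges.append((int(idx[v]), int(idx[w]), step))
    return edges


def bellman_ford_cost(cost_arr, spacing, start, goal):
    """Independent oracle: plain edge-list relaxation."""
    shape = cost_arr.shape
    n = int(np.prod(shape))
    c = cost_arr.ravel()
    edges = [(u, v, (c[u] + c[v]) / 2 * step) for u, v, step in _edges_26(shape, spacing)]
    dist = np.full(n, np.inf)
    s = int(np.ravel_multi_index(start, shape))
    g = int(np.ravel_multi_index(goal, shape))
    dist[s] = 0.0
    for _ in range(n - 1):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    return float(dist[g])


class TestDijkstra:
    def test_start_equals_goal(self):
        field = CostField(np.ones((3, 3, 3)), (1, 1, 1), np.ones((3, 3, 3), np.uint8))
        path, cost = dijkstra_path(field, (1, 1, 1), (1, 1, 1))
        assert path == [(1, 1, 1)] and cost == 0.0

    def test_uniform_3x3x1_matches_exhaustive_enumeration(self):
        shape = (3, 3, 1)
        field = CostField(np.ones(shape), (1, 1, 1), np.ones(shape, np.uint8))
        _, got = dijkstra_path(field, (0, 0, 0), (2, 2, 0))

        # enumerate every simple path between opposite corners
        def all_paths(v, goal, visited):
            if v == goal:
                yield [v]
                return
            for d in itertools.product((-1, 0, 1), repeat=2):
                if d == (0, 0):
                    continue
                w = (v[0] + d[0], v[1] + d[1], 0)
                if 0 <= w[0] < 3 and 0 <= w[1] < 3 and w not in visited:
                    for rest in all_paths(w, goal, visited | {w}):
                        yield [v] + rest

        def path_cost(p):
            return sum(
                np.linalg.norm(np.subtract(a, b))  # unit costs: (1+1)/2 * step
                for a, b in zip(p, p[1:])
            )

        best = min(path_cost(p) for p in all_paths((0, 0, 0), (2, 2, 0), {(0, 0, 0)}))
        assert got == pytest.approx(best, abs=1e-12)

    def test_matches_bellman_ford_on_random_fields(self):
        rng = np.random.default_rng(2024)
        spacing = (1.0, 0.8, 1.3)
        for _ in range(20):
            cost = rng.uniform(0.05, 2.0, size=(5, 5, 5))
            field = CostField(cost, spacing, np.ones((5, 5, 5), np.uint8))
            start = tuple(rng.integers(0, 5, 3))
            goal = tuple(rng.integers(0, 5, 3))
            _, got = dijkstra_path(field, start, goal)
            want = bellman_ford_cost(cost, spacing, start, goal)
            assert got == pytest.approx(want, rel=1e-10)

    def test_deterministic_path_on_ties(self):
        field = CostField(np.ones((4, 4, 4)), (1, 1, 1), np.ones((4, 4, 4), np.uint8))
        p1, _ = dijkstra_path(field, (0, 0, 0), (3, 3, 3))
        p2, _ = dijkstra_path(field, (0, 0, 0), (3, 3, 3))
        assert p1 == p2

    def test_out_of_grid_voxel_rejected(self):
        field = CostField(np.ones((3, 3, 3)), (1, 1, 1), np.ones((3, 3, 3), np.uint8))
        with pytest.raises(ValueError, match="outside grid"):
            dijkstra_path(field, (0, 0, 0), (5, 0, 0))


# ---------------------------------------------------------------------------
# extraction on phantoms
# ---------------------------------------------------------------------------

class TestExtractCenterline:
    def test_straight_tube_recovery(self, straight_phantom):
        vol, truth = straight_phantom
        seg = segment_classical(vol)
        path = extract_centerline(seg.pancreas_mask, seg.duct_mask)
        duct_pts = CenterlinePath(path.points[path.source == SOURCE_DUCT])
        err = directed_mean_distance(duct_pts, truth.centerline)
        assert err < 0.5 * max(vol.spacing_mm)

    def test_curved_tube_recovery_and_monotone_arc_length(self, curved_phantom):
        _, vol, truth = curved_phantom
        seg = segment_classical(vol)
        path = extract_centerline(seg.pancreas_mask, seg.duct_mask)
        duct_pts = CenterlinePath(path.points[path.source == SOURCE_DUCT])
        err = directed_mean_distance(duct_pts, truth.centerline)
        assert err < 1.0 * max(vol.spacing_mm)
        assert np.all(np.diff(path.arc_length_mm) > 0)

    def test_duct_dominance_when_duct_spans_whole_course(self, curved_phantom):
        _, vol, _ = curved_phantom
        seg = segment_classical(vol)
        path = extract_centerline(seg.pancreas_mask, seg.duct_mask)
        assert np.mean(path.source == SOURCE_DUCT) >= 0.90

    def test_fallback_runs_through_pancreas_center(self, curved_phantom):
        _, vol, truth = curved_phantom
        seg = segment_classical(vol)
        path = extract_centerline(seg.pancreas_mask, None)
        idx = np.rint(seg.pancreas_mask.world_to_index(path.points)).astype(int)
        idx = np.clip(idx, 0, np.asarray(seg.pancreas_mask.shape) - 1)
        assert np.all(seg.pancreas_mask.data[idx[:, 0], idx[:, 1], idx[:, 2]])
        from scipy.spatial import cKDTree

        axis = medial_axis_voxels(seg.pancreas_mask)
        d, _ = cKDTree(axis).query(path.points, workers=1)
        assert d.mean() < 2.0 * max(vol.spacing_mm)

    def test_smoothing_stays_within_two_voxels_of_raw_path(self, curved_phantom):
        _, vol, truth = curved_phantom
        seg = segment_classical(vol)
        head, tail = detect_endpoints(seg.pancreas_mask)
        field = build_cost_field(seg.pancreas_mask, seg.duct_mask)
        voxels, _ = dijkstra_path(field, head, tail)
        raw = seg.pancreas_mask.index_to_world(np.asarray(voxels, float))
        smoothed = _smooth_polyline(raw, 9)
        moved = np.linalg.norm(smoothed - raw, axis=1)
        assert moved.max() <= 2.0 * max(vol.spacing_mm)

    def test_consecutive_points_closer_than_two_voxel_diagonals(self, curved_phantom):
        _, vol, _ = curved_phantom
        seg = segment_classical(vol)
        path = extract_centerline(seg.pancreas_mask, seg.duct_mask)
        diag = np.linalg.norm(vol.spacing_mm)
        assert np.all(np.linalg.norm(np.diff(path.points, axis=0), axis=1) < 2 * diag)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestCenterlineDistance:
    def _line(self, offset=0.0, shift=0.0):
        s = np.linspace(0, 50, 101) + shift
        return CenterlinePath(np.column_stack([s, np.full_like(s, offset), np.zeros_like(s)]))

    def test_identity(self):
        p = self._line()
        assert centerline_distance(p, p) == (0.0, 0.0)

    def test_parallel_lines(self):
        mean, haus = centerline_distance(self._line(), self._line(offset=3.0))
        assert mean == pytest.approx(3.0, abs=1e-9)
        assert haus == pytest.approx(3.0, abs=1e-9)

    def test_longitudinal_shift_along_same_support(self):
        mean, haus = centerline_distance(self._line(), self._line(shift=1.0))
        assert mean < 0.05
        assert haus <= 1.0 + 1e-9

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError):
            centerline_distance(
                CenterlinePath(np.zeros((1, 3))), self._line()
            )
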