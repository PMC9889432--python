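"""MPD centerline detection: endpoints, cost field, Dijkstra routing.

The centerline is defined by a two-case rule: (a) where the segmented
duct exists, the path runs through the duct lumen (attracted to its
medial core); (b) where the duct is undetectable, the path falls back to
running approximately through the center of the segmented pancreas.
Both cases are realized by a single nonnegative cost field — cheap and
medial inside the duct, moderate and medial inside the pancreas, a large
finite barrier outside — and a deterministic Dijkstra search between the
geodesically farthest pair of pancreas voxels (head at larger world-x by
anatomical convention, configurable).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import SegmentationMask, require_same_grid
from .path import CenterlinePath, DegeneratePathError, SOURCE_DUCT, SOURCE_FALLBACK

REGION_OUTSIDE = 0
REGION_PANCREAS = 1
REGION_DUCT = 2

_CONN26 = ndimage.generate_binary_structure(3, 3)


class RoutingError(RuntimeError):
    """Goal unreachable from start in the cost graph."""


@dataclass
class CenterlineParams:
    """Tunables of the centerline stage (defaults fit the phantom scale)."""

    epsilon: float = 0.01          # duct cost scale (≪ pancreas costs)
    barrier: float = 1.0e6         # finite outside-pancreas traversal cost
    smooth_window: int = 9         # moving-average window (path points)
    resample_step_mm: float = 0.5  # uniform arc-length output step
    gap_tolerance_mm: float = 5.0  # fallback run longer than this → segment break
    endpoint_snap_mm: float = 10.0  # snap endpoints to a nearby duct terminus (0 = off)
    head_axis: int = 0             # world axis of the head/tail convention
    head_sign: int = 1             # head at +axis extreme


@dataclass
class CostField:
    """Per-voxel traversal cost with region provenance flags."""

    cost: np.ndarray               # float, strictly positive, finite
    spacing_mm: tuple[float, float, float]
    region: np.ndarray             # uint8: 0 outside, 1 pancreas, 2 duct

    def __post_init__(self):
        if self.cost.shape != self.region.shape:
            raise ValueError("cost and region grids differ")


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

def geodesic_bfs(mask: np.ndarray, seed_voxel: tuple[int, int, int]) -> np.ndarray:
    """26-connected hop distance from a seed, restricted to the mask.

    Returns an int array with -1 outside the reachable set.
    """
    dist = np.full(mask.shape, -1, dtype=np.int32)
    frontier = np.zeros_like(mask)
    frontier[seed_voxel] = True
    dist[seed_voxel] = 0
    d = 0
    visited = frontier.copy()
    while frontier.any():
        d += 1
        frontier = ndimage.binary_dilation(frontier, structure=_CONN26) & mask & ~visited
        dist[frontier] = d
        visited |= frontier
    return dist


def _farthest(dist: np.ndarray) -> tuple[int, int, int]:
    """Voxel with maximal finite distance; ties broken lexicographically."""
    dmax = dist.max()
    flat = int(np.flatnonzero(dist == dmax)[0])
    return tuple(int(v) for v in np.unravel_index(flat, dist.shape))


def detect_endpoints(
    pancreas_mask: SegmentationMask,
    head_axis: int = 0,
    head_sign: int = 1,
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Geodesically farthest voxel pair, oriented head-to-tail.

    Two breadth-first sweeps (the classic tree-diameter heuristic, exact
    enough on tubular masks): BFS from an arbitrary voxel finds one
    extremity; BFS from that extremity finds the opposite one.  The head
    is the endpoint with the larger ``head_sign``-signed coordinate along
    ``head_axis``.
    """
    m = pancreas_mask.data
    if not m.any():
        raise ValueError("empty pancreas mask: no endpoints")
    labels, n = ndimage.label(m, structure=_CONN26)
    if n > 1:
        warnings.warn(f"pancreas mask has {n} components; using the largest")
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (int(np.argmax(sizes)) + 1)
    seed = tuple(int(v) for v in np.argwhere(m)[0])
    a = _farthest(geodesic_bfs(m, seed))
    dist_a = geodesic_bfs(m, a)
    b = _farthest(dist_a)
    if a == b:
        warnings.warn("degenerate pancreas mask: single-voxel path")
        return a, a
    if head_sign * (a[head_axis] - b[head_axis]) >= 0:
        return a, b
    return b, a


# ---------------------------------------------------------------------------
# cost field
# ---------------------------------------------------------------------------

def build_cost_field(
    pancreas_mask: SegmentationMask,
    duct_mask: SegmentationMask | None = None,
    params: CenterlineParams | None = None,
) -> CostField:
    """Medialness cost field realizing the two-case centerline rule.

    Inside each region the cost is ``scale / (1 + d_boundary)`` with
    ``d_boundary`` the Euclidean distance (mm, anisotropy-aware) to the
    region boundary, so medial voxels are cheapest; the scale is
    ``epsilon`` inside the duct and 1 inside the pancreas, keeping every
    duct voxel strictly cheaper than every pancreas voxel at organ scale.
    Outside the pancreas the cost is a large finite barrier.
    """
    params = params or CenterlineParams()
    if not pancreas_mask.data.any():
        raise ValueError("empty pancreas mask: cannot build cost field")
    spacing = pancreas_mask.spacing_mm
    panc = pancreas_mask.data
    if duct_mask is not None:
        require_same_grid(pancreas_mask, duct_mask, "pancreas and duct masks")
        duct = duct_mask.data & panc
    else:
        duct = np.zeros_like(panc)

    cost = np.full(panc.shape, params.barrier, dtype=np.float64)
    d_panc = ndimage.distance_transform_edt(panc, sampling=spacing)
    cost[panc] = 1.0 / (1.0 + d_panc[panc])
    if duct.any():
        d_duct = ndimage.distance_transform_edt(duct, sampling=spacing)
        cost[duct] = params.epsilon / (1.0 + d_duct[duct])

    region = np.zeros(panc.shape, dtype=np.uint8)
    region[panc] = REGION_PANCREAS
    region[duct] = REGION_DUCT
    return CostField(cost=cost, spacing_mm=spacing, region=region)


# ---------------------------------------------------------------------------
# Dijkstra on the voxel graph
# ---------------------------------------------------------------------------

def _neighbor_table(shape, spacing):
    """26-connectivity offsets on a 1-padded flat grid + mm step lengths."""
    padded = tuple(s + 2 for s in shape)
    offs, steps = [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                offs.append(
                    di * padded[1] * padded[2] + dj * padded[2] + dk
                )
                steps.append(
                    np.sqrt(
                        (di * spacing[0]) ** 2
                        + (dj * spacing[1]) ** 2
                        + (dk * spacing[2]) ** 2
                    )
                )
    return padded, np.asarray(offs, dtype=np.int64), np.asarray(steps)


def dijkstra_path(
    cost: CostField,
    start_voxel: tuple[int, int, int],
    goal_voxel: tuple[int, int, int],
) -> tuple[list[tuple[int, int, int]], float]:
    """Minimum-cost voxel path under 26-connectivity.

    Edge weight between voxels u, v is ``(cost(u) + cost(v)) / 2`` times
    the Euclidean step length in mm (anisotropic spacing respected).
    Ties in the priority queue are broken by flat voxel index, and
    predecessors update only on strict improvement, so the result is
    bit-reproducible.
    """
    shape = cost.cost.shape
    for name, v in (("start", start_voxel), ("goal", goal_voxel)):
        if any(c < 0 or c >= s for c, s in zip(v, shape)):
            raise ValueError(f"{name} voxel {v} outside grid {shape}")
    padded, offs, steps = _neighbor_table(shape, cost.spacing_mm)
    c = np.full(padded, np.inf)
    c[1:-1, 1:-1, 1:-1] = cost.cost
    c_flat = c.ravel()
    half_steps = steps / 2.0

    def to_flat(v):
        return (v[0] + 1) * padded[1] * padded[2] + (v[1] + 1) * padded[2] + (v[2] + 1)

    start = to_flat(start_voxel)
    goal = to_flat(goal_voxel)
    dist = np.full(c_flat.shape, np.inf)
    pred = np.full(c_flat.shape, -1, dtype=np.int64)
    done = np.zeros(c_flat.shape, dtype=bool)
    dist[start] = 0.0
    heap = [(0.0, start)]
    while heap:
        du, u = heapq.heappop(heap)
        if done[u] or du > dist[u]:
            continue
        done[u] = True
        if u == goal:
            break
        nbs = u + offs
        nd = du + (c_flat[u] + c_flat[nbs]) * half_steps
        better = nd < dist[nbs]
        if better.any():
            for v, dv in zip(nbs[better], nd[better]):
                dist[v] = dv
                pred[v] = u
                heapq.heappush(heap, (float(dv), int(v)))
    if not np.isfinite(dist[goal]):
        raise RoutingError(f"goal {goal_voxel} unreachable from {start_voxel}")

    # reconstruct, goal -> start, then reverse
    chain = []
    v = goal
    while v != -1:
        i, rem = divmod(v, padded[1] * padded[2])
        j, k = divmod(rem, padded[2])
        chain.append((int(i - 1), int(j - 1), int(k - 1)))
        v = int(pred[v]) if v != start else -1
    chain.reverse()
    return chain, float(dist[goal])


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-preserving reflection padding."""
    if window <= 1 or len(points) < 3:
        return points
    w = min(window if window % 2 == 1 else window + 1, 2 * (len(points) // 2) - 1)
    if w <= 1:
        return points
    half = w // 2
    # mirror *through* the endpoints (odd reflection): a straight end is a
    # fixed point of the averaging, so smoothing does not retract the path
    head_pad = 2 * points[0] - points[half:0:-1]
    tail_pad = 2 * points[-1] - points[-2:-half - 2:-1]
    padded = np.concatenate([head_pad, points, tail_pad])
    kernel = np.ones(w) / w
    return np.column_stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(3)]
    )


def _recenter_in_lumen(
    points: np.ndarray,
    duct_mask: SegmentationMask,
    ball_mm: float | None = None,
    iterations: int = 2,
) -> np.ndarray:
    """Pull in-duct path points toward the local lumen centroid.

    A small-ball mean-shift constrained to the plane perpendicular to
    the local path tangent: each point moves toward the centroid of duct
    voxel centers within ``ball_mm``, with the longitudinal component of
    the shift removed so the path is centered laterally without being
    retracted at the duct end faces.  Fallback stretches (no duct voxels
    nearby) are untouched.
    """
    ball = ball_mm if ball_mm is not None else 1.5 * max(duct_mask.spacing_mm)
    duct_world = duct_mask.index_to_world(np.argwhere(duct_mask.data).astype(float))
    tree = cKDTree(duct_world)
    pts = points.copy()
    for _ in range(iterations):
        tangents = np.gradient(pts, axis=0)
        tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
        neighborhoods = tree.query_ball_point(pts, ball, workers=1)
        for i, nb in enumerate(neighborhoods):
            if len(nb) >= 3:
                shift = duct_world[nb].mean(axis=0) - pts[i]
                shift -= np.dot(shift, tangents[i]) * tangents[i]
                pts[i] = pts[i] + shift
    return pts


def extract_centerline(
    pancreas_mask: SegmentationMask,
    duct_mask: SegmentationMask | None = None,
    params: CenterlineParams | None = None,
) -> CenterlinePath:
    """Head-to-tail MPD centerline from segmentation masks.

    Composes endpoint detection, cost-field construction and Dijkstra
    routing; converts the voxel path to world mm, smooths it with a short
    moving average, resamples at uniform arc-length steps, labels each
    point duct/fallback by duct-mask membership, and marks a segment
    break wherever a fallback run exceeds the gap tolerance (a
    tumor-interrupted duct).
    """
    params = params or CenterlineParams()
    head, tail = detect_endpoints(pancreas_mask, params.head_axis, params.head_sign)
    if head == tail:
        raise DegeneratePathError("single-voxel pancreas mask: no path")
    if duct_mask is not None and duct_mask.data.any() and params.endpoint_snap_mm > 0:
        # the geodesic extremes of the gland sit on its outer surface; when
        # the duct terminus is nearby, start the route there instead so the
        # detected course opens and closes on the duct itself
        duct_world = duct_mask.index_to_world(np.argwhere(duct_mask.data).astype(float))
        tree = cKDTree(duct_world)
        snapped = []
        for v in (head, tail):
            d, j = tree.query(pancreas_mask.index_to_world(np.asarray(v, float)), workers=1)
            if d <= params.endpoint_snap_mm:
                v = tuple(
                    int(c)
                    for c in np.rint(duct_mask.world_to_index(duct_world[j]))
                )
            snapped.append(v)
        head, tail = snapped
        if head == tail:
            raise DegeneratePathError("degenerate endpoints after duct snapping")
    cost = build_cost_field(pancreas_mask, duct_mask, params)
    voxels, _ = dijkstra_path(cost, head, tail)
    pts = pancreas_mask.index_to_world(np.asarray(voxels, dtype=float))
    pts = _smooth_polyline(pts, params.smooth_window)
    if duct_mask is not None and duct_mask.data.any():
        pts = _recenter_in_lumen(pts, duct_mask)
        # second smoothing pass removes the voxel-centroid jitter the
        # recentering introduces, which otherwise inflates arc length
        pts = _smooth_polyline(pts, params.smooth_window)
    raw = CenterlinePath(pts)
    path = raw.resample(params.resample_step_mm)

    if duct_mask is not None and duct_mask.data.any():
        idx = np.rint(duct_mask.world_to_index(path.points)).astype(int)
        idx = np.clip(idx, 0, np.asarray(duct_mask.shape) - 1)
        in_duct = duct_mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        in_duct = np.zeros(len(path), dtype=bool)
    source = np.where(in_duct, SOURCE_DUCT, SOURCE_FALLBACK).astype(object)

    breaks = []
    s = path.arc_length_mm
    i = 0
    n = len(path)
    while i < n:
        if not in_duct[i]:
            j = i
            while j < n and not in_duct[j]:
                j += 1
            run_mm = s[min(j, n - 1)] - s[i]
            interior = i > 0 and j < n
            if interior and run_mm > params.gap_tolerance_mm:
                breaks.append(j)  # next duct point starts a new segment
            i = j
        else:
            i += 1
    return CenterlinePath(path.points, source, tuple(breaks))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def centerline_distance(
    path_a: CenterlinePath,
    path_b: CenterlinePath,
    step_mm: float = 0.25,
) -> tuple[float, float]:
    """Symmetric mean closest-point and Hausdorff distances (mm)."""
    for p in (path_a, path_b):
        if len(p) < 2 or p.total_length_mm <= 0:
            raise DegeneratePathError("centerline_distance needs non-degenerate paths")
    a = path_a.resample(step_mm).points
    b = path_b.resample(step_mm).points
    d_ab, _ = cKDTree(b).query(a, workers=1)
    d_ba, _ = cKDTree(a).query(b, workers=1)
    mean = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hausdorff = max(float(d_ab.max()), float(d_ba.max()))
    return mean, hausdorff


def directed_mean_distance(
    path_a: CenterlinePath,
    path_b: CenterlinePath,
    step_mm: float = 0.25,
) -> float:
    """Mean distance from points of ``path_a`` to the support of ``path_b``."""
    a = path_a.resample(step_mm).points if len(path_a) > 1 else path_a.points
    b = path_b.resample(step_mm).points
    d, _ = cKDTree(b).query(a, workers=1)
    return float(d.mean())


def medial_axis_voxels(mask: SegmentationMask) -> np.ndarray:
    """World coordinates of the mask's medial axis (3D skeleton).

    Thinning-based skeletonization reaches into the rounded ends of a
    tubular organ, unlike a bare distance-transform ridge, so distances
    from a head-to-tail path to this set are meaningful along the whole
    course.
    """
    from skimage.morphology import skeletonize

    skel = skeletonize(mask.data)
    if not skel.any():  # tiny masks can thin away entirely
        skel = mask.data
    return mask.index_to_world(np.argwhere(skel).astype(float))
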