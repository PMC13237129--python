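"""Shared fixtures and independent oracles.

The two oracles here deliberately avoid the code paths they check:

* ``mc_intersection_area`` estimates the intersection area of two polygons
  by rasterization — uniform points in the joint bounding box classified
  with a pure-numpy crossing-number test (no shapely).
* ``brute_force_contacts`` groups touch frames by pairwise union-find over
  the adjacency relation |f_i - f_j| <= max_gap + 1, instead of the linear
  consecutive-frame scan used by the implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from scanstop.geometry import Polygon


# ---------------------------------------------------------------------------
# random polygon generators
# ---------------------------------------------------------------------------

def random_convex_polygon(rng: np.random.Generator, n_vertices: int,
                          center=(0.0, 0.0), scale: float = 1.0) -> Polygon:
    """Convex polygon: points at sorted angles on a wobbly circle, then the
    convex hull property holds because radii vary slowly."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles
    while np.any(np.diff(angles) < 1e-3):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radius = scale * (1.0 + 0.15 * rng.uniform(-1, 1))
    pts = np.column_stack([np.cos(angles), np.sin(angles)]) * radius
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices] + np.asarray(center))


def random_star_polygon(rng: np.random.Generator, n_vertices: int,
                        center=(0.0, 0.0), scale: float = 1.0) -> Polygon:
    """Simple (possibly strongly concave) polygon: random radius at each of
    n sorted angles about the center — star-shaped, hence never
    self-intersecting."""
    # angle increments bounded away from 0 and pi so the ring stays simple
    incr = rng.uniform(0.5, 1.5, n_vertices)
    angles = 2 * np.pi * np.cumsum(incr) / incr.sum()
    radii = scale * rng.uniform(0.3, 1.0, n_vertices)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return Polygon(pts + np.asarray(center))


# ---------------------------------------------------------------------------
# Monte-Carlo rasterization oracle (independent of shapely)
# ---------------------------------------------------------------------------

def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized crossing-number (even-odd) point-in-polygon test."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y)) & (
            x < (x2 - x1) * (y - y1) / (y2 - y1) + x1)
        inside ^= crosses
    return inside


def mc_intersection_area(a: Polygon, b: Polygon, n_points: int,
                         rng: np.random.Generator) -> float:
    """Monte-Carlo rasterization estimate of the intersection area.

    One uniform point is jittered inside each cell of a regular grid over
    the overlap of the two bounding boxes (outside which the intersection is
    empty by definition).  Stratification keeps the estimator unbiased while
    confining its variance to boundary cells.
    """
    ax0, ay0, ax1, ay1 = a.bounds
    bx0, by0, bx1, by1 = b.bounds
    x0, y0 = max(ax0, bx0), max(ay0, by0)
    x1, y1 = min(ax1, bx1), min(ay1, by1)
    if x0 >= x1 or y0 >= y1:
        return 0.0
    w, h = x1 - x0, y1 - y0
    nx = max(1, int(round(np.sqrt(n_points * w / h))))
    ny = max(1, n_points // nx)
    gx = x0 + (np.arange(nx) + 0.5) / nx * w
    gy = y0 + (np.arange(ny) + 0.5) / ny * h
    pts = np.column_stack([np.repeat(gx, ny), np.tile(gy, nx)])
    pts += rng.uniform(-0.5, 0.5, pts.shape) * np.array([w / nx, h / ny])
    inside = points_in_polygon(pts, a.vertices) & \
        points_in_polygon(pts, b.vertices)
    return inside.mean() * w * h


# ---------------------------------------------------------------------------
# brute-force contact assembly oracle
# ---------------------------------------------------------------------------

def brute_force_contacts(frames: set[int], max_gap: int) -> list[list[int]]:
    """Partition touch frames into contacts by pairwise union-find."""
    frames = sorted(frames)
    parent = list(range(len(frames)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            if abs(frames[i] - frames[j]) <= max_gap + 1:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, f in enumerate(frames):
        groups.setdefault(find(i), []).append(f)
    return sorted(groups.values())


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def unit_square(offset=(0.0, 0.0)) -> Polygon:
    ox, oy = offset
    return Polygon([(ox, oy), (ox + 1, oy), (ox + 1, oy + 1), (ox, oy + 1)])


def make_track(track_id, population, frames, centroids, polygons=None):
    """Terse Track builder for hand-constructed fixtures."""
    from scanstop.io import Observation, Track
    if polygons is None:
        polygons = [None] * len(frames)
    obs = tuple(
        Observation(frame=f, centroid=tuple(c), polygon=p)
        for f, c, p in zip(frames, centroids, polygons)
    )
    return Track(track_id, population, obs)


def square_track(track_id, population, frames, centroids, half=5.0):
    """Track whose footprint is an axis-aligned square around each
    centroid."""
    polys = [
        Polygon([(x - half, y - half), (x + half, y - half),
                 (x + half, y + half), (x - half, y + half)])
        for x, y in centroids
    ]
    return make_track(track_id, population, frames, centroids, polys)
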