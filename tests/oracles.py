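"""Independent brute-force oracles for the point-pattern metrics.

These deliberately avoid scipy.spatial: Voronoi cells are built by
intersecting half-planes with shapely polygons (O(n²)), neighbor relations
by checking that the bisector of a pair contributes a positive-length edge
to the clipped cell, and NND by exhaustive pairwise distances.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Polygon, box

_BIG = 1.0e6  # half-extent of the bounding square standing in for the plane


def _halfplane(p: np.ndarray, q: np.ndarray) -> Polygon:
    """Large polygon covering the side of the (p, q) bisector closer to p."""
    mid = (p + q) / 2.0
    n = q - p                      # outward normal (away from p)
    n = n / np.linalg.norm(n)
    t = np.array([-n[1], n[0]])    # tangent along the bisector
    a = mid + t * 4 * _BIG
    b = mid - t * 4 * _BIG
    return Polygon([tuple(a), tuple(b),
                    tuple(b - n * 8 * _BIG), tuple(a - n * 8 * _BIG)])


def voronoi_cell(pts: np.ndarray, i: int) -> Polygon:
    """Voronoi cell of point i clipped to a huge square."""
    cell = box(-_BIG, -_BIG, _BIG, _BIG)
    for j in range(len(pts)):
        if j != i:
            cell = cell.intersection(_halfplane(pts[i], pts[j]))
    return cell


def _touches_big_box(cell: Polygon) -> bool:
    xmin, ymin, xmax, ymax = cell.bounds
    edge = 0.5 * _BIG
    return (xmin < -edge or ymin < -edge or xmax > edge or ymax > edge)


def bound_cells_oracle(pts: np.ndarray, roi_bounds: tuple) -> tuple[list, list]:
    """Indices and areas of cells that are finite and inside the closed ROI."""
    x0, y0, x1, y1 = roi_bounds
    roi_poly = box(x0, y0, x1, y1)
    idx, areas = [], []
    for i in range(len(pts)):
        cell = voronoi_cell(pts, i)
        if cell.is_empty or _touches_big_box(cell):
            continue
        if roi_poly.covers(cell):
            idx.append(i)
            areas.append(cell.area)
    return idx, areas


def density_oracle(pts: np.ndarray, roi_bounds: tuple) -> tuple[float, int]:
    idx, areas = bound_cells_oracle(pts, roi_bounds)
    return len(idx) / (sum(areas) * 1e-6), len(idx)


def neighbors_oracle(pts: np.ndarray, i: int, tol: float = 1e-6) -> list[int]:
    """j is a Voronoi neighbor of i iff their bisector contributes a
    positive-length edge to cell i.

    The cell is dilated by a nanometre so that boundary edges, which lie
    exactly on the bisector lines, intersect them robustly.
    """
    cell = voronoi_cell(pts, i).buffer(1e-9, join_style=2)
    nbrs = []
    for j in range(len(pts)):
        if j == i:
            continue
        mid = (pts[i] + pts[j]) / 2.0
        d = pts[j] - pts[i]
        t = np.array([-d[1], d[0]])
        t = t / np.linalg.norm(t)
        bisector = LineString([tuple(mid + t * 4 * _BIG),
                               tuple(mid - t * 4 * _BIG)])
        if cell.intersection(bisector).length > tol:
            nbrs.append(j)
    return nbrs


def nnd_oracle(pts: np.ndarray, roi_bounds: tuple) -> float:
    x0, y0, x1, y1 = roi_bounds
    inside = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
              & (pts[:, 1] >= y0) & (pts[:, 1] <= y1))
    dists = []
    for i in np.flatnonzero(inside):
        d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        dists.append(d.min())
    return float(np.mean(dists))


def icd_oracle(pts: np.ndarray, roi_bounds: tuple) -> float:
    idx, _ = bound_cells_oracle(pts, roi_bounds)
    per_cell = []
    for i in idx:
        nbrs = neighbors_oracle(pts, i)
        d = np.sqrt(((pts[nbrs] - pts[i]) ** 2).sum(axis=1))
        per_cell.append(d.mean())
    return float(np.mean(per_cell))
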