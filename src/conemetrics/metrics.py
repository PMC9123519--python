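"""Point-pattern metrics of the cone mosaic: bound Voronoi density, nearest
neighbor distance (NND) and intercell distance (ICD) on a region of interest.

All coordinates are continuous µm in a y-down image frame with the origin at
the patch top-left.  The three metrics follow the conventions of the bound
Voronoi framework commonly used for cone mosaics:

* **bound density** — tessellate *all* supplied points (points outside the
  ROI are needed to close the cells of points near its edge); a cell is
  *bound* iff its polygon is finite and lies entirely inside the ROI; the
  density is the number of bound cells divided by the summed area of the
  bound cells (not the ROI area), in cones/mm².
* **NND** — mean, over points inside the ROI, of the distance to the nearest
  other point (candidates drawn from all points).
* **ICD** — per bound cell, the mean distance to its Voronoi (Delaunay)
  neighbors; reported as the mean over bound cells.

For a jitter-free hexagonal mosaic of spacing ``s`` these give exactly
``2/(sqrt(3) s²)``, ``s`` and ``s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

from .errors import ParameterError, UndefinedMetricError

logger = logging.getLogger(__name__)

_DEGENERACY_JITTER_UM = 1e-9  # deterministic nudge applied when Qhull fails


@dataclass(frozen=True)
class ROI:
    """Axis-aligned square/rectangular region of interest, in µm.

    The default 200 × 200 µm size (0.04 mm²) is the standard sampling window
    for parafoveal cone metrics.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (200.0, 200.0)
    eccentricity_deg: float | None = None
    meridian: str | None = None

    def __post_init__(self) -> None:
        if not (self.size[0] > 0 and self.size[1] > 0):
            raise ParameterError(f"ROI size must be positive, got {self.size}")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in µm."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.size[0], y0 + self.size[1])

    @property
    def center(self) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + self.size[0] / 2.0, y0 + self.size[1] / 2.0)

    @property
    def area_mm2(self) -> float:
        return self.size[0] * self.size[1] * 1e-6

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed ROI."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.bounds
        return ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0) & (pts[:, 1] <= y1))


@dataclass(frozen=True)
class MetricSet:
    """Bound density, NND and ICD for one ROI / grader / modality."""

    bound_density: float          # cones/mm²
    nnd_mean: float               # µm
    icd_mean: float               # µm
    n_cones_total: int
    n_cones_bound: int
    grader: str = ""
    modality: str = ""
    roi: ROI | None = None


@dataclass(frozen=True)
class RoiTransform:
    """2×3 affine matrix mapping one modality's coordinates (µm) to the
    other's: ``p' = A @ p + t`` with ``A = matrix[:, :2]``, ``t = matrix[:, 2]``.
    """

    matrix: tuple = field(default=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)))

    def as_array(self) -> np.ndarray:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ParameterError(f"transform must be 2x3, got shape {m.shape}")
        return m

    @property
    def linear_det(self) -> float:
        return float(np.linalg.det(self.as_array()[:, :2]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        m = self.as_array()
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ m[:, :2].T + m[:, 2]


def _as_points(coords: Sequence) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1 and pts.size == 0:
        pts = pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"coordinates must be (n, 2), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ParameterError("coordinates contain non-finite values")
    return pts


def _collinear(pts: np.ndarray) -> bool:
    if len(pts) < 3:
        return True
    centered = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9) < 2


def _voronoi(pts: np.ndarray) -> Voronoi:
    """Voronoi tessellation with a deterministic sub-nanometre nudge as a
    fallback for exactly degenerate (e.g. cocircular) inputs."""
    try:
        return Voronoi(pts)
    except QhullError:
        rng = np.random.default_rng(0)
        nudged = pts + rng.normal(0.0, _DEGENERACY_JITTER_UM, pts.shape)
        logger.warning("degenerate tessellation input; applying %g um jitter",
                       _DEGENERACY_JITTER_UM)
        return Voronoi(nudged)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(x @ np.roll(y, -1) - y @ np.roll(x, -1)))


def _bound_cells_impl(pts: np.ndarray, roi: ROI,
                      vor: Voronoi) -> tuple[np.ndarray, np.ndarray]:
    x0, y0, x1, y1 = roi.bounds
    v = vor.vertices
    vertex_ok = ((v[:, 0] >= x0) & (v[:, 0] <= x1)
                 & (v[:, 1] >= y0) & (v[:, 1] <= y1))
    idx: list[int] = []
    areas: list[float] = []
    # a bound cell's generator lies inside the cell, hence inside the ROI,
    # so only points inside the ROI need checking
    for i in np.flatnonzero(roi.contains(pts)):
        region = vor.regions[vor.point_region[i]]
        if len(region) < 3 or -1 in region:
            continue  # unbounded cell
        if all(vertex_ok[j] for j in region):
            idx.append(int(i))
            areas.append(_polygon_area(v[region]))
    return np.asarray(idx, dtype=int), np.asarray(areas, dtype=float)


def bound_cells(coords: Sequence, roi: ROI) -> tuple[np.ndarray, np.ndarray]:
    """Indices of points whose Voronoi cells are bound in ``roi`` and the
    corresponding cell areas (µm²).

    A cell is bound iff its polygon is finite and every vertex lies inside
    the closed ROI (a vertex exactly on the boundary counts as inside).
    """
    pts = _as_points(coords)
    inside = roi.contains(pts)
    if inside.sum() < 3 or _collinear(pts[inside]):
        raise UndefinedMetricError(
            "need at least 3 non-collinear points inside the ROI")
    return _bound_cells_impl(pts, roi, _voronoi(pts))


def voronoi_bound_density(coords: Sequence, roi: ROI) -> tuple[float, int]:
    """Bound Voronoi cone density (cones/mm²) and number of bound cells."""
    idx, areas = bound_cells(coords, roi)
    if len(idx) == 0:
        raise UndefinedMetricError("no Voronoi cell is bound inside the ROI")
    density = len(idx) / (areas.sum() * 1e-6)  # µm² -> mm²
    return float(density), int(len(idx))


def nnd_mean(coords: Sequence, roi: ROI) -> float:
    """Mean nearest-neighbor distance (µm) over points inside the ROI.

    Neighbor candidates are drawn from *all* points, so a point just outside
    the ROI can be the nearest neighbor of one inside.
    """
    pts = _as_points(coords)
    if len(pts) < 2:
        raise UndefinedMetricError("need at least 2 points for NND")
    inside = roi.contains(pts)
    if not inside.any():
        raise UndefinedMetricError("no points inside the ROI")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts[inside], k=2)
    return float(dists[:, 1].mean())


def _delaunay_adjacency(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (indptr, indices) of Delaunay neighbor lists."""
    try:
        tri = Delaunay(pts)
    except QhullError:
        rng = np.random.default_rng(0)
        tri = Delaunay(pts + rng.normal(0.0, _DEGENERACY_JITTER_UM, pts.shape))
    return tri.vertex_neighbor_vertices


def _icd_over(pts: np.ndarray, idx: np.ndarray) -> float:
    indptr, indices = _delaunay_adjacency(pts)
    per_cell = []
    for i in idx:
        nb = indices[indptr[i]:indptr[i + 1]]
        if len(nb) == 0:
            raise UndefinedMetricError(f"degenerate tessellation at point {i}")
        d = np.sqrt(((pts[nb] - pts[i]) ** 2).sum(axis=1))
        per_cell.append(d.mean())
    return float(np.mean(per_cell))


def icd_mean(coords: Sequence, roi: ROI) -> float:
    """Mean intercell distance (µm) over bound cells.

    Per bound cell, the distance to each of its Delaunay/Voronoi neighbors
    (bound or not) is averaged; the per-cell means are then averaged.
    """
    pts = _as_points(coords)
    idx, _ = bound_cells(pts, roi)
    if len(idx) == 0:
        raise UndefinedMetricError("no bound cells for ICD")
    return _icd_over(pts, idx)


def compute_metrics(coords: Sequence, roi: ROI, *, grader: str = "",
                    modality: str = "") -> MetricSet:
    """All three mosaic metrics on one ROI (single tessellation pass)."""
    pts = _as_points(coords)
    idx, areas = bound_cells(pts, roi)
    if len(idx) == 0:
        raise UndefinedMetricError("no Voronoi cell is bound inside the ROI")
    density = len(idx) / (areas.sum() * 1e-6)
    return MetricSet(
        bound_density=float(density),
        nnd_mean=nnd_mean(pts, roi),
        icd_mean=_icd_over(pts, idx),
        n_cones_total=int(roi.contains(pts).sum()),
        n_cones_bound=int(len(idx)),
        grader=grader,
        modality=modality,
        roi=roi,
    )


def density_to_spacing(d: float) -> float:
    """Hexagonally equivalent center-to-center spacing s (µm) of a mosaic of
    density ``d`` (cones/mm²): ``s = 1000 * sqrt(2 / (sqrt(3) d))``."""
    if not d > 0:
        raise ParameterError(f"density must be > 0, got {d!r}")
    return 1000.0 * float(np.sqrt(2.0 / (np.sqrt(3.0) * d)))


def spacing_to_density(s: float) -> float:
    """Inverse of :func:`density_to_spacing`: cones/mm² for spacing s in µm."""
    if not s > 0:
        raise ParameterError(f"spacing must be > 0, got {s!r}")
    return 2.0 / (np.sqrt(3.0) * (s / 1000.0) ** 2)


def colocalize_roi(roi_src: ROI, t: RoiTransform) -> ROI:
    """Map an ROI into the other modality's frame through an affine transform.

    The returned ROI keeps the source's physical size and axis alignment;
    only its *center* is transformed.  Any rotation/shear in the transform is
    discarded (and logged), since the downstream extraction is axis-aligned.
    """
    m = t.as_array()
    det = t.linear_det
    if abs(det) < 1e-12:
        raise ParameterError("ROI transform is not invertible")
    if not (0.8 <= abs(det) <= 1.25):
        logger.warning("transform is far from rigid (|det|=%.3f)", abs(det))
    lin = m[:, :2]
    if abs(lin[0, 1]) > 1e-12 or abs(lin[1, 0]) > 1e-12:
        logger.info("discarding rotation/shear component of ROI transform")
    cx, cy = t.apply(np.array([roi_src.center]))[0]
    return ROI(origin=(cx - roi_src.size[0] / 2.0, cy - roi_src.size[1] / 2.0),
               size=roi_src.size,
               eccentricity_deg=roi_src.eccentricity_deg,
               meridian=roi_src.meridian)
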