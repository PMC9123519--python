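"""Synthetic cone mosaics, two-modality image rendering, and grader simulation.

Real parafoveal cone mosaics are close to hexagonally packed, with density
falling with eccentricity (roughly 6,700–18,800 cones/mm² over the 3°–10°
range studied here).  The generator produces a row-offset hexagonal lattice
of the requested density, perturbs it with isotropic Gaussian positional
jitter, and optionally drops cones at random.

Rendering emulates the two imaging modalities as stacks of frames: each cone
is a Gaussian reflectance spot whose brightness varies from frame to frame
(short-term variation in cone reflectivity), the whole frame is rigidly
translated by per-frame eye motion, an optional central hyperreflective
artifact partially obscures the mosaic, and additive sensor noise is applied.
Averaging registered frames recovers signal-to-noise, as in device real-time
averaging plus offline averaging.

Grader simulation perturbs a coordinate list the way a human marker would:
small positional jitter, missed cones, and spurious marks.

One global integer seed feeds independent sub-streams (mosaic, render,
grader) via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .metrics import density_to_spacing

BASE_SPOT_AMPLITUDE = 1000.0  # peak intensity of a unit-reflectance cone


@dataclass(frozen=True)
class MosaicGroundTruth:
    """True cone coordinates together with the parameters that generated them.

    ``points`` is an (n, 2) float array of (x, y) positions in µm, y-down,
    origin at the field's top-left corner.
    """

    points: np.ndarray
    density_nominal: float        # cones/mm²
    jitter_sd: float              # µm
    dropout_frac: float
    field_size: tuple[float, float]  # (width, height) µm
    seed: int

    @property
    def spacing(self) -> float:
        """Hexagonally equivalent lattice spacing (µm)."""
        return density_to_spacing(self.density_nominal)


@dataclass(frozen=True)
class RenderConfig:
    """Parameters of the frame renderer.

    ``psf_sigma`` is the Gaussian point-spread sigma in µm; ``reflectance_cv``
    the per-cone per-frame coefficient of variation of spot brightness
    (lognormal with unit median); ``motion_sd`` the SD of the rigid per-frame
    translation in µm; the artifact is a Gaussian hyperreflective blob.
    """

    psf_sigma: float = 1.5          # µm
    pixel_scale: float = 1.0        # µm/pixel
    reflectance_cv: float = 0.15
    noise_sd: float = 20.0          # intensity units (spot peak is 1000)
    artifact_on: bool = False
    artifact_center: tuple[float, float] | None = None  # µm; None = field center
    artifact_radius: float = 40.0   # µm
    artifact_amplitude: float = 800.0
    n_frames: int = 15
    motion_sd: float = 1.0          # µm per frame

    def __post_init__(self) -> None:
        if not self.psf_sigma > 0:
            raise ParameterError("psf_sigma must be > 0")
        if not self.pixel_scale > 0:
            raise ParameterError("pixel_scale must be > 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")


@dataclass(frozen=True)
class GraderModel:
    """Stochastic model of a human grader marking cone centers."""

    jitter_sd: float = 0.0     # µm
    miss_rate: float = 0.0     # probability a true cone is not marked
    false_rate: float = 0.0    # spurious marks per mm²
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ParameterError("miss_rate must be in [0, 1]")
        if self.jitter_sd < 0 or self.false_rate < 0:
            raise ParameterError("jitter_sd and false_rate must be >= 0")


@dataclass
class FrameStack:
    """A stack of co-located frames with one shared linear scale."""

    frames: np.ndarray            # (n_frames, H, W) float
    scale: float                  # µm/pixel
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ImagePatch:
    """A single 2-D intensity image with its linear scale."""

    image: np.ndarray             # (H, W) float
    scale: float                  # µm/pixel
    metadata: dict = field(default_factory=dict)


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def hex_lattice(spacing: float, field_size: tuple[float, float]) -> np.ndarray:
    """Row-offset hexagonal lattice clipped to [0, W] × [0, H] (µm)."""
    w, h = field_size
    row_height = spacing * np.sqrt(3.0) / 2.0
    rows = int(np.floor(h / row_height)) + 1
    pts = []
    for j in range(rows):
        y = j * row_height
        x_off = (j % 2) * spacing / 2.0
        n_x = int(np.floor((w - x_off) / spacing)) + 1
        x = x_off + spacing * np.arange(n_x)
        pts.append(np.column_stack([x, np.full(n_x, y)]))
    return np.vstack(pts)


def generate_mosaic(density: float, field_size: tuple[float, float],
                    jitter_sd: float = 0.0, dropout_frac: float = 0.0,
                    seed: int = 0) -> MosaicGroundTruth:
    """Generate a jittered hexagonal cone mosaic of nominal ``density``.

    Parameters
    ----------
    density : float
        Target cone density in cones/mm².
    field_size : (float, float)
        Field width and height in µm; each side must span at least five
        lattice spacings so that interior metrics are meaningful.
    jitter_sd : float
        Isotropic Gaussian positional jitter, µm.
    dropout_frac : float
        Fraction of cones removed at random.
    seed : int
        Global seed; the mosaic uses its first spawned sub-stream.
    """
    if not density > 0:
        raise ParameterError(f"density must be > 0, got {density!r}")
    if not (field_size[0] > 0 and field_size[1] > 0):
        raise ParameterError(f"field_size must be positive, got {field_size}")
    if not 0.0 <= dropout_frac <= 1.0:
        raise ParameterError("dropout_frac must be in [0, 1]")
    spacing = density_to_spacing(density)
    if min(field_size) < 5 * spacing:
        raise ParameterError(
            f"field sides must be >= 5 lattice spacings ({5 * spacing:.1f} µm)")
    rng, _, _ = _streams(seed)
    pts = hex_lattice(spacing, field_size)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], 0.0, field_size[0])
        pts[:, 1] = np.clip(pts[:, 1], 0.0, field_size[1])
    if dropout_frac > 0:
        keep = rng.random(len(pts)) >= dropout_frac
        pts = pts[keep]
    return MosaicGroundTruth(points=pts, density_nominal=density,
                             jitter_sd=jitter_sd, dropout_frac=dropout_frac,
                             field_size=tuple(field_size), seed=seed)


def _add_gaussian_spot(frame: np.ndarray, x_px: float, y_px: float,
                       sigma_px: float, amplitude: float) -> None:
    """Add a Gaussian spot to ``frame`` over a ±4σ window, in place."""
    h, w = frame.shape
    half = int(np.ceil(4 * sigma_px))
    r0 = max(int(np.floor(y_px)) - half, 0)
    r1 = min(int(np.ceil(y_px)) + half + 1, h)
    c0 = max(int(np.floor(x_px)) - half, 0)
    c1 = min(int(np.ceil(x_px)) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    frame[r0:r1, c0:c1] += amplitude * np.exp(
        -((cc - x_px) ** 2 + (rr - y_px) ** 2) / (2.0 * sigma_px ** 2))


def render_frames(mosaic: MosaicGroundTruth, cfg: RenderConfig,
                  seed: int | None = None) -> FrameStack:
    """Render a mosaic into an n-frame stack under one modality's optics.

    Pixel (row 0, col 0) is centered at (0.5·scale, 0.5·scale) µm, so a cone
    at µm position (x, y) peaks at pixel column ``x/scale − 0.5``.
    The per-frame motion shifts (µm, applied to all cones of that frame) are
    recorded in ``metadata['motion_um']``.
    """
    if len(mosaic.points) == 0:
        raise ParameterError("mosaic has no points to render")
    if cfg.pixel_scale >= 2 * cfg.psf_sigma:
        warnings.warn("pixel_scale >= 2*psf_sigma: render is undersampled",
                      stacklevel=2)
    if seed is None:
        seed = mosaic.seed
    _, rng, _ = _streams(seed)
    w_um, h_um = mosaic.field_size
    width = int(np.ceil(w_um / cfg.pixel_scale))
    height = int(np.ceil(h_um / cfg.pixel_scale))
    sigma_px = cfg.psf_sigma / cfg.pixel_scale
    n_pts = len(mosaic.points)

    motion = (rng.normal(0.0, cfg.motion_sd, (cfg.n_frames, 2))
              if cfg.motion_sd > 0 else np.zeros((cfg.n_frames, 2)))
    if cfg.reflectance_cv > 0:
        sigma_log = np.sqrt(np.log1p(cfg.reflectance_cv ** 2))
        refl = rng.lognormal(0.0, sigma_log, (cfg.n_frames, n_pts))
    else:
        refl = np.ones((cfg.n_frames, n_pts))

    art_center = cfg.artifact_center if cfg.artifact_center is not None \
        else (w_um / 2.0, h_um / 2.0)

    frames = np.zeros((cfg.n_frames, height, width), dtype=float)
    for f in range(cfg.n_frames):
        frame = frames[f]
        dx, dy = motion[f]
        for i, (x, y) in enumerate(mosaic.points):
            _add_gaussian_spot(frame,
                               (x + dx) / cfg.pixel_scale - 0.5,
                               (y + dy) / cfg.pixel_scale - 0.5,
                               sigma_px,
                               BASE_SPOT_AMPLITUDE * refl[f, i])
        if cfg.artifact_on:
            _add_gaussian_spot(frame,
                               (art_center[0] + dx) / cfg.pixel_scale - 0.5,
                               (art_center[1] + dy) / cfg.pixel_scale - 0.5,
                               (cfg.artifact_radius / 2.0) / cfg.pixel_scale,
                               cfg.artifact_amplitude)
        if cfg.noise_sd > 0:
            frame += rng.normal(0.0, cfg.noise_sd, frame.shape)
    return FrameStack(frames=frames, scale=cfg.pixel_scale,
                      metadata={"motion_um": motion.tolist(),
                                "seed": seed,
                                "config": cfg.__dict__.copy()})


def simulate_grader(coords: Sequence, model: GraderModel,
                    field_size: tuple[float, float] | None = None) -> np.ndarray:
    """Apply grader behavior to a list of true cone coordinates.

    Retained points are jittered by an isotropic Gaussian, misses are removed
    with probability ``miss_rate``, and spurious marks are added as a Poisson
    process of intensity ``false_rate`` per mm² over ``field_size`` (or the
    bounding box of the input when not given).  With an all-zero model the
    output equals the input exactly.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 2).copy()
    if model.jitter_sd == 0 and model.miss_rate == 0 and model.false_rate == 0:
        return pts
    _, _, rng = _streams(model.seed)
    if model.miss_rate > 0 and len(pts):
        pts = pts[rng.random(len(pts)) >= model.miss_rate]
    if model.jitter_sd > 0 and len(pts):
        pts = pts + rng.normal(0.0, model.jitter_sd, pts.shape)
    if model.false_rate > 0:
        if field_size is not None:
            x0 = y0 = 0.0
            x1, y1 = field_size
        elif len(pts):
            x0, y0 = pts.min(axis=0)
            x1, y1 = pts.max(axis=0)
        else:
            raise ParameterError("false_rate > 0 needs field_size or points")
        area_mm2 = (x1 - x0) * (y1 - y0) * 1e-6
        n_false = rng.poisson(model.false_rate * area_mm2)
        if n_false:
            false_pts = np.column_stack([rng.uniform(x0, x1, n_false),
                                         rng.uniform(y0, y1, n_false)])
            pts = np.vstack([pts, false_pts]) if len(pts) else false_pts
    return pts


def with_seed(model: GraderModel, seed: int) -> GraderModel:
    """A copy of a grader model with a different seed (per-ROI reseeding)."""
    return replace(model, seed=seed)
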