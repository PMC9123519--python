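"""Frame registration, quality-based frame selection/averaging, and
semi-automatic cone detection.

The processing chain mirrors typical photoreceptor-imaging practice: frames
of a stack are rigidly aligned by cross-correlation to an automatically
chosen reference, poor frames are dropped, the rest are averaged to raise
the signal-to-noise ratio, and cone centers are then found as local maxima
of a difference-of-Gaussians band-pass image, optionally corrected by manual
add/remove edits (the "semi-automatic" step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import ParameterError
from .synthetic import FrameStack, ImagePatch


@dataclass(frozen=True)
class DetectionConfig:
    """Cone-detector parameters (all length units in µm).

    ``lowpass_sigma`` sets the band-pass: the image is filtered with a
    difference of Gaussians with sigmas (lowpass_sigma, 2·lowpass_sigma),
    matched to the spot size.  ``threshold_quantile`` is applied to the
    filtered intensity distribution; maxima below it are discarded.
    ``min_separation`` is the greedy non-maximum-suppression radius.
    """

    lowpass_sigma: float = 1.8
    min_separation: float = 4.0
    threshold_quantile: float = 0.80
    roi_margin: float = 0.0
    #: PSF sigma (µm) for Wiener pre-sharpening; None disables deconvolution.
    #: When cones are blurred to near the packing spacing, deconvolving with
    #: the (known or estimated) PSF restores the intercone contrast that the
    #: band-pass alone cannot.
    deconv_sigma: float | None = None
    deconv_reg: float = 3e-4

    def __post_init__(self) -> None:
        if not self.min_separation > 0:
            raise ParameterError("min_separation must be > 0")
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ParameterError("threshold_quantile must be in (0, 1)")
        if not self.lowpass_sigma > 0:
            raise ParameterError("lowpass_sigma must be > 0")
        if self.deconv_sigma is not None and not self.deconv_sigma > 0:
            raise ParameterError("deconv_sigma must be > 0 or None")
        if not self.deconv_reg > 0:
            raise ParameterError("deconv_reg must be > 0")


@dataclass(frozen=True)
class EditList:
    """Manual corrections: removals matched within ``match_radius`` are
    applied first, then additions are appended."""

    additions: tuple = ()
    removals: tuple = ()
    match_radius: float = 2.0   # µm

    def __post_init__(self) -> None:
        if not self.match_radius > 0:
            raise ParameterError("match_radius must be > 0")


def _pairwise_shifts_to_reference(frames: np.ndarray,
                                  upsample: int) -> tuple[np.ndarray, int]:
    """Shifts (row, col, px) aligning each frame to the best reference.

    Frames are first aligned to frame 0; the reference is the aligned frame
    with the highest mean Pearson correlation to the other aligned frames;
    shifts are then re-expressed relative to that reference.
    """
    n = len(frames)
    shifts0 = np.zeros((n, 2))
    for i in range(1, n):
        shifts0[i], _, _ = phase_cross_correlation(
            frames[0], frames[i], upsample_factor=upsample,
            normalization=None)
    aligned = np.stack([
        ndimage.shift(frames[i], shifts0[i], order=1, mode="nearest")
        if np.any(shifts0[i]) else frames[i]
        for i in range(n)
    ])
    flat = aligned.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    corr = (flat @ flat.T) / np.outer(norms, norms)
    mean_corr = (corr.sum(axis=1) - 1.0) / max(n - 1, 1)
    ref = int(np.argmax(mean_corr))
    return shifts0 - shifts0[ref], ref


def register_frames(stack: FrameStack, upsample: int = 20) -> FrameStack:
    """Rigidly align all frames of a stack by cross-correlation.

    Translation-only: the synthetic eye-motion model is a per-frame rigid
    shift, so no affine degrees of freedom are fitted.  The applied shifts
    (in pixels, (row, col) convention) and the chosen reference frame index
    are logged in the output metadata.  A single-frame stack is returned
    unchanged; a frame whose estimated shift exceeds a quarter of the frame
    is flagged as unreliable.
    """
    if stack.n_frames < 2:
        out = FrameStack(frames=stack.frames.copy(), scale=stack.scale,
                         metadata=dict(stack.metadata))
        out.metadata.update({"registration_shifts_px": [[0.0, 0.0]],
                             "reference_frame": 0, "flagged_frames": []})
        return out
    shifts, ref = _pairwise_shifts_to_reference(stack.frames, upsample)
    h, w = stack.frames.shape[1:]
    flagged = [int(i) for i in range(len(shifts))
               if abs(shifts[i][0]) > h / 4 or abs(shifts[i][1]) > w / 4]
    registered = np.stack([
        ndimage.shift(stack.frames[i], shifts[i], order=1, mode="nearest")
        if np.any(shifts[i]) else stack.frames[i].copy()
        for i in range(stack.n_frames)
    ])
    out = FrameStack(frames=registered, scale=stack.scale,
                     metadata=dict(stack.metadata))
    out.metadata.update({
        "registration_shifts_px": shifts.tolist(),
        "reference_frame": ref,
        "flagged_frames": flagged,
    })
    return out


def select_and_average(stack: FrameStack, keep_frac: float = 1.0) -> ImagePatch:
    """Rank frames by correlation to the stack median image and average the
    best ``keep_frac`` of them (mean projection)."""
    if not 0.0 < keep_frac <= 1.0:
        raise ParameterError("keep_frac must be in (0, 1]")
    n = stack.n_frames
    n_keep = int(np.ceil(keep_frac * n))
    if n_keep < 1:
        warnings.warn("keep_frac selects no frame; keeping the best one",
                      stacklevel=2)
        n_keep = 1
    median_img = np.median(stack.frames, axis=0)
    med = (median_img - median_img.mean()).ravel()
    med_norm = np.linalg.norm(med) or 1.0
    scores = np.empty(n)
    for i in range(n):
        f = (stack.frames[i] - stack.frames[i].mean()).ravel()
        scores[i] = float(f @ med) / ((np.linalg.norm(f) or 1.0) * med_norm)
    kept = np.sort(np.argsort(-scores)[:n_keep])
    avg = stack.frames[kept].mean(axis=0)
    meta = dict(stack.metadata)
    meta.update({"kept_frames": kept.tolist(),
                 "frame_scores": scores.tolist(),
                 "n_averaged": int(n_keep)})
    return ImagePatch(image=avg, scale=stack.scale, metadata=meta)


def _wiener_sharpen(data: np.ndarray, sigma_px: float, reg: float) -> np.ndarray:
    """Tikhonov-regularized inverse filtering with a Gaussian transfer
    function: ``F_out = F_in * H / (H² + reg)``.  Mean-subtracted, so the
    result is invariant (up to scale) to positive affine intensity changes."""
    h, w = data.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    transfer = np.exp(-2.0 * np.pi ** 2 * sigma_px ** 2 * (fx ** 2 + fy ** 2))
    spectrum = np.fft.fft2(data - data.mean())
    return np.real(np.fft.ifft2(spectrum * transfer
                                / (transfer ** 2 + reg)))


def _local_maxima(band: np.ndarray, threshold: float) -> np.ndarray:
    """(row, col) of strict-neighborhood local maxima above ``threshold``."""
    footprint_max = ndimage.maximum_filter(band, size=3, mode="nearest")
    mask = (band >= footprint_max) & (band > threshold)
    mask[0, :] = mask[-1, :] = False
    mask[:, 0] = mask[:, -1] = False
    return np.argwhere(mask)


def _subpixel_offset(band: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """1-D quadratic peak interpolation along each axis, clipped to ±0.5 px."""
    def interp(fm: float, f0: float, fp: float) -> float:
        denom = fm - 2.0 * f0 + fp
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))
    dy = interp(band[r - 1, c], band[r, c], band[r + 1, c])
    dx = interp(band[r, c - 1], band[r, c], band[r, c + 1])
    return dx, dy


def detect_cones(img: ImagePatch, cfg: DetectionConfig = DetectionConfig(),
                 edits: EditList | None = None) -> np.ndarray:
    """Detect cone centers in an averaged image; returns (n, 2) µm positions.

    Pipeline: difference-of-Gaussians band-pass (sigmas ``lowpass_sigma`` and
    ``2·lowpass_sigma``), local maxima above the ``threshold_quantile`` of the
    band-pass intensity, greedy suppression of maxima closer than
    ``min_separation`` (brighter wins; ties broken by lower y then lower x),
    quadratic sub-pixel refinement, then manual removals and additions.
    The quantile threshold makes the detector invariant to positive affine
    intensity rescaling.
    """
    if img.scale is None or not img.scale > 0:
        raise ParameterError("image has no valid µm/pixel scale")
    scale = float(img.scale)
    data = np.asarray(img.image, dtype=float)
    if cfg.deconv_sigma is not None:
        data = _wiener_sharpen(data, cfg.deconv_sigma / scale, cfg.deconv_reg)
    s1 = cfg.lowpass_sigma / scale
    band = (ndimage.gaussian_filter(data, s1)
            - ndimage.gaussian_filter(data, 2.0 * s1))
    threshold = float(np.quantile(band, cfg.threshold_quantile))
    peaks = _local_maxima(band, threshold)
    coords: list[tuple[float, float]] = []
    if len(peaks):
        values = band[peaks[:, 0], peaks[:, 1]]
        # brighter first; ties by lower row (y) then lower column (x)
        order = np.lexsort((peaks[:, 1], peaks[:, 0], -values))
        peaks = peaks[order]
        min_sep_px = cfg.min_separation / scale
        accepted: list[tuple[int, int]] = []
        acc_arr = np.empty((0, 2))
        for r, c in peaks:
            if len(accepted):
                d2 = ((acc_arr[:, 0] - r) ** 2 + (acc_arr[:, 1] - c) ** 2)
                if d2.min() < min_sep_px ** 2:
                    continue
            accepted.append((int(r), int(c)))
            acc_arr = np.asarray(accepted, dtype=float)
        h, w = band.shape
        margin_px = cfg.roi_margin / scale
        for r, c in accepted:
            if (r < margin_px or c < margin_px
                    or r >= h - margin_px or c >= w - margin_px):
                continue
            dx, dy = _subpixel_offset(band, r, c)
            coords.append(((c + 0.5 + dx) * scale, (r + 0.5 + dy) * scale))
    out = np.asarray(coords, dtype=float).reshape(-1, 2)
    if edits is not None:
        out = apply_edits(out, edits)
    return out


def apply_edits(coords: np.ndarray, edits: EditList) -> np.ndarray:
    """Apply manual removals (nearest match within radius) then additions."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    for rx, ry in edits.removals:
        if len(pts) == 0:
            break
        d = np.hypot(pts[:, 0] - rx, pts[:, 1] - ry)
        j = int(np.argmin(d))
        if d[j] <= edits.match_radius:
            pts = np.delete(pts, j, axis=0)
    if edits.additions:
        add = np.asarray(edits.additions, dtype=float).reshape(-1, 2)
        pts = np.vstack([pts, add]) if len(pts) else add
    return pts


def match_points(truth: Sequence, detected: Sequence,
                 radius: float = 2.0) -> dict:
    """Greedy one-to-one matching of detected points to ground truth within
    ``radius`` µm; returns recall, precision and the match index pairs."""
    t = np.asarray(truth, dtype=float).reshape(-1, 2)
    d = np.asarray(detected, dtype=float).reshape(-1, 2)
    if len(t) == 0 or len(d) == 0:
        return {"recall": 0.0, "precision": 0.0, "matches": []}
    diff = t[:, None, :] - d[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    pairs = []
    used_t: set[int] = set()
    used_d: set[int] = set()
    order = np.argsort(dist, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > radius:
            break
        if i in used_t or j in used_d:
            continue
        used_t.add(int(i))
        used_d.add(int(j))
        pairs.append((int(i), int(j)))
    return {"recall": len(pairs) / len(t),
            "precision": len(pairs) / len(d),
            "matches": pairs}
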