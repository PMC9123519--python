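"""Reading and writing the package's on-disk formats.

Coordinates travel as CSV (``id,x_um,y_um``), frame stacks as multipage
16-bit TIFF with a JSON sidecar carrying the µm/pixel scale, ROIs and
configurations as JSON, metrics tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .metrics import ROI, MetricSet
from .synthetic import FrameStack, ImagePatch


def write_coords(path: str | Path, coords: np.ndarray) -> None:
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"id": np.arange(len(pts)),
                       "x_um": pts[:, 0], "y_um": pts[:, 1]})
    df.to_csv(path, index=False)


def read_coords(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"x_um", "y_um"} - set(df.columns)
    if missing:
        raise ParameterError(f"coordinate CSV missing columns {sorted(missing)}")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def write_roi(path: str | Path, roi: ROI) -> None:
    doc = {"origin_um": list(roi.origin), "size_um": list(roi.size),
           "eccentricity_deg": roi.eccentricity_deg, "meridian": roi.meridian}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_roi(path: str | Path) -> ROI:
    doc = json.loads(Path(path).read_text())
    return ROI(origin=tuple(doc["origin_um"]), size=tuple(doc["size_um"]),
               eccentricity_deg=doc.get("eccentricity_deg"),
               meridian=doc.get("meridian"))


def _sidecar_path(tiff_path: str | Path) -> Path:
    p = Path(tiff_path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write frames as multipage 16-bit TIFF plus a JSON sidecar."""
    frames = np.asarray(stack.frames, dtype=float)
    lo, hi = frames.min(), frames.max()
    span = (hi - lo) or 1.0
    scaled = ((frames - lo) / span * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, scaled, photometric="minisblack")
    meta = {k: v for k, v in stack.metadata.items()
            if _json_safe(v)}
    doc = {"scale_um_per_px": stack.scale, "n_frames": int(stack.n_frames),
           "intensity_range": [float(lo), float(hi)], **meta}
    _sidecar_path(path).write_text(json.dumps(doc, indent=2, default=str))


def read_stack(path: str | Path) -> FrameStack:
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    doc = json.loads(_sidecar_path(path).read_text())
    lo, hi = doc.get("intensity_range", [0.0, 65535.0])
    frames = frames / 65535.0 * (hi - lo) + lo
    meta = {k: v for k, v in doc.items()
            if k not in ("scale_um_per_px", "n_frames", "intensity_range")}
    return FrameStack(frames=frames, scale=float(doc["scale_um_per_px"]),
                      metadata=meta)


def write_image(path: str | Path, img: ImagePatch) -> None:
    write_stack(path, FrameStack(frames=np.asarray(img.image)[None],
                                 scale=img.scale, metadata=img.metadata))


def read_image(path: str | Path) -> ImagePatch:
    stack = read_stack(path)
    return ImagePatch(image=stack.frames[0], scale=stack.scale,
                      metadata=stack.metadata)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def metrics_to_frame(metric_sets: list[tuple[str, MetricSet]]) -> pd.DataFrame:
    """Tidy table of MetricSets, one row per (roi_id, grader, modality).

    Reported precision follows the field's convention: densities rounded to
    whole cones/mm², spacings to 0.01 µm.
    """
    rows = []
    for roi_id, ms in metric_sets:
        rows.append({
            "roi_id": roi_id,
            "modality": ms.modality,
            "grader": ms.grader,
            "bound_density": round(ms.bound_density),
            "nnd_um": round(ms.nnd_mean, 2),
            "icd_um": round(ms.icd_mean, 2),
            "n_bound": ms.n_cones_bound,
            "n_total": ms.n_cones_total,
        })
    return pd.DataFrame(rows)


def read_edit_list(path: str | Path, match_radius: float = 2.0):
    """Read a manual-correction CSV with header ``action,x_um,y_um``."""
    from .detection import EditList

    df = pd.read_csv(path)
    missing = {"action", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ParameterError(f"edit CSV missing columns {sorted(missing)}")
    adds = [tuple(r) for r in
            df.loc[df["action"] == "add", ["x_um", "y_um"]].to_numpy()]
    rems = [tuple(r) for r in
            df.loc[df["action"] == "remove", ["x_um", "y_um"]].to_numpy()]
    bad = set(df["action"]) - {"add", "remove"}
    if bad:
        raise ParameterError(f"unknown edit actions {sorted(bad)}")
    return EditList(additions=tuple(adds), removals=tuple(rems),
                    match_radius=match_radius)


def dataclass_to_json(path: str | Path, obj) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(obj), indent=2, default=str))
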