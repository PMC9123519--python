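"""Linear image scale (µm/pixel) from ocular biometry and device geometry.

Both imaging modalities produce images whose angular extent is fixed by the
scanner, so the linear retinal scale depends on the eye being imaged.  The
conversion uses an assumed retinal magnification factor (RMF, µm of retina
per degree of visual angle) for a reference schematic eye, scaled linearly
by the subject's measured axial length (AL):

* confocal SLO with a known scan angle ``theta`` over ``I_s`` raw pixels::

      scale = (theta / I_s) * RMF * (AL / AL_ref)

* AO ophthalmoscope calibrated by imaging a Ronchi ruling (period ``T``
  µm/cycle) through a model eye of focal length ``f1`` µm, sampled at
  ``T_s`` pixels/cycle::

      scale = (T / (f1 * T_s)) * (180 / pi) * RMF * (AL / AL_ref)

Defaults are RMF = 291 µm/deg at a 24.0 mm reference axial length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

#: Retinal magnification factor (µm per degree) of the reference schematic eye.
DEFAULT_RMF_UM_PER_DEG = 291.0
#: Axial length (mm) of the reference schematic eye.
DEFAULT_AL_REF_MM = 24.0


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ParameterError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of a confocal SLO acquisition.

    Parameters
    ----------
    theta : float
        Scan size in degrees.
    I_s : float
        Number of pixels across the raw image.
    AL : float
        Subject axial length in mm.
    RMF : float
        Retinal magnification factor, µm/deg at the reference eye.
    AL_ref : float
        Reference axial length in mm.
    """

    theta: float
    I_s: float
    AL: float
    RMF: float = DEFAULT_RMF_UM_PER_DEG
    AL_ref: float = DEFAULT_AL_REF_MM

    def __post_init__(self) -> None:
        _require_positive(theta=self.theta, I_s=self.I_s, AL=self.AL,
                          RMF=self.RMF, AL_ref=self.AL_ref)


@dataclass(frozen=True)
class RonchiCalibration:
    """Ronchi-ruling calibration of an AO scanner.

    ``T`` is the ruling periodicity (µm/cycle), ``f1`` the model-eye focal
    length (µm) and ``T_s`` the measured sampling period of the ruling in the
    model-eye image (pixels/cycle).
    """

    T: float
    f1: float
    T_s: float
    AL: float
    RMF: float = DEFAULT_RMF_UM_PER_DEG
    AL_ref: float = DEFAULT_AL_REF_MM

    def __post_init__(self) -> None:
        _require_positive(T=self.T, f1=self.f1, T_s=self.T_s, AL=self.AL,
                          RMF=self.RMF, AL_ref=self.AL_ref)


def hmm_scale(g: ScanGeometry) -> float:
    """Linear scale (µm/pixel) of a scan-angle-specified confocal SLO image."""
    return (g.theta / g.I_s) * g.RMF * (g.AL / g.AL_ref)


def aoslo_scale(c: RonchiCalibration) -> float:
    """Linear scale (µm/pixel) of an AO image from a Ronchi calibration.

    ``T/(f1*T_s)`` is the angular subtense of one pixel in radians; the
    ``180/pi`` factor converts it to degrees before applying the RMF.
    """
    return (c.T / (c.f1 * c.T_s)) * (180.0 / math.pi) * c.RMF * (c.AL / c.AL_ref)


def degrees_to_um(deg: float, AL: float,
                  rmf: float = DEFAULT_RMF_UM_PER_DEG,
                  al_ref: float = DEFAULT_AL_REF_MM) -> float:
    """Convert an angular extent on the retina to µm for an eye of axial
    length ``AL`` (mm)."""
    if not AL > 0:
        raise ParameterError(f"AL must be > 0, got {AL!r}")
    return deg * rmf * (AL / al_ref)


def um_to_degrees(um: float, AL: float,
                  rmf: float = DEFAULT_RMF_UM_PER_DEG,
                  al_ref: float = DEFAULT_AL_REF_MM) -> float:
    """Inverse of :func:`degrees_to_um`."""
    if not AL > 0:
        raise ParameterError(f"AL must be > 0, got {AL!r}")
    return um / (rmf * (AL / al_ref))
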