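"""Grey-level to arena luminance calibration and double-cone luminance.

Two distinct photometric layers:

* :class:`CalibrationCurve` maps nominal stimulus grey (reflectance
  fraction in [0, 1]) to luminance in the experimental arena, anchored at
  the measured endpoints of the printed patterns: the darkest grey at
  13 cd/m^2 and the lightest at 216 cd/m^2.  Linear by default; a gamma
  shape is available because real print/illumination chains are
  nonlinear.

* :func:`double_cone_luminance` computes the avian achromatic signal as
  the spectral integral reflectance x illuminant x double-cone
  sensitivity.  Birds are thought to use the double cones (with oil-
  droplet filtering) for luminance vision; the packaged sensitivity curve
  is a smooth synthetic stand-in, not measured data — supply a measured
  curve for real work.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stimulus import StimulusImage

__all__ = [
    "CalibrationCurve",
    "SpectralSensitivity",
    "grey_to_luminance",
    "effective_michelson",
    "double_cone_luminance",
    "load_double_cone_sensitivity",
    "load_arena_illuminant",
    "read_spectrum_csv",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Strictly increasing grey -> luminance (cd/m^2) mapping."""

    anchor_dark: float = 13.0
    anchor_light: float = 216.0
    shape: str = "linear"  # "linear" | "gamma"
    gamma_exponent: float = 2.2

    def __post_init__(self):
        if not (self.anchor_light > self.anchor_dark > 0):
            raise ValueError("need anchor_light > anchor_dark > 0")
        if self.shape not in ("linear", "gamma"):
            raise ValueError("shape must be 'linear' or 'gamma'")
        if self.shape == "gamma" and self.gamma_exponent <= 0:
            raise ValueError("gamma_exponent must be positive")


def grey_to_luminance(grey, curve: CalibrationCurve = CalibrationCurve()):
    """Map grey level(s) in [0, 1] to arena luminance in cd/m^2.

    grey=0 gives the dark anchor, grey=1 the light anchor, exactly.
    """
    g = np.asarray(grey, dtype=float)
    if np.any(g < 0.0) or np.any(g > 1.0):
        raise ValueError("grey levels must lie in [0, 1]")
    if curve.shape == "gamma":
        g = g**curve.gamma_exponent
    lum = curve.anchor_dark + (curve.anchor_light - curve.anchor_dark) * g
    return float(lum) if np.isscalar(grey) else lum


def effective_michelson(image: StimulusImage, curve: CalibrationCurve = CalibrationCurve()) -> float:
    """Michelson contrast of the stimulus in arena luminance units.

    Computed on the luminance-mapped masked pixels; because luminance is
    positive this is always <= 1, and it is smaller than the nominal grey
    contrast whenever the dark anchor is above zero.
    """
    vals = image.pixels[image.mask]
    if vals.size == 0:
        raise ValueError("stimulus mask is empty")
    lum = grey_to_luminance(vals, curve)
    lmin, lmax = float(lum.min()), float(lum.max())
    return (lmax - lmin) / (lmax + lmin)


@dataclass(frozen=True)
class SpectralSensitivity:
    """Relative quantal spectral sensitivity on an increasing nm grid."""

    wavelengths: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sensitivity, dtype=float)
        if wl.ndim != 1 or wl.shape != s.shape:
            raise ValueError("wavelengths and sensitivity must be equal-length 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(~np.isfinite(s)) or np.any(s < 0):
            raise ValueError("sensitivity must be finite and non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivity", s)


def _common_grid(*pairs):
    """Resample (wavelength, value) pairs onto their overlapping grid by
    linear interpolation; the grid is the densest input restricted to the
    common range."""
    los = [p[0][0] for p in pairs]
    his = [p[0][-1] for p in pairs]
    lo, hi = max(los), min(his)
    if lo >= hi:
        raise ValueError(
            f"wavelength ranges do not overlap (common range [{lo}, {hi}] nm)"
        )
    grid = max((p[0] for p in pairs), key=len)
    grid = grid[(grid >= lo) & (grid <= hi)]
    return grid, [np.interp(grid, wl, v) for wl, v in pairs]


def double_cone_luminance(
    reflectance: tuple[np.ndarray, np.ndarray] | np.ndarray,
    illuminant: tuple[np.ndarray, np.ndarray] | np.ndarray,
    sens: SpectralSensitivity,
) -> float:
    """Double-cone-weighted luminance of a reflecting surface.

    Integrates reflectance(lambda) * illuminant(lambda) * sensitivity(lambda)
    over the common wavelength range (trapezoidal rule).  Reflectance and
    illuminant are either (wavelength, value) pairs or arrays already on
    the sensitivity grid.  Linear in reflectance and illuminant; arbitrary
    units.
    """
    wl0 = sens.wavelengths

    def as_pair(x):
        if isinstance(x, tuple):
            return np.asarray(x[0], dtype=float), np.asarray(x[1], dtype=float)
        return wl0, np.asarray(x, dtype=float)

    rw, rv = as_pair(reflectance)
    iw, iv = as_pair(illuminant)
    if np.any(rv < 0) or np.any(iv < 0):
        raise ValueError("reflectance and illuminant must be non-negative")
    grid, (r, i, s) = _common_grid((rw, rv), (iw, iv), (wl0, sens.sensitivity))
    return float(np.trapezoid(r * i * s, grid))


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength_nm, value) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _load_packaged(name: str) -> tuple[np.ndarray, np.ndarray]:
    with resources.files("apostim.data").joinpath(name).open("rb") as fh:
        return read_spectrum_csv(fh)


def load_double_cone_sensitivity() -> SpectralSensitivity:
    """Packaged *synthetic* chicken double-cone sensitivity stand-in.

    A smooth unimodal curve peaking in the mid-long wavelengths with an
    oil-droplet-style short-wavelength cut-off, normalized to peak 1, on
    the 350-800 nm grid at 1 nm.  Shape-plausible only; replace with a
    measured curve for photometric work.
    """
    wl, s = _load_packaged("double_cone_sensitivity_synthetic.csv")
    return SpectralSensitivity(wl, s)


def load_arena_illuminant() -> tuple[np.ndarray, np.ndarray]:
    """Packaged *synthetic* arena illuminant stand-in (4700 K blackbody,
    normalized), 350-800 nm at 1 nm, emulating halogen daylight bulbs."""
    return _load_packaged("arena_illuminant_synthetic.csv")
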