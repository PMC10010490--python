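"""Spectral preprocessing: Savitzky-Golay, MSC and median filtering.

Raw reflectance spectra carry baseline drift, multiplicative scatter
from the irregular seed surface, and white noise. Three transforms are
compared:

* ``SG`` — Savitzky-Golay local least-squares polynomial smoothing;
* ``MSC`` — multiplicative scatter correction, regressing each spectrum
  on a reference and removing the fitted gain/offset;
* ``MF`` — a running median along the spectral axis.

The MSC reference defaults to the calibration-set mean spectrum and is
frozen there, so prediction-set spectra are corrected against the same
reference (no information leakage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _nd_median
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessSpec",
    "Preprocessor",
    "savitzky_golay",
    "msc",
    "median_filter",
    "METHODS",
]

METHODS = ("raw", "SG", "MSC", "MF")


@dataclass
class PreprocessSpec:
    """Which transform to apply and its window parameters."""

    method: str = "raw"
    sg_window: int = 11
    sg_polyorder: int = 3
    mf_window: int = 5
    msc_reference: np.ndarray | str = "mean-of-calibration"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        for name in ("sg_window", "mf_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")


def _as_2d(spectra: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim != 2:
        raise ValueError("spectra must be 1-D or 2-D")
    return arr, False


def savitzky_golay(spectra, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the spectral axis.

    Each band is replaced by the value of the least-squares polynomial
    of the given order fitted over the centered window; the first/last
    half-windows take the edge-window polynomial's values (so the
    filter remains exact on polynomials up to ``polyorder``).
    """
    arr, squeeze = _as_2d(spectra)
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > arr.shape[1]:
        raise ValueError("window exceeds band count")
    out = savgol_filter(arr, window_length=window, polyorder=polyorder,
                        axis=1, mode="interp")
    return out[0] if squeeze else out


def msc(spectra, reference=None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is fitted as x ~ a + b * reference by least squares
    and returned as (x - a) / b, which removes any per-spectrum affine
    scatter distortion of the reference shape. ``reference`` defaults to
    the mean of the given spectra.
    """
    arr, squeeze = _as_2d(spectra)
    ref = arr.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (arr.shape[1],):
        raise ValueError("reference length must equal band count")
    ref_c = ref - ref.mean()
    denom = np.dot(ref_c, ref_c)
    if denom == 0:
        raise ValueError("reference spectrum is constant")
    x_mean = arr.mean(axis=1)
    b = (arr - x_mean[:, None]) @ ref_c / denom
    if np.any(b == 0):
        raise ValueError("fitted slope is zero for some spectrum")
    a = x_mean - b * ref.mean()
    out = (arr - a[:, None]) / b[:, None]
    return out[0] if squeeze else out


def median_filter(spectra, window: int = 5) -> np.ndarray:
    """Running median along the spectral axis with reflected edges."""
    arr, squeeze = _as_2d(spectra)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    out = _nd_median(arr, size=(1, window), mode="reflect")
    return out[0] if squeeze else out


class Preprocessor:
    """Stateful wrapper applying a :class:`PreprocessSpec`.

    ``fit`` captures anything learned from the calibration set (for MSC,
    its mean spectrum); ``transform`` then applies the same frozen
    transform to calibration and prediction spectra alike.
    """

    def __init__(self, spec: PreprocessSpec | str = "raw"):
        if isinstance(spec, str):
            spec = PreprocessSpec(method=spec)
        self.spec = spec
        self.reference_: np.ndarray | None = None
        if isinstance(spec.msc_reference, np.ndarray):
            self.reference_ = np.asarray(spec.msc_reference, dtype=float)

    def fit(self, calibration_spectra: np.ndarray) -> "Preprocessor":
        if self.spec.method == "MSC" and self.reference_ is None:
            self.reference_ = np.asarray(calibration_spectra, float).mean(axis=0)
        return self

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.method == "raw":
            return np.asarray(spectra, dtype=float).copy()
        if s.method == "SG":
            return savitzky_golay(spectra, s.sg_window, s.sg_polyorder)
        if s.method == "MF":
            return median_filter(spectra, s.mf_window)
        if s.method == "MSC":
            if self.reference_ is None:
                raise RuntimeError("MSC preprocessor must be fit before transform")
            return msc(spectra, self.reference_)
        raise AssertionError(s.method)

    def fit_transform(self, spectra: np.ndarray) -> np.ndarray:
        return self.fit(spectra).transform(spectra)
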