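"""Vegetation indices, derivative spectra, SPAD correlation profiles and
single-index linear SPAD models.

Six indices are supported.  NDVI and RVI take their red/NIR anchors at
configurable wavelengths (defaults 670 and 800 nm); the narrow-band indices
reference fixed wavelengths resolved to the nearest grid band:

    NDVI  = (NIR - R) / (NIR + R)
    RVI   = NIR / R
    PhRI  = (R550 - R531) / (R550 + R531)
    MCARI = (R701 - R671) - 0.2 (R701 - R549) (R701 / R671)
    TCARI = 3 [ (R700 - R675) - 0.2 (R700 - R500) (R700 / R670) ]   (as-printed)
          = 3 [ (R700 - R670) - 0.2 (R700 - R550) (R700 / R670) ]   (canonical)

TCARI circulates in two forms; both are implemented and the as-printed
variant is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import SmootherConfig, savgol_smooth
from .synthetic import SampleSet, WavelengthGrid

__all__ = [
    "VI_NAMES",
    "UndefinedIndexError",
    "CorrelationProfile",
    "VIModel",
    "band_at",
    "compute_vi",
    "compute_vi_table",
    "first_derivative",
    "correlation_profile",
    "fit_vi_model",
]

VI_NAMES = ("NDVI", "RVI", "PhRI", "MCARI", "TCARI", "GI")


class UndefinedIndexError(ZeroDivisionError):
    """A vegetation-index denominator vanished."""


def band_at(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    wavelength_nm: float,
    tolerance_nm: float = 5.0,
) -> np.ndarray:
    """Reflectance at the grid band nearest ``wavelength_nm``.

    Works on single spectra or stacks (bands on the last axis).  Exact ties
    resolve toward the shorter wavelength; no band within tolerance raises.
    """
    idx = grid.nearest(wavelength_nm, tolerance_nm)
    return np.asarray(spectrum)[..., idx]


def _safe_div(num, den, context: str):
    den = np.asarray(den, dtype=float)
    if np.any(den == 0.0):
        raise UndefinedIndexError(f"zero denominator while computing {context}")
    return num / den


def compute_vi(
    spectrum: np.ndarray,
    name: str,
    grid: WavelengthGrid | None = None,
    red_nm: float = 670.0,
    nir_nm: float = 800.0,
    tcari_variant: str = "as-printed",
    tolerance_nm: float = 5.0,
) -> np.ndarray:
    """One vegetation index for a spectrum or a stack of spectra."""
    grid = grid or WavelengthGrid.default()
    b = lambda w: band_at(spectrum, grid, w, tolerance_nm)
    if name == "NDVI":
        nir, red = b(nir_nm), b(red_nm)
        return _safe_div(nir - red, nir + red, "NDVI")
    if name == "RVI":
        return _safe_div(b(nir_nm), b(red_nm), "RVI")
    if name == "PhRI":
        r550, r531 = b(550.0), b(531.0)
        return _safe_div(r550 - r531, r550 + r531, "PhRI")
    if name == "MCARI":
        r701, r671, r549 = b(701.0), b(671.0), b(549.0)
        return (r701 - r671) - 0.2 * (r701 - r549) * _safe_div(r701, r671, "MCARI")
    if name == "TCARI":
        if tcari_variant == "as-printed":
            r700, r675, r500, r670 = b(700.0), b(675.0), b(500.0), b(670.0)
            return 3.0 * ((r700 - r675)
                          - 0.2 * (r700 - r500) * _safe_div(r700, r670, "TCARI"))
        if tcari_variant == "canonical":
            r700, r670, r550 = b(700.0), b(670.0), b(550.0)
            return 3.0 * ((r700 - r670)
                          - 0.2 * (r700 - r550) * _safe_div(r700, r670, "TCARI"))
        raise ValueError(f"unknown TCARI variant {tcari_variant!r}")
    if name == "GI":
        return _safe_div(b(554.0), b(677.0), "GI")
    raise ValueError(f"unknown vegetation index {name!r}; expected one of {VI_NAMES}")


def compute_vi_table(samples: SampleSet, names=VI_NAMES, **kwargs):
    """DataFrame of vegetation indices, one column per index."""
    import pandas as pd

    return pd.DataFrame(
        {n: compute_vi(samples.reflectance, n, samples.grid, **kwargs) for n in names}
    )


def first_derivative(
    spectrum: np.ndarray,
    grid: WavelengthGrid | None = None,
    method: str = "savgol",
    window: int = 7,
    polyorder: int = 2,
) -> np.ndarray:
    """First-order derivative spectrum, reflectance per nm (band axis last).

    ``savgol`` differentiates through the Savitzky-Golay polynomial (the same
    filter used for smoothing); ``finite_difference`` uses central
    differences and serves as the independent cross-check.
    """
    grid = grid or WavelengthGrid.default()
    spec = np.asarray(spectrum, dtype=float)
    if spec.shape[-1] < 3 or spec.shape[-1] != grid.n_bands:
        raise ValueError("need >= 3 bands matching the wavelength grid")
    wl = grid.wavelengths_nm
    if method == "savgol":
        delta = float(np.mean(np.diff(wl)))
        cfg = SmootherConfig(window=window, polyorder=polyorder, derivative_order=1)
        return savgol_smooth(spec, cfg, delta_nm=delta)
    if method == "finite_difference":
        return np.gradient(spec, wl, axis=-1)
    raise ValueError(f"unknown derivative method {method!r}")


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-band Pearson correlation of reflectance (raw and first-derivative)
    with SPAD."""

    wavelengths_nm: np.ndarray
    r_raw: np.ndarray
    r_deriv: np.ndarray


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    out = np.full(X.shape[1], np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return np.clip(out, -1.0, 1.0)


def correlation_profile(samples: SampleSet, deriv_method: str = "savgol") -> CorrelationProfile:
    """Fig-6-style per-band correlation profile of spectra vs SPAD."""
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation profile")
    if np.ptp(samples.spad) == 0:
        raise ValueError("SPAD is constant; correlation undefined")
    r_raw = _pearson_columns(samples.reflectance, samples.spad)
    deriv = first_derivative(samples.reflectance, samples.grid, method=deriv_method)
    r_deriv = _pearson_columns(deriv, samples.spad)
    return CorrelationProfile(samples.grid.wavelengths_nm, r_raw, r_deriv)


@dataclass(frozen=True)
class VIModel:
    """Single-index linear SPAD model: spad ~ slope * VI + intercept."""

    vi: str
    slope: float
    intercept: float
    r2: float
    rmse: float

    def predict(self, vi_values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(vi_values, dtype=float) + self.intercept


def fit_vi_model(samples: SampleSet, name: str, **vi_kwargs) -> VIModel:
    """Ordinary least squares of SPAD on one vegetation index.

    R-squared is the squared Pearson correlation of fitted vs measured SPAD;
    RMSE is the root mean squared residual over the fitting samples.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit a VI model")
    vi = np.asarray(compute_vi(samples.reflectance, name, samples.grid, **vi_kwargs))
    if np.ptp(vi) == 0:
        raise ValueError(f"{name} is constant over the samples; OLS undefined")
    res = stats.linregress(vi, samples.spad)
    fitted = res.slope * vi + res.intercept
    rmse = float(np.sqrt(np.mean((samples.spad - fitted) ** 2)))
    return VIModel(
        vi=name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        rmse=rmse,
    )
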