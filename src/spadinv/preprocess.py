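"""Radiometric preprocessing: DN to reflectance, irradiance consistency,
dark/flat hooks, Savitzky-Golay smoothing, and minimal ENVI cube I/O.

The empirical-line step converts raw digital numbers to surface reflectance
with the two-point line anchored by calibration plates of known reflectance:

    rho_t = (DN_t - DN_1) / (DN_2 - DN_1) * (rho_2 - rho_1) + rho_1

A least-squares generalization over >= 2 plates is provided for noisy
plate readings.  Out-of-range reflectance (< 0 or > 1) is flagged in a QA
mask rather than clipped, so the affine algebra the pipeline relies on is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "CalibrationPlate",
    "IrradianceRecord",
    "SmootherConfig",
    "DegenerateCalibrationError",
    "EmpiricalLine",
    "ReflectanceResult",
    "dn_to_reflectance",
    "fit_multiplate_line",
    "irradiance_correction",
    "savgol_smooth",
    "dark_flat_hooks",
    "write_envi",
    "read_envi",
]


class DegenerateCalibrationError(ValueError):
    """Calibration plates do not determine a line (equal DN or reflectance)."""


@dataclass(frozen=True)
class CalibrationPlate:
    """Reference panel: nominal reflectance and its mean DN (per band)."""

    rho: float
    dn: float | np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"plate reflectance {self.rho} outside (0, 1)")
        if not np.all(np.isfinite(self.dn)):
            raise ValueError("plate DN must be finite")


@dataclass(frozen=True)
class IrradianceRecord:
    """Downwelling irradiance for one image and the reference image."""

    e_j: float
    e_ref: float

    def __post_init__(self) -> None:
        if self.e_j <= 0 or self.e_ref <= 0:
            raise ValueError("irradiance values must be positive")

    @property
    def c_j(self) -> float:
        """Multiplicative correction factor for image j."""
        return self.e_j / self.e_ref


@dataclass(frozen=True)
class SmootherConfig:
    window: int = 7
    polyorder: int = 2
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("need 0 <= polyorder < window")
        if self.derivative_order not in (0, 1):
            raise ValueError("derivative_order must be 0 or 1")


class ReflectanceResult(NamedTuple):
    reflectance: np.ndarray
    out_of_range: np.ndarray  # True where reflectance < 0 or > 1


def dn_to_reflectance(
    dn_target: float | np.ndarray,
    plate_lo: CalibrationPlate,
    plate_hi: CalibrationPlate,
) -> ReflectanceResult:
    """Two-point empirical-line DN -> reflectance, applied element-wise.

    Plate DNs map exactly to their nominal reflectances.  Per-band plate
    DNs broadcast along the last axis of ``dn_target`` (cube convention:
    bands last).  Values outside [0, 1] are flagged, not clipped.
    """
    dn1 = np.asarray(plate_lo.dn, dtype=float)
    dn2 = np.asarray(plate_hi.dn, dtype=float)
    denom = dn2 - dn1
    bad = ~(np.abs(denom) > 0)
    if np.any(bad):
        which = np.flatnonzero(np.atleast_1d(bad))
        raise DegenerateCalibrationError(
            f"plates have equal DN in band(s) {which.tolist()}; empirical line undefined"
        )
    dn_t = np.asarray(dn_target, dtype=float)
    rho = (dn_t - dn1) / denom * (plate_hi.rho - plate_lo.rho) + plate_lo.rho
    return ReflectanceResult(rho, (rho < 0.0) | (rho > 1.0))


@dataclass(frozen=True)
class EmpiricalLine:
    """Per-band affine DN -> reflectance map with fit residuals."""

    slope: np.ndarray
    intercept: np.ndarray
    residual: np.ndarray  # per-band RMS residual of the plate fit

    def apply(self, dn_target: np.ndarray) -> ReflectanceResult:
        rho = np.asarray(dn_target, dtype=float) * self.slope + self.intercept
        return ReflectanceResult(rho, (rho < 0.0) | (rho > 1.0))


def fit_multiplate_line(plates: list[CalibrationPlate]) -> EmpiricalLine:
    """Least-squares empirical line over >= 2 calibration plates.

    With exactly two plates this reproduces the two-point line.  Plate DNs
    may be scalars or per-band vectors (all the same length).
    """
    if len(plates) < 2:
        raise ValueError("need at least two calibration plates")
    rhos = np.array([p.rho for p in plates])
    if np.unique(rhos).size < 2:
        raise DegenerateCalibrationError("all plates have identical reflectance")
    dns = np.stack([np.atleast_1d(np.asarray(p.dn, float)) for p in plates])  # (p, bands)
    if np.all(dns == dns[0]):
        raise DegenerateCalibrationError("all plates have identical DN")
    n_bands = dns.shape[1]
    slope = np.empty(n_bands)
    intercept = np.empty(n_bands)
    residual = np.empty(n_bands)
    for b in range(n_bands):
        A = np.column_stack([dns[:, b], np.ones(len(plates))])
        coef, *_ = np.linalg.lstsq(A, rhos, rcond=None)
        slope[b], intercept[b] = coef
        residual[b] = float(np.sqrt(np.mean((A @ coef - rhos) ** 2)))
    if n_bands == 1:
        slope, intercept, residual = slope[0], intercept[0], residual[0]
    return EmpiricalLine(slope=slope, intercept=intercept, residual=residual)


def irradiance_correction(image_j: np.ndarray, rec: IrradianceRecord) -> np.ndarray:
    """Scale image j by C_j = E_j / E_ref to a common irradiance level."""
    return np.asarray(image_j, dtype=float) * rec.c_j


def savgol_smooth(spectrum: np.ndarray, cfg: SmootherConfig | None = None,
                  delta_nm: float = 1.0) -> np.ndarray:
    """Savitzky-Golay polish along the band axis (last axis).

    ``delta_nm`` is the band spacing, relevant only when
    ``cfg.derivative_order == 1`` (output then in reflectance per nm).
    """
    cfg = cfg or SmootherConfig()
    spec = np.asarray(spectrum, dtype=float)
    if cfg.window > spec.shape[-1]:
        raise ValueError(
            f"window {cfg.window} exceeds the number of bands {spec.shape[-1]}"
        )
    return savgol_filter(
        spec, cfg.window, cfg.polyorder, deriv=cfg.derivative_order,
        delta=delta_nm, axis=-1,
    )


def dark_flat_hooks(
    cube: np.ndarray,
    dark_frame: np.ndarray | None = None,
    flat_frame: np.ndarray | None = None,
) -> np.ndarray:
    """Generic dark-current / flat-field hook: (cube - dark) / flat.

    The instrument vendor's calibration is proprietary; this hook applies
    user-supplied frames and is the identity when none are given.
    """
    out = np.asarray(cube, dtype=float)
    if dark_frame is not None:
        dark = np.asarray(dark_frame, dtype=float)
        if dark.shape != out.shape:
            raise ValueError(f"dark frame shape {dark.shape} != cube shape {out.shape}")
        out = out - dark
    if flat_frame is not None:
        flat = np.asarray(flat_frame, dtype=float)
        if flat.shape != out.shape:
            raise ValueError(f"flat frame shape {flat.shape} != cube shape {out.shape}")
        out = out / flat
    return out


# ---------------------------------------------------------------------------
# minimal ENVI (header + band-sequential binary) I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(path, cube: np.ndarray, wavelengths_nm: np.ndarray,
               dtype=np.float32) -> Path:
    """Write (rows, cols, bands) cube as ENVI .hdr + BSQ binary; returns the
    header path (data sits next to it without extension)."""
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be 3-D (rows, cols, bands)")
    rows, cols, bands = cube.shape
    if len(wavelengths_nm) != bands:
        raise ValueError("wavelength list length must equal the band count")
    data = np.ascontiguousarray(np.moveaxis(cube, 2, 0).astype(dtype))  # BSQ
    data.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in wavelengths_nm)
    hdr = (
        "ENVI\n"
        "description = {spadinv synthetic cube}\n"
        f"samples = {cols}\nlines = {rows}\nbands = {bands}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def read_envi(hdr_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI header + BSQ/BIL/BIP binary; returns (cube, wavelengths)
    with cube shaped (rows, cols, bands) as float64."""
    hdr_path = Path(hdr_path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    key, buf = None, []
    for line in text.splitlines():
        if "=" in line and not buf:
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if val.startswith("{") and not val.endswith("}"):
                buf = [val]
            else:
                fields[key] = val
        elif buf:
            buf.append(line.strip())
            if line.strip().endswith("}"):
                fields[key] = " ".join(buf)
                buf = []
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    wl_txt = fields.get("wavelength", "{}").strip("{} ")
    wavelengths = np.array([float(w) for w in wl_txt.split(",") if w.strip()])

    raw = np.fromfile(hdr_path.with_suffix(""), dtype=dtype, offset=offset)
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols)
        cube = np.moveaxis(cube, 0, 2)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols)
        cube = np.moveaxis(cube, 1, 2)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return cube.astype(np.float64), wavelengths
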