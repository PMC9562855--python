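"""Fit statistics, model comparison tables, SPAD-threshold severity
classification and per-pixel severity maps.

Accuracy is summarized by the coefficient of determination, computed as the
squared Pearson correlation between measured and predicted values, and the
root mean square error

    RMSE = sqrt( sum_i (y_i - yhat_i)^2 / n ).

Severity classes follow a descending-SPAD convention: three strictly
decreasing cut points partition predicted SPAD into grades I (healthy,
high SPAD) through IV (severe, low SPAD), with boundary values assigned to
the lower-severity class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import WavelengthGrid

__all__ = [
    "FitStats",
    "SeverityThresholds",
    "SeverityMap",
    "fit_stats",
    "cv_percent",
    "compare_models",
    "classify_severity",
    "severity_map",
]


@dataclass(frozen=True)
class FitStats:
    r2: float
    rmse: float
    n: int


def fit_stats(measured: np.ndarray, predicted: np.ndarray) -> FitStats:
    """R-squared (squared Pearson r of measured vs predicted) and RMSE."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("measured and predicted must share a length >= 2")
    if np.ptp(y) == 0:
        raise ValueError("measured values are constant; R2 undefined")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if np.ptp(yhat) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return FitStats(r2=min(max(r2, 0.0), 1.0), rmse=rmse, n=y.size)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * sd / mean, in percent."""
    if mean <= 0:
        raise ValueError("mean must be positive for a coefficient of variation")
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return 100.0 * sd / mean


def compare_models(
    models: dict,
    X_mod: np.ndarray,
    y_mod: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    ids_mod: np.ndarray | None = None,
    ids_val: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-model fit statistics on the modeling and validation sets.

    ``models`` maps a display name to anything with a ``predict`` method (or
    a bare callable).  When sample ids are given for both sets, an overlap
    raises, guarding against train/validation leakage.
    """
    if ids_mod is not None and ids_val is not None:
        overlap = set(np.asarray(ids_mod).tolist()) & set(np.asarray(ids_val).tolist())
        if overlap:
            raise ValueError(f"modeling/validation sets overlap on ids {sorted(overlap)[:5]}")
    rows = []
    for name, model in models.items():
        predict = model.predict if hasattr(model, "predict") else model
        sm = fit_stats(y_mod, predict(X_mod))
        sv = fit_stats(y_val, predict(X_val))
        rows.append({
            "model": name,
            "r2_modeling": sm.r2, "rmse_modeling": sm.rmse,
            "r2_validation": sv.r2, "rmse_validation": sv.rmse,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SeverityThresholds:
    """Three strictly decreasing SPAD cut points separating grades I-IV."""

    cuts: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.cuts) != 3 or not (self.cuts[0] > self.cuts[1] > self.cuts[2]):
            raise ValueError("need exactly 3 strictly decreasing SPAD cut points")

    @classmethod
    def from_class_means(cls, means) -> "SeverityThresholds":
        """Midpoints between adjacent class-mean SPAD values."""
        m = np.asarray(means, dtype=float)
        if m.size != 4 or not np.all(np.diff(m) < 0):
            raise ValueError("need 4 strictly decreasing class means")
        return cls(tuple((m[:-1] + m[1:]) / 2.0))


DEFAULT_THRESHOLDS = SeverityThresholds.from_class_means((57.0, 51.0, 43.0, 34.0))


def classify_severity(
    spad: float | np.ndarray,
    thresholds: SeverityThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Map SPAD to severity grade 1..4 (I..IV).

    Intervals are closed on the high-SPAD side: spad >= cuts[0] is grade I,
    cuts[1] <= spad < cuts[0] grade II, and so on; lower SPAD never maps to
    a lower severity.
    """
    spad = np.asarray(spad, dtype=float)
    cuts = np.asarray(thresholds.cuts)
    grade = 1 + (spad < cuts[0]).astype(int) + (spad < cuts[1]) + (spad < cuts[2])
    return grade if grade.ndim else int(grade)


@dataclass
class SeverityMap:
    classes: np.ndarray           # (rows, cols) ints 1..4, 0 where masked
    qa_mask: np.ndarray           # True where the pixel is masked out
    legend: dict[int, str]
    spad: np.ndarray | None = None  # per-pixel predicted SPAD


_LEGEND = {1: "I (healthy)", 2: "II (mild)", 3: "III (moderate)", 4: "IV (severe)"}


def severity_map(
    cube: np.ndarray,
    model,
    wavelengths_nm,
    grid: WavelengthGrid,
    thresholds: SeverityThresholds = DEFAULT_THRESHOLDS,
    qa_mask: np.ndarray | None = None,
    tolerance_nm: float = 5.0,
) -> SeverityMap:
    """Per-pixel SPAD prediction and severity grade over a reflectance cube.

    ``wavelengths_nm`` are the model's input bands (e.g. the SPA selection);
    each must resolve on the cube's grid or the call fails listing the
    misses.  Pixels flagged in ``qa_mask`` stay masked (class 0).
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3 or cube.shape[2] != grid.n_bands:
        raise ValueError("cube must be (rows, cols, bands) on the given grid")
    missing, idx = [], []
    for w in wavelengths_nm:
        try:
            idx.append(grid.nearest(w, tolerance_nm))
        except ValueError:
            missing.append(float(w))
    if missing:
        raise ValueError(f"cube does not cover required wavelengths {missing}")

    rows, cols, _ = cube.shape
    X = cube[:, :, idx].reshape(-1, len(idx))
    spad = np.asarray(model.predict(X), dtype=float).reshape(rows, cols)
    classes = classify_severity(spad, thresholds).astype(int)
    if qa_mask is None:
        qa_mask = np.zeros((rows, cols), dtype=bool)
    else:
        qa_mask = np.asarray(qa_mask, dtype=bool)
        if qa_mask.shape != (rows, cols):
            raise ValueError("qa_mask shape must match the cube's spatial shape")
    classes = np.where(qa_mask, 0, classes)
    return SeverityMap(classes=classes, qa_mask=qa_mask, legend=dict(_LEGEND), spad=spad)
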