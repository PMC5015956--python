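"""Gray-scale and cell-count calibration.

Transmissive scans of the same plate on different scanners (or the same
scanner at different times) report different raw intensities for the same
physical opacity.  A gray-scale strip of segments with manufacturer-stated
opacities, imaged alongside every plate, anchors a polynomial map from raw
pixel intensity to a standardized *pixel opacity*.  A second polynomial,
fitted once against flow-cytometry / OD reference counts, converts
background-subtracted pixel opacity into cells per pixel.

Strip localization on images is out of scope here: per-segment mean
intensities are supplied as a two-column table (``intensity,opacity``),
and cell-count pairs as ``opacity,cells``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when a calibration cannot be fitted from the supplied pairs."""


@dataclass
class OpacityImage:
    """Calibrated 2-D pixel-opacity array with its acquisition time.

    ``n_clamped`` counts raw pixels outside the calibration's valid range
    that were clamped before evaluation (specular artifacts etc.).
    """

    values: np.ndarray
    timestamp_hr: float
    n_clamped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class OpacityCalibration:
    """Polynomial map raw intensity -> standardized pixel opacity.

    Coefficients are in ascending power order.  The map is strictly
    monotone over ``valid_range`` so pixel intensity ordering is preserved.
    """

    coefficients: np.ndarray
    valid_range: tuple[float, float]
    degree: int
    residual_rmse: float = 0.0

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    @classmethod
    def identity(cls, valid_range: tuple[float, float] = (0.0, 255.0)):
        return cls(np.array([0.0, 1.0]), valid_range, degree=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "opacity",
                "degree": self.degree,
                "coefficients": list(self.coefficients),
                "range": list(self.valid_range),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OpacityCalibration":
        d = json.loads(text)
        return cls(
            np.asarray(d["coefficients"], dtype=float),
            tuple(d["range"]),
            int(d["degree"]),
        )


@dataclass
class CellCountCalibration:
    """Polynomial map background-subtracted opacity -> cells per pixel.

    With ``constrained_zero`` (the default) the polynomial has no constant
    term, so zero opacity maps to zero cells.  Predictions are clipped at
    zero on evaluation.
    """

    coefficients: np.ndarray  # ascending powers; coefficients[0] is the intercept
    constrained_zero: bool = True
    degree: int = 5
    residual_rmse: float = 0.0

    def __call__(self, x: np.ndarray | float):
        y = np.polynomial.polynomial.polyval(x, self.coefficients)
        return np.clip(y, 0.0, None)

    @classmethod
    def identity(cls):
        return cls(np.array([0.0, 1.0]), constrained_zero=True, degree=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "cells",
                "degree": self.degree,
                "coefficients": list(self.coefficients),
                "constrained_zero": self.constrained_zero,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CellCountCalibration":
        d = json.loads(text)
        return cls(
            np.asarray(d["coefficients"], dtype=float),
            bool(d["constrained_zero"]),
            int(d["degree"]),
        )


def fit_opacity_calibration(
    segment_intensities,
    target_opacities,
    degree: int = 3,
) -> OpacityCalibration:
    """Fit the raw-intensity -> opacity polynomial from strip segments.

    Parameters
    ----------
    segment_intensities, target_opacities
        Mean raw intensity of each strip segment and the manufacturer's
        stated opacity for it.  Equal length, at least ``degree + 2`` pairs.
    degree
        Polynomial degree (default 3).

    Raises
    ------
    CalibrationError
        Too few segments, duplicated intensities, or a fit that is not
        strictly monotone over the data range.
    """
    x = np.asarray(segment_intensities, dtype=float)
    y = np.asarray(target_opacities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("intensity and opacity lists must have equal length")
    if x.size < degree + 2:
        raise CalibrationError(
            f"need at least {degree + 2} segment pairs for degree {degree}, "
            f"got {x.size}"
        )
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise CalibrationError("segment intensities must be distinct")

    series = np.polynomial.Polynomial.fit(x, y, degree)
    coeffs = series.convert().coef
    rmse = float(np.sqrt(np.mean((np.polynomial.polynomial.polyval(x, coeffs) - y) ** 2)))

    # monotonicity over the data range: derivative keeps one sign
    grid = np.linspace(x[0], x[-1], 512)
    deriv = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coeffs)
    )
    if not (np.all(deriv > 0) or np.all(deriv < 0)):
        raise CalibrationError(
            "fitted opacity polynomial is not strictly monotone over "
            f"[{x[0]:.3g}, {x[-1]:.3g}]; check segment pairs or lower the degree"
        )
    return OpacityCalibration(
        coefficients=coeffs,
        valid_range=(float(x[0]), float(x[-1])),
        degree=degree,
        residual_rmse=rmse,
    )


def apply_opacity_calibration(
    cal: OpacityCalibration, image: np.ndarray, timestamp_hr: float = 0.0
) -> OpacityImage:
    """Elementwise polynomial evaluation of *cal* on a raw grayscale array.

    Raw values outside the calibration's valid range are clamped to it;
    the number of clamped pixels is tallied on the result and logged.
    """
    arr = np.asarray(image, dtype=float)
    lo, hi = cal.valid_range
    n_clamped = int(np.count_nonzero((arr < lo) | (arr > hi)))
    if n_clamped:
        log.warning("opacity calibration: clamped %d out-of-range pixels", n_clamped)
        arr = np.clip(arr, lo, hi)
    return OpacityImage(values=cal(arr), timestamp_hr=timestamp_hr, n_clamped=n_clamped)


def fit_cell_calibration(
    opacity_values,
    cell_counts,
    degree: int = 5,
    constrained_zero: bool = True,
) -> CellCountCalibration:
    """Fit the background-subtracted-opacity -> cells-per-pixel polynomial.

    With ``constrained_zero`` the design matrix omits the constant term so
    the fit passes through the origin (no colony, no cells).
    """
    x = np.asarray(opacity_values, dtype=float)
    y = np.asarray(cell_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("opacity and cell-count lists must have equal length")
    if x.size < degree + 2:
        raise CalibrationError(
            f"need at least {degree + 2} pairs for degree {degree}, got {x.size}"
        )
    if np.any(y < 0):
        raise CalibrationError("cell counts must be non-negative")
    if np.all(x == 0):
        raise CalibrationError("all opacity values are zero")

    powers = np.arange(1 if constrained_zero else 0, degree + 1)
    design = x[:, None] ** powers[None, :]
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    coeffs = np.zeros(degree + 1)
    coeffs[powers] = sol
    rmse = float(
        np.sqrt(np.mean((np.polynomial.polynomial.polyval(x, coeffs) - y) ** 2))
    )
    return CellCountCalibration(
        coefficients=coeffs,
        constrained_zero=constrained_zero,
        degree=degree,
        residual_rmse=rmse,
    )


def cells_from_opacity(cal: CellCountCalibration, bg_subtracted) -> np.ndarray:
    """Cells per pixel from background-subtracted opacity, clipped at 0."""
    arr = np.asarray(bg_subtracted, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("background-subtracted opacities must be finite")
    return cal(arr)


def load_calibration_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column calibration CSV, returning (x, y) arrays."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CalibrationError(f"{path}: expected a two-column calibration table")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
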