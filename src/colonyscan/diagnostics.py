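"""Residual-bias and precision diagnostics.

The adjacency false-positive test quantifies spatial bias on a plate of
(nominally) identical colonies: for each focal experimental colony, the
doubling times of its immediately adjacent experimental colonies are
compared to the mean of all nonadjacent experimental colonies with a
one-sample Student's t-test (H0: zero difference).  If all variation is
random the rejection fraction equals the significance level (5% at
alpha = 0.05); any systematic excess is spatial bias, because neighbors
share whatever local bias affects the focal position.  Control positions
(every fourth) are excluded from the focal, adjacent, and nonadjacent
sets throughout.  Tests are deliberately uncorrected for multiplicity —
the chance-expectation logic requires raw per-colony tests.

Precision summaries: the plate CV (percent coefficient of variation over
all values) and the neighbor CV distribution (CV within each focal
colony's Moore neighborhood; under iid noise its median matches the plate
CV, while smooth bias pushes it below).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .layout import PlateLayout, control_mask

#: 3x3 Moore kernel with the focal cell excluded
_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass
class BiasReport:
    """Adjacency false-positive rate and CV summaries for one plate."""

    fp_rate: float
    alpha: float
    n_tested: int
    n_skipped: int
    cv_plate: float | None = None
    neighbor_cv_median: float | None = None
    neighbor_cv_iqr: tuple[float, float] | None = None
    neighbor_cv_range: tuple[float, float] | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2)


def _neighbor_sums(values: np.ndarray, mask: np.ndarray):
    """Per-cell Moore-neighbor count, sum, and sum of squares over mask."""
    v = np.where(mask, values, 0.0)
    k = ndimage.convolve(mask.astype(float), _KERNEL, mode="constant", cval=0.0)
    s1 = ndimage.convolve(v, _KERNEL, mode="constant", cval=0.0)
    s2 = ndimage.convolve(v * v, _KERNEL, mode="constant", cval=0.0)
    return k, s1, s2


def adjacency_fp_rate(
    layout: PlateLayout, values: np.ndarray, alpha: float = 0.05
) -> BiasReport:
    """Fraction of focal colonies whose neighbors differ from the plate.

    ``values`` is a rows x cols array (NaN for missing positions).  For
    each focal experimental colony with at least two valid experimental
    neighbors, the neighbor values are t-tested against the mean of all
    nonadjacent experimental values (nonadjacent = experimental minus the
    focal colony and its neighbors).  Zero-variance neighborhoods are
    skipped and counted.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (layout.rows, layout.cols):
        raise ValueError("values must be a rows x cols array")
    exp = ~control_mask(layout) & np.isfinite(values)
    n_exp = int(exp.sum())
    if n_exp < 100:
        raise ValueError(f"need >= 100 finite experimental positions, got {n_exp}")

    k, s1, s2 = _neighbor_sums(values, exp)
    total_sum = float(np.sum(values[exp]))

    focal = exp & (k >= 2)
    kk = k[focal]
    m = s1[focal] / kk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2[focal] - kk * m**2) / (kk - 1)
    var = np.maximum(var, 0.0)

    n_nonadj = n_exp - kk - 1
    mu0 = (total_sum - s1[focal] - values[focal]) / n_nonadj

    sd = np.sqrt(var)
    testable = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m - mu0) / (sd / np.sqrt(kk))
    p = 2.0 * stats.t.sf(np.abs(t[testable]), df=kk[testable] - 1)
    n_tested = int(testable.sum())
    n_skipped = int(focal.sum()) - n_tested + int((exp & (k < 2)).sum())
    fp = float(np.mean(p < alpha)) if n_tested else 0.0
    return BiasReport(fp_rate=fp, alpha=alpha, n_tested=n_tested, n_skipped=n_skipped)


def plate_cv(values: np.ndarray) -> float:
    """Percent coefficient of variation, sample sd (n-1 denominator)."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need >= 2 finite values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def neighbor_cv(layout: PlateLayout, values: np.ndarray) -> np.ndarray:
    """Per-focal CV over each experimental colony's Moore neighbors.

    Neighborhoods with fewer than two valid experimental values are
    skipped.  Returns the array of percent CVs (one per usable focal).
    """
    values = np.asarray(values, dtype=float)
    exp = ~control_mask(layout) & np.isfinite(values)
    k, s1, s2 = _neighbor_sums(values, exp)
    focal = exp & (k >= 2)
    kk = k[focal]
    m = s1[focal] / kk
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.maximum((s2[focal] - kk * m**2) / (kk - 1), 0.0)
        cv = 100.0 * np.sqrt(var) / m
    return cv[np.isfinite(cv)]


def bias_report(
    layout: PlateLayout, values: np.ndarray, alpha: float = 0.05
) -> BiasReport:
    """Full per-plate report: fp rate, plate CV, neighbor-CV summary."""
    rep = adjacency_fp_rate(layout, values, alpha=alpha)
    rep.cv_plate = plate_cv(values)
    ncv = neighbor_cv(layout, values)
    if ncv.size:
        rep.neighbor_cv_median = float(np.median(ncv))
        rep.neighbor_cv_iqr = (
            float(np.percentile(ncv, 25)),
            float(np.percentile(ncv, 75)),
        )
        rep.neighbor_cv_range = (float(ncv.min()), float(ncv.max()))
    return rep
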