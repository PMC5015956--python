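"""Reference-grid spatial normalization and downstream normalizations.

Pinned plates carry systematic position-dependent growth bias (edge
effects, agar-thickness gradients, pinning variation) that survives even
careful experimental standardization.  With an isogenic control strain at
every fourth position (the lower-right position of every tetrad), the
control doubling times form an evenly spaced reference grid from which a
per-position *normalization surface* — the doubling time expected at each
position absent any genotype effect — is interpolated.  The relative
phenotype of an experimental colony is then

    rel = log2(surface_dt / observed_dt)

so a colony growing slower than its local expectation (longer doubling
time) scores negative: a growth defect.

All interpolation happens in log2(doubling time) space, where the
multiplicative spatial bias acting on growth rates becomes additive.
Surface fitting is a Gaussian-kernel local-polynomial (default local
quadratic) regression over the retained controls.  The polynomial terms
remove the boundary bias a plain kernel mean would suffer at the plate
edges (including the two control-free edges, row 0 and col 0, which
receive extrapolated values), and a local quadratic admits a generous
bandwidth: with only a quarter of positions carrying controls, the
surface's own estimation noise — which neighboring colonies share and
which therefore inflates the adjacency false-positive diagnostic — is
the binding error term, and it shrinks with the effective number of
controls under the kernel.  The default bandwidth of three tetrad
spacings balances that variance against lack-of-fit to softly
undulating, plate-scale bias fields.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth_features import GrowthFeatures
from .layout import PlateLayout, Position, control_mask

log = logging.getLogger(__name__)

#: kernel bandwidth in array-index units; the control lattice spacing is 2
DEFAULT_BANDWIDTH = 6.0

#: local polynomial order of the surface smoother (2 = local quadratic)
DEFAULT_SURFACE_ORDER = 2


class NormalizationError(RuntimeError):
    """The control grid cannot support a trustworthy surface."""


@dataclass
class NormalizationSurface:
    """Per-position expected doubling time interpolated from controls."""

    expected_dt: np.ndarray  # rows x cols, hours; finite everywhere
    source_controls: list  # Position
    excluded_controls: list  # Position


@dataclass
class PhenotypeTable:
    """Per-position phenotypes of one plate in one condition.

    ``frame`` columns: plate, row, col, strain, dt_min_hr,
    rel_phenotype_log2, flags.
    """

    frame: pd.DataFrame
    plate_id: str = "plate-0"
    condition_id: str = "basal"


# ---------------------------------------------------------------------------
# control outlier removal


def filter_control_outliers(
    controls: list[tuple[Position, float]],
) -> tuple[list[tuple[Position, float]], list[Position]]:
    """Remove controls with extreme doubling times before surface fitting.

    A control is extreme when its log2 doubling time lies outside
    median +/- 3 x scaled MAD of all finite controls.  Returns the
    retained (position, dt) pairs and the removed positions; aborts when
    more than half the controls would be removed (the grid is then
    untrustworthy).
    """
    finite = [(p, v) for p, v in controls if v is not None and math.isfinite(v) and v > 0]
    if len(finite) < 8:
        raise NormalizationError(
            f"need >= 8 finite control doubling times, got {len(finite)}"
        )
    vals = np.log2([v for _, v in finite])
    med = np.median(vals)
    mad = stats.median_abs_deviation(vals, scale="normal")
    keep = np.abs(vals - med) <= 3.0 * mad
    removed = [finite[i][0] for i in np.nonzero(~keep)[0]]
    n_bad = len(controls) - int(keep.sum())
    if n_bad > 0.5 * len(controls):
        raise NormalizationError(
            f"{n_bad}/{len(controls)} controls removed as outliers or "
            "non-finite; surface untrustworthy"
        )
    retained = [finite[i] for i in np.nonzero(keep)[0]]
    log.info(
        "control outlier filter: removed %d of %d controls", len(removed), len(controls)
    )
    return retained, removed


# ---------------------------------------------------------------------------
# surface construction


def _poly_design(dr: np.ndarray, dc: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(dr), dr, dc]
    if order >= 2:
        cols += [dr * dr, dr * dc, dc * dc]
    return np.stack(cols, axis=1)


def build_surface(
    layout: PlateLayout,
    retained: list[tuple[Position, float]],
    bandwidth: float = DEFAULT_BANDWIDTH,
    order: int = DEFAULT_SURFACE_ORDER,
) -> NormalizationSurface:
    """Interpolate the control grid into a full-plate expectation surface.

    Gaussian-kernel local-polynomial regression of log2(dt) on (row, col)
    over the retained controls, evaluated at every plate position and
    exponentiated back to hours.  The local polynomial extrapolates the
    local trend beyond the control hull, covering the control-free row 0
    and col 0 edges; evaluation points where the weighted design is
    ill-conditioned fall back to the kernel-weighted mean.
    """
    if len(retained) < 8:
        raise NormalizationError(f"need >= 8 retained controls, got {len(retained)}")
    if order not in (1, 2):
        raise ValueError("surface order must be 1 (local linear) or 2 (local quadratic)")
    cr = np.array([p.row for p, _ in retained], dtype=float)
    cc = np.array([p.col for p, _ in retained], dtype=float)
    cz = np.log2([v for _, v in retained])
    if np.unique(cr).size < 4 or np.unique(cc).size < 4:
        raise NormalizationError(
            "degenerate control geometry: controls span fewer than 4 "
            "tetrad rows or columns"
        )

    rows, cols = layout.rows, layout.cols
    rr, qq = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts_r = rr.ravel().astype(float)
    pts_c = qq.ravel().astype(float)

    zhat = np.empty(pts_r.size)
    for i in range(pts_r.size):
        dr = cr - pts_r[i]
        dc = cc - pts_c[i]
        w = np.exp(-(dr**2 + dc**2) / (2.0 * bandwidth**2))
        X = _poly_design(dr, dc, order)
        Xw = X * w[:, None]
        A = Xw.T @ X
        b = Xw.T @ cz
        try:
            cond_ok = np.linalg.cond(A) < 1e8
        except np.linalg.LinAlgError:
            cond_ok = False
        if cond_ok:
            zhat[i] = np.linalg.solve(A, b)[0]
        else:
            zhat[i] = float(np.average(cz, weights=np.maximum(w, 1e-300)))
    surface = (2.0 ** zhat).reshape(rows, cols)
    if not np.all(np.isfinite(surface)):
        raise NormalizationError("surface evaluation produced non-finite values")
    return NormalizationSurface(
        expected_dt=surface,
        source_controls=[p for p, _ in retained],
        excluded_controls=[],
    )


def surface_from_features(
    layout: PlateLayout,
    features: list[GrowthFeatures],
    bandwidth: float = DEFAULT_BANDWIDTH,
    order: int = DEFAULT_SURFACE_ORDER,
) -> NormalizationSurface:
    """Outlier-filter the control features and build the surface."""
    controls = [
        (f.position, f.dt_min)
        for f in features
        if f.position is not None and layout.is_control(f.position.row, f.position.col)
    ]
    retained, removed = filter_control_outliers(controls)
    surf = build_surface(layout, retained, bandwidth=bandwidth, order=order)
    surf.excluded_controls = removed
    return surf


# ---------------------------------------------------------------------------
# plate, between-plate, and condition normalization


def normalize_plate(
    features: list[GrowthFeatures],
    surface: NormalizationSurface,
    strain_map: pd.DataFrame | None = None,
    plate_id: str = "plate-0",
    condition_id: str = "basal",
) -> PhenotypeTable:
    """Relative phenotype per colony: log2(surface_dt / observed_dt).

    Slower-than-expected growth (observed doubling time above the local
    surface) scores negative, i.e. a growth defect.  Colonies with
    non-positive or missing doubling times get NaN phenotypes and a flag.
    """
    strain_lookup = {}
    if strain_map is not None:
        strain_lookup = {
            (int(r.row), int(r.col)): str(r.strain) for r in strain_map.itertuples()
        }
    rows = []
    for f in features:
        p = f.position
        exp_dt = float(surface.expected_dt[p.row, p.col])
        flags = set(f.flags)
        if f.dt_min is None or not math.isfinite(f.dt_min) or f.dt_min <= 0:
            rel = math.nan
            flags.add("nonpositive-dt")
        else:
            rel = math.log2(exp_dt / f.dt_min)
        rows.append(
            {
                "plate": plate_id,
                "row": p.row,
                "col": p.col,
                "strain": strain_lookup.get((p.row, p.col), ""),
                "dt_min_hr": f.dt_min,
                "rel_phenotype_log2": rel,
                "flags": ";".join(sorted(flags)),
            }
        )
    return PhenotypeTable(
        frame=pd.DataFrame(rows), plate_id=plate_id, condition_id=condition_id
    )


def normalize_between_plates(
    layout: PlateLayout, plates: list[PhenotypeTable]
) -> tuple[list[PhenotypeTable], dict[str, float]]:
    """Align plates of one condition on their raw control means.

    Each plate's doubling times are shifted (additively in log2, i.e.
    multiplicatively in hours) so that its mean control log2 doubling time
    — before any spatial normalization — equals the pooled control mean
    over all plates.  Shifts are logged; they are expected to be small.
    Plates without finite controls are excluded with a warning.
    """
    cmask = control_mask(layout)
    plate_means, usable = {}, []
    all_vals = []
    for t in plates:
        fr = t.frame
        is_ctl = cmask[fr["row"].to_numpy(int), fr["col"].to_numpy(int)]
        vals = fr.loc[is_ctl, "dt_min_hr"].to_numpy(float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size == 0:
            log.warning("plate %s has no finite controls; excluded", t.plate_id)
            continue
        plate_means[t.plate_id] = np.mean(np.log2(vals))
        all_vals.append(np.log2(vals))
        usable.append(t)
    if len(usable) < 2:
        raise NormalizationError("need >= 2 plates with controls to align")
    grand = float(np.mean(np.concatenate(all_vals)))
    shifts = {}
    adjusted = []
    for t in usable:
        shift = grand - plate_means[t.plate_id]
        shifts[t.plate_id] = shift
        fr = t.frame.copy()
        fr["dt_min_hr"] = fr["dt_min_hr"] * 2.0**shift
        adjusted.append(
            PhenotypeTable(frame=fr, plate_id=t.plate_id, condition_id=t.condition_id)
        )
        log.info("between-plate shift for %s: %+.4f log2", t.plate_id, shift)
    return adjusted, shifts


def condition_difference(
    stress: PhenotypeTable, basal: PhenotypeTable
) -> pd.DataFrame:
    """Condition-specific effect: stress phenotype minus basal phenotype.

    Positions are matched on (row, col); rows whose strain identities
    disagree between the two tables are dropped (the count is logged).
    The subtraction removes general growth defects shared between the two
    environments, leaving the gene-by-condition effect.
    """
    s = stress.frame[["row", "col", "strain", "rel_phenotype_log2"]]
    b = basal.frame[["row", "col", "strain", "rel_phenotype_log2"]]
    merged = s.merge(b, on=["row", "col"], suffixes=("_stress", "_basal"))
    mismatched = merged["strain_stress"] != merged["strain_basal"]
    if mismatched.any():
        log.warning(
            "condition_difference: dropped %d position(s) with mismatched strains",
            int(mismatched.sum()),
        )
    merged = merged[~mismatched].copy()
    merged["strain"] = merged["strain_stress"]
    merged["condition_effect_log2"] = (
        merged["rel_phenotype_log2_stress"] - merged["rel_phenotype_log2_basal"]
    )
    return merged[
        [
            "row",
            "col",
            "strain",
            "rel_phenotype_log2_basal",
            "rel_phenotype_log2_stress",
            "condition_effect_log2",
        ]
    ]
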