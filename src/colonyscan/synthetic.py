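"""Synthetic plates with known ground truth.

Every upstream stage is testable without instrument data: this module
simulates per-colony sigmoid growth in cell counts, multiplies growth
rates by a smooth spatial bias field, adds pinning (initial population)
and measurement noise, and renders the resulting populations as opacity
domes on plate images.

Growth model.  In log2 cell counts each colony follows a
Chapman-Richards sigmoid anchored at its initial population:

    l(t) = l0 + D * (1 - exp(-r t))**nu

with D doublings over the experiment and shape nu.  Its steepest log2
slope is s_max = D * r * (1 - 1/nu)**(nu - 1), so the rate r is solved
from a prescribed true minimum doubling time dt = 1/s_max.  Default
conditions mirror a standard agar phenomics run: mean doubling time
2.0 hr, about 5 population doublings, 72 hr of scans at 20-min intervals
(217 timepoints; the scanner floor is one scan per 7 min).

Spatial bias is a plate-scale, softly undulating multiplicative field on
growth rate (random tilt plus one half-period cosine mode per axis),
standardized so its log2 amplitude equals ``bias_amplitude``.  Neighbor
nutrient competition is deliberately not simulated.

Rendering draws each colony as a truncated-paraboloid opacity dome whose
integrated opacity equals its population (identity cell calibration) and
whose radius grows as population**(1/3), so colony area doubles far more
slowly than cell count — as on real transmissive scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import OpacityImage
from .growth_features import GrowthCurve
from .layout import PlateLayout, Position, control_mask

MIN_SCAN_INTERVAL_HR = 7.0 / 60.0  # hardware floor between scans


@dataclass
class SimParams:
    """Study conditions for the growth-curve simulator.

    mean_dt : hours, plate-mean true minimum doubling time (2.0 hr, the
        wild-type value in basal medium).
    doublings : log2 span of each colony's growth (about 5 on dense
        formats).
    bias_amplitude : log2 scale of the smooth spatial field multiplying
        growth rate (0.05 -> about 5% spatial sd in doubling time, the
        dominant term of a raw plate CV near 5%).
    pinning_cv : lognormal CV of the deposited initial population (0.25;
        pin-transfer is noisy).
    noise_cv : multiplicative per-timepoint measurement noise (0.02,
        matching ~2% residual measurement error).
    t_end, dt_interval : 72 hr scanned every 20 min -> 217 timepoints.
    initial_cells : mean deposited population (2e4 cells).
    shape_nu : Chapman-Richards shape (4 -> a few hours of lag before the
        steepest growth, as observed on plates).
    """

    mean_dt: float = 2.0
    doublings: float = 5.0
    bias_amplitude: float = 0.05
    pinning_cv: float = 0.25
    noise_cv: float = 0.02
    t_end: float = 72.0
    dt_interval: float = 1.0 / 3.0
    initial_cells: float = 2.0e4
    shape_nu: float = 4.0


@dataclass
class SimTruth:
    """Ground truth for one simulated plate."""

    layout: PlateLayout
    dt_true: np.ndarray  # rows x cols, hours (instantaneous minimum)
    initial_cells: np.ndarray
    final_cells: np.ndarray
    strain: np.ndarray  # object array of labels
    strain_effect_log2: np.ndarray  # log2 doubling-time handicap per position
    bias_field: np.ndarray  # multiplicative rate factors
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.layout.rows):
            for c in range(self.layout.cols):
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "strain": self.strain[r, c],
                        "dt_true_hr": self.dt_true[r, c],
                        "initial_cells": self.initial_cells[r, c],
                        "final_cells": self.final_cells[r, c],
                        "strain_effect_log2": self.strain_effect_log2[r, c],
                        "bias_rate_factor": self.bias_field[r, c],
                    }
                )
        return pd.DataFrame(rows)


def time_grid(t_end: float = 72.0, dt_interval: float = 1.0 / 3.0) -> np.ndarray:
    """Scan times in hours, 0 through t_end inclusive at dt_interval."""
    if dt_interval < MIN_SCAN_INTERVAL_HR - 1e-12:
        raise ValueError(
            f"scan interval {dt_interval * 60:.1f} min below the 7-min floor"
        )
    n = int(round(t_end / dt_interval)) + 1
    return np.arange(n) * dt_interval


def smooth_bias_field(
    layout: PlateLayout, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Softly undulating multiplicative rate field, unit-centered.

    A random plate-scale surface (tilt + one half-period cosine mode per
    axis + their interaction) standardized to zero mean and unit sd, then
    scaled so the log2 rate factor has sd ``amplitude``.
    """
    r = np.linspace(-1.0, 1.0, layout.rows)[:, None]
    c = np.linspace(-1.0, 1.0, layout.cols)[None, :]
    a = rng.standard_normal(6)
    phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
    f = (
        a[0] * r
        + a[1] * c
        + a[2] * r * c
        + a[3] * np.cos(0.5 * np.pi * r + phase_r)
        + a[4] * np.cos(0.5 * np.pi * c + phase_c)
        + a[5] * np.cos(0.5 * np.pi * r + phase_r) * np.cos(0.5 * np.pi * c + phase_c)
    )
    sd = f.std()
    if sd < 1e-12 or amplitude == 0:
        return np.ones((layout.rows, layout.cols))
    z = (f - f.mean()) / sd
    return 2.0 ** (amplitude * z)


def _cr_log2(t: np.ndarray, l0: float, doublings: float, r: float, nu: float):
    return l0 + doublings * (1.0 - np.exp(-r * t)) ** nu


def cr_rate_for_dt(dt: float, doublings: float, nu: float) -> float:
    """Rate r giving steepest log2 slope 1/dt for the anchored sigmoid."""
    return 1.0 / (dt * doublings * (1.0 - 1.0 / nu) ** (nu - 1.0))


def simulate_growth_curves(
    layout: PlateLayout,
    params: SimParams | None = None,
    seed: int = 0,
    strain_map: np.ndarray | None = None,
    strain_effects: dict[str, float] | None = None,
) -> tuple[SimTruth, list[GrowthCurve]]:
    """Simulate ground-truth growth curves for every plate position.

    ``strain_map`` (rows x cols object array) defaults to the reserved
    label ``CONTROL`` at control positions and ``WT`` elsewhere;
    ``strain_effects`` maps labels to log2 doubling-time handicaps
    (+1 -> doubling time twice the plate mean).  The true doubling time
    at a position is ``mean_dt * 2**effect / bias`` (bias multiplies
    rate).  Fully reproducible from ``seed``.
    """
    p = params or SimParams()
    if p.dt_interval < MIN_SCAN_INTERVAL_HR - 1e-12:
        raise ValueError(
            f"scan interval {p.dt_interval * 60:.1f} min below the 7-min floor"
        )
    rng = np.random.default_rng(seed)
    times = time_grid(p.t_end, p.dt_interval)
    rows, cols = layout.rows, layout.cols

    if strain_map is None:
        strain_map = np.where(control_mask(layout), "CONTROL", "WT").astype(object)
    effects = np.zeros((rows, cols))
    if strain_effects:
        for label, eff in strain_effects.items():
            effects[strain_map == label] = eff

    bias = smooth_bias_field(layout, p.bias_amplitude, rng)
    dt_true = p.mean_dt * 2.0**effects / bias

    if p.pinning_cv > 0:
        sig = np.sqrt(np.log1p(p.pinning_cv**2))
        init = p.initial_cells * rng.lognormal(-0.5 * sig**2, sig, size=(rows, cols))
    else:
        init = np.full((rows, cols), p.initial_cells)

    l0 = np.log2(init)
    rates = 1.0 / (
        dt_true * p.doublings * (1.0 - 1.0 / p.shape_nu) ** (p.shape_nu - 1.0)
    )
    # trajectories: (T, rows, cols)
    growth = (1.0 - np.exp(-rates[None, :, :] * times[:, None, None])) ** p.shape_nu
    logpop = l0[None, :, :] + p.doublings * growth
    pop = 2.0**logpop
    if p.noise_cv > 0:
        sig = np.sqrt(np.log1p(p.noise_cv**2))
        pop = pop * rng.lognormal(-0.5 * sig**2, sig, size=pop.shape)

    truth = SimTruth(
        layout=layout,
        dt_true=dt_true,
        initial_cells=init,
        final_cells=2.0 ** (l0 + p.doublings),
        strain=strain_map,
        strain_effect_log2=effects,
        bias_field=bias,
        seed=seed,
    )
    curves = [
        GrowthCurve(times=times, raw=pop[:, q.row, q.col], position=q)
        for q in layout.positions()
    ]
    return truth, curves


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderParams:
    """How simulated populations are drawn as plate images.

    px_per_colony : lattice pitch in pixels (>= 8).
    bg_level : background opacity of the empty agar field.
    pixel_noise_sd : additive Gaussian pixel noise, opacity units.
    radius_scale : colony radius = radius_scale * pitch * pop_frac**(1/3),
        with pop_frac the population relative to the plate maximum, so the
        largest colony stays inside its grid cell.
    """

    px_per_colony: int = 16
    bg_level: float = 20.0
    pixel_noise_sd: float = 2.0
    radius_scale: float = 0.38


def render_plate_series(
    truth: SimTruth,
    curves: list[GrowthCurve],
    render: RenderParams | None = None,
    seed: int = 0,
) -> list[OpacityImage]:
    """Draw the simulated plate at every timepoint as opacity images.

    Each colony is a truncated paraboloid centered on its lattice point;
    the profile is rescaled so the summed opacity above background equals
    the colony population exactly (identity cell calibration).  The
    radius follows population**(1/3), so footprint area grows far more
    slowly than cell count.  Background is a flat field plus Gaussian
    pixel noise.
    """
    rp = render or RenderParams()
    if rp.px_per_colony < 8:
        raise ValueError("px_per_colony must be >= 8")
    if 2.0 * rp.radius_scale >= 1.0:
        raise ValueError(
            "radius_scale too large: neighboring colony domes would overlap"
        )
    rng = np.random.default_rng(seed)
    layout = truth.layout
    px = rp.px_per_colony
    H, W = layout.rows * px, layout.cols * px
    times = curves[0].times
    pop = np.zeros((times.size, layout.rows, layout.cols))
    for cu in curves:
        pop[:, cu.position.row, cu.position.col] = cu.raw
    pop_max = float(pop.max())
    if pop_max <= 0:
        r0 = 0.0
    else:
        r0 = rp.radius_scale * px / pop_max ** (1.0 / 3.0)

    centers_y = (np.arange(layout.rows) + 0.5) * px - 0.5
    centers_x = (np.arange(layout.cols) + 0.5) * px - 0.5

    images = []
    for ti in range(times.size):
        canvas = np.full((H, W), rp.bg_level, dtype=float)
        for ri in range(layout.rows):
            for ci in range(layout.cols):
                population = pop[ti, ri, ci]
                if population <= 0:
                    continue
                R = max(1.0, r0 * population ** (1.0 / 3.0))
                cy, cx = centers_y[ri], centers_x[ci]
                y0, y1 = int(np.floor(cy - R)), int(np.ceil(cy + R)) + 1
                x0, x1 = int(np.floor(cx - R)), int(np.ceil(cx + R)) + 1
                yy = np.arange(y0, y1)[:, None] - cy
                xx = np.arange(x0, x1)[None, :] - cx
                prof = np.clip(1.0 - (yy**2 + xx**2) / R**2, 0.0, None)
                total = prof.sum()
                if total <= 0:
                    continue
                canvas[y0:y1, x0:x1] += prof * (population / total)
        if rp.pixel_noise_sd > 0:
            canvas = canvas + rng.normal(0.0, rp.pixel_noise_sd, size=canvas.shape)
        images.append(OpacityImage(values=canvas, timestamp_hr=float(times[ti])))
    return images


def simulate_null_plate(
    layout: PlateLayout,
    mu: float = 2.0,
    sigma: float = 0.1,
    seed: int = 0,
    distribution: str = "normal",
) -> np.ndarray:
    """Per-position iid doubling times with no spatial structure.

    The null for the adjacency false-positive test: under it the
    rejection fraction should equal the significance level.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (layout.rows, layout.cols)
    if distribution == "normal":
        return mu + sigma * rng.standard_normal(shape)
    if distribution == "lognormal":
        return mu * np.exp(sigma * rng.standard_normal(shape))
    raise ValueError(f"unknown distribution {distribution!r}")
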