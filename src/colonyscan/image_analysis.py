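"""Virtual gridding, colony segmentation, and per-position measurement.

A plate image contains an R x C lattice of colonies.  Analysis places a
virtual grid over the plate (one intersection per expected colony center),
then works per grid cell: the local window is partitioned into colony
pixels, clean local-background pixels, and "trash" pixels that cannot be
confidently assigned to either (the safety-margin ring around the colony
and any stray blobs).  The median local-background opacity is subtracted
from every colony pixel, the cell-count calibration converts the remainder
to cells per pixel, and the per-pixel counts are summed into the colony
population size.

Series are analyzed in reverse chronological order: the grid is fitted on
the last (largest-colony) image and reused verbatim for all earlier
images, where small colonies would be hard to localize on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .calibration import CellCountCalibration, OpacityImage, cells_from_opacity
from .growth_features import GrowthCurve
from .layout import PlateLayout, Position

log = logging.getLogger(__name__)


class GriddingError(RuntimeError):
    """Grid detection failed (blank image, non-periodic signal, ...)."""


@dataclass
class Grid:
    """Fitted colony-center lattice and the per-cell window size."""

    centers: np.ndarray  # (rows, cols, 2) pixel (y, x) of each lattice point
    spacing: tuple[float, float]  # (dy, dx) pixels
    window: tuple[int, int]  # (h, w) pixels per cell


@dataclass
class ColonySegmentation:
    """Colony / background / trash partition of one grid-cell window.

    The three masks are pairwise disjoint and cover the window exactly.
    ``bbox`` locates the window inside the full image (y0, y1, x0, x1).
    """

    colony_mask: np.ndarray
    background_mask: np.ndarray
    trash_mask: np.ndarray
    bbox: tuple[int, int, int, int]


@dataclass
class ColonyMeasurement:
    """Calibrated population size of one colony at one timepoint."""

    population: float  # cells, summed over colony pixels
    area_px: int
    background_level: float  # opacity
    timestamp_hr: float
    valid: bool = True


# ---------------------------------------------------------------------------
# grid detection


def _fit_axis_lattice(coords: np.ndarray, n: int, extent: int) -> tuple[np.ndarray, float]:
    """Fit n regularly spaced lattice lines to 1-D blob-centroid coordinates.

    Centroids are clustered into candidate lines by gap splitting, the
    spacing is estimated robustly from inter-line gaps (integer multiples
    absorb missing lines), and offset/spacing are refined by least squares
    on (integer index, line center).  Returns (line positions, spacing).
    """
    s = np.sort(coords)
    if n == 1:
        return np.array([float(np.median(s))]), float(extent)
    rough = (s[-1] - s[0]) / (n - 1)
    if rough <= 0:
        raise GriddingError("all detected blobs collapse onto one lattice line")
    # split sorted coords into clusters wherever the gap exceeds half a period
    breaks = np.where(np.diff(s) > 0.5 * rough)[0]
    clusters = np.split(s, breaks + 1)
    centers = np.array([c.mean() for c in clusters])
    if centers.size < 2:
        raise GriddingError("non-periodic axis signal: a single blob cluster found")
    if centers.size > n:
        raise GriddingError(
            f"detected {centers.size} lattice lines but layout has {n}"
        )
    gaps = np.diff(centers)
    spacing0 = np.median(gaps)
    steps = np.maximum(1, np.round(gaps / spacing0).astype(int))
    idx = np.concatenate([[0], np.cumsum(steps)])
    spacing, offset = np.polyfit(idx, centers, 1)
    if idx[-1] >= n:
        raise GriddingError(
            f"detected lattice spans {idx[-1] + 1} periods but layout has {n}"
        )
    # anchor the n-line lattice: shift detected index 0 to lattice index t,
    # preferring the placement that centers the lattice in the image
    best_lines, best_score = None, np.inf
    for t in range(n - idx[-1]):
        lines = offset + (np.arange(n) - t) * spacing
        if lines[0] < -0.5 * spacing or lines[-1] > extent + 0.5 * spacing:
            continue
        score = abs((lines[0] + lines[-1]) / 2 - extent / 2)
        if score < best_score:
            best_lines, best_score = lines, score
    if best_lines is None:
        raise GriddingError("fitted lattice does not fit inside the image")
    return best_lines, float(spacing)


def detect_grid(
    img: OpacityImage, layout: PlateLayout, min_blob_px: int = 4
) -> Grid:
    """Place the virtual colony-center grid over a plate image.

    Colony blobs are found by Otsu thresholding and connected components;
    their centroids are reduced to robust per-axis lattice fits (the grid
    is separable), and the full rows x cols lattice is generated, covering
    positions with no visible colony.

    Raises :class:`GriddingError` when the image is blank or the blob
    pattern is not periodic enough to anchor the lattice.
    """
    v = img.values
    if v.max() - v.min() <= 1e-12:
        raise GriddingError("blank image: no contrast to grid on")
    thresh = threshold_otsu(v)
    lab = label(v > thresh)
    props = [p for p in regionprops(lab) if p.area >= min_blob_px]
    if len(props) < max(4, layout.n_positions // 10):
        raise GriddingError(
            f"only {len(props)} candidate colony blobs found on a "
            f"{layout.format}-format plate"
        )
    cys = np.array([p.centroid[0] for p in props])
    cxs = np.array([p.centroid[1] for p in props])
    ys, dy = _fit_axis_lattice(cys, layout.rows, v.shape[0])
    xs, dx = _fit_axis_lattice(cxs, layout.cols, v.shape[1])
    centers = np.empty((layout.rows, layout.cols, 2))
    centers[:, :, 0] = ys[:, None]
    centers[:, :, 1] = xs[None, :]
    window = (max(3, int(round(dy))), max(3, int(round(dx))))
    return Grid(centers=centers, spacing=(dy, dx), window=window)


# ---------------------------------------------------------------------------
# segmentation


def _window_bounds(grid: Grid, p: Position, shape: tuple[int, int]):
    cy, cx = grid.centers[p.row, p.col]
    h, w = grid.window
    y0 = int(round(cy - h / 2))
    x0 = int(round(cx - w / 2))
    y0c, x0c = max(0, y0), max(0, x0)
    y1c, x1c = min(shape[0], y0 + h), min(shape[1], x0 + w)
    return y0c, y1c, x0c, x1c


def segment_colony(
    img: OpacityImage,
    grid: Grid,
    p: Position,
    margin: int = 2,
    contrast_guard: float = 5.0,
) -> ColonySegmentation:
    """Partition one grid-cell window into colony / background / trash.

    The window is Otsu-thresholded (with a minimum-contrast guard that
    declares "no colony" on flat windows); the above-threshold connected
    component nearest the window center seeds the colony, which is then
    grown down to just above the local background level so dim colony
    rims are not misread as background.  Other blobs and a ``margin``-pixel
    dilation ring around the colony are trash; everything else is clean
    local background.

    Otsu alone is unreliable when the colony covers only a handful of
    pixels (its threshold then splits the background noise instead), so
    the threshold is floored at a robust background estimate: window
    median + 5 x scaled MAD.
    """
    y0, y1, x0, x1 = _window_bounds(grid, p, img.values.shape)
    w = img.values[y0:y1, x0:x1]
    empty = np.zeros(w.shape, dtype=bool)
    bbox = (y0, y1, x0, x1)
    if w.size == 0:
        return ColonySegmentation(empty, empty.copy(), empty.copy(), bbox)
    vrange = float(w.max() - w.min())
    if vrange < contrast_guard:
        return ColonySegmentation(empty, np.ones_like(empty), empty.copy(), bbox)

    med = float(np.median(w))
    robust_floor = med + 5.0 * 1.4826 * float(np.median(np.abs(w - med)))
    thresh = max(float(threshold_otsu(w)), robust_floor)
    strong = w > thresh
    lab = label(strong)
    if lab.max() == 0:
        return ColonySegmentation(empty, np.ones_like(empty), empty.copy(), bbox)

    center = np.array([(w.shape[0] - 1) / 2.0, (w.shape[1] - 1) / 2.0])
    props = regionprops(lab)
    dists = [
        np.min(np.hypot(pr.coords[:, 0] - center[0], pr.coords[:, 1] - center[1]))
        for pr in props
    ]
    colony_label = props[int(np.argmin(dists))].label

    # hysteresis growth: extend the seed down to just above local background
    below = w[~strong]
    bg_med = float(np.median(below)) if below.size else float(w.min())
    mad = float(np.median(np.abs(below - bg_med))) if below.size else 0.0
    low = bg_med + max(3.0 * 1.4826 * mad, 1e-9 * vrange)
    weak = w > low
    weak_lab = label(weak)
    seed_labels = np.unique(weak_lab[lab == colony_label])
    seed_labels = seed_labels[seed_labels > 0]
    colony = np.isin(weak_lab, seed_labels) if seed_labels.size else (lab == colony_label)

    trash = weak & ~colony  # stray blobs and noise speckles
    if margin > 0:
        ring = ndimage.binary_dilation(colony, iterations=margin) & ~colony
        trash |= ring
    background = ~(colony | trash)
    return ColonySegmentation(colony, background, trash, bbox)


def measure_colony(
    seg: ColonySegmentation, img: OpacityImage, cal: CellCountCalibration
) -> ColonyMeasurement:
    """Background-subtract and calibrate one segmented window.

    The background level is the median opacity over clean background
    pixels (robust to residual blob pixels); the population is the sum of
    per-pixel cell counts over colony pixels, each clipped at zero.
    """
    y0, y1, x0, x1 = seg.bbox
    w = img.values[y0:y1, x0:x1]
    if not seg.background_mask.any():
        return ColonyMeasurement(
            population=np.nan,
            area_px=int(seg.colony_mask.sum()),
            background_level=np.nan,
            timestamp_hr=img.timestamp_hr,
            valid=False,
        )
    bg = float(np.median(w[seg.background_mask]))
    area = int(seg.colony_mask.sum())
    if area == 0:
        pop = 0.0
    else:
        pop = float(np.sum(cells_from_opacity(cal, w[seg.colony_mask] - bg)))
    return ColonyMeasurement(
        population=pop,
        area_px=area,
        background_level=bg,
        timestamp_hr=img.timestamp_hr,
        valid=True,
    )


# ---------------------------------------------------------------------------
# series analysis


def analyze_series(
    images: list[OpacityImage],
    layout: PlateLayout,
    cal: CellCountCalibration,
    margin: int = 2,
    contrast_guard: float = 5.0,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Extract one raw growth curve per plate position from an image series.

    The grid is detected on the LAST image and reused with fixed centers
    for all earlier images (reverse-chronological analysis: late images
    with large colonies anchor the localization of early, faint ones).
    Per-image measurement failures become missing points, never aborts.

    Returns the curves (row-major position order) and a tidy long-format
    measurement table (one row per position and timepoint).
    """
    if not images:
        raise ValueError("need at least one image")
    stamps = np.array([im.timestamp_hr for im in images], dtype=float)
    if stamps.size > 1 and np.any(np.diff(stamps) <= 0):
        raise ValueError("image timestamps must be strictly increasing")

    grid = detect_grid(images[-1], layout)

    n_t = len(images)
    pops = np.full((n_t, layout.rows, layout.cols), np.nan)
    areas = np.zeros((n_t, layout.rows, layout.cols), dtype=int)
    bgs = np.full((n_t, layout.rows, layout.cols), np.nan)
    valid = np.zeros((n_t, layout.rows, layout.cols), dtype=bool)

    for ti in range(n_t - 1, -1, -1):  # reverse chronological
        img = images[ti]
        for p in layout.positions():
            seg = segment_colony(img, grid, p, margin=margin, contrast_guard=contrast_guard)
            m = measure_colony(seg, img, cal)
            pops[ti, p.row, p.col] = m.population
            areas[ti, p.row, p.col] = m.area_px
            bgs[ti, p.row, p.col] = m.background_level
            valid[ti, p.row, p.col] = m.valid

    curves = [
        GrowthCurve(times=stamps, raw=pops[:, p.row, p.col], position=p)
        for p in layout.positions()
    ]
    records = []
    for ti in range(n_t):
        for p in layout.positions():
            records.append(
                (
                    p.row,
                    p.col,
                    stamps[ti],
                    pops[ti, p.row, p.col],
                    areas[ti, p.row, p.col],
                    bgs[ti, p.row, p.col],
                    valid[ti, p.row, p.col],
                )
            )
    table = pd.DataFrame(
        records,
        columns=[
            "row",
            "col",
            "time_hr",
            "population_cells",
            "area_px",
            "background_opacity",
            "valid",
        ],
    )
    return curves, table


# ---------------------------------------------------------------------------
# image / table IO


def read_image(path: str | Path, timestamp_hr: float = 0.0) -> np.ndarray:
    """Read a single-channel TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=2)
    return arr.astype(float)


def load_timestamps(path: str | Path) -> pd.DataFrame:
    """Sidecar CSV mapping image filename to acquisition time in hours."""
    df = pd.read_csv(path)
    if not {"filename", "hours"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns filename,hours")
    return df


def curves_from_table(table: pd.DataFrame, layout: PlateLayout) -> list[GrowthCurve]:
    """Rebuild per-position GrowthCurves from the long-format CSV layout."""
    curves = []
    for p in layout.positions():
        sub = table[(table["row"] == p.row) & (table["col"] == p.col)].sort_values(
            "time_hr"
        )
        curves.append(
            GrowthCurve(
                times=sub["time_hr"].to_numpy(float),
                raw=sub["population_cells"].to_numpy(float),
                position=p,
            )
        )
    return curves
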