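"""Plate formats, grid coordinates, tetrad/control structure, and neighborhoods.

Pinned colony arrays come in the SBS doubling series of formats: 96
(8 x 12), 384 (16 x 24) and 1536 (32 x 48).  When a lower-density array is
replicated four-fold onto the next denser format, every position of the
source array becomes a 2 x 2 "tetrad" of positions on the target plate.
Reserving one fixed position per tetrad for an isogenic control strain
yields an evenly spaced reference grid covering exactly a quarter of the
plate; with 0-based row-major indexing (row 0 at the image top, col 0 at
the left) the lower-right position of every tetrad is the one with odd row
and odd column index.  A consequence is that two of the four outer plate
edges (row 0 and col 0) carry no controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: rows x cols for each supported pinning format
FORMATS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


@dataclass(frozen=True, order=True)
class Position:
    """0-based (row, col) array coordinate on a plate."""

    row: int
    col: int


@dataclass(frozen=True)
class PlateLayout:
    """Grid geometry and control-position rule for one pinning format."""

    format: int
    rows: int
    cols: int

    @property
    def n_positions(self) -> int:
        return self.rows * self.cols

    def is_control(self, row: int, col: int) -> bool:
        """Lower-right position of every tetrad: odd row AND odd col."""
        return row % 2 == 1 and col % 2 == 1

    def contains(self, p: Position) -> bool:
        return 0 <= p.row < self.rows and 0 <= p.col < self.cols

    def positions(self) -> Iterator[Position]:
        """All positions in row-major order."""
        for r in range(self.rows):
            for c in range(self.cols):
                yield Position(r, c)


def make_layout(format: int) -> PlateLayout:
    """Build the layout for a pinning format.

    Parameters
    ----------
    format : int
        One of 96, 384 or 1536 (the allowed pinned-plate formats).

    Raises
    ------
    ValueError
        If *format* is not an allowed pinning format.
    """
    if format not in FORMATS:
        raise ValueError(
            f"unsupported plate format {format!r}; allowed formats are "
            f"{sorted(FORMATS)}"
        )
    rows, cols = FORMATS[format]
    return PlateLayout(format=format, rows=rows, cols=cols)


def control_positions(layout: PlateLayout) -> list[Position]:
    """Control positions (one per tetrad) in deterministic row-major order.

    Exactly ``rows * cols / 4`` positions, all with odd row and odd col.
    """
    return [p for p in layout.positions() if layout.is_control(p.row, p.col)]


def experimental_positions(layout: PlateLayout) -> list[Position]:
    """The complement of :func:`control_positions`, row-major order."""
    return [p for p in layout.positions() if not layout.is_control(p.row, p.col)]


def control_mask(layout: PlateLayout) -> np.ndarray:
    """Boolean rows x cols array, True at control positions."""
    mask = np.zeros((layout.rows, layout.cols), dtype=bool)
    mask[1::2, 1::2] = True
    return mask


def neighbors(
    layout: PlateLayout, p: Position, scheme: str = "moore8"
) -> set[Position]:
    """In-bounds positions immediately adjacent to *p*.

    Adjacency is the 8-neighbor Moore scheme (Chebyshev distance 1);
    positions on plate edges and corners have clipped neighborhoods.
    """
    if scheme != "moore8":
        raise ValueError(f"unknown neighborhood scheme {scheme!r}")
    if not layout.contains(p):
        raise ValueError(f"position {p} is outside the {layout.format} layout")
    out = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            q = Position(p.row + dr, p.col + dc)
            if layout.contains(q):
                out.add(q)
    return out
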