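"""Regular planar grid shared by the simulator, reader and aggregator.

The grid lives in a projected (planar, metre-based) CRS.  Cell ``(iy, ix)``
covers the rectangle ``[x0 + ix*cs, x0 + (ix+1)*cs] x [y0 + iy*cs, y0 +
(iy+1)*cs]`` and arrays are indexed ``values[t, iy, ix]``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular square-celled grid in planar metres."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have nx >= 1 and ny >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def width(self) -> float:
        return self.nx * self.cell_size

    @property
    def height(self) -> float:
        return self.ny * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def cell_bounds(self, iy: int, ix: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell."""
        cs = self.cell_size
        return (
            self.x0 + ix * cs,
            self.y0 + iy * cs,
            self.x0 + (ix + 1) * cs,
            self.y0 + (iy + 1) * cs,
        )

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)
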