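"""Planar km grids and named raster layers.

All spatial data live on regular grids in a planar coordinate system with
kilometre units (the GB analyses this package emulates use the British
National Grid with units converted to km). A :class:`GridSpec` describes the
geometry; a :class:`Raster` couples a value matrix to a grid. Row index 0 is
the *bottom* row (origin is the lower-left corner); cell centers sit at
``origin + (col + 0.5, row + 0.5) * cell_km``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DegenerateLayerError(ValueError):
    """Raised when a raster layer is constant and cannot be standardized."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid on a planar km coordinate system."""

    nrows: int
    ncols: int
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid edges in km."""
        x0, y0 = self.origin
        return (x0, x0 + self.ncols * self.cell_km, y0, y0 + self.nrows * self.cell_km)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as two ``(nrows, ncols)`` arrays (x, y)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_km
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell_km
        return np.meshgrid(xs, ys)

    def center_points(self) -> np.ndarray:
        """All cell centers as an ``(nrows*ncols, 2)`` array, row-major."""
        cx, cy = self.cell_centers()
        return np.column_stack([cx.ravel(), cy.ravel()])

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        xmin, xmax, ymin, ymax = self.extent
        return (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
            & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )

    def cell_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; raises if outside."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if not self.contains(xy).all():
            raise ValueError("point(s) outside grid domain")
        x0, y0 = self.origin
        col = np.clip(((xy[:, 0] - x0) / self.cell_km).astype(int), 0, self.ncols - 1)
        row = np.clip(((xy[:, 1] - y0) / self.cell_km).astype(int), 0, self.nrows - 1)
        return row, col


@dataclass
class Raster:
    """A named layer of values on a :class:`GridSpec`.

    Missing cells are NaN and propagate through arithmetic and
    standardization.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None) -> "Raster":
        return Raster(self.grid, np.asarray(values, dtype=float),
                      self.name if name is None else name,
                      self.units if units is None else units)

    def value_at(self, xy: np.ndarray) -> np.ndarray:
        """Layer value of the cell containing each point (no interpolation)."""
        row, col = self.grid.cell_index(xy)
        return self.values[row, col]

    def standardize(self) -> "Raster":
        """Z-score the layer: subtract the mean, divide by the population sd.

        Layers are complete populations of cells, so the 1/n standard
        deviation is used. A constant layer raises
        :class:`DegenerateLayerError` — such a layer carries no information
        and must be dropped, not silently zeroed.
        """
        vals = self.values
        mask = np.isfinite(vals)
        sd = float(np.std(vals[mask]))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateLayerError(f"layer {self.name!r} is constant; drop it")
        out = np.full_like(vals, np.nan)
        out[mask] = (vals[mask] - np.mean(vals[mask])) / sd
        return self.copy_with(out)


def standardize(x: Raster) -> Raster:
    """Functional alias for :meth:`Raster.standardize`."""
    return x.standardize()


def stack_standardize(layers: dict[str, Raster]) -> dict[str, Raster]:
    """Standardize every layer in a stack, keyed by name."""
    return {k: v.standardize() for k, v in layers.items()}
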