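"""Regular raster lattices and single-band layers.

The spatial unit of the whole package is a cell of a regular projected
grid.  :class:`Lattice` carries the grid geometry plus the rook (4-)
adjacency that the conditional autoregressive spatial effect is defined
on; :class:`RasterLayer` is one band of values on that grid with a
nodata mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Lattice", "RasterLayer", "make_lattice"]


@dataclass(frozen=True)
class Lattice:
    """Geometry of a regular grid of square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 3 each so that rook adjacency has
        interior structure.
    cell_size
        Side length of a cell in km.
    origin
        Projected (x, y) of the top-left corner of the top-left cell.
    crs_label
        Free-text label of the projected CRS.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "synthetic-utm"

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise InvalidArgumentError(
                f"lattice needs n_rows >= 3 and n_cols >= 3, "
                f"got {self.n_rows} x {self.n_cols}"
            )
        if self.cell_size <= 0:
            raise InvalidArgumentError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        """Cell area in km^2."""
        return self.cell_size**2

    def rook_edges(self) -> np.ndarray:
        """Unique rook-adjacency edges as an (n_edges, 2) array of flat indices.

        Each edge appears once with ``i < j``; symmetry and absence of
        self-edges hold by construction.
        """
        idx = np.arange(self.n_cells).reshape(self.shape)
        horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
        vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
        return np.concatenate([horiz, vert], axis=0)

    def neighbour_lists(self) -> list[np.ndarray]:
        """Rook neighbours of every cell, as flat indices."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_cells)]
        for i, j in self.rook_edges():
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.asarray(sorted(n), dtype=np.intp) for n in nbrs]

    def n_neighbours(self) -> np.ndarray:
        """Number of rook neighbours per cell (2, 3 or 4)."""
        counts = np.zeros(self.n_cells, dtype=np.intp)
        edges = self.rook_edges()
        np.add.at(counts, edges[:, 0], 1)
        np.add.at(counts, edges[:, 1], 1)
        return counts

    def checkerboard(self) -> np.ndarray:
        """Boolean colouring where no two rook neighbours share a colour."""
        r, c = np.indices(self.shape)
        return ((r + c) % 2 == 0).ravel()

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of cell centres, flat order."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols) * self.cell_size + x0 + self.cell_size / 2
        rows = y0 - (np.arange(self.n_rows) * self.cell_size + self.cell_size / 2)
        xx, yy = np.meshgrid(cols, rows)
        return xx.ravel(), yy.ravel()

    def cell_of_point(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat cell index containing each projected point; -1 if outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(np.intp)
        row = np.floor((y0 - y) / self.cell_size).astype(np.intp)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out


@dataclass
class RasterLayer:
    """One band of real values on a lattice, with a nodata mask."""

    lattice: Lattice
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(self.lattice.shape)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.lattice.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool).reshape(
                self.lattice.shape
            )
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise InvalidArgumentError("non-finite values outside the nodata mask")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.lattice,
            np.asarray(values, dtype=float),
            self.nodata_mask.copy(),
            self.units if units is None else units,
        )

    def total(self) -> float:
        """Sum of valid cell values."""
        return float(self.values[~self.nodata_mask].sum())

    def mean(self) -> float:
        return float(self.values[~self.nodata_mask].mean())


def make_lattice(
    n_rows: int,
    n_cols: int,
    cell_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    crs_label: str = "synthetic-utm",
) -> Lattice:
    """Create a lattice; raises :class:`InvalidArgumentError` on bad dims."""
    return Lattice(n_rows, n_cols, cell_size, origin, crs_label)


def check_same_lattice(*layers) -> Lattice:
    """Assert all arguments share one lattice shape and return it."""
    lat = layers[0].lattice
    for lay in layers[1:]:
        if lay.lattice.shape != lat.shape:
            raise InvalidArgumentError(
                f"lattice mismatch: {lay.lattice.shape} vs {lat.shape}"
            )
    return lat
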