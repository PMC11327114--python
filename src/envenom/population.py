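"""Population bias correction and annual interpolation.

Decadal population-density projections are bias-corrected against a
reference series by the mean observed-to-predicted quotient per cell,
then interpolated to annual layers with shape-preserving piecewise cubic
Hermite polynomials (PCHIP), which pass through the decadal knots
exactly, introduce no new extrema between knots, and keep non-negative
knots non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InvalidArgumentError
from .lattice import Lattice

__all__ = [
    "PopulationSeries",
    "population_bias_factor",
    "hermite_annual",
    "project_population",
]


@dataclass
class PopulationSeries:
    """Population density (persons/km^2) layers for listed years."""

    lattice: Lattice
    years: np.ndarray
    density: np.ndarray  # (n_years, n_rows, n_cols)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (len(self.years), *self.lattice.shape):
            raise InvalidArgumentError("density must be (n_years, n_rows, n_cols)")
        if np.any(np.diff(self.years) <= 0):
            raise InvalidArgumentError("years must be strictly increasing")
        if np.any(self.density < 0):
            raise InvalidArgumentError("negative population density")

    def layer(self, year: int) -> np.ndarray:
        pos = np.flatnonzero(self.years == year)
        if pos.size == 0:
            raise InvalidArgumentError(f"year {year} not in series")
        return self.density[int(pos[0])]

    def totals(self) -> np.ndarray:
        """National population per year (density times cell area)."""
        return self.density.reshape(len(self.years), -1).sum(axis=1) * self.lattice.cell_area


def population_bias_factor(
    observed: PopulationSeries,
    predicted: PopulationSeries,
    min_predicted: float = 0.5,
) -> np.ndarray:
    """Cellwise mean quotient of observed to predicted over overlap years.

    Cells where the predicted density is below ``min_predicted``
    persons/km^2 in every overlap year are near-empty and carry no usable
    ratio; they take the study-area mean factor instead.
    """
    overlap = np.intersect1d(observed.years, predicted.years)
    if overlap.size == 0:
        raise InvalidArgumentError("no overlapping years between series")
    ratios = []
    valid = []
    for year in overlap:
        obs = observed.layer(int(year))
        pred = predicted.layer(int(year))
        ok = pred >= min_predicted
        ratios.append(np.where(ok, obs / np.maximum(pred, min_predicted), np.nan))
        valid.append(ok)
    stack = np.stack(ratios)
    any_valid = np.stack(valid).any(axis=0)
    finite = stack[np.isfinite(stack)]
    fallback = float(finite.mean()) if finite.size else 1.0
    with np.errstate(invalid="ignore"):
        sums = np.nansum(stack, axis=0)
        counts = np.isfinite(stack).sum(axis=0)
    factor = np.where(any_valid, sums / np.maximum(counts, 1), fallback)
    return factor


def hermite_annual(decadal: PopulationSeries, years) -> PopulationSeries:
    """Interpolate decadal layers to annual ones with per-cell PCHIP.

    Requested years must lie within the knot span; extrapolation is
    refused.
    """
    years = np.asarray(list(years), dtype=int)
    if len(decadal.years) < 2:
        raise InvalidArgumentError("need at least 2 knot years")
    if years.size == 0:
        raise InvalidArgumentError("empty year range")
    if years.min() < decadal.years[0] or years.max() > decadal.years[-1]:
        raise InvalidArgumentError(
            f"requested years {years.min()}-{years.max()} extend beyond knots "
            f"{decadal.years[0]}-{decadal.years[-1]}"
        )
    interp = PchipInterpolator(decadal.years.astype(float), decadal.density, axis=0)
    dens = interp(years.astype(float))
    # PCHIP cannot undershoot below the knot minimum, but guard rounding.
    dens = np.maximum(dens, 0.0)
    return PopulationSeries(decadal.lattice, years, dens)


def project_population(
    decadal_raw: PopulationSeries, factor: np.ndarray, years
) -> PopulationSeries:
    """Bias-correct decadal layers cellwise, then interpolate annually."""
    factor = np.asarray(factor, dtype=float)
    if factor.shape != decadal_raw.lattice.shape:
        raise InvalidArgumentError("factor shape does not match lattice")
    if not np.all(np.isfinite(factor)):
        raise InvalidArgumentError("bias factor must be finite")
    corrected = PopulationSeries(
        decadal_raw.lattice,
        decadal_raw.years.copy(),
        decadal_raw.density * factor[np.newaxis],
    )
    return hermite_annual(corrected, years)
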