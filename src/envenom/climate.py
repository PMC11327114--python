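"""Climate stacks, delta-method bias correction and bioclim summaries.

A :class:`ClimateStack` holds monthly minimum/maximum temperature (degC)
and total rainfall (mm) layers per year on one lattice.  Bias correction
follows the modified delta method: additive *difference* factors
(observed minus modelled reference climatology) for temperature, and
multiplicative *ratio* factors (observed over modelled) for rainfall and
other strictly positive variables.  Applying a correction field to the
modelled reference period reproduces the observed reference climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .lattice import Lattice

__all__ = [
    "ClimateStack",
    "CorrectionField",
    "DownscaleValidation",
    "difference_correction",
    "ratio_correction",
    "apply_delta",
    "validate_downscale",
    "bioclim_summaries",
    "rolling_climate_mean",
    "select_climate_window",
]

VARIABLES = ("tmin", "tmax", "rain")

#: Correction kind the delta method uses per variable: additive for
#: temperatures, multiplicative for rainfall.
DEFAULT_KINDS = {"tmin": "difference", "tmax": "difference", "rain": "ratio"}


@dataclass
class ClimateStack:
    """Monthly climate layers per year.

    ``tmin``, ``tmax`` and ``rain`` are arrays of shape
    ``(n_years, 12, n_rows, n_cols)`` aligned with ``years``.
    """

    lattice: Lattice
    years: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        shape = (len(self.years), 12, *self.lattice.shape)
        for name in VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise InvalidArgumentError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        if np.any(self.tmin > self.tmax + 1e-9):
            raise InvalidArgumentError("tmin exceeds tmax somewhere")
        if np.any(self.rain < 0):
            raise InvalidArgumentError("negative rainfall")

    def year_index(self, year: int) -> int:
        pos = np.flatnonzero(self.years == year)
        if pos.size == 0:
            raise InvalidArgumentError(f"year {year} not in stack {self.years.tolist()}")
        return int(pos[0])

    def get(self, variable: str) -> np.ndarray:
        if variable not in VARIABLES:
            raise InvalidArgumentError(f"unknown climate variable {variable!r}")
        return getattr(self, variable)

    def subset_years(self, years) -> "ClimateStack":
        idx = [self.year_index(int(y)) for y in np.asarray(years)]
        return ClimateStack(
            self.lattice,
            self.years[idx],
            self.tmin[idx],
            self.tmax[idx],
            self.rain[idx],
        )

    def climatology(self) -> dict[str, np.ndarray]:
        """Multi-year mean per variable and calendar month: (12, nr, nc)."""
        return {v: self.get(v).mean(axis=0) for v in VARIABLES}


@dataclass
class CorrectionField:
    """Per-month, per-cell delta-method correction factors for one stack.

    ``values[var]`` has shape (12, n_rows, n_cols); ``kind[var]`` is
    ``"difference"`` (added) or ``"ratio"`` (multiplied, strictly > 0).
    """

    lattice: Lattice
    kind: dict[str, str]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for var, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (12, *self.lattice.shape):
                raise InvalidArgumentError(f"correction for {var} has wrong shape")
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError(f"non-finite correction for {var}")
            if self.kind[var] == "ratio" and np.any(arr <= 0):
                raise InvalidArgumentError(f"ratio correction for {var} not positive")
            self.values[var] = arr


@dataclass(frozen=True)
class DownscaleValidation:
    """Agreement statistics between observed and backcast series."""

    r: float
    slope: float
    intercept: float
    rmse: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise InvalidArgumentError("correlation outside [-1, 1]")
        if self.rmse < 0:
            raise InvalidArgumentError("negative rmse")


def climate_to_netcdf(stack: ClimateStack, path) -> None:
    """Write a stack as a NetCDF cube (year, month, row, col per variable)."""
    import xarray as xr

    ds = xr.Dataset(
        {v: (("year", "month", "row", "col"), stack.get(v)) for v in VARIABLES},
        coords={"year": stack.years, "month": np.arange(1, 13)},
        attrs={
            "cell_size_km": stack.lattice.cell_size,
            "origin_x": stack.lattice.origin[0],
            "origin_y": stack.lattice.origin[1],
            "crs_label": stack.lattice.crs_label,
        },
    )
    ds.to_netcdf(str(path), engine="scipy")


def climate_from_netcdf(path, lattice: Lattice | None = None) -> ClimateStack:
    """Read a stack written by :func:`climate_to_netcdf`."""
    import xarray as xr

    from .lattice import make_lattice

    with xr.open_dataset(str(path), engine="scipy") as ds:
        years = ds["year"].values
        arrs = {v: ds[v].values.copy() for v in VARIABLES}
        if lattice is None:
            nr, nc = arrs["tmax"].shape[2:]
            lattice = make_lattice(
                nr, nc, float(ds.attrs.get("cell_size_km", 1.0)),
                (float(ds.attrs.get("origin_x", 0.0)), float(ds.attrs.get("origin_y", 0.0))),
                str(ds.attrs.get("crs_label", "synthetic-utm")),
            )
    return ClimateStack(lattice, years, arrs["tmin"], arrs["tmax"], arrs["rain"])


def climate_to_tiffs(stack: ClimateStack, directory) -> list:
    """Write one multi-page TIFF per variable (pages = year x month)."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    ny = len(stack.years)
    for v in VARIABLES:
        p = directory / f"climate_{v}.tif"
        tifffile.imwrite(str(p), stack.get(v).reshape(ny * 12, *stack.lattice.shape))
        paths.append(p)
    return paths


def climate_from_tiffs(directory, years, lattice: Lattice) -> ClimateStack:
    """Read stacks written by :func:`climate_to_tiffs`."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    years = np.asarray(list(years), dtype=int)
    arrs = {}
    for v in VARIABLES:
        arr = tifffile.imread(str(directory / f"climate_{v}.tif"))
        arrs[v] = arr.reshape(len(years), 12, *lattice.shape)
    return ClimateStack(lattice, years, arrs["tmin"], arrs["tmax"], arrs["rain"])


def _check_reference_pair(observed: ClimateStack, modelled: ClimateStack) -> None:
    if observed.lattice.shape != modelled.lattice.shape:
        raise InvalidArgumentError("reference stacks on different lattices")
    if len(observed.years) == 0 or len(modelled.years) == 0:
        raise InvalidArgumentError("empty reference period")


def difference_correction(
    observed_ref: ClimateStack,
    modelled_ref: ClimateStack,
    variables: tuple[str, ...] = ("tmin", "tmax"),
) -> CorrectionField:
    """Additive correction: observed minus modelled reference climatology."""
    _check_reference_pair(observed_ref, modelled_ref)
    obs = observed_ref.climatology()
    mod = modelled_ref.climatology()
    values = {v: obs[v] - mod[v] for v in variables}
    return CorrectionField(
        observed_ref.lattice, {v: "difference" for v in variables}, values
    )


def ratio_correction(
    observed_ref: ClimateStack,
    modelled_ref: ClimateStack,
    variables: tuple[str, ...] = ("rain",),
    floor: float = 0.01,
) -> CorrectionField:
    """Multiplicative correction: observed over floored modelled climatology.

    The floor guards dry cells where the modelled climatology is ~0; the
    resulting factor is also floored so the field stays strictly positive.
    """
    if floor <= 0:
        raise InvalidArgumentError("floor must be positive")
    _check_reference_pair(observed_ref, modelled_ref)
    obs = observed_ref.climatology()
    mod = modelled_ref.climatology()
    values = {
        v: np.maximum(np.maximum(obs[v], 0.0) / np.maximum(mod[v], floor), 1e-12)
        for v in variables
    }
    return CorrectionField(observed_ref.lattice, {v: "ratio" for v in variables}, values)


def apply_delta(modelled_future: ClimateStack, correction: CorrectionField) -> ClimateStack:
    """Apply correction factors to a modelled stack, month by month.

    Difference kinds add, ratio kinds multiply.  Corrected tmin is capped
    at corrected tmax (independent monthly corrections can cross in rare
    cells) and rainfall floored at 0.
    """
    if modelled_future.lattice.shape != correction.lattice.shape:
        raise InvalidArgumentError("correction computed on a different lattice")
    out = {}
    for var in VARIABLES:
        arr = modelled_future.get(var).copy()
        if var in correction.values:
            corr = correction.values[var][np.newaxis]  # broadcast over years
            if correction.kind[var] == "difference":
                arr = arr + corr
            else:
                arr = arr * corr
        out[var] = arr
    out["rain"] = np.maximum(out["rain"], 0.0)
    out["tmin"] = np.minimum(out["tmin"], out["tmax"])
    return ClimateStack(
        modelled_future.lattice, modelled_future.years.copy(), out["tmin"], out["tmax"], out["rain"]
    )


def validate_downscale(observed: np.ndarray, backcast: np.ndarray) -> DownscaleValidation:
    """Pooled-over-cells validation of a backcast against observations.

    Both inputs are arrays of annual values per cell (any matching
    shapes); pairs are pooled and summarised by Pearson's r, the OLS
    slope/intercept of observed on backcast, and the RMSE between the
    two series.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    back = np.asarray(backcast, dtype=float).ravel()
    if obs.shape != back.shape:
        raise InvalidArgumentError("observed and backcast shapes differ")
    if obs.size < 3:
        raise InvalidArgumentError("need at least 3 pooled pairs")
    if np.ptp(back) == 0:
        raise InvalidArgumentError("constant backcast: correlation undefined")
    res = stats.linregress(back, obs)
    rmse = float(np.sqrt(np.mean((obs - back) ** 2)))
    return DownscaleValidation(float(res.rvalue), float(res.slope), float(res.intercept), rmse)


def bioclim_summaries(stack: ClimateStack, year: int) -> dict[str, np.ndarray]:
    """Annual bioclim summaries for one year.

    Means over the 12 months for tmin and tmax, total over the 12 months
    for rainfall; each value is a (n_rows, n_cols) array.
    """
    i = stack.year_index(year)
    return {
        "mean_tmin": stack.tmin[i].mean(axis=0),
        "mean_tmax": stack.tmax[i].mean(axis=0),
        "total_rain": stack.rain[i].sum(axis=0),
    }


def rolling_climate_mean(
    stack: ClimateStack, year: int, window: int = 3
) -> dict[str, np.ndarray]:
    """Bioclim summaries averaged over ``year`` and the preceding years.

    The default window of 3 means the focal year plus the two preceding,
    matching the span that best explained observed incidence.
    """
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    years = range(year - window + 1, year + 1)
    sums: dict[str, np.ndarray] | None = None
    for y in years:
        s = bioclim_summaries(stack, y)  # raises if history insufficient
        if sums is None:
            sums = {k: v.copy() for k, v in s.items()}
        else:
            for k in sums:
                sums[k] += s[k]
    assert sums is not None
    return {k: v / window for k, v in sums.items()}


def select_climate_window(
    counts: np.ndarray,
    population: np.ndarray,
    stack: ClimateStack,
    survey_year: int,
    candidate_windows=range(1, 11),
) -> int:
    """Pick the climate-averaging window that best explains incidence.

    For each candidate window a Poisson regression of per-cell counts on
    the three windowed bioclim summaries with a log-population offset is
    fitted; the window minimising AIC wins, ties going to the smaller
    window.
    """
    import statsmodels.api as sm

    candidates = sorted(set(int(w) for w in candidate_windows))
    if not candidates:
        raise InvalidArgumentError("no candidate windows")
    y = np.asarray(counts, dtype=float).ravel()
    pop = np.asarray(population, dtype=float).ravel()
    if y.shape != pop.shape:
        raise InvalidArgumentError("counts and population shapes differ")
    offset = np.log(np.maximum(pop, 1e-8))
    best_w, best_aic = None, np.inf
    for w in candidates:
        summ = rolling_climate_mean(stack, survey_year, window=w)
        X = np.column_stack([summ[k].ravel() for k in ("mean_tmin", "mean_tmax", "total_rain")])
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
        X = sm.add_constant(X, has_constant="add")
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        if fit.aic < best_aic - 1e-9:
            best_w, best_aic = w, fit.aic
    assert best_w is not None
    return best_w
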