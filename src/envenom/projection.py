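"""Scenario projections 2010-2050 and change statistics.

Drives the full annual pipeline — bias-corrected climate, rolling
3-year bioclim means, CLUE-style land cover allocation, population
interpolation, per-species abundance projection — upscales the 1 km
layers to the 5 km model grid (block sums for intensities and
population, majority vote for land cover) and evaluates expected
envenoming incidence with the fitted parameters held constant.  The
change statistics (per-pixel trends, percentage change, national
accumulated change with standard errors, RCM consensus, dominant
species, per-transition summaries) are computed from the resulting
annual series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import (
    SPECIES,
    NicheModel,
    SpeciesAbundanceSet,
    apply_expert_weights,
    estimate_niche,
    fit_abundance_model,
    niche_distance,
    project_abundance,
)
from .climate import (
    ClimateStack,
    apply_delta,
    difference_correction,
    ratio_correction,
    rolling_climate_mean,
)
from .errors import InvalidArgumentError
from .landcover import (
    CLASSES,
    N_CLASSES,
    DemandTrajectory,
    LandCoverMap,
    TransitionRules,
    derived_covariates,
    fit_location_factors,
    simulate_landcover,
)
from .lattice import Lattice, RasterLayer, make_lattice
from .model import EnvenomingParams, forward_incidence
from .population import PopulationSeries, hermite_annual
from .synth import SyntheticTruth, TrendSpec, elevation_surface, gen_climate

__all__ = [
    "Scenario",
    "ScenarioRun",
    "ChangeSummary",
    "upscale_sum",
    "upscale_majority",
    "run_scenario",
    "pixel_trend",
    "pct_change",
    "national_series",
    "rcm_consensus",
    "dominant_species",
    "transition_change_summary",
]

_SSP_PAIRING = {
    "SSP1": ("none", ("historical-trend",)),
    "SSP2": ("RCP4.5", ("CNRM-CM5", "GFDL-CM3", "MPI-ESM-LR")),
    "SSP5": ("RCP8.5", ("CNRM-CM5", "GFDL-CM3", "MPI-ESM-LR")),
}


@dataclass
class Scenario:
    """One SSP-RCP-RCM projection: identifiers plus trajectory knobs."""

    ssp_id: str
    rcp_id: str
    rcm_id: str
    trend: TrendSpec = TrendSpec()
    demand_end_shares: tuple[float, ...] | None = None
    population_growth: tuple[float, ...] = (1.08, 1.06, 1.04, 1.02)
    rcm_temp_bias: float = 1.5
    rcm_rain_factor: float = 0.85

    def __post_init__(self) -> None:
        if self.ssp_id not in _SSP_PAIRING:
            raise InvalidArgumentError(f"unknown SSP {self.ssp_id!r}")
        rcp, rcms = _SSP_PAIRING[self.ssp_id]
        if self.rcp_id != rcp:
            raise InvalidArgumentError(f"{self.ssp_id} pairs with RCP {rcp!r}, not {self.rcp_id!r}")
        if self.rcm_id not in rcms:
            raise InvalidArgumentError(f"{self.ssp_id} admits RCMs {rcms}, not {self.rcm_id!r}")

    @property
    def name(self) -> str:
        return f"{self.ssp_id}-{self.rcp_id}-{self.rcm_id}"


@dataclass
class ScenarioRun:
    """Annual coarse-grid outputs of one scenario projection."""

    scenario: Scenario
    years: np.ndarray
    coarse_lattice: Lattice
    incidence: np.ndarray          # (n_years, R, C) expected cases per coarse cell
    population: np.ndarray         # (n_years, R, C) persons per coarse cell
    landcover_coarse: dict[int, LandCoverMap]
    abundance_coarse: dict[int, SpeciesAbundanceSet]
    landcover_fine: dict[int, LandCoverMap] = field(default_factory=dict)


@dataclass
class ChangeSummary:
    """Per-pixel and national change statistics for one scenario."""

    slope: np.ndarray              # per-cell OLS slope of incidence vs year
    pct: np.ndarray                # per-cell % change 2010 -> 2050 (NaN where masked)
    national: pd.DataFrame         # year, pct_change, se
    transitions: pd.DataFrame


# ---------------------------------------------------------------------------
# Upscaling
# ---------------------------------------------------------------------------

def _blocks(arr: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = arr.shape
    if nr % factor or nc % factor:
        raise InvalidArgumentError(
            f"dimensions {arr.shape} not divisible by factor {factor}"
        )
    return arr.reshape(nr // factor, factor, nc // factor, factor)


def upscale_sum(layer: np.ndarray, factor: int = 5) -> np.ndarray:
    """Aggregate each factor x factor block by summation (total conserved)."""
    return _blocks(np.asarray(layer, dtype=float), factor).sum(axis=(1, 3))


def upscale_majority(landcover: LandCoverMap, factor: int = 5) -> LandCoverMap:
    """Coarse class = modal class per block; ties go to the lowest class code."""
    b = _blocks(landcover.classes.astype(float), factor)
    counts = np.stack(
        [(b == k).sum(axis=(1, 3)) for k in range(N_CLASSES)]
    )  # (5, R, C)
    coarse = np.argmax(counts, axis=0)  # first maximum = lowest class index
    R, C = coarse.shape
    lat = landcover.lattice
    coarse_lat = make_lattice(
        R, C, lat.cell_size * factor, lat.origin, lat.crs_label
    )
    return LandCoverMap(coarse_lat, coarse)


# ---------------------------------------------------------------------------
# Scenario pipeline
# ---------------------------------------------------------------------------

def _scenario_climate(scenario: Scenario, fixture: SyntheticTruth, years: np.ndarray) -> ClimateStack:
    """Deterministic trend continuation for SSP1; bias-corrected RCM stack otherwise."""
    need = np.arange(years[0] - 2, years[-1] + 1)
    if scenario.rcm_id == "historical-trend":
        # smooth projection of the observed reference climatology: the
        # no-further-emissions pathway extends the historical trend with
        # no resimulated interannual weather
        ref_years = fixture.climate.years[fixture.climate.years <= years[0]]
        clim = fixture.climate.subset_years(ref_years).climatology()
        ny = need.size
        decades = (need - years[0]) / 10.0
        warm = scenario.trend.warming_per_decade * decades
        rmult = scenario.trend.rain_multiplier_per_decade**decades
        tmin = clim["tmin"][None] + warm[:, None, None, None]
        tmax = clim["tmax"][None] + warm[:, None, None, None]
        rain = clim["rain"][None] * rmult[:, None, None, None]
        return ClimateStack(fixture.lattice, need, tmin, tmax, rain)
    rcm_index = _SSP_PAIRING[scenario.ssp_id][1].index(scenario.rcm_id)
    raw = gen_climate(
        fixture.lattice, need, scenario.trend,
        seed=int(np.random.SeedSequence([fixture.seed, 7, rcm_index]).generate_state(1)[0] % (2**31)),
    )
    # systematic RCM bias the delta correction must remove
    modelled = ClimateStack(
        raw.lattice, raw.years,
        raw.tmin + scenario.rcm_temp_bias,
        raw.tmax + scenario.rcm_temp_bias,
        raw.rain * scenario.rcm_rain_factor,
    )
    ref_years = np.intersect1d(fixture.climate.years, need[need <= years[0]])
    if ref_years.size == 0:
        raise InvalidArgumentError("no overlapping reference years for bias correction")
    obs_ref = fixture.climate.subset_years(ref_years)
    mod_ref = modelled.subset_years(ref_years)
    corr_t = difference_correction(obs_ref, mod_ref, variables=("tmin", "tmax"))
    corr_r = ratio_correction(obs_ref, mod_ref, variables=("rain",))
    corrected = apply_delta(apply_delta(modelled, corr_t), corr_r)
    return corrected


def _scenario_population(scenario: Scenario, fixture: SyntheticTruth, years: np.ndarray) -> PopulationSeries:
    """Decadal densities from the 2010 base under the scenario growth, then PCHIP."""
    base = fixture.population.layer(int(years[0]))
    urban = fixture.landcover.mask("urban").astype(float)
    decades = np.arange(years[0], years[-1] + 1, 10)
    growth = np.asarray(scenario.population_growth, dtype=float)
    if growth.size != decades.size - 1:
        raise InvalidArgumentError("population growth must cover each decade interval")
    layers = [base]
    for g in growth:
        prev = layers[-1]
        w = 1.0 + urban
        w = w * prev.sum() / (prev * w).sum() if (prev * w).sum() > 0 else w
        layers.append(prev * (1.0 + (g - 1.0) * w))
    decadal = PopulationSeries(fixture.lattice, decades, np.stack(layers))
    return hermite_annual(decadal, years)


def _climate_standardizer(summaries: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    return {
        k: (float(v.mean()), float(max(v.std(), 1e-12))) for k, v in summaries.items()
    }


def _abundance_covariates(
    summaries: dict[str, np.ndarray],
    landcover: LandCoverMap,
    standardizer: dict[str, tuple[float, float]],
    niche: NicheModel,
) -> dict[str, np.ndarray]:
    lc = derived_covariates(landcover)
    m_t, s_t = standardizer["mean_tmax"]
    m_r, s_r = standardizer["total_rain"]
    clim_layers = {"mean_tmax": summaries["mean_tmax"], "total_rain": summaries["total_rain"]}
    return {
        "z_tmax": (summaries["mean_tmax"] - m_t) / s_t,
        "z_rain": (summaries["total_rain"] - m_r) / s_r,
        "prop_agriculture": lc["prop_agriculture"],
        "dist_forest": lc["dist_forest"],
        "niche_dist": niche_distance(niche, clim_layers),
    }


def fit_species_models(
    fixture: SyntheticTruth, baseline_summaries: dict[str, np.ndarray]
) -> dict[str, dict]:
    """Per-species niche models and intensity coefficients from occurrences."""
    if fixture.occurrences is None:
        raise InvalidArgumentError("fixture carries no occurrence points")
    lat = fixture.lattice
    standardizer = _climate_standardizer(baseline_summaries)
    clim_layers = {
        "mean_tmax": baseline_summaries["mean_tmax"],
        "total_rain": baseline_summaries["total_rain"],
    }
    out = {}
    for sp in SPECIES:
        pts = fixture.occurrences[fixture.occurrences["species"] == sp]
        niche = estimate_niche(pts, clim_layers, lat)
        cells = lat.cell_of_point(pts["x"].to_numpy(), pts["y"].to_numpy())
        counts = np.bincount(cells, minlength=lat.n_cells).reshape(lat.shape)
        cov = _abundance_covariates(baseline_summaries, fixture.landcover, standardizer, niche)
        coeffs = fit_abundance_model(counts, cov, cell_area=lat.cell_area)
        out[sp] = {"niche": niche, "coefficients": coeffs, "standardizer": standardizer}
    return out


def run_scenario(
    scenario: Scenario,
    fitted: EnvenomingParams,
    fixture: SyntheticTruth,
    years=range(2010, 2051),
    upscale_factor: int = 5,
    elasticity: float = 4.0,
    rules: TransitionRules | None = None,
    demand: DemandTrajectory | None = None,
    store_landcover_fine: bool = False,
) -> ScenarioRun:
    """Project annual envenoming incidence under one scenario.

    Every stage is deterministic given the fixture seed and scenario
    identifiers.  Errors from pipeline stages are re-raised tagged with
    the stage and year.
    """
    years = np.asarray(list(years), dtype=int)
    lat = fixture.lattice
    climate = _scenario_climate(scenario, fixture, years)

    pop = _scenario_population(scenario, fixture, years)

    # land cover demand and location factors
    start_lc = fixture.landcover
    counts0 = start_lc.counts()
    if demand is None:
        if scenario.demand_end_shares is None:
            end_counts = counts0.copy()
        else:
            shares = np.asarray(scenario.demand_end_shares, dtype=float)
            if abs(shares.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError("demand_end_shares must sum to 1")
            end_counts = np.floor(shares * lat.n_cells).astype(int)
            end_counts[np.argmax(end_counts)] += lat.n_cells - end_counts.sum()
        demand = DemandTrajectory.linear(counts0, end_counts, years)

    elev = elevation_surface(lat)
    base_summ = rolling_climate_mean(climate, int(years[0]), window=3)

    def lc_drivers(year: int):
        summ = rolling_climate_mean(climate, int(year), window=3)
        return [
            RasterLayer(lat, np.log1p(pop.layer(int(year)))),
            RasterLayer(lat, elev / 1000.0),
            RasterLayer(lat, summ["mean_tmax"]),
        ]

    try:
        factors = fit_location_factors(start_lc, lc_drivers(int(years[0])))
    except Exception as exc:  # noqa: BLE001 - tag stage and re-raise
        raise type(exc)(f"stage=location_factors year={years[0]}: {exc}") from exc

    drivers_by_year = {int(y): lc_drivers(int(y)) for y in years[1:]}
    try:
        lc_by_year = simulate_landcover(
            start_lc, demand, factors, drivers_by_year, rules, elasticity
        )
    except Exception as exc:  # noqa: BLE001
        raise type(exc)(f"stage=landcover_allocation: {exc}") from exc

    species_models = fit_species_models(fixture, base_summ)
    weights = fixture.species.weights

    R, C = lat.n_rows // upscale_factor, lat.n_cols // upscale_factor
    incid = np.empty((years.size, R, C))
    pop_coarse = np.empty((years.size, R, C))
    lc_coarse: dict[int, LandCoverMap] = {}
    ab_coarse: dict[int, SpeciesAbundanceSet] = {}
    h2010_coarse = None

    for iy, year in enumerate(years):
        year = int(year)
        try:
            summ = rolling_climate_mean(climate, year, window=3)
            lc_y = lc_by_year[year]
            S_layers = {}
            for sp in SPECIES:
                m = species_models[sp]
                cov = _abundance_covariates(summ, lc_y, m["standardizer"], m["niche"])
                S_layers[sp] = project_abundance(
                    m["coefficients"], cov, cell_area=lat.cell_area
                )
            S_fine = apply_expert_weights(
                SpeciesAbundanceSet(lat, S_layers), weights
            )
            # upscale to the model grid: block sums aggregate intensity and
            # population; the model consumes per-km^2 intensities (sums over
            # block area) so the 1 km-scale parameters keep their meaning,
            # while the case multiplier uses the total coarse population
            block = upscale_factor**2
            S_c = SpeciesAbundanceSet(
                make_lattice(R, C, lat.cell_size * upscale_factor, lat.origin, lat.crs_label),
                {sp: upscale_sum(S_fine.layers[sp], upscale_factor) / block for sp in SPECIES},
                dict(weights),
            )
            H_c = upscale_sum(pop.layer(year) * lat.cell_area, upscale_factor)
            lc_c = upscale_majority(lc_y, upscale_factor)
            if h2010_coarse is None:
                h2010_coarse = RasterLayer(
                    lc_c.lattice, upscale_sum(pop.layer(year), upscale_factor) / block,
                    units="persons/km2",
                )
            incid[iy] = forward_incidence(lc_c, h2010_coarse, H_c, S_c, fitted, rho=0.0)
            pop_coarse[iy] = H_c
            if year in (years[0], years[-1]):
                lc_coarse[year] = lc_c
                ab_coarse[year] = S_c
        except Exception as exc:  # noqa: BLE001
            raise type(exc)(f"stage=projection year={year}: {exc}") from exc

    return ScenarioRun(
        scenario=scenario,
        years=years,
        coarse_lattice=lc_coarse[int(years[0])].lattice,
        incidence=incid,
        population=pop_coarse,
        landcover_coarse=lc_coarse,
        abundance_coarse=ab_coarse,
        landcover_fine=dict(lc_by_year) if store_landcover_fine else {},
    )


# ---------------------------------------------------------------------------
# Change statistics
# ---------------------------------------------------------------------------

def pixel_trend(series: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Per-cell OLS slope of incidence against calendar year."""
    series = np.asarray(series, dtype=float)
    years = np.asarray(years, dtype=float)
    if years.size < 3:
        raise InvalidArgumentError("need at least 3 years for a trend")
    t = years - years.mean()
    flat = series.reshape(years.size, -1)
    slope = (t @ (flat - flat.mean(axis=0))) / (t @ t)
    return slope.reshape(series.shape[1:])


def pct_change(inc_start: np.ndarray, inc_end: np.ndarray) -> np.ndarray:
    """100 * (end - start) / start, NaN-masked where start is zero."""
    a0 = np.asarray(inc_start, dtype=float)
    a1 = np.asarray(inc_end, dtype=float)
    if a0.shape != a1.shape:
        raise InvalidArgumentError("layers misaligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (a1 - a0) / a0
    out[a0 == 0] = np.nan
    return out


def national_series(
    series: np.ndarray, population: np.ndarray, years: np.ndarray
) -> pd.DataFrame:
    """Accumulated national percentage change with propagated SE per year.

    The national incidence rate (total cases over total population) is
    regressed on year; accumulated change at year t is the fitted change
    since the first year relative to the fitted baseline, with the SE
    scaled from the slope's standard error.
    """
    years = np.asarray(years, dtype=float)
    if years.size < 3:
        raise InvalidArgumentError("need at least 3 years")
    cases = np.asarray(series, dtype=float).reshape(years.size, -1).sum(axis=1)
    pop = np.asarray(population, dtype=float).reshape(years.size, -1).sum(axis=1)
    rate = cases / pop
    t = years - years.mean()
    slope = float((t @ (rate - rate.mean())) / (t @ t))
    resid = rate - (rate.mean() + slope * t)
    dof = years.size - 2
    se_slope = float(np.sqrt((resid @ resid) / dof / (t @ t)))
    base = rate.mean() + slope * (years[0] - years.mean())
    dt = years - years[0]
    return pd.DataFrame(
        {
            "year": years.astype(int),
            "rate": rate,
            "pct_change": 100.0 * slope * dt / base,
            "se": 100.0 * se_slope * dt / base,
        }
    )


def rcm_consensus(slope_layers: list[np.ndarray]) -> tuple[np.ndarray, dict[int, float]]:
    """Count RCMs projecting strictly decreasing incidence per cell.

    Returns the per-cell count (0..len(layers)) and the fraction of the
    total area in each count.
    """
    if not slope_layers:
        raise InvalidArgumentError("need at least one slope layer")
    stack = np.stack([np.asarray(s, dtype=float) for s in slope_layers])
    consensus = (stack < 0).sum(axis=0)
    n = consensus.size
    fractions = {
        k: float((consensus == k).sum() / n) for k in range(len(slope_layers) + 1)
    }
    return consensus, fractions


def dominant_species(
    S: SpeciesAbundanceSet, params: EnvenomingParams, weighting: str = "cb"
) -> np.ndarray:
    """Per-cell index of the most abundant species, coefficient-weighted.

    The default weight is c_s * S_s * exp(b_s), using both printed
    coefficient families; ``weighting="c"`` uses c_s * S_s only.  Ties
    go to the lower species index.
    """
    if not S.layers:
        raise InvalidArgumentError("empty abundance set")
    if weighting not in ("cb", "c"):
        raise InvalidArgumentError(f"unknown weighting {weighting!r}")
    names = S.species
    idx = [SPECIES.index(n) for n in names]
    w = params.c[idx] * (np.exp(params.b[idx]) if weighting == "cb" else 1.0)
    stack = np.stack([w[i] * S.layers[n] for i, n in enumerate(names)])
    return np.argmax(stack, axis=0)


def transition_change_summary(
    lc_start: LandCoverMap, lc_end: LandCoverMap, pct: np.ndarray
) -> pd.DataFrame:
    """Percentage-change distribution per observed land cover transition.

    One row per (from, to) pair present in the maps: cell count, median,
    IQR bounds and the 2.5th/97.5th percentiles of the per-cell
    percentage change; NaN-masked cells are ignored within a transition.
    """
    if lc_start.lattice.shape != lc_end.lattice.shape:
        raise InvalidArgumentError("maps misaligned")
    pct = np.asarray(pct, dtype=float)
    rows = []
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            sel = (lc_start.classes == i) & (lc_end.classes == j)
            if not sel.any():
                continue
            vals = pct[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append(
                {
                    "from": CLASSES[i],
                    "to": CLASSES[j],
                    "n_cells": int(sel.sum()),
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                    "p2.5": float(np.percentile(vals, 2.5)),
                    "p97.5": float(np.percentile(vals, 97.5)),
                }
            )
    return pd.DataFrame(rows, columns=["from", "to", "n_cells", "median", "q25", "q75", "p2.5", "p97.5"])


def summarize_run(run: ScenarioRun) -> ChangeSummary:
    """All change statistics for one scenario run."""
    slope = pixel_trend(run.incidence, run.years)
    pct = pct_change(run.incidence[0], run.incidence[-1])
    national = national_series(run.incidence, run.population, run.years)
    y0, y1 = int(run.years[0]), int(run.years[-1])
    transitions = transition_change_summary(
        run.landcover_coarse[y0], run.landcover_coarse[y1], pct
    )
    return ChangeSummary(slope=slope, pct=pct, national=national, transitions=transitions)
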