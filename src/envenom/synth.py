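"""Synthetic raster landscapes and forward-simulated envenoming data.

Generates inputs with the statistical structure of the study system —
spatially autocorrelated monthly climate with scenario trends over a
fixed elevation-like gradient, a five-class land cover mosaic, decadal
population grids with growth, seven species abundance surfaces driven by
climate, land-cover covariates and niche-centroid distance, and
envenoming counts drawn from the forward model — so that every
downstream stage is testable without external downloads.

All randomness flows from one master seed through documented
``numpy.random.SeedSequence`` streams: (seed, 0) climate, (seed, 1)
land cover, (seed, 2) population, (seed, 3) species, (seed, 4) the
ICAR field, and (seed, 5, year) incidence draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .abundance import SPECIES, SpeciesAbundanceSet
from .climate import ClimateStack, bioclim_summaries
from .errors import ChecksumError, InvalidArgumentError
from .landcover import CLASSES, N_CLASSES, LandCoverMap, derived_covariates
from .lattice import Lattice, RasterLayer, make_lattice
from .model import EnvenomingParams, ObservedIncidence, forward_incidence, sample_car
from .population import PopulationSeries
from . import raster_io

__all__ = [
    "TrendSpec",
    "SyntheticTruth",
    "gen_climate",
    "gen_landcover",
    "gen_population",
    "gen_species_truth",
    "simulate_incidence",
    "default_params",
    "default_species_spec",
    "make_default_truth",
    "write_fixture",
    "read_fixture",
]


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), *stream])))


def _smooth_field(rng: np.random.Generator, shape, width: int) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed by a moving-average kernel."""
    f = ndimage.uniform_filter(rng.standard_normal(shape), size=width, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def elevation_surface(lattice: Lattice, peak_m: float = 1800.0) -> np.ndarray:
    """Fixed central-hill elevation gradient (m), highlands mid-grid."""
    r, c = np.indices(lattice.shape)
    rc, cc = 0.58 * lattice.n_rows, 0.52 * lattice.n_cols
    sig = 0.22 * max(lattice.n_rows, lattice.n_cols)
    return peak_m * np.exp(-(((r - rc) ** 2) + (c - cc) ** 2) / (2 * sig**2))


@dataclass(frozen=True)
class TrendSpec:
    """Scenario climate trend: per-decade warming (degC) and rain multiplier."""

    warming_per_decade: float = 0.0
    rain_multiplier_per_decade: float = 1.0

    def __post_init__(self) -> None:
        if self.rain_multiplier_per_decade <= 0:
            raise InvalidArgumentError("rain multiplier must be > 0")


def gen_climate(
    lattice: Lattice,
    years,
    trend: TrendSpec = TrendSpec(),
    seed: int = 0,
    smooth_width: int = 5,
    interannual_sd: float = 0.25,
    spatial_sd: float = 0.6,
) -> ClimateStack:
    """Monthly tmin/tmax/rain stacks with trends over an elevation gradient.

    Temperatures follow a lowland seasonal cycle minus a 6.5 degC/km
    lapse over the fixed elevation surface, plus smoothed random fields;
    rainfall is seasonal, wetter on the highlands, with multiplicative
    lognormal noise.  Trends accrue linearly (temperature) or
    geometrically (rainfall) per decade from the first year.
    """
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise InvalidArgumentError("empty year range")
    rng = _rng(seed, 0)
    elev = elevation_surface(lattice)
    months = np.arange(12)
    season_t = 1.5 * np.cos(2 * np.pi * (months - 3) / 12)
    season_r = 150.0 + 120.0 * np.sin(2 * np.pi * (months - 4) / 12) ** 2
    lapse = 6.5e-3 * elev  # degC
    wetness = 1.0 + 0.0004 * elev

    ny = years.size
    tmax = np.empty((ny, 12, *lattice.shape))
    tmin = np.empty_like(tmax)
    rain = np.empty_like(tmax)
    for iy, year in enumerate(years):
        decades = (year - years[0]) / 10.0
        warm = trend.warming_per_decade * decades
        rmult = trend.rain_multiplier_per_decade**decades
        year_anom = rng.normal(0.0, interannual_sd)
        for m in range(12):
            noise_t = spatial_sd * _smooth_field(rng, lattice.shape, smooth_width)
            noise_r = _smooth_field(rng, lattice.shape, smooth_width)
            tmax[iy, m] = 30.0 + season_t[m] - lapse + warm + year_anom + noise_t
            drange = np.maximum(8.0 + 1.0 * _smooth_field(rng, lattice.shape, smooth_width), 2.0)
            tmin[iy, m] = tmax[iy, m] - drange
            rain[iy, m] = season_r[m] * wetness * rmult * np.exp(0.15 * noise_r)
    return ClimateStack(lattice, years, tmin, tmax, rain)


def gen_landcover(
    lattice: Lattice,
    class_fractions=(0.30, 0.20, 0.30, 0.10, 0.10),
    smoothness: float = 3.0,
    seed: int = 0,
) -> LandCoverMap:
    """Five-class mosaic whose realized shares match requested fractions.

    Per-class smoothed score fields compete for cells; classes claim
    their quota of highest-scoring unassigned cells in turn, so realized
    counts differ from targets only by integer rounding.
    """
    fractions = np.asarray(class_fractions, dtype=float)
    if fractions.shape != (N_CLASSES,):
        raise InvalidArgumentError("need one fraction per land cover class")
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise InvalidArgumentError("fractions must be >= 0 and sum to 1")
    rng = _rng(seed, 1)
    width = max(int(round(smoothness)), 1)
    scores = np.stack(
        [_smooth_field(rng, lattice.shape, width).ravel() for _ in range(N_CLASSES)]
    )
    n = lattice.n_cells
    quota = np.floor(fractions * n).astype(int)
    quota[np.argmax(quota)] += n - quota.sum()
    out = np.full(n, -1, dtype=np.intp)
    unassigned = np.ones(n, dtype=bool)
    for k in np.argsort(-quota):  # biggest class first
        if quota[k] == 0:
            continue
        idx = np.flatnonzero(unassigned)
        take = idx[np.argsort(-scores[k, idx], kind="stable")[: quota[k]]]
        out[take] = k
        unassigned[take] = False
    out[out < 0] = 0
    return LandCoverMap(lattice, out)


def gen_population(
    lattice: Lattice,
    base_density: float = 300.0,
    growth=(1.08, 1.06, 1.04, 1.02),
    urban_bias: float = 1.0,
    seed: int = 0,
    urban_mask: np.ndarray | None = None,
    years=(2010, 2020, 2030, 2040, 2050),
) -> PopulationSeries:
    """Decadal density grids with growth concentrated near urban cells.

    National totals multiply exactly by each decade's growth factor; when
    ``urban_bias`` > 0 the increment is weighted towards urban cells (or,
    lacking a mask, the densest cells) with weights renormalised so the
    total is conserved.
    """
    if base_density < 0:
        raise InvalidArgumentError("negative base density")
    growth = np.asarray(growth, dtype=float)
    years = np.asarray(years, dtype=int)
    if growth.size != years.size - 1:
        raise InvalidArgumentError("need one growth multiplier per decade interval")
    if np.any(growth <= 0):
        raise InvalidArgumentError("growth multipliers must be > 0")
    rng = _rng(seed, 2)
    # lognormal spread wide enough to span rural hamlets to dense towns
    base = base_density * np.exp(1.2 * _smooth_field(rng, lattice.shape, 5))
    base *= base_density / base.mean() if base.mean() > 0 else 1.0
    if urban_mask is None:
        urban_proxy = (base > np.quantile(base, 0.85)).astype(float)
    else:
        urban_proxy = np.asarray(urban_mask, dtype=float).reshape(lattice.shape)
    layers = [base]
    for g in growth:
        prev = layers[-1]
        w = 1.0 + urban_bias * urban_proxy
        w = w * prev.sum() / (prev * w).sum() if (prev * w).sum() > 0 else w
        layers.append(prev * (1.0 + (g - 1.0) * w))
    return PopulationSeries(lattice, years, np.stack(layers))


def default_species_spec() -> pd.DataFrame:
    """True per-species intensity coefficients for the seven taxa.

    Columns: log-intensity intercept; slopes on standardized annual mean
    tmax and total rainfall; slopes on proportion agriculture, distance
    to forest (per km) and niche-centroid distance; and the niche
    centroid in standardized (tmax, rain) space.  Dry-zone taxa centre on
    warm/dry conditions, wet-zone taxa on cool/wet ones.
    """
    rows = {
        #                     int   tmax   rain   agri  dfor  niche  n_tmax n_rain
        "Bungarus caeruleus":          (0.0,  0.25, -0.20, 0.50, 0.05, -0.80,  1.5, -1.2),
        "Bungarus ceylonicus":         (-0.4, -0.20,  0.25, 0.00, -0.15, -1.00, -1.5,  1.2),
        "Daboia russelii":             (0.2,  0.20, -0.10, 0.60, 0.05, -0.60,  0.6, -0.2),
        "Echis carinatus":             (-0.5,  0.30, -0.30, 0.20, 0.10, -1.20,  2.0, -1.8),
        "Hypnale spp":                 (0.3, -0.15,  0.20, 0.30, -0.10, -0.70, -0.6,  0.8),
        "Naja naja":                   (0.1,  0.10, -0.05, 0.50, 0.05, -0.50,  0.2,  0.3),
        "Trimeresurus trigonocephalus": (-0.3, -0.25,  0.25, 0.00, -0.20, -1.00, -1.8,  1.6),
    }
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["intercept", "b_tmax", "b_rain", "b_agri", "b_dforest",
                 "b_niche", "niche_tmax", "niche_rain"],
    )


def species_covariates(
    climate: ClimateStack, landcover: LandCoverMap, year: int | None = None,
    summaries: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Standardized climate plus land-cover covariates for intensity models."""
    if summaries is None:
        summaries = bioclim_summaries(climate, int(year if year is not None else climate.years[0]))
    lc = derived_covariates(landcover)
    z_tmax = summaries["mean_tmax"]
    z_rain = summaries["total_rain"]
    return {
        "z_tmax": (z_tmax - z_tmax.mean()) / max(z_tmax.std(), 1e-12),
        "z_rain": (z_rain - z_rain.mean()) / max(z_rain.std(), 1e-12),
        "prop_agriculture": lc["prop_agriculture"],
        "dist_forest": lc["dist_forest"],
    }


def _species_surface(row: pd.Series, cov: dict[str, np.ndarray]) -> np.ndarray:
    niche_dist = np.sqrt(
        (cov["z_tmax"] - row["niche_tmax"]) ** 2 + (cov["z_rain"] - row["niche_rain"]) ** 2
    )
    eta = (
        row["intercept"]
        + row["b_tmax"] * cov["z_tmax"]
        + row["b_rain"] * cov["z_rain"]
        + row["b_agri"] * cov["prop_agriculture"]
        + row["b_dforest"] * cov["dist_forest"]
        + row["b_niche"] * niche_dist
    )
    return np.exp(eta)


def gen_species_truth(
    lattice: Lattice,
    climate: ClimateStack,
    landcover: LandCoverMap,
    spec: pd.DataFrame | None = None,
    seed: int = 0,
    n_points: int = 150,
) -> tuple[SpeciesAbundanceSet, pd.DataFrame]:
    """True abundance index surfaces plus sampled occurrence points.

    Surfaces are log-linear in the covariates of
    :func:`species_covariates` and the distance to each species' niche
    centroid; occurrences are a multinomial draw over cells with
    probability proportional to intensity, jittered within the cell.
    """
    spec = default_species_spec() if spec is None else spec
    missing = [s for s in SPECIES if s not in spec.index]
    if missing:
        raise InvalidArgumentError(f"species missing from spec: {missing}")
    rng = _rng(seed, 3)
    cov = species_covariates(climate, landcover)
    layers: dict[str, np.ndarray] = {}
    records = []
    xs, ys = lattice.cell_centres()
    for name in SPECIES:
        S = _species_surface(spec.loc[name], cov)
        layers[name] = S
        p = S.ravel() / S.sum()
        counts = rng.multinomial(n_points, p)
        cells = np.repeat(np.arange(lattice.n_cells), counts)
        jx = rng.uniform(-0.5, 0.5, cells.size) * lattice.cell_size
        jy = rng.uniform(-0.5, 0.5, cells.size) * lattice.cell_size
        for cell, dx, dy in zip(cells, jx, jy):
            records.append({"species": name, "x": xs[cell] + dx, "y": ys[cell] + dy})
    occ = pd.DataFrame.from_records(records, columns=["species", "x", "y"])
    return SpeciesAbundanceSet(lattice, layers), occ


def default_params() -> EnvenomingParams:
    """Plausible generating parameters for the default synthetic system.

    Contact is highest in agriculture and tea, lowest in urban cells;
    Russell's viper and the hump-nosed vipers carry the largest species
    contact rates, matching their prominence among biting species.
    """
    return EnvenomingParams(
        beta0=np.array([-5.0, -4.6, -4.0, -5.6, -4.3]),
        beta1=np.array([0.12, 0.10, 0.10, -0.15, 0.08]),
        c=np.array([0.25, 0.10, 0.35, 0.15, 0.40, 0.30, 0.12]),
        B0=-1.0,
        B=np.array([0.40, 0.30, 0.20, -0.30, 0.10]),
        b=np.array([0.15, 0.05, 0.25, 0.10, 0.20, 0.15, 0.05]),
        tau=1000.0,
    )


@dataclass
class SyntheticTruth:
    """A fully specified synthetic study system on one lattice."""

    params: EnvenomingParams
    species: SpeciesAbundanceSet
    population: PopulationSeries
    landcover: LandCoverMap
    climate: ClimateStack
    rho: np.ndarray
    seed: int
    occurrences: pd.DataFrame | None = None
    species_spec: pd.DataFrame = field(default_factory=default_species_spec)

    def __post_init__(self) -> None:
        shapes = {
            self.species.lattice.shape,
            self.population.lattice.shape,
            self.landcover.lattice.shape,
            self.climate.lattice.shape,
        }
        if len(shapes) != 1:
            raise InvalidArgumentError("truth layers live on different lattices")
        self.rho = np.asarray(self.rho, dtype=float).reshape(-1)

    @property
    def lattice(self) -> Lattice:
        return self.landcover.lattice

    def population_cells(self, year: int) -> np.ndarray:
        """Persons per cell (density times cell area) for one year."""
        return self.population.layer(year) * self.lattice.cell_area

    def h2010_layer(self) -> RasterLayer:
        return RasterLayer(self.lattice, self.population_cells(int(self.population.years[0])),
                           units="persons")

    def expected_incidence(self, year: int) -> np.ndarray:
        """Closed-form dHe for one year under the true parameters."""
        H = self.population_cells(year)
        return forward_incidence(
            self.landcover, self.h2010_layer(), H, self.species, self.params,
            rho=self.rho.reshape(self.lattice.shape),
        )


def simulate_incidence(truth: SyntheticTruth, year: int, seed: int = 0) -> ObservedIncidence:
    """Draw per-cell envenoming counts around the closed-form mean.

    Counts are Poisson with mean dHe, capped at the cell population so
    the observation invariant y <= H holds in the rare extreme draw.
    """
    if year not in truth.population.years and not (
        truth.population.years[0] <= year <= truth.population.years[-1]
    ):
        raise InvalidArgumentError(f"year {year} outside truth range")
    mu = truth.expected_incidence(year)
    H = truth.population_cells(year)
    rng = _rng(seed, 5, int(year))
    counts = np.minimum(rng.poisson(mu).astype(float), np.floor(H))
    return ObservedIncidence(truth.lattice, counts, H, int(year))


def make_default_truth(
    seed: int = 0,
    n_rows: int = 20,
    n_cols: int = 20,
    years=range(2008, 2051),
    trend: TrendSpec = TrendSpec(),
    class_fractions=(0.30, 0.20, 0.30, 0.10, 0.10),
    base_density: float = 300.0,
    growth=(1.08, 1.06, 1.04, 1.02),
    params: EnvenomingParams | None = None,
) -> SyntheticTruth:
    """Assemble the default 20x20 synthetic study system.

    The default lattice is 20x20 at 1 km cells so that 5x block
    upscaling yields a 4x4 coarse grid; climate starts in 2008 so a
    3-year rolling window exists for every projection year from 2010.
    """
    lattice = make_lattice(n_rows, n_cols, 1.0)
    params = params or default_params()
    clim = gen_climate(lattice, years, trend, seed)
    lc = gen_landcover(lattice, class_fractions, seed=seed)
    pop = gen_population(
        lattice, base_density, growth, urban_bias=1.0, seed=seed,
        urban_mask=lc.mask("urban"),
    )
    species, occ = gen_species_truth(lattice, clim, lc, seed=seed)
    rho = sample_car(lattice, params.tau, _rng(seed, 4))
    return SyntheticTruth(params, species, pop, lc, clim, rho, seed, occurrences=occ)


# ---------------------------------------------------------------------------
# Fixture persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(truth: SyntheticTruth, directory: str | Path) -> dict:
    """Persist a truth object: rasters as TIFF, tables as CSV, manifest JSON.

    The manifest records the master seed and a sha256 checksum per file;
    :func:`read_fixture` refuses tampered fixtures.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lat = truth.lattice
    files: dict[str, str] = {}

    def _save(name: str, arr: np.ndarray) -> None:
        raster_io.write_layer(directory / name, arr, lat)
        files[name] = _sha256(directory / name)

    _save("landcover.tif", truth.landcover.classes.astype(np.int32) + 1)
    _save("rho.tif", truth.rho.reshape(lat.shape))
    for i, year in enumerate(truth.population.years):
        _save(f"population_{year}.tif", truth.population.density[i])
    for s in truth.species.species:
        safe = s.replace(" ", "_").replace(".", "")
        _save(f"abundance_{safe}.tif", truth.species.layers[s])
    import tifffile

    ny = len(truth.climate.years)
    for var in ("tmin", "tmax", "rain"):
        arr = truth.climate.get(var).reshape(ny * 12, *lat.shape)
        tifffile.imwrite(str(directory / f"climate_{var}.tif"), arr)
        files[f"climate_{var}.tif"] = _sha256(directory / f"climate_{var}.tif")
    if truth.occurrences is not None:
        truth.occurrences.to_csv(directory / "occurrences.csv", index=False)
        files["occurrences.csv"] = _sha256(directory / "occurrences.csv")
    truth.species_spec.to_csv(directory / "species_spec.csv")
    files["species_spec.csv"] = _sha256(directory / "species_spec.csv")
    names, vec = truth.params.to_vector()
    manifest = {
        "seed": int(truth.seed),
        "lattice": {
            "n_rows": lat.n_rows, "n_cols": lat.n_cols, "cell_size": lat.cell_size,
            "origin": list(lat.origin), "crs_label": lat.crs_label,
        },
        "params": dict(zip(names, map(float, vec))),
        "expert_weights": truth.species.weights,
        "climate_years": truth.climate.years.tolist(),
        "population_years": truth.population.years.tolist(),
        "files": files,
    }
    raster_io.write_json(directory / "manifest.json", manifest)
    return manifest


def read_fixture(directory: str | Path) -> SyntheticTruth:
    """Load a fixture written by :func:`write_fixture`, verifying checksums."""
    import tifffile

    directory = Path(directory)
    manifest = raster_io.read_json(directory / "manifest.json")
    for name, digest in manifest["files"].items():
        actual = _sha256(directory / name)
        if actual != digest:
            raise ChecksumError(f"checksum mismatch for {name}")
    latspec = manifest["lattice"]
    lat = Lattice(
        latspec["n_rows"], latspec["n_cols"], latspec["cell_size"],
        tuple(latspec["origin"]), latspec["crs_label"],
    )
    p = manifest["params"]
    params = EnvenomingParams(
        beta0=[p[f"beta0[{c}]"] for c in CLASSES],
        beta1=[p[f"beta1[{c}]"] for c in CLASSES],
        c=[p[f"c[{s}]"] for s in SPECIES],
        B0=p["B0"],
        B=[p[f"B[{c}]"] for c in CLASSES],
        b=[p[f"b[{s}]"] for s in SPECIES],
        tau=p["tau"],
    )
    lc_arr, _ = raster_io.read_layer(directory / "landcover.tif")
    landcover = LandCoverMap(lat, lc_arr.astype(np.intp) - 1)
    rho, _ = raster_io.read_layer(directory / "rho.tif")
    pop_years = manifest["population_years"]
    dens = np.stack(
        [raster_io.read_layer(directory / f"population_{y}.tif")[0] for y in pop_years]
    )
    population = PopulationSeries(lat, pop_years, dens)
    layers = {}
    for s in SPECIES:
        safe = s.replace(" ", "_").replace(".", "")
        layers[s], _ = raster_io.read_layer(directory / f"abundance_{safe}.tif")
    species = SpeciesAbundanceSet(lat, layers, dict(manifest["expert_weights"]))
    years = manifest["climate_years"]
    stacks = {}
    for var in ("tmin", "tmax", "rain"):
        arr = tifffile.imread(str(directory / f"climate_{var}.tif"))
        stacks[var] = arr.reshape(len(years), 12, *lat.shape)
    climate = ClimateStack(lat, years, stacks["tmin"], stacks["tmax"], stacks["rain"])
    occ = None
    if (directory / "occurrences.csv").exists():
        occ = pd.read_csv(directory / "occurrences.csv")
    spec = pd.read_csv(directory / "species_spec.csv", index_col=0)
    return SyntheticTruth(
        params, species, population, landcover, climate,
        np.asarray(rho, dtype=float), manifest["seed"], occurrences=occ, species_spec=spec,
    )
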