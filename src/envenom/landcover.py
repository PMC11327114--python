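"""Land cover maps and a CLUE-style annual change allocator.

The legend is fixed at five classes — forest, degraded forest,
agriculture, urban, tea plantation — encoded 0..4 in memory and 1..5 in
files.  Annual change is simulated with the competitive-allocation
mechanism of the CLUE-S family: each cell receives the legal class
maximising logit-suitability plus a conversion-elasticity bonus for
staying put plus a per-class offset, and the offsets are adjusted
iteratively until the allocated class counts match demand.

When the offset iteration converges with zero tolerance the resulting
map is exactly the assignment maximising total score subject to demand:
the offsets are dual prices, and per-cell argmax with demand met is
complementary slackness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit

from .errors import InvalidArgumentError, NonConvergenceError, SeparationError
from .lattice import Lattice, RasterLayer

__all__ = [
    "CLASSES",
    "LandCoverMap",
    "TransitionRules",
    "DemandTrajectory",
    "LocationFactors",
    "TreeCoverField",
    "fit_location_factors",
    "suitability",
    "allocate_year",
    "simulate_landcover",
    "categories_to_proportion",
    "derived_covariates",
]

CLASSES = ("forest", "degraded_forest", "agriculture", "urban", "tea")
N_CLASSES = len(CLASSES)

#: Midpoints of the five 20% tree-cover bands, before rescaling.
TREE_BAND_MIDPOINTS = np.array([0.10, 0.30, 0.50, 0.70, 0.90])


@dataclass
class LandCoverMap:
    """Categorical land cover on a lattice; codes 0..4 per ``CLASSES``."""

    lattice: Lattice
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.intp).reshape(self.lattice.shape)
        if self.classes.min() < 0 or self.classes.max() >= N_CLASSES:
            raise InvalidArgumentError("class codes must lie in 0..4")

    @property
    def flat(self) -> np.ndarray:
        return self.classes.ravel()

    def counts(self) -> np.ndarray:
        """Cells per class, length 5."""
        return np.bincount(self.flat, minlength=N_CLASSES)

    def shares(self) -> np.ndarray:
        return self.counts() / self.lattice.n_cells

    def mask(self, class_name: str) -> np.ndarray:
        return self.classes == CLASSES.index(class_name)

    def copy(self) -> "LandCoverMap":
        return LandCoverMap(self.lattice, self.classes.copy())


@dataclass
class TransitionRules:
    """Which (from, to) conversions are legal, plus immutable cells."""

    allowed: np.ndarray = field(default=None)  # type: ignore[assignment]
    restrictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.allowed is None:
            self.allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.shape != (N_CLASSES, N_CLASSES):
            raise InvalidArgumentError("allowed must be 5x5")
        if not np.all(np.diag(self.allowed)):
            raise InvalidArgumentError("staying in the same class must be allowed")
        if self.restrictions is not None:
            self.restrictions = np.asarray(self.restrictions, dtype=bool)


@dataclass
class DemandTrajectory:
    """Target cell counts per class for each simulated year."""

    years: np.ndarray
    targets: np.ndarray  # (n_years, 5)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.targets = np.asarray(self.targets, dtype=np.intp)
        if self.targets.shape != (len(self.years), N_CLASSES):
            raise InvalidArgumentError("targets must be (n_years, 5)")

    def for_year(self, year: int) -> np.ndarray:
        pos = np.flatnonzero(self.years == year)
        if pos.size == 0:
            raise InvalidArgumentError(f"no demand for year {year}")
        return self.targets[int(pos[0])]

    @staticmethod
    def linear(start_counts: np.ndarray, end_counts: np.ndarray, years) -> "DemandTrajectory":
        """Linear interpolation of counts between the first and last year.

        Rounding residue is assigned to the largest class so each year's
        targets sum exactly to the total cell count.
        """
        years = np.asarray(list(years), dtype=int)
        start = np.asarray(start_counts, dtype=float)
        end = np.asarray(end_counts, dtype=float)
        total = int(round(start.sum()))
        if int(round(end.sum())) != total:
            raise InvalidArgumentError("start and end demand totals differ")
        frac = (years - years[0]) / max(years[-1] - years[0], 1)
        targets = np.rint(start[None, :] + frac[:, None] * (end - start)[None, :]).astype(np.intp)
        fix = total - targets.sum(axis=1)
        targets[np.arange(len(years)), np.argmax(targets, axis=1)] += fix
        return DemandTrajectory(years, targets)


@dataclass
class LocationFactors:
    """Per-class logistic-regression coefficients over driver layers."""

    driver_names: list[str]
    intercepts: np.ndarray  # (5,)
    coefficients: np.ndarray  # (5, n_drivers)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not (np.all(np.isfinite(self.intercepts)) and np.all(np.isfinite(self.coefficients))):
            raise InvalidArgumentError("non-finite location-factor coefficients")


@dataclass
class TreeCoverField:
    """Tree cover as 5 categorical bands and/or a proportion in [0, 0.99]."""

    lattice: Lattice
    categories: np.ndarray | None = None  # 1..5
    proportion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.categories is None and self.proportion is None:
            raise InvalidArgumentError("need categories or proportion")
        if self.categories is not None:
            self.categories = np.asarray(self.categories, dtype=np.intp).reshape(
                self.lattice.shape
            )
            if self.categories.min() < 1 or self.categories.max() > 5:
                raise InvalidArgumentError("tree-cover categories must lie in 1..5")
        if self.proportion is not None:
            self.proportion = np.asarray(self.proportion, dtype=float).reshape(
                self.lattice.shape
            )
            if self.proportion.min() < 0 or self.proportion.max() > 0.99 + 1e-12:
                raise InvalidArgumentError("tree-cover proportion must lie in [0, 0.99]")


def fit_location_factors(
    landcover: LandCoverMap, drivers: list[RasterLayer], driver_names: list[str] | None = None
) -> LocationFactors:
    """Logistic regression of each class's presence/absence on drivers.

    Raises :class:`SeparationError` (naming the class) on perfect
    separation or a degenerate single-class response.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if len(drivers) < 1:
        raise InvalidArgumentError("need at least one driver")
    X = np.column_stack([d.flat for d in drivers])
    names = driver_names or [f"driver{i}" for i in range(X.shape[1])]
    Xc = sm.add_constant(X, has_constant="add")
    intercepts = np.zeros(N_CLASSES)
    coefs = np.zeros((N_CLASSES, X.shape[1]))
    counts = landcover.counts()
    for k, cname in enumerate(CLASSES):
        y = (landcover.flat == k).astype(float)
        if counts[k] < 10 or counts[k] > landcover.lattice.n_cells - 10:
            raise SeparationError(
                f"class {cname!r} present in {counts[k]} cells: presence/absence "
                "response is degenerate"
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                fit = sm.Logit(y, Xc).fit(disp=0, tol=1e-8, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as exc:
            raise SeparationError(f"logistic fit failed for class {cname!r}: {exc}") from exc
        if not fit.mle_retvals.get("converged", False):
            raise SeparationError(f"logistic fit did not converge for class {cname!r}")
        intercepts[k] = fit.params[0]
        coefs[k] = fit.params[1:]
    return LocationFactors(names, intercepts, coefs)


def suitability(factors: LocationFactors, drivers: list[RasterLayer]) -> np.ndarray:
    """Per-class presence probabilities, shape (5, n_rows, n_cols)."""
    if len(drivers) != factors.coefficients.shape[1]:
        raise InvalidArgumentError(
            f"expected {factors.coefficients.shape[1]} drivers, got {len(drivers)}"
        )
    X = np.stack([d.values for d in drivers])  # (p, nr, nc)
    eta = factors.intercepts[:, None, None] + np.einsum("kp,pij->kij", factors.coefficients, X)
    return expit(eta)


def _scores(
    suit: np.ndarray, current: np.ndarray, elasticity: np.ndarray, allowed: np.ndarray
) -> np.ndarray:
    """Base allocation scores (n_cells, 5): logit-suitability + stay bonus."""
    p = np.clip(suit.reshape(N_CLASSES, -1).T, 1e-12, 1 - 1e-12)
    score = logit(p)
    score[np.arange(current.size), current] += elasticity[current]
    legal = allowed[current]  # (n_cells, 5)
    score[~legal] = -np.inf
    return score


def allocate_year(
    current: LandCoverMap,
    suit: np.ndarray,
    demand: np.ndarray,
    rules: TransitionRules | None = None,
    elasticity: np.ndarray | float = 0.5,
    tol: int = 1,
    max_iter: int = 1000,
) -> LandCoverMap:
    """Allocate one year of land cover change by competitive bidding.

    Per-class offsets are adjusted until allocated counts match demand
    within ``tol`` cells; restricted cells keep their class and count
    toward demand.  Raises :class:`NonConvergenceError` carrying the last
    offsets if the budget is exhausted.
    """
    rules = rules or TransitionRules()
    demand = np.asarray(demand, dtype=np.intp)
    if demand.shape != (N_CLASSES,):
        raise InvalidArgumentError("demand must have one target per class")
    n = current.lattice.n_cells
    if demand.sum() != n:
        raise InvalidArgumentError(
            f"demand sums to {demand.sum()} but lattice has {n} cells"
        )
    elasticity = np.broadcast_to(np.asarray(elasticity, dtype=float), (N_CLASSES,)).copy()
    cur = current.flat
    restricted = (
        rules.restrictions.ravel()
        if rules.restrictions is not None
        else np.zeros(n, dtype=bool)
    )
    free = ~restricted
    base = _scores(suit, cur, elasticity, rules.allowed)
    fixed_counts = np.bincount(cur[restricted], minlength=N_CLASSES)
    free_idx = np.flatnonzero(free)

    offsets = np.zeros(N_CLASSES)
    step = 4.0
    best_dev = np.inf
    best_assign = cur.copy()
    best_offsets = offsets.copy()
    stall = 0
    for _ in range(max_iter):
        assign = cur.copy()
        assign[free_idx] = np.argmax(base[free_idx] + offsets, axis=1)
        counts = np.bincount(assign[free_idx], minlength=N_CLASSES) + fixed_counts
        dev = counts - demand
        max_dev = int(np.abs(dev).max())
        if max_dev < best_dev:
            best_dev, best_assign, best_offsets = max_dev, assign, offsets.copy()
            stall = 0
        else:
            stall += 1
            if stall >= 20:
                step *= 0.7
                stall = 0
        if best_dev <= tol:
            return LandCoverMap(current.lattice, best_assign)
        offsets = offsets - step * dev / n
        offsets -= offsets.mean()
    # the dual iteration can stall a few cells from demand when marginal
    # cells cycle between classes; finish with greedy legal swaps that
    # each sacrifice the least score
    repaired = _repair(best_assign, base, demand, free, tol)
    if repaired is not None:
        return LandCoverMap(current.lattice, repaired)
    raise NonConvergenceError(
        f"allocation not within tol={tol} after {max_iter} iterations "
        f"(best max deviation {best_dev})",
        offsets=best_offsets,
    )


def _repair(assign, base, demand, free, tol):
    """Move free cells from surplus to deficit classes, cheapest first."""
    assign = assign.copy()
    for _ in range(assign.size):
        counts = np.bincount(assign, minlength=N_CLASSES)
        dev = counts - demand
        if np.abs(dev).max() <= tol:
            return assign
        deficit = int(np.argmin(dev))
        surplus = np.flatnonzero(dev > 0)
        cand = free & np.isin(assign, surplus) & np.isfinite(base[:, deficit])
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            return None
        loss = base[idx, assign[idx]] - base[idx, deficit]
        assign[idx[np.argmin(loss)]] = deficit
    return None


def simulate_landcover(
    start: LandCoverMap,
    demand: DemandTrajectory,
    factors: LocationFactors,
    drivers_by_year,
    rules: TransitionRules | None = None,
    elasticity: np.ndarray | float = 0.5,
    tol: int = 1,
    max_iter: int = 1000,
) -> dict[int, LandCoverMap]:
    """Apply :func:`allocate_year` year by year.

    ``drivers_by_year`` maps each simulated year (after the first) to its
    driver layer list, so dynamic drivers such as climate and population
    are refreshed annually; a plain list is treated as static drivers.
    """
    out = {int(demand.years[0]): start.copy()}
    currentmap = start
    for year in demand.years[1:]:
        year = int(year)
        drivers = (
            drivers_by_year[year] if isinstance(drivers_by_year, dict) else drivers_by_year
        )
        suit = suitability(factors, drivers)
        try:
            currentmap = allocate_year(
                currentmap, suit, demand.for_year(year), rules, elasticity, tol, max_iter
            )
        except NonConvergenceError as exc:
            raise NonConvergenceError(f"year {year}: {exc}", offsets=exc.offsets) from exc
        out[year] = currentmap
    return out


def categories_to_proportion(tree: TreeCoverField, reference_mean: float) -> TreeCoverField:
    """Reclassify banded tree cover to proportions matching a reference mean.

    Band midpoints are rescaled by one factor so the study-area mean
    equals ``reference_mean``; results are clamped to [0, 0.99].
    """
    if not 0.0 < reference_mean < 0.99:
        raise InvalidArgumentError("reference_mean must lie in (0, 0.99)")
    if tree.categories is None:
        raise InvalidArgumentError("tree cover has no categories to reclassify")
    mid = TREE_BAND_MIDPOINTS[tree.categories - 1]
    factor = reference_mean / mid.mean()
    prop = np.clip(mid * factor, 0.0, 0.99)
    return TreeCoverField(tree.lattice, categories=tree.categories.copy(), proportion=prop)


def derived_covariates(
    landcover: LandCoverMap,
    tree: TreeCoverField | None = None,
    neighbourhood: int = 1,
) -> dict[str, np.ndarray]:
    """Land-cover covariates feeding the snake abundance models.

    Returns the proportion of agriculture within the square neighbourhood
    of radius ``neighbourhood`` cells, the Euclidean distance (km) to the
    nearest forest cell (0 on forest; inf sentinel with a warning when no
    forest exists), and the tree-cover proportion pass-through.
    """
    if neighbourhood < 1:
        raise InvalidArgumentError("neighbourhood radius must be >= 1")
    agri = (landcover.classes == CLASSES.index("agriculture")).astype(float)
    size = 2 * neighbourhood + 1
    prop_agri = ndimage.uniform_filter(agri, size=size, mode="nearest")
    forest = landcover.classes == CLASSES.index("forest")
    if not forest.any():
        warnings.warn("no forest cells: distance-to-forest set to inf", stacklevel=2)
        dist = np.full(landcover.lattice.shape, np.inf)
    else:
        dist = ndimage.distance_transform_edt(~forest) * landcover.lattice.cell_size
    out = {"prop_agriculture": prop_agri, "dist_forest": dist}
    if tree is not None:
        if tree.proportion is None:
            raise InvalidArgumentError("tree cover field lacks proportions")
        out["tree_cover"] = tree.proportion.copy()
    return out
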