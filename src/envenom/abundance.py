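"""Snake abundance index surfaces.

Each of the seven medically relevant taxa gets a relative abundance
index surface S_s — a log-linear intensity in climate summaries,
land-cover-derived covariates and the distance to the species' climatic
niche centroid — optionally adjusted by a multiplicative expert
relative-abundance weight.  The index is an intensity, not a census
count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidArgumentError
from .lattice import Lattice

__all__ = [
    "SPECIES",
    "NicheModel",
    "SpeciesAbundanceSet",
    "estimate_niche",
    "niche_distance",
    "fit_abundance_model",
    "project_abundance",
    "apply_expert_weights",
]

#: The seven medically relevant land snakes of Sri Lanka.
SPECIES = (
    "Bungarus caeruleus",
    "Bungarus ceylonicus",
    "Daboia russelii",
    "Echis carinatus",
    "Hypnale spp",
    "Naja naja",
    "Trimeresurus trigonocephalus",
)
N_SPECIES = len(SPECIES)


@dataclass
class NicheModel:
    """Climatic niche centroid in per-variable standardized space."""

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if np.any(self.sds <= 0):
            raise InvalidArgumentError("standardization sds must be > 0")
        p = len(self.variables)
        if not (self.means.shape == self.sds.shape == self.centroid.shape == (p,)):
            raise InvalidArgumentError("niche model dimension mismatch")

    def standardize(self, layers: dict[str, np.ndarray]) -> np.ndarray:
        """Stack requested variables standardized: (p, n_rows, n_cols)."""
        missing = [v for v in self.variables if v not in layers]
        if missing:
            raise InvalidArgumentError(f"missing climate variables: {missing}")
        X = np.stack([np.asarray(layers[v], dtype=float) for v in self.variables])
        return (X - self.means[:, None, None]) / self.sds[:, None, None]


@dataclass
class SpeciesAbundanceSet:
    """Abundance index layer and expert weight per species."""

    lattice: Lattice
    layers: dict[str, np.ndarray]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.layers) != set(SPECIES) and len(self.layers) == 0:
            raise InvalidArgumentError("empty abundance set")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float).reshape(self.lattice.shape)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise InvalidArgumentError(f"abundance for {name} must be finite and >= 0")
            self.layers[name] = arr
        for name in self.layers:
            self.weights.setdefault(name, 1.0)
            if self.weights[name] <= 0:
                raise InvalidArgumentError(f"non-positive expert weight for {name}")

    @property
    def species(self) -> list[str]:
        return list(self.layers)

    def matrix(self) -> np.ndarray:
        """(n_cells, n_species) matrix of indices in species order."""
        return np.stack([self.layers[s].ravel() for s in self.species], axis=1)

    def national_means(self) -> dict[str, float]:
        return {s: float(a.mean()) for s, a in self.layers.items()}


def estimate_niche(
    occurrences: pd.DataFrame, climate_summary: dict[str, np.ndarray], lattice: Lattice
) -> NicheModel:
    """Niche centroid from occurrence points.

    Variables are standardized over the whole study area; the centroid is
    the mean of the standardized climate at the occupied cells.
    """
    if len(occurrences) < 5:
        raise InvalidArgumentError("need at least 5 occurrence points")
    cells = lattice.cell_of_point(occurrences["x"].to_numpy(), occurrences["y"].to_numpy())
    if np.any(cells < 0):
        raise InvalidArgumentError("occurrence points fall outside the lattice")
    variables = sorted(climate_summary)
    X = np.stack([np.asarray(climate_summary[v], dtype=float).ravel() for v in variables])
    means = X.mean(axis=1)
    sds = X.std(axis=1)
    if np.any(sds <= 0):
        raise InvalidArgumentError("a climate variable is constant over the study area")
    Z = (X - means[:, None]) / sds[:, None]
    centroid = Z[:, cells].mean(axis=1)
    return NicheModel(variables, means, sds, centroid)


def niche_distance(niche: NicheModel, climate_summary: dict[str, np.ndarray]) -> np.ndarray:
    """Euclidean distance to the centroid in standardized climate space."""
    Z = niche.standardize(climate_summary)
    diff = Z - niche.centroid[:, None, None]
    return np.sqrt((diff**2).sum(axis=0))


def fit_abundance_model(
    gridded_counts: np.ndarray,
    covariates: dict[str, np.ndarray],
    cell_area: float = 1.0,
):
    """Log-linear intensity fit of gridded occurrence counts on covariates.

    A Poisson count regression with a log cell-area offset; with an
    intercept included the fitted intensity integrates to the total count
    over the lattice.  Constant covariates are unidentifiable and are
    dropped with a warning.  Returns a ``(names, coefficients)`` pair
    with the intercept first.
    """
    import statsmodels.api as sm

    y = np.asarray(gridded_counts, dtype=float).ravel()
    if np.any(y < 0):
        raise InvalidArgumentError("negative counts")
    if y.sum() == 0:
        raise DegenerateDataError("all counts are zero: intensity scale unidentifiable")
    names, cols = [], []
    for name in sorted(covariates):
        col = np.asarray(covariates[name], dtype=float).ravel()
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {name!r} is constant and was dropped", stacklevel=2)
            continue
        names.append(name)
        cols.append(col)
    X = sm.add_constant(np.column_stack(cols) if cols else np.empty((y.size, 0)),
                        has_constant="add")
    offset = np.full(y.size, np.log(cell_area))
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    return ["intercept"] + names, np.asarray(fit.params, dtype=float)


def project_abundance(
    coefficients: tuple[list[str], np.ndarray],
    covariates_for_year: dict[str, np.ndarray],
    cell_area: float = 1.0,
) -> np.ndarray:
    """Evaluate S_s = exp(linear predictor) on new covariate layers.

    ``covariates_for_year`` must contain every fitted covariate (built
    from the rolling 3-year climate mean and that year's land cover).
    """
    names, coefs = coefficients
    if names[0] != "intercept" or len(names) != len(coefs):
        raise InvalidArgumentError("malformed coefficient vector")
    missing = [n for n in names[1:] if n not in covariates_for_year]
    if missing:
        raise InvalidArgumentError(f"missing covariates: {missing}")
    first = np.asarray(covariates_for_year[names[1]]) if len(names) > 1 else None
    shape = first.shape if first is not None else None
    eta = np.full(shape if shape else (1,), coefs[0] + np.log(cell_area), dtype=float)
    for name, beta in zip(names[1:], coefs[1:]):
        eta = eta + beta * np.asarray(covariates_for_year[name], dtype=float)
    S = np.exp(eta)
    if not np.all(np.isfinite(S)):
        raise InvalidArgumentError("non-finite projected abundance")
    return S


def apply_expert_weights(
    layers: SpeciesAbundanceSet, weights: dict[str, float]
) -> SpeciesAbundanceSet:
    """Multiply each species layer by its expert relative-abundance weight."""
    for s, w in weights.items():
        if w <= 0:
            raise InvalidArgumentError(f"non-positive weight for {s}")
    new_layers = {
        s: arr * weights.get(s, 1.0) for s, arr in layers.layers.items()
    }
    new_weights = {s: layers.weights[s] * weights.get(s, 1.0) for s in layers.layers}
    return SpeciesAbundanceSet(layers.lattice, new_layers, new_weights)
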