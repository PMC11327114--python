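"""The mechanistic snakebite envenoming incidence model.

Envenoming cases per cell and year follow a mass-action bite process
combined with a conditional envenoming probability:

    dHe_i = H_i * (1 - exp(-h_i)) * Penv_i
    h_i   = max(0, beta_i * sum_s c_s S_{s,i} + rho_i)
    beta_i = exp(beta0[L_i] + beta1[L_i] * log(1 + H2010_i))
    logit Penv_i = B0 + B[L_i] + sum_s b_s S_{s,i}

where H is the susceptible population, S_s the per-species abundance
index, L the land cover class, and rho an intrinsic conditional
autoregressive (ICAR) random effect on the rook lattice with precision
tau and a sum-to-zero constraint.  With 5 land cover classes and 7
species the bite submodel has 17 free parameters (beta0, beta1, c) and
the envenoming submodel 13 (B0, B, b).

Parameters are estimated by adaptive random-walk Metropolis-within-Gibbs
sampling with a Poisson observation model (binomial optional), Gibbs
updates for tau, chequerboard single-site updates for rho re-centred to
sum to zero each sweep, and two invariant "ridge" moves that trade the
overall scale of c against the beta0 intercepts and the B offsets
against B0 — directions the likelihood cannot identify and only the
priors pin down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .abundance import N_SPECIES, SPECIES, SpeciesAbundanceSet
from .errors import InvalidArgumentError
from .landcover import CLASSES, N_CLASSES, LandCoverMap
from .lattice import Lattice, RasterLayer, check_same_lattice

__all__ = [
    "EnvenomingParams",
    "CarField",
    "ObservedIncidence",
    "PriorSpec",
    "McmcResult",
    "contact_rate",
    "bite_hazard",
    "bite_probability",
    "envenoming_probability",
    "expected_incidence",
    "forward_incidence",
    "car_log_density",
    "sample_car",
    "log_likelihood",
    "fit_mcmc",
    "dic",
    "posterior_predictive_check",
    "residual_summary",
]

_TINY = 1e-300


@dataclass
class EnvenomingParams:
    """All coefficients of the bite and envenoming submodels."""

    beta0: np.ndarray  # (5,) log contact-rate intercept per land cover class
    beta1: np.ndarray  # (5,) log contact-rate slope on log(1 + population)
    c: np.ndarray      # (7,) species contact rates, >= 0
    B0: float          # envenoming intercept
    B: np.ndarray      # (5,) land cover envenoming coefficients
    b: np.ndarray      # (7,) species envenoming slopes
    tau: float = 1.0   # ICAR precision, > 0

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.beta0.shape != (N_CLASSES,) or self.beta1.shape != (N_CLASSES,):
            raise InvalidArgumentError("beta0/beta1 need one value per land cover class")
        if self.c.shape != (N_SPECIES,) or self.b.shape != (N_SPECIES,):
            raise InvalidArgumentError("c/b need one value per species")
        if self.B.shape != (N_CLASSES,):
            raise InvalidArgumentError("B needs one value per land cover class")
        if np.any(self.c < 0):
            raise InvalidArgumentError("species contact rates must be >= 0")
        if self.tau <= 0:
            raise InvalidArgumentError("CAR precision tau must be > 0")

    @property
    def n_bite_parameters(self) -> int:
        """Free parameters of the bite submodel: 2*|classes| + |species|."""
        return 2 * N_CLASSES + N_SPECIES

    @property
    def n_envenoming_parameters(self) -> int:
        """Free parameters of the envenoming submodel: 1 + |classes| + |species|."""
        return 1 + N_CLASSES + N_SPECIES

    def to_vector(self) -> tuple[list[str], np.ndarray]:
        """Flatten the 30 fixed effects plus tau with stable names."""
        names = (
            [f"beta0[{c}]" for c in CLASSES]
            + [f"beta1[{c}]" for c in CLASSES]
            + [f"c[{s}]" for s in SPECIES]
            + ["B0"]
            + [f"B[{c}]" for c in CLASSES]
            + [f"b[{s}]" for s in SPECIES]
            + ["tau"]
        )
        vec = np.concatenate(
            [self.beta0, self.beta1, self.c, [self.B0], self.B, self.b, [self.tau]]
        )
        return names, vec


@dataclass
class CarField:
    """ICAR random effect values on a lattice, constrained to sum to zero."""

    lattice: Lattice
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float).ravel()
        if self.rho.size != self.lattice.n_cells:
            raise InvalidArgumentError("rho length does not match lattice")
        if abs(self.rho.sum()) > 1e-6 * max(1.0, np.abs(self.rho).max()) + 1e-9:
            raise InvalidArgumentError("rho must sum to zero (identifiability)")


@dataclass
class ObservedIncidence:
    """Envenoming counts and susceptible population per cell for one period."""

    lattice: Lattice
    y: np.ndarray
    H: np.ndarray
    period: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).reshape(self.lattice.shape)
        self.H = np.asarray(self.H, dtype=float).reshape(self.lattice.shape)
        if np.any(self.y < 0) or np.any(self.H < 0):
            raise InvalidArgumentError("counts and population must be >= 0")
        if np.any(self.y > self.H + 1e-9):
            raise InvalidArgumentError("counts exceed population somewhere")


@dataclass
class PriorSpec:
    """Priors and observation family for the Bayesian fit.

    Fixed effects get Normal(0, sd_fixed^2) on their linear scales,
    species contact rates half-Normal(0, sd_c), and tau a Gamma
    (shape, rate) prior; the observation family is "poisson" (default)
    or "binomial".
    """

    sd_fixed: float = 10.0
    sd_c: float = 5.0
    tau_shape: float = 1.0
    tau_rate: float = 0.01
    family: str = "poisson"

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "binomial"):
            raise InvalidArgumentError(f"unknown family {self.family!r}")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def contact_rate(
    landcover: LandCoverMap, H2010: RasterLayer, params: EnvenomingParams
) -> np.ndarray:
    """Human-snake contact rate beta_i per cell (strictly positive)."""
    check_same_lattice(landcover, H2010)
    L = landcover.classes
    return np.exp(params.beta0[L] + params.beta1[L] * np.log1p(H2010.values))


def bite_hazard(
    beta: np.ndarray,
    params: EnvenomingParams,
    S: SpeciesAbundanceSet | np.ndarray,
    rho: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Bite hazard h_i = max(0, beta_i * sum_s c_s S_si + rho_i)."""
    Smat = S.matrix() if isinstance(S, SpeciesAbundanceSet) else np.asarray(S, dtype=float)
    beta = np.asarray(beta, dtype=float)
    weighted = (Smat @ params.c).reshape(beta.shape)
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float).reshape(-1)
                              if np.ndim(rho) else rho, beta.size).reshape(beta.shape)
    return np.maximum(beta * weighted + rho_arr, 0.0)


_BELOW_ONE = np.nextafter(1.0, 0.0)


def bite_probability(h: np.ndarray) -> np.ndarray:
    """p = 1 - exp(-h), the mass-action bite probability.

    Mathematically p < 1 for finite hazard; the result is clamped to the
    largest float below 1 so the open-interval invariant survives
    rounding at extreme hazards.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise InvalidArgumentError("hazard must be >= 0")
    return np.minimum(-np.expm1(-h), _BELOW_ONE)


def envenoming_probability(
    landcover: LandCoverMap, S: SpeciesAbundanceSet | np.ndarray, params: EnvenomingParams
) -> np.ndarray:
    """Penv_i = inv-logit(B0 + B[L_i] + sum_s b_s S_si), in (0, 1)."""
    Smat = S.matrix() if isinstance(S, SpeciesAbundanceSet) else np.asarray(S, dtype=float)
    L = landcover.classes
    eta = params.B0 + params.B[L] + (Smat @ params.b).reshape(L.shape)
    # clamp to the open interval: expit saturates to exactly 0/1 in floats
    return np.clip(expit(eta), 5e-324, _BELOW_ONE)


def expected_incidence(H: np.ndarray, p_bite: np.ndarray, p_env: np.ndarray) -> np.ndarray:
    """Expected new envenoming cases dHe_i = H_i p_bite,i Penv_i (<= H_i)."""
    H = np.asarray(H, dtype=float)
    p_bite = np.asarray(p_bite, dtype=float)
    p_env = np.asarray(p_env, dtype=float)
    if H.shape != p_bite.shape or H.shape != p_env.shape:
        raise InvalidArgumentError("misaligned layers")
    if np.any(p_bite < 0) or np.any(p_bite >= 1.0 + 1e-12):
        raise InvalidArgumentError("p_bite outside [0, 1)")
    if np.any(p_env <= 0) or np.any(p_env >= 1):
        raise InvalidArgumentError("p_env outside (0, 1)")
    return H * p_bite * p_env


def forward_incidence(
    landcover: LandCoverMap,
    H2010: RasterLayer,
    H: np.ndarray,
    S: SpeciesAbundanceSet | np.ndarray,
    params: EnvenomingParams,
    rho: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Full forward evaluation of expected incidence dHe on one lattice."""
    beta = contact_rate(landcover, H2010, params)
    h = bite_hazard(beta, params, S, rho)
    return expected_incidence(np.asarray(H, dtype=float), bite_probability(h),
                              envenoming_probability(landcover, S, params))


# ---------------------------------------------------------------------------
# ICAR density
# ---------------------------------------------------------------------------

def _check_connected(lattice: Lattice, edges: np.ndarray) -> None:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = lattice.n_cells
    w = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(w, directed=False)
    if ncomp != 1:
        raise InvalidArgumentError("adjacency graph is disconnected")


def car_quadratic(rho: np.ndarray, edges: np.ndarray) -> float:
    """Pairwise-difference quadratic form sum_{i~j} (rho_i - rho_j)^2."""
    diff = rho[edges[:, 0]] - rho[edges[:, 1]]
    return float(diff @ diff)


def car_log_density(rho: CarField, tau: float, _check: bool = True) -> float:
    """Intrinsic-CAR log density up to an additive constant.

    log p(rho | tau) = (n-1)/2 log tau - tau/2 sum_{i~j} (rho_i - rho_j)^2
    on the sum-to-zero subspace; the precision matrix tau (D - W) has
    rank n-1 on a connected lattice, hence the (n-1)/2 normaliser.
    """
    if tau <= 0:
        raise InvalidArgumentError("tau must be > 0")
    edges = rho.lattice.rook_edges()
    if _check:
        _check_connected(rho.lattice, edges)
    n = rho.lattice.n_cells
    return 0.5 * (n - 1) * np.log(tau) - 0.5 * tau * car_quadratic(rho.rho, edges)


def sample_car(lattice: Lattice, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one ICAR field on the sum-to-zero subspace (dense eigendecomposition)."""
    if tau <= 0:
        raise InvalidArgumentError("tau must be > 0")
    n = lattice.n_cells
    edges = lattice.rook_edges()
    Q = np.zeros((n, n))
    Q[edges[:, 0], edges[:, 1]] = -1.0
    Q[edges[:, 1], edges[:, 0]] = -1.0
    np.fill_diagonal(Q, lattice.n_neighbours().astype(float))
    Q *= tau
    vals, vecs = np.linalg.eigh(Q)
    keep = vals > 1e-8 * vals.max()
    z = rng.standard_normal(int(keep.sum()))
    rho = vecs[:, keep] @ (z / np.sqrt(vals[keep]))
    return rho - rho.mean()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _poisson_ll_cells(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    out = y * np.log(mu + _TINY) - mu - gammaln(y + 1.0)
    return out


def log_likelihood(obs: ObservedIncidence, delta_He: np.ndarray, family: str = "poisson") -> float:
    """Observation log likelihood of the counts given expected incidence.

    Poisson by default; the binomial alternative uses p = dHe / H on
    cells with population.  A zero mean with a positive count yields
    -inf.
    """
    y = obs.y.ravel()
    mu = np.asarray(delta_He, dtype=float).ravel()
    if mu.shape != y.shape:
        raise InvalidArgumentError("expected-incidence shape mismatch")
    if np.any(mu < 0):
        raise InvalidArgumentError("negative expected incidence")
    if np.any((mu == 0) & (y > 0)):
        return -np.inf
    if family == "poisson":
        return float(_poisson_ll_cells(y, mu).sum())
    if family == "binomial":
        H = obs.H.ravel()
        ok = H > 0
        p = np.clip(mu[ok] / H[ok], 1e-12, 1 - 1e-12)
        yk, Hk = y[ok], H[ok]
        ll = (
            gammaln(Hk + 1) - gammaln(yk + 1) - gammaln(Hk - yk + 1)
            + yk * np.log(p) + (Hk - yk) * np.log1p(-p)
        )
        return float(ll.sum())
    raise InvalidArgumentError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _map_fixed_effects(y, H, L, lh, Smat, priors: "PriorSpec") -> np.ndarray:
    """Posterior mode of the 30 fixed effects (rho = 0), xi = log c scale."""
    from scipy.optimize import minimize

    def neg_logpost(theta):
        beta0, beta1 = theta[:5], theta[5:10]
        xi, B0 = theta[10:17], theta[17]
        B, b = theta[18:23], theta[23:30]
        c = np.exp(np.clip(xi, -20, 5))
        with np.errstate(over="ignore"):
            beta_cell = np.exp(np.clip(beta0[L] + beta1[L] * lh, -500, 50))
        hz = beta_cell * (Smat @ c)
        sig = expit(B0 + B[L] + Smat @ b)
        mu = H * sig * (-np.expm1(-hz))
        if priors.family == "poisson":
            llv = y * np.log(mu + _TINY) - mu
        else:
            p = np.clip(mu / np.maximum(H, 1e-12), 1e-12, 1 - 1e-12)
            llv = y * np.log(p) + (H - y) * np.log1p(-p)
        v = priors.sd_fixed**2
        lp = -(beta0 @ beta0 + beta1 @ beta1 + B0**2 + B @ B + b @ b) / (2 * v)
        lp += -np.exp(2 * np.clip(xi, -20, 5)).sum() / (2 * priors.sd_c**2) + xi.sum()
        return -(llv.sum() + lp)

    x0 = np.concatenate(
        [np.full(5, -3.0), np.zeros(5), np.full(7, np.log(0.3)), [0.0], np.zeros(5), np.zeros(7)]
    )
    res = minimize(neg_logpost, x0, method="L-BFGS-B", options={"maxiter": 500})
    return res.x


def _slice_1d(logp, x0: float, rng: np.random.Generator, w: float = 1.0) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    level = logp(x0) + np.log(rng.random() + _TINY)
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(50):
        if logp(left) <= level:
            break
        left -= w
    for _ in range(50):
        if logp(right) <= level:
            break
        right += w
    for _ in range(100):
        x1 = left + rng.random() * (right - left)
        if logp(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


@dataclass
class McmcResult:
    """Posterior draws, summaries, diagnostics and DIC from one fit."""

    names: list[str]
    draws: np.ndarray              # (n_chains, n_kept, 31): 30 fixed effects + tau
    loglik_draws: np.ndarray       # (n_chains, n_kept)
    mu_draws: np.ndarray           # (n_chains, n_thinned, n_cells) expected incidence
    rho_mean: np.ndarray           # posterior mean ICAR field
    summary: pd.DataFrame          # index = names; median, q5, q95, rhat, ess
    accept_rates: dict[str, float]
    seed: int

    def median(self, name: str) -> float:
        return float(self.summary.loc[name, "median"])

    def interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        lo = (1 - level) / 2
        d = self.draws[:, :, self.names.index(name)].ravel()
        return (float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo)))

    def predicted_median(self) -> np.ndarray:
        """Per-cell posterior median of expected incidence."""
        stacked = self.mu_draws.reshape(-1, self.mu_draws.shape[-1])
        return np.median(stacked, axis=0)

    def save(self, directory) -> None:
        """Persist chains as CSV (one row per draw) plus JSON diagnostics."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        n_chains, n_kept, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(n_chains * n_kept, -1), columns=self.names
        )
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_kept))
        frame.insert(1, "draw", np.tile(np.arange(n_kept), n_chains))
        frame.to_csv(directory / "chains.csv", index=False)
        report = {
            "seed": self.seed,
            "n_chains": int(n_chains),
            "n_kept": int(n_kept),
            "accept_rates": self.accept_rates,
            "rhat": {n: float(self.summary.loc[n, "rhat"]) for n in self.names},
            "ess": {n: float(self.summary.loc[n, "ess"]) for n in self.names},
        }
        (directory / "diagnostics.json").write_text(json.dumps(report, indent=2))


def _summarise(names, draws) -> pd.DataFrame:
    import arviz as az

    idata = az.from_dict(
        posterior={n: draws[:, :, i] for i, n in enumerate(names)}
    )
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for i, n in enumerate(names):
        d = draws[:, :, i].ravel()
        rows.append(
            {
                "median": np.median(d),
                "q5": np.quantile(d, 0.05),
                "q95": np.quantile(d, 0.95),
                "rhat": float(rhat[n].values),
                "ess": float(ess[n].values),
            }
        )
    return pd.DataFrame(rows, index=names)


def fit_mcmc(
    obs: ObservedIncidence,
    S: SpeciesAbundanceSet,
    landcover: LandCoverMap,
    H2010: RasterLayer,
    priors: PriorSpec | None = None,
    n_chains: int = 3,
    n_iter: int = 20000,
    seed: int = 0,
    thin_mu: int = 20,
) -> McmcResult:
    """Fit the envenoming model by adaptive Metropolis-within-Gibbs.

    The first half of each chain is warmup (adaptation of proposal
    scales by Robbins-Monro recursion towards 0.35 acceptance) and is
    discarded.  tau gets an exact conjugate Gibbs update; rho is updated
    site-wise over the two chequerboard colours and re-centred to sum to
    zero every sweep.
    """
    if n_chains < 2:
        raise InvalidArgumentError("need at least 2 chains for split-Rhat")
    if n_iter < 200:
        raise InvalidArgumentError("n_iter too small for warmup")
    priors = priors or PriorSpec()
    lat = check_same_lattice(obs, landcover, H2010)

    y = obs.y.ravel()
    H = obs.H.ravel()
    L = landcover.flat
    lh = np.log1p(H2010.flat)
    Smat = S.matrix()
    n = y.size
    edges = lat.rook_edges()
    _check_connected(lat, edges)
    nbr_deg = lat.n_neighbours().astype(float)
    # neighbour sums via sparse matrix for vectorised rho updates
    from scipy.sparse import coo_matrix

    W = coo_matrix(
        (
            np.ones(2 * len(edges)),
            (
                np.concatenate([edges[:, 0], edges[:, 1]]),
                np.concatenate([edges[:, 1], edges[:, 0]]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    colour = lat.checkerboard()
    colours = [np.flatnonzero(colour), np.flatnonzero(~colour)]
    W_by_colour = [W[cells] for cells in colours]
    class_cells = [np.flatnonzero(L == k) for k in range(N_CLASSES)]
    gln = gammaln(y + 1.0)

    n_warm = n_iter // 2
    n_keep = n_iter - n_warm
    n_fixed = 30
    names = (
        [f"beta0[{c}]" for c in CLASSES]
        + [f"beta1[{c}]" for c in CLASSES]
        + [f"c[{s}]" for s in SPECIES]
        + ["B0"]
        + [f"B[{c}]" for c in CLASSES]
        + [f"b[{s}]" for s in SPECIES]
        + ["tau"]
    )

    # log-likelihood terms per cell with data-only constants dropped; the
    # constant is restored when recording absolute log likelihoods
    if priors.family == "poisson":
        ll_const = -float(gln.sum())

        def cell_ll(mu, idx=None):
            yv = y if idx is None else y[idx]
            return yv * np.log(mu + _TINY) - mu
    else:
        ll_const = float(
            (gammaln(H + 1) - gln - gammaln(np.maximum(H - y, 0) + 1)).sum()
        )

        def cell_ll(mu, idx=None):
            yv = y if idx is None else y[idx]
            Hv = H if idx is None else H[idx]
            p = np.clip(mu / np.maximum(Hv, 1e-12), 1e-12, 1 - 1e-12)
            return yv * np.log(p) + (Hv - yv) * np.log1p(-p)

    all_draws = np.empty((n_chains, n_keep, n_fixed + 1))
    all_ll = np.empty((n_chains, n_keep))
    n_thin_keep = n_keep // thin_mu
    all_mu = np.empty((n_chains, n_thin_keep, n))
    rho_accum = np.zeros(n)
    acc_report: dict[str, float] = {}

    # posterior-mode initialization (rho = 0): all chains start in the
    # typical set, jittered, so warmup adapts to the right geometry
    theta_map = _map_fixed_effects(y, H, L, lh, Smat, priors)

    for chain in range(n_chains):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, chain])))
        start = theta_map + rng.normal(0.0, 0.2, theta_map.size)
        beta0 = start[:5].copy()
        beta1 = start[5:10].copy()
        c = np.exp(start[10:17])
        B0 = float(start[17])
        B = start[18:23].copy()
        b = start[23:30].copy()
        tau = float(rng.gamma(2.0, 1.0)) + 0.5
        # start rho at the clipped MAP hazard residual: a zero start makes
        # the first tau Gibbs draw enormous and freezes the field
        bc0 = np.exp(np.clip(beta0[L] + beta1[L] * lh, -500, 50))
        sig0 = expit(B0 + B[L] + Smat @ b)
        hz0 = bc0 * (Smat @ np.exp(start[10:17]))
        with np.errstate(divide="ignore", invalid="ignore"):
            target = -np.log1p(-np.clip(y / np.maximum(H * sig0, 1e-12), 0.0, 0.95))
        rho = np.clip(target - hz0, -0.3, 0.3)
        rho = rho - rho.mean() + rng.normal(0.0, 0.01, n)
        rho -= rho.mean()

        beta_cell = np.exp(beta0[L] + beta1[L] * lh)
        sumcS = Smat @ c
        eta_env = B0 + B[L] + Smat @ b
        sig = expit(eta_env)
        Hsig = H * sig
        Scol = [np.ascontiguousarray(Smat[:, s]) for s in range(N_SPECIES)]
        lh_by_class = [lh[idx] for idx in class_cells]

        def full_state():
            hz = np.maximum(beta_cell * sumcS + rho, 0.0)
            m = Hsig * (-np.expm1(-hz))
            return m, cell_ll(m)

        mu, ll_cells = full_state()
        ll = ll_cells.sum()

        # species contact rates are sampled as xi = log c: the half-Normal
        # prior on c plus the exp Jacobian gives log p(xi) = -e^{2xi}/2sd_c^2 + xi
        xi = np.log(np.maximum(c, 1e-6))

        def fixed_prior(beta0, beta1, xi, B0, B, b):
            v = priors.sd_fixed**2
            lp = -(beta0 @ beta0 + beta1 @ beta1 + B0**2 + B @ B + b @ b) / (2 * v)
            lp += -np.exp(2 * xi).sum() / (2 * priors.sd_c**2) + xi.sum()
            return lp

        lp_fixed = fixed_prior(beta0, beta1, xi, B0, B, b)

        scales = np.full(n_fixed, 0.1)
        scale_rho = 0.1
        batch = 50
        # adaptive-covariance block proposal (switched on mid-warmup)
        am_start = max(200, min(1000, n_warm // 2))
        am_moments_start = min(300, n_warm // 4)
        n_am = 8
        n_rho_sweeps = 3
        am_batches = 0
        am_mean = np.zeros(n_fixed)
        am_m2 = np.zeros((n_fixed, n_fixed))
        am_n = 0
        am_chol = 0.05 * np.eye(n_fixed)
        am_scale = 2.38 / np.sqrt(n_fixed)
        am_acc = 0.0
        am_prop = 0
        acc_batch = np.zeros(n_fixed)
        mlh = np.array([v.mean() for v in lh_by_class])
        mS = Smat.mean(axis=0)
        scale_r01 = np.full(N_CLASSES, 0.3)
        scale_rb = np.full(N_SPECIES, 0.3)
        acc_r01 = np.zeros(N_CLASSES)
        acc_rb = np.zeros(N_SPECIES)
        rho_batch_acc = 0.0
        rho_batch_n = 0
        ridge_acc = np.zeros(2)
        kept = 0

        sd2f = 2 * priors.sd_fixed**2
        sd2c = 2 * priors.sd_c**2

        for it in range(n_iter):
            # --- scalar fixed-effect updates -------------------------------
            steps = rng.standard_normal(n_fixed) * scales
            logu = np.log(rng.random(n_fixed + 2))
            for j in range(n_fixed):
                stepv = steps[j]
                if j < 5:  # beta0[k]: beta scales by e^step on class cells
                    k = j
                    idx = class_cells[k]
                    nbc = beta_cell[idx] * np.exp(stepv)
                    nhz = np.maximum(nbc * sumcS[idx] + rho[idx], 0.0)
                    nmu = Hsig[idx] * (-np.expm1(-nhz))
                    nllv = cell_ll(nmu, idx)
                    cand = beta0[k] + stepv
                    dprior = -(cand**2 - beta0[k] ** 2) / sd2f
                    dll = nllv.sum() - ll_cells[idx].sum()
                    if logu[j] < dll + dprior:
                        beta0[k] = cand
                        beta_cell[idx] = nbc
                        mu[idx] = nmu
                        ll_cells[idx] = nllv
                        ll += dll
                        lp_fixed += dprior
                        acc_batch[j] += 1
                elif j < 10:  # beta1[k]: beta scales by e^(step*log1p(H))
                    k = j - 5
                    idx = class_cells[k]
                    nbc = beta_cell[idx] * np.exp(stepv * lh_by_class[k])
                    nhz = np.maximum(nbc * sumcS[idx] + rho[idx], 0.0)
                    nmu = Hsig[idx] * (-np.expm1(-nhz))
                    nllv = cell_ll(nmu, idx)
                    cand = beta1[k] + stepv
                    dprior = -(cand**2 - beta1[k] ** 2) / sd2f
                    dll = nllv.sum() - ll_cells[idx].sum()
                    if logu[j] < dll + dprior:
                        beta1[k] = cand
                        beta_cell[idx] = nbc
                        mu[idx] = nmu
                        ll_cells[idx] = nllv
                        ll += dll
                        lp_fixed += dprior
                        acc_batch[j] += 1
                elif j < 17:  # xi[s] = log c[s]
                    s_i = j - 10
                    cand_xi = xi[s_i] + stepv
                    cand_c = np.exp(cand_xi)
                    nsum = sumcS + (cand_c - c[s_i]) * Scol[s_i]
                    nhz = np.maximum(beta_cell * nsum + rho, 0.0)
                    nmu = Hsig * (-np.expm1(-nhz))
                    nllv = cell_ll(nmu)
                    dprior = -(cand_c**2 - c[s_i] ** 2) / sd2c + stepv
                    nll = nllv.sum()
                    if logu[j] < nll - ll + dprior:
                        xi[s_i] = cand_xi
                        c[s_i] = cand_c
                        sumcS, mu, ll_cells, ll = nsum, nmu, nllv, nll
                        lp_fixed += dprior
                        acc_batch[j] += 1
                elif j == 17:  # B0: p_env rescales, bite side untouched
                    cand = B0 + stepv
                    nsig = expit(eta_env + stepv)
                    nmu = mu * (nsig / sig)
                    nllv = cell_ll(nmu)
                    dprior = -(cand**2 - B0**2) / sd2f
                    nll = nllv.sum()
                    if logu[j] < nll - ll + dprior:
                        B0 = cand
                        eta_env = eta_env + stepv
                        sig, Hsig = nsig, H * nsig
                        mu, ll_cells, ll = nmu, nllv, nll
                        lp_fixed += dprior
                        acc_batch[j] += 1
                elif j < 23:  # B[k]
                    k = j - 18
                    idx = class_cells[k]
                    nsig = expit(eta_env[idx] + stepv)
                    nmu = mu[idx] * (nsig / sig[idx])
                    nllv = cell_ll(nmu, idx)
                    cand = B[k] + stepv
                    dprior = -(cand**2 - B[k] ** 2) / sd2f
                    dll = nllv.sum() - ll_cells[idx].sum()
                    if logu[j] < dll + dprior:
                        B[k] = cand
                        eta_env[idx] += stepv
                        sig[idx] = nsig
                        Hsig[idx] = H[idx] * nsig
                        mu[idx] = nmu
                        ll_cells[idx] = nllv
                        ll += dll
                        lp_fixed += dprior
                        acc_batch[j] += 1
                else:  # b[s]
                    s_i = j - 23
                    cand = b[s_i] + stepv
                    neta = eta_env + stepv * Scol[s_i]
                    nsig = expit(neta)
                    nmu = mu * (nsig / sig)
                    nllv = cell_ll(nmu)
                    dprior = -(cand**2 - b[s_i] ** 2) / sd2f
                    nll = nllv.sum()
                    if logu[j] < nll - ll + dprior:
                        b[s_i] = cand
                        eta_env, sig, Hsig = neta, nsig, H * nsig
                        mu, ll_cells, ll = nmu, nllv, nll
                        lp_fixed += dprior
                        acc_batch[j] += 1

            # --- correlated near-ridge moves -------------------------------
            # (beta0[k], beta1[k]): within a class only beta0 + beta1*lh is
            # well identified; move along the direction that preserves it at
            # the class-mean log-population.
            rsteps = rng.standard_normal(N_CLASSES + N_SPECIES)
            rlogu = np.log(rng.random(N_CLASSES + N_SPECIES))
            for k in range(N_CLASSES):
                d = rsteps[k] * scale_r01[k]
                idx = class_cells[k]
                nb0 = beta0[k] + d * mlh[k]
                nb1 = beta1[k] - d
                nbc = beta_cell[idx] * np.exp(d * (mlh[k] - lh_by_class[k]))
                nhz = np.maximum(nbc * sumcS[idx] + rho[idx], 0.0)
                nmu = Hsig[idx] * (-np.expm1(-nhz))
                nllv = cell_ll(nmu, idx)
                dprior = -(nb0**2 - beta0[k] ** 2 + nb1**2 - beta1[k] ** 2) / sd2f
                dll = nllv.sum() - ll_cells[idx].sum()
                if rlogu[k] < dll + dprior:
                    beta0[k], beta1[k] = nb0, nb1
                    beta_cell[idx] = nbc
                    mu[idx] = nmu
                    ll_cells[idx] = nllv
                    ll += dll
                    lp_fixed += dprior
                    acc_r01[k] += 1
            # (b[s], B0): shifting b[s] is compensated at the mean abundance.
            for s_i in range(N_SPECIES):
                d = rsteps[N_CLASSES + s_i] * scale_rb[s_i]
                nb = b[s_i] + d
                nB0 = B0 - d * mS[s_i]
                neta = eta_env + d * (Scol[s_i] - mS[s_i])
                nsig = expit(neta)
                nmu = mu * (nsig / sig)
                nllv = cell_ll(nmu)
                dprior = -(nb**2 - b[s_i] ** 2 + nB0**2 - B0**2) / sd2f
                nll = nllv.sum()
                if rlogu[N_CLASSES + s_i] < nll - ll + dprior:
                    b[s_i], B0 = nb, nB0
                    eta_env, sig, Hsig = neta, nsig, H * nsig
                    mu, ll_cells, ll = nmu, nllv, nll
                    lp_fixed += dprior
                    acc_rb[s_i] += 1

            # --- ridge moves (likelihood-invariant directions) -------------
            # (a) xi -> xi + d, beta0 -> beta0 - d leaves the hazard
            # invariant; sample the 1-D conditional over d by slice sampling.
            def ridge_logp(d):
                return (
                    -np.sum((beta0 - d) ** 2) / sd2f
                    - np.exp(2 * (xi + d)).sum() / sd2c
                    + N_SPECIES * d
                )

            d = _slice_1d(ridge_logp, 0.0, rng, w=1.0)
            if d != 0.0:
                xi = xi + d
                c = np.exp(xi)
                beta0 = beta0 - d
                beta_cell = beta_cell * np.exp(-d)
                sumcS = sumcS * np.exp(d)
                lp_fixed = fixed_prior(beta0, beta1, xi, B0, B, b)
                ridge_acc[0] += 1
            # (b) B0 -> B0 + d, B -> B - d leaves eta_env invariant; the
            # conditional over d under the Normal priors is Gaussian: Gibbs.
            var_d = priors.sd_fixed**2 / (1 + N_CLASSES)
            mean_d = (B.sum() - B0) / (1 + N_CLASSES)
            d = rng.normal(mean_d, np.sqrt(var_d))
            B0, B = B0 + d, B - d
            lp_fixed = fixed_prior(beta0, beta1, xi, B0, B, b)
            ridge_acc[1] += 1

            # --- adaptive-covariance block move over all 30 fixed effects --
            # (Haario-style: running moments over the whole chain give
            # diminishing adaptation, so post-warmup use stays ergodic)
            theta = np.concatenate([beta0, beta1, xi, [B0], B, b])
            if it >= am_start:
                for i_am in range(n_am):
                    # an occasional triple-scale proposal jumps soft ridges
                    jump = 3.0 if i_am == n_am - 1 else 1.0
                    prop = theta + am_chol @ rng.standard_normal(n_fixed) * (am_scale * jump)
                    p_beta0, p_beta1 = prop[:5], prop[5:10]
                    p_xi, p_B0 = prop[10:17], prop[17]
                    p_B, p_b = prop[18:23], prop[23:30]
                    p_c = np.exp(p_xi)
                    nbc = np.exp(p_beta0[L] + p_beta1[L] * lh)
                    nsum = Smat @ p_c
                    neta = p_B0 + p_B[L] + Smat @ p_b
                    nsig = expit(neta)
                    nhz = np.maximum(nbc * nsum + rho, 0.0)
                    nmu = H * nsig * (-np.expm1(-nhz))
                    nllv = cell_ll(nmu)
                    nll = nllv.sum()
                    lp_new = fixed_prior(p_beta0, p_beta1, p_xi, p_B0, p_B, p_b)
                    if np.log(rng.random()) < nll - ll + lp_new - lp_fixed:
                        beta0, beta1, xi, B0, B, b = p_beta0, p_beta1, p_xi, p_B0, p_B, p_b
                        c = p_c
                        beta_cell, sumcS, eta_env = nbc, nsum, neta
                        sig, Hsig = nsig, H * nsig
                        mu, ll_cells, ll, lp_fixed = nmu, nllv, nll, lp_new
                        theta = prop
                        am_acc += jump == 1.0
                    if jump == 1.0:
                        am_prop += 1
            if it >= am_moments_start:
                am_mean += theta
                am_m2 += np.outer(theta, theta)
                am_n += 1
            if it + 1 >= am_start and (it + 1) % 200 == 0:
                cov = am_m2 / am_n - np.outer(am_mean / am_n, am_mean / am_n)
                cov += 1e-6 * np.eye(n_fixed)
                try:
                    am_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
            if am_prop >= 100:
                am_batches += 1
                am_scale *= np.exp(
                    (am_acc / am_prop - 0.23) * 0.7 / np.sqrt(am_batches)
                )
                am_acc = 0.0
                am_prop = 0

            # --- tau: conjugate Gibbs --------------------------------------
            q = car_quadratic(rho, edges)
            tau = float(
                rng.gamma(priors.tau_shape + 0.5 * (n - 1), 1.0 / (priors.tau_rate + 0.5 * q))
            )

            # --- rho: chequerboard single-site updates ---------------------
            # several sweeps per iteration: the spatial field is the slow
            # partner of the weakly identified fixed effects
            for cells, Wc in zip(colours * n_rho_sweeps, W_by_colour * n_rho_sweeps):
                prop = rho[cells] + rng.normal(0.0, scale_rho, cells.size)
                nbr_sum = Wc.dot(rho)
                dpri = -0.5 * tau * (
                    nbr_deg[cells] * (prop**2 - rho[cells] ** 2)
                    - 2.0 * nbr_sum * (prop - rho[cells])
                )
                hz_new = np.maximum(beta_cell[cells] * sumcS[cells] + prop, 0.0)
                mu_new = Hsig[cells] * (-np.expm1(-hz_new))
                llc_new = cell_ll(mu_new, cells)
                acc = np.log(rng.random(cells.size)) < (llc_new - ll_cells[cells] + dpri)
                hit = cells[acc]
                rho[hit] = prop[acc]
                mu[hit] = mu_new[acc]
                ll_cells[hit] = llc_new[acc]
                rho_batch_acc += acc.sum()
                rho_batch_n += cells.size
            # re-centre and refresh cached state (also caps float drift
            # from the incremental updates above)
            rho -= rho.mean()
            mu, ll_cells = full_state()
            ll = ll_cells.sum()

            # --- adaptation during warmup ----------------------------------
            if it < n_warm and (it + 1) % batch == 0:
                rate = acc_batch / batch
                scales *= np.exp((rate - 0.35) / np.sqrt((it + 1) / batch))
                acc_batch[:] = 0.0
                scale_r01 *= np.exp((acc_r01 / batch - 0.35) / np.sqrt((it + 1) / batch))
                scale_rb *= np.exp((acc_rb / batch - 0.35) / np.sqrt((it + 1) / batch))
                acc_r01[:] = 0.0
                acc_rb[:] = 0.0
                rrate = rho_batch_acc / max(rho_batch_n, 1)
                scale_rho *= np.exp((rrate - 0.35) / np.sqrt((it + 1) / batch))
                rho_batch_acc = 0.0
                rho_batch_n = 0

            if it >= n_warm:
                all_draws[chain, kept, :5] = beta0
                all_draws[chain, kept, 5:10] = beta1
                all_draws[chain, kept, 10:17] = c
                all_draws[chain, kept, 17] = B0
                all_draws[chain, kept, 18:23] = B
                all_draws[chain, kept, 23:30] = b
                all_draws[chain, kept, 30] = tau
                all_ll[chain, kept] = ll + ll_const
                if kept % thin_mu == 0 and kept // thin_mu < n_thin_keep:
                    all_mu[chain, kept // thin_mu] = mu
                rho_accum += rho / (n_keep * n_chains)
                kept += 1
        acc_report[f"chain{chain}_rho"] = float(rho_batch_acc / max(rho_batch_n, 1))

    summary = _summarise(names, all_draws)
    return McmcResult(
        names=names,
        draws=all_draws,
        loglik_draws=all_ll,
        mu_draws=all_mu,
        rho_mean=rho_accum,
        summary=summary,
        accept_rates=acc_report,
        seed=seed,
    )


def _params_from_vector(vec: np.ndarray) -> EnvenomingParams:
    return EnvenomingParams(
        beta0=vec[:5], beta1=vec[5:10], c=np.maximum(vec[10:17], 0.0),
        B0=float(vec[17]), B=vec[18:23], b=vec[23:30], tau=float(max(vec[30], 1e-9)),
    )


def dic(
    result: McmcResult,
    obs: ObservedIncidence,
    S: SpeciesAbundanceSet,
    landcover: LandCoverMap,
    H2010: RasterLayer,
    family: str = "poisson",
) -> float:
    """Deviance information criterion: Dbar + pD, pD = Dbar - D(theta_bar).

    The plug-in deviance uses the posterior mean of the expected
    incidence surface (the mean-parameterisation focus): the hazard floor
    makes the deviance at the posterior mean of the raw parameters
    degenerate (zero mean with positive count) on sparse cells.
    """
    if result.draws.size == 0:
        raise InvalidArgumentError("empty draws")
    d_bar = float(np.mean(-2.0 * result.loglik_draws))
    mu_bar = result.mu_draws.reshape(-1, result.mu_draws.shape[-1]).mean(axis=0)
    d_hat = -2.0 * log_likelihood(obs, mu_bar, family=family)
    p_d = d_bar - d_hat
    return d_bar + p_d


def posterior_predictive_check(
    result: McmcResult, obs: ObservedIncidence, n_mc: int = 999, seed: int = 0
) -> dict[str, float]:
    """Spatially corrected posterior predictive correlation check.

    Pearson's r between observed counts and the posterior-median expected
    incidence, with a Monte Carlo p value against a null of random torus
    shifts of the observed field, which preserve its spatial
    autocorrelation structure while breaking alignment with the
    prediction.
    """
    if n_mc < 99:
        raise InvalidArgumentError("need at least 99 Monte Carlo shifts")
    pred = result.predicted_median().reshape(obs.lattice.shape)
    yf = obs.y.ravel()
    pf = pred.ravel()
    if np.ptp(yf) == 0 or np.ptp(pf) == 0:
        raise InvalidArgumentError("constant field: correlation undefined")
    r = float(np.corrcoef(yf, pf)[0, 1])
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 9151])))
    nr, nc = obs.lattice.shape
    exceed = 0
    for _ in range(n_mc):
        dr = int(rng.integers(0, nr))
        dc = int(rng.integers(0, nc))
        if dr == 0 and dc == 0:
            dr = nr // 2
        shifted = np.roll(obs.y, (dr, dc), axis=(0, 1)).ravel()
        if np.corrcoef(shifted, pf)[0, 1] >= r:
            exceed += 1
    p_mc = (1 + exceed) / (n_mc + 1)
    return {"r": r, "p_mc": float(p_mc)}


def residual_summary(result: McmcResult, obs: ObservedIncidence) -> dict[str, np.ndarray | float]:
    """Raw residuals y - posterior-median dHe and their mean."""
    pred = result.predicted_median().reshape(obs.lattice.shape)
    resid = obs.y - pred
    return {"mean": float(resid.mean()), "residuals": resid}
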