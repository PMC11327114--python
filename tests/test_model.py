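import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from envenom.abundance import SPECIES, SpeciesAbundanceSet
from envenom.errors import InvalidArgumentError
from envenom.landcover import CLASSES, LandCoverMap
from envenom.lattice import RasterLayer, make_lattice
from envenom.model import (
    CarField,
    EnvenomingParams,
    McmcResult,
    ObservedIncidence,
    bite_hazard,
    bite_probability,
    car_log_density,
    car_quadratic,
    contact_rate,
    dic,
    envenoming_probability,
    expected_incidence,
    fit_mcmc,
    forward_incidence,
    log_likelihood,
    posterior_predictive_check,
    residual_summary,
    sample_car,
)
from envenom.synth import make_default_truth, simulate_incidence


def _params(**kw):
    base = dict(
        beta0=np.zeros(5), beta1=np.zeros(5), c=np.full(7, 0.3),
        B0=0.0, B=np.zeros(5), b=np.zeros(7), tau=1.0,
    )
    base.update(kw)
    return EnvenomingParams(**base)


class TestParameterCounts:
    def test_bite_submodel_has_17_parameters(self):
        assert _params().n_bite_parameters == 17

    def test_envenoming_submodel_has_13_parameters(self):
        assert _params().n_envenoming_parameters == 13

    def test_default_legend_sizes(self):
        assert len(SPECIES) == 7
        assert len(CLASSES) == 5

    def test_negative_contact_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _params(c=np.array([-0.1, 0, 0, 0, 0, 0, 0], dtype=float))


class TestForwardModel:
    @pytest.fixture()
    def grid(self, rng):
        lat = make_lattice(6, 6)
        lc = LandCoverMap(lat, rng.integers(0, 5, lat.n_cells))
        H = RasterLayer(lat, rng.gamma(3.0, 150.0, lat.shape))
        S = SpeciesAbundanceSet(lat, {s: rng.gamma(2, 0.5, lat.shape) for s in SPECIES})
        return lat, lc, H, S

    def test_zero_coefficients_give_unit_contact(self, grid):
        lat, lc, H, S = grid
        assert np.allclose(contact_rate(lc, H, _params()), 1.0)

    def test_contact_decreasing_in_population_when_slope_negative(self, grid):
        lat, lc, H, S = grid
        p = _params(beta1=np.full(5, -0.3))
        beta = contact_rate(lc, H, p)
        order = np.argsort(H.flat)
        for k in range(5):
            cells = np.flatnonzero(lc.flat == k)
            if len(cells) > 1:
                vals = beta.ravel()[cells]
                hs = H.flat[cells]
                assert np.all(np.diff(vals[np.argsort(hs)]) <= 1e-12)

    def test_contact_matches_naive_loop(self, grid, rng):
        lat, lc, H, S = grid
        p = _params(beta0=rng.standard_normal(5), beta1=0.1 * rng.standard_normal(5))
        beta = contact_rate(lc, H, p)
        for i in range(6):
            for j in range(6):
                k = lc.classes[i, j]
                ref = np.exp(p.beta0[k] + p.beta1[k] * np.log1p(H.values[i, j]))
                assert beta[i, j] == pytest.approx(ref, rel=1e-12)

    def test_hazard_arithmetic_and_floor(self):
        lat = make_lattice(3, 3)
        beta = np.ones(lat.shape)
        S = np.zeros((9, 7))
        S[:, 0] = 3.0
        p = _params(c=np.array([2.0, 0, 0, 0, 0, 0, 0], dtype=float))
        h = bite_hazard(beta, p, S, rho=0.0)
        assert np.allclose(h, 6.0)
        h2 = bite_hazard(beta, p, S, rho=np.full(9, -10.0))
        assert np.allclose(h2, 0.0)  # floored
        h3 = bite_hazard(beta, _params(), np.zeros((9, 7)), rho=0.0)
        assert np.allclose(h3, 0.0)

    def test_bite_probability_closed_forms(self):
        assert bite_probability(np.array([0.0]))[0] == 0.0
        assert bite_probability(np.array([np.log(2.0)]))[0] == pytest.approx(0.5)
        assert 1.0 - bite_probability(np.array([50.0]))[0] < 1e-15
        assert bite_probability(np.array([50.0]))[0] < 1.0
        with pytest.raises(InvalidArgumentError):
            bite_probability(np.array([-0.1]))

    def test_envenoming_probability_closed_forms(self, grid):
        lat, lc, H, S = grid
        zero_S = SpeciesAbundanceSet(lat, {s: np.zeros(lat.shape) for s in SPECIES})
        assert np.allclose(envenoming_probability(lc, zero_S, _params()), 0.5)
        from scipy.special import logit

        p = _params(B0=float(logit(0.8)))
        assert np.allclose(envenoming_probability(lc, zero_S, p), 0.8)

    def test_envenoming_probability_matches_naive_loop(self, grid, rng):
        lat, lc, H, S = grid
        p = _params(B0=0.3, B=rng.standard_normal(5), b=0.2 * rng.standard_normal(7))
        pe = envenoming_probability(lc, S, p)
        Smat = S.matrix()
        for i in range(6):
            for j in range(6):
                cell = i * 6 + j
                eta = p.B0 + p.B[lc.classes[i, j]] + Smat[cell] @ p.b
                assert pe[i, j] == pytest.approx(1 / (1 + np.exp(-eta)), rel=1e-12)

    def test_expected_incidence_arithmetic_and_bound(self, rng):
        H = np.array([[1000.0, 10.0, 1.0]] * 3)
        pb = np.full((3, 3), 0.1)
        pe = np.full((3, 3), 0.5)
        out = expected_incidence(H, pb, pe)
        assert out[0, 0] == pytest.approx(50.0)
        assert np.all(out <= H)
        assert np.all(expected_incidence(H, np.zeros((3, 3)), pe) == 0)

    def test_incidence_monotone_in_abundance(self, grid, rng):
        """With c_s > 0 and b_s >= 0, raising any one species' abundance
        never lowers expected incidence."""
        lat, lc, H, S = grid
        p = _params(
            beta0=np.full(5, -3.0), beta1=np.full(5, 0.1),
            c=rng.uniform(0.05, 0.5, 7), b=rng.uniform(0.0, 0.3, 7), B0=-1.0,
        )
        Hpop = H.values
        base = forward_incidence(lc, H, Hpop, S, p)
        for s in SPECIES[:3]:
            bumped = {k: v.copy() for k, v in S.layers.items()}
            bumped[s] = bumped[s] + 0.5
            S2 = SpeciesAbundanceSet(lat, bumped)
            out = forward_incidence(lc, H, Hpop, S2, p)
            assert np.all(out >= base - 1e-12)


class TestCarDensity:
    def test_zero_field_quadratic(self):
        lat = make_lattice(3, 3)
        rho = CarField(lat, np.zeros(9))
        n = 9
        assert car_log_density(rho, 2.0) == pytest.approx(0.5 * (n - 1) * np.log(2.0))

    def test_hand_computed_quadratic_on_3x3(self):
        lat = make_lattice(3, 3)
        vals = np.arange(9, dtype=float)
        vals -= vals.mean()
        edges = lat.rook_edges()
        hand = sum((vals[i] - vals[j]) ** 2 for i, j in edges)
        assert car_quadratic(vals, edges) == pytest.approx(hand, rel=1e-12)

    def test_density_ratio_matches_dense_pseudoinverse_gaussian(self, rng):
        """On a 3x3 lattice the ICAR log-density difference between two
        fields equals the multivariate-normal ratio built from the dense
        pseudo-inverse covariance."""
        lat = make_lattice(3, 3)
        tau = 1.7
        edges = lat.rook_edges()
        Q = np.zeros((9, 9))
        Q[edges[:, 0], edges[:, 1]] = -tau
        Q[edges[:, 1], edges[:, 0]] = -tau
        np.fill_diagonal(Q, tau * lat.n_neighbours())
        cov = np.linalg.pinv(Q)
        mvn = multivariate_normal(mean=np.zeros(9), cov=cov, allow_singular=True)
        for _ in range(5):
            a = rng.standard_normal(9)
            a -= a.mean()
            b = rng.standard_normal(9)
            b -= b.mean()
            ours = car_log_density(CarField(lat, a), tau) - car_log_density(CarField(lat, b), tau)
            ref = mvn.logpdf(a) - mvn.logpdf(b)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_unbalanced_rho_rejected(self):
        lat = make_lattice(3, 3)
        with pytest.raises(InvalidArgumentError):
            CarField(lat, np.ones(9))

    def test_sample_car_is_centred_and_scales_with_tau(self, rng):
        lat = make_lattice(10, 10)
        a = sample_car(lat, 10.0, np.random.default_rng(1))
        b = sample_car(lat, 1000.0, np.random.default_rng(1))
        assert abs(a.sum()) < 1e-9
        assert a.std() == pytest.approx(10.0 * b.std(), rel=1e-9)


class TestLikelihood:
    def _obs(self, y, H=10.0):
        lat = make_lattice(3, 3)
        return ObservedIncidence(lat, np.full(lat.shape, float(y)), np.full(lat.shape, H), 2010)

    def test_zero_counts_unit_mean_closed_form(self):
        obs = self._obs(0.0)
        assert log_likelihood(obs, np.ones((3, 3))) == pytest.approx(-9.0)

    def test_zero_mean_with_positive_count_is_minus_inf(self):
        obs = self._obs(1.0)
        assert log_likelihood(obs, np.zeros((3, 3))) == -np.inf

    def test_mean_at_count_maximises_term(self):
        obs = self._obs(4.0)
        at_mode = log_likelihood(obs, np.full((3, 3), 4.0))
        assert at_mode > log_likelihood(obs, np.full((3, 3), 5.0))
        assert at_mode > log_likelihood(obs, np.full((3, 3), 3.0))

    def test_matches_scipy_pmf_sum(self, rng):
        from scipy.stats import poisson

        lat = make_lattice(4, 4)
        mu = rng.gamma(2.0, 3.0, lat.shape)
        y = rng.poisson(mu).astype(float)
        obs = ObservedIncidence(lat, y, np.full(lat.shape, 1e4), 2010)
        ref = poisson.logpmf(y, mu).sum()
        assert log_likelihood(obs, mu) == pytest.approx(ref, rel=1e-10)

    def test_binomial_family(self, rng):
        from scipy.stats import binom

        lat = make_lattice(4, 4)
        H = np.full(lat.shape, 50.0)
        p = rng.uniform(0.05, 0.3, lat.shape)
        y = rng.binomial(50, p).astype(float)
        obs = ObservedIncidence(lat, y, H, 2010)
        ref = binom.logpmf(y, 50, p).sum()
        assert log_likelihood(obs, H * p, family="binomial") == pytest.approx(ref, rel=1e-10)


def _toy_result(lat, y, mu):
    """Hand-built McmcResult with constant draws for DIC/PPC edge cases."""
    names = [f"p{i}" for i in range(30)] + ["tau"]
    draws = np.ones((2, 10, 31))
    obs = ObservedIncidence(lat, y, np.full(lat.shape, 1e5), 2010)
    ll = log_likelihood(obs, mu)
    return McmcResult(
        names=names,
        draws=draws,
        loglik_draws=np.full((2, 10), ll),
        mu_draws=np.tile(mu.ravel(), (2, 2, 1)),
        rho_mean=np.zeros(lat.n_cells),
        summary=pd.DataFrame({"median": np.ones(31)}, index=names),
        accept_rates={},
        seed=0,
    ), obs


class TestDicAndChecks:
    def test_degenerate_chain_gives_zero_pd(self, rng):
        lat = make_lattice(5, 5)
        mu = rng.gamma(3.0, 2.0, lat.shape)
        y = rng.poisson(mu).astype(float)
        res, obs = _toy_result(lat, y, mu)
        val = dic(res, obs, None, None, None)
        assert val == pytest.approx(-2 * log_likelihood(obs, mu), rel=1e-12)

    def test_ppc_perfect_prediction_gives_unit_r(self, rng):
        lat = make_lattice(5, 5)
        y = rng.poisson(5.0, lat.shape).astype(float)
        res, obs = _toy_result(lat, y, y.astype(float))
        out = posterior_predictive_check(res, obs, n_mc=99, seed=1)
        assert out["r"] == pytest.approx(1.0)
        assert out["p_mc"] <= 0.05

    def test_ppc_calibrated_under_independence(self, rng):
        """Unrelated prediction and observation fields should rarely reject."""
        lat = make_lattice(20, 20)
        rejections = 0
        n_sims = 30
        for k in range(n_sims):
            local = np.random.default_rng(k)
            y = local.poisson(5.0, lat.shape).astype(float)
            pred = local.gamma(3.0, 2.0, lat.shape)
            res, obs = _toy_result(lat, y, pred)
            out = posterior_predictive_check(res, obs, n_mc=199, seed=k)
            rejections += out["p_mc"] <= 0.05
        assert rejections <= 0.2 * n_sims

    def test_residuals_zero_for_perfect_fit(self, rng):
        lat = make_lattice(5, 5)
        y = rng.poisson(5.0, lat.shape).astype(float)
        res, obs = _toy_result(lat, y, y.astype(float))
        out = residual_summary(res, obs)
        assert out["mean"] == 0.0
        assert np.all(out["residuals"] == 0)


class TestSampler:
    def test_same_seed_gives_identical_chains(self):
        truth = make_default_truth(seed=5)
        obs = simulate_incidence(truth, 2010, seed=6)
        kw = dict(n_chains=2, n_iter=400, seed=11)
        a = fit_mcmc(obs, truth.species, truth.landcover, truth.h2010_layer(), **kw)
        b = fit_mcmc(obs, truth.species, truth.landcover, truth.h2010_layer(), **kw)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.mu_draws, b.mu_draws)

    def test_chain_persistence_round_trip(self, tmp_path):
        truth = make_default_truth(seed=5)
        obs = simulate_incidence(truth, 2010, seed=6)
        res = fit_mcmc(obs, truth.species, truth.landcover, truth.h2010_layer(),
                       n_chains=2, n_iter=300, seed=13)
        res.save(tmp_path)
        frame = pd.read_csv(tmp_path / "chains.csv")
        assert len(frame) == 2 * 150
        assert "c[Hypnale spp]" in frame.columns
        import json

        report = json.loads((tmp_path / "diagnostics.json").read_text())
        assert report["n_chains"] == 2
        assert "rhat" in report

    def test_flat_data_collapses_fitted_hazard(self):
        """All-zero counts: the fitted incidence surface and the implied
        bite hazard collapse towards zero.  (The bare c_s are confounded
        with the contact intercepts, so the identified quantity is the
        hazard product, not c alone.)"""
        truth = make_default_truth(seed=5)
        obs = simulate_incidence(truth, 2010, seed=6)
        zero = ObservedIncidence(obs.lattice, np.zeros(obs.lattice.shape), obs.H, 2010)
        res = fit_mcmc(zero, truth.species, truth.landcover, truth.h2010_layer(),
                       n_chains=2, n_iter=1500, seed=12)
        mu_med = res.predicted_median()
        assert mu_med.mean() < 0.05
        assert np.all(mu_med / np.maximum(obs.H.ravel(), 1.0) < 1e-3)
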