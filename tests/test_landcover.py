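import itertools

import numpy as np
import pytest

from envenom.errors import InvalidArgumentError, NonConvergenceError, SeparationError
from envenom.landcover import (
    CLASSES,
    DemandTrajectory,
    LandCoverMap,
    TransitionRules,
    TreeCoverField,
    _scores,
    allocate_year,
    categories_to_proportion,
    derived_covariates,
    fit_location_factors,
    simulate_landcover,
    suitability,
)
from envenom.lattice import RasterLayer, make_lattice
from envenom.synth import gen_landcover


class TestLocationFactors:
    def test_recovers_generating_logistic(self, rng):
        """Presence generated from logistic(0.5 + 2 x) is recovered for the
        focal class; a driver unrelated to the map gets a near-zero slope."""
        lat = make_lattice(20, 20)
        x = rng.standard_normal(lat.shape)
        p = 1 / (1 + np.exp(-(0.5 + 2.0 * x)))
        forest = rng.random(lat.shape) < p
        other = rng.integers(1, 5, lat.shape)
        lc = LandCoverMap(lat, np.where(forest, 0, other))
        factors = fit_location_factors(lc, [RasterLayer(lat, x)])
        assert factors.coefficients[0, 0] == pytest.approx(2.0, abs=0.8)
        assert factors.intercepts[0] == pytest.approx(0.5, abs=0.6)

    def test_unrelated_driver_slope_small(self, rng):
        lat = make_lattice(20, 20)
        lc = gen_landcover(lat, (0.3, 0.2, 0.3, 0.1, 0.1), seed=3)
        noise = RasterLayer(lat, rng.standard_normal(lat.shape))
        factors = fit_location_factors(lc, [noise])
        assert np.all(np.abs(factors.coefficients) < 1.0)

    def test_single_class_map_rejected(self):
        lat = make_lattice(5, 5)
        lc = LandCoverMap(lat, np.zeros(lat.shape, dtype=int))
        with pytest.raises(SeparationError):
            fit_location_factors(lc, [RasterLayer(lat, np.random.default_rng(0).random(lat.shape))])


class TestSuitability:
    def test_zero_coefficients_give_half(self):
        lat = make_lattice(4, 4)
        from envenom.landcover import LocationFactors

        f = LocationFactors(["x"], np.zeros(5), np.zeros((5, 1)))
        s = suitability(f, [RasterLayer(lat, np.random.default_rng(1).random(lat.shape))])
        assert np.allclose(s, 0.5)

    def test_large_intercept_saturates(self):
        lat = make_lattice(4, 4)
        from envenom.landcover import LocationFactors

        f = LocationFactors(["x"], np.full(5, 30.0), np.zeros((5, 1)))
        s = suitability(f, [RasterLayer(lat, np.zeros(lat.shape))])
        assert np.all(s > 0.999999)

    def test_matches_naive_loop(self, rng):
        lat = make_lattice(4, 4)
        from envenom.landcover import LocationFactors

        coefs = rng.standard_normal((5, 2))
        inter = rng.standard_normal(5)
        f = LocationFactors(["a", "b"], inter, coefs)
        drivers = [RasterLayer(lat, rng.standard_normal(lat.shape)) for _ in range(2)]
        s = suitability(f, drivers)
        for k in range(5):
            for i in range(4):
                for j in range(4):
                    eta = inter[k] + sum(
                        coefs[k, d] * drivers[d].values[i, j] for d in range(2)
                    )
                    assert s[k, i, j] == pytest.approx(1 / (1 + np.exp(-eta)), rel=1e-12)


class TestAllocator:
    def test_fixed_point_with_matching_demand(self, rng):
        lat = make_lattice(8, 8)
        lc = gen_landcover(lat, (0.3, 0.2, 0.3, 0.1, 0.1), seed=1)
        suit = np.full((5, 8, 8), 0.5)
        out = allocate_year(lc, suit, lc.counts(), tol=0)
        assert np.array_equal(out.classes, lc.classes)

    def test_demand_shift_converts_highest_suitability_cells(self, rng):
        """Ten forest cells must convert to agriculture, picked in order of
        agricultural suitability."""
        lat = make_lattice(8, 8)
        classes = np.zeros(64, dtype=int)
        classes[:12] = 1
        classes[12:24] = 2
        classes[24:30] = 3
        classes[30:36] = 4
        rng.shuffle(classes)
        lc = LandCoverMap(lat, classes)
        # small non-degenerate noise on the other classes; agriculture's
        # suitability carries the real signal
        suit = 0.5 + 0.01 * rng.standard_normal((5, 8, 8))
        agri_pref = rng.random(64)
        suit[2] = (0.2 + 0.6 * agri_pref).reshape(8, 8)
        demand = lc.counts().copy()
        demand[0] -= 10
        demand[2] += 10
        out = allocate_year(lc, suit, demand, tol=0, elasticity=5.0)
        changed = np.flatnonzero((lc.flat == 0) & (out.flat == 2))
        assert len(changed) == 10
        # converted forest cells are exactly the 10 with top agri suitability
        forest = np.flatnonzero(lc.flat == 0)
        top10 = forest[np.argsort(-agri_pref[forest])[:10]]
        assert set(changed) == set(top10)

    def test_infeasible_demand_raises_nonconvergence(self):
        lat = make_lattice(4, 4)
        lc = LandCoverMap(lat, np.full(16, 3))  # all urban
        allowed = np.eye(5, dtype=bool)  # nothing may change
        demand = np.array([16, 0, 0, 0, 0])  # wants all forest
        with pytest.raises(NonConvergenceError) as err:
            allocate_year(lc, np.full((5, 4, 4), 0.5), demand,
                          TransitionRules(allowed=allowed), max_iter=50)
        assert err.value.offsets is not None

    def test_matches_exhaustive_search_on_tiny_maps(self, rng):
        """With tol 0 the competitive allocation equals the assignment
        maximising total score subject to demand (checked exhaustively)."""
        lat = make_lattice(3, 3)
        for _ in range(10):
            lc = LandCoverMap(lat, rng.integers(0, 5, 9))
            suit = rng.random((5, 3, 3)) * 0.9 + 0.05
            demand = np.bincount(rng.integers(0, 5, 9), minlength=5)
            rules = TransitionRules()
            base = _scores(suit, lc.flat, np.full(5, 0.5), rules.allowed)
            best = max(
                base[np.arange(9), list(perm)].sum()
                for perm in set(itertools.permutations(np.repeat(np.arange(5), demand)))
            )
            out = allocate_year(lc, suit, demand, rules, 0.5, tol=0, max_iter=2000)
            got = base[np.arange(9), out.flat].sum()
            assert got == pytest.approx(best, abs=1e-9)

    def test_restricted_cells_never_change(self, rng):
        lat = make_lattice(8, 8)
        lc = gen_landcover(lat, (0.3, 0.2, 0.3, 0.1, 0.1), seed=2)
        restrict = np.zeros(lat.shape, dtype=bool)
        restrict[:2] = True
        demand = lc.counts().copy()
        demand[0] -= 5
        demand[2] += 5
        out = allocate_year(
            lc, np.random.default_rng(5).random((5, 8, 8)), demand,
            TransitionRules(restrictions=restrict), tol=1,
        )
        assert np.array_equal(out.classes[:2], lc.classes[:2])


class TestSimulateLandcover:
    @pytest.fixture()
    def setup(self, rng):
        lat = make_lattice(10, 10)
        lc = gen_landcover(lat, (0.3, 0.2, 0.3, 0.1, 0.1), seed=4)
        drivers = [RasterLayer(lat, rng.standard_normal(lat.shape))]
        factors = fit_location_factors(lc, drivers)
        return lat, lc, drivers, factors

    def test_constant_demand_keeps_map_stable(self, setup):
        lat, lc, drivers, factors = setup
        demand = DemandTrajectory.linear(lc.counts(), lc.counts(), range(2010, 2021))
        series = simulate_landcover(lc, demand, factors, drivers, elasticity=4.0)
        churn = (series[2020].classes != lc.classes).sum()
        assert churn <= 5

    def test_monotone_urban_demand_growth(self, setup):
        lat, lc, drivers, factors = setup
        end = lc.counts().copy()
        shift = min(10, end[0] - 1)
        end[0] -= shift
        end[3] += shift
        demand = DemandTrajectory.linear(lc.counts(), end, range(2010, 2021))
        series = simulate_landcover(lc, demand, factors, drivers)
        urban = [series[y].counts()[3] for y in range(2010, 2021)]
        assert all(b >= a - 1 for a, b in zip(urban, urban[1:]))
        assert urban[-1] == pytest.approx(end[3], abs=1)

    def test_deterministic_rerun(self, setup):
        lat, lc, drivers, factors = setup
        demand = DemandTrajectory.linear(lc.counts(), lc.counts(), range(2010, 2016))
        a = simulate_landcover(lc, demand, factors, drivers)
        b = simulate_landcover(lc, demand, factors, drivers)
        for y in a:
            assert np.array_equal(a[y].classes, b[y].classes)


class TestTreeCover:
    def test_single_band_maps_to_reference(self):
        lat = make_lattice(4, 4)
        tree = TreeCoverField(lat, categories=np.ones(lat.shape, dtype=int))
        out = categories_to_proportion(tree, 0.10)
        assert np.allclose(out.proportion, 0.10)

    def test_mixed_bands_mean_equals_reference(self, rng):
        lat = make_lattice(6, 6)
        tree = TreeCoverField(lat, categories=rng.integers(1, 6, lat.shape))
        out = categories_to_proportion(tree, 0.35)
        assert out.proportion.mean() == pytest.approx(0.35, abs=1e-9)

    def test_clamped_at_099(self):
        lat = make_lattice(4, 4)
        cats = np.ones(lat.shape, dtype=int)
        cats[0, 0] = 5
        out = categories_to_proportion(TreeCoverField(lat, categories=cats), 0.9)
        assert out.proportion.max() <= 0.99

    def test_reference_out_of_range_rejected(self):
        lat = make_lattice(4, 4)
        tree = TreeCoverField(lat, categories=np.ones(lat.shape, dtype=int))
        with pytest.raises(InvalidArgumentError):
            categories_to_proportion(tree, 1.2)


class TestDerivedCovariates:
    def test_all_agriculture(self):
        lat = make_lattice(5, 5)
        lc = LandCoverMap(lat, np.full(25, 2))
        with pytest.warns(UserWarning):
            cov = derived_covariates(lc)
        assert np.allclose(cov["prop_agriculture"], 1.0)
        assert np.all(np.isinf(cov["dist_forest"]))

    def test_forest_cells_have_zero_distance(self, rng):
        lat = make_lattice(6, 6)
        lc = gen_landcover(lat, (0.4, 0.2, 0.2, 0.1, 0.1), seed=8)
        cov = derived_covariates(lc)
        assert np.all(cov["dist_forest"][lc.mask("forest")] == 0)

    def test_distance_matches_bruteforce_scan(self, rng):
        lat = make_lattice(12, 12, cell_size=2.0)
        lc = gen_landcover(lat, (0.15, 0.25, 0.3, 0.15, 0.15), seed=9)
        cov = derived_covariates(lc)
        fr, fc = np.nonzero(lc.mask("forest"))
        for i in range(12):
            for j in range(12):
                d = np.sqrt((fr - i) ** 2 + (fc - j) ** 2).min() * 2.0
                assert cov["dist_forest"][i, j] == pytest.approx(d, rel=1e-9)
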