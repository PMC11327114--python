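import numpy as np
import pytest

from envenom.abundance import SPECIES, SpeciesAbundanceSet
from envenom.errors import InvalidArgumentError
from envenom.landcover import LandCoverMap
from envenom.lattice import make_lattice
from envenom.projection import (
    Scenario,
    dominant_species,
    national_series,
    pct_change,
    pixel_trend,
    rcm_consensus,
    run_scenario,
    summarize_run,
    transition_change_summary,
    upscale_majority,
    upscale_sum,
)
from envenom.synth import TrendSpec, make_default_truth


class TestUpscaling:
    def test_uniform_ones_sum_to_block_size(self):
        out = upscale_sum(np.ones((10, 10)), factor=5)
        assert out.shape == (2, 2)
        assert np.all(out == 25.0)

    def test_total_conserved_and_matches_block_loop(self, rng):
        arr = rng.gamma(2.0, 3.0, (20, 20))
        out = upscale_sum(arr, 5)
        assert out.sum() == pytest.approx(arr.sum(), rel=1e-12)
        for bi in range(4):
            for bj in range(4):
                block = arr[bi * 5:(bi + 1) * 5, bj * 5:(bj + 1) * 5]
                assert out[bi, bj] == pytest.approx(block.sum(), rel=1e-12)

    def test_nondivisible_dimensions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            upscale_sum(np.ones((11, 10)), 5)

    def test_majority_vote(self):
        lat = make_lattice(15, 15)
        classes = np.full(lat.shape, 2, dtype=int)
        block = np.zeros(25, dtype=int)
        block[:12] = 3  # 12 urban vs 13 forest in the first block
        classes[:5, :5] = block.reshape(5, 5)
        out = upscale_majority(LandCoverMap(lat, classes), 5)
        assert out.classes[0, 0] == 0  # forest wins 13-12
        assert np.all(out.classes.ravel()[1:] == 2)

    def test_majority_tie_goes_to_lowest_class(self):
        lat = make_lattice(12, 12)
        classes = np.full(lat.shape, 1, dtype=int)
        classes[:4, :4] = np.array([0] * 8 + [3] * 8).reshape(4, 4)
        out = upscale_majority(LandCoverMap(lat, classes), 4)
        assert out.classes[0, 0] == 0

    def test_majority_matches_counting_oracle(self, rng):
        lat = make_lattice(20, 20)
        lc = LandCoverMap(lat, rng.integers(0, 5, 400))
        out = upscale_majority(lc, 5)
        for bi in range(4):
            for bj in range(4):
                block = lc.classes[bi * 5:(bi + 1) * 5, bj * 5:(bj + 1) * 5]
                counts = np.bincount(block.ravel(), minlength=5)
                assert out.classes[bi, bj] == np.argmax(counts)


class TestTrendStatistics:
    def test_constant_series_zero_slope(self):
        years = np.arange(2010, 2020)
        series = np.ones((10, 4, 4)) * 7.0
        assert np.allclose(pixel_trend(series, years), 0.0)

    def test_exact_linear_slope(self):
        years = np.array([2010, 2011, 2012])
        series = np.stack([np.full((3, 3), v) for v in (1.0, 2.0, 3.0)])
        assert np.allclose(pixel_trend(series, years), 1.0)

    def test_matches_closed_form_ols(self, rng):
        years = np.arange(2010, 2031)
        series = rng.standard_normal((21, 5, 5))
        slopes = pixel_trend(series, years)
        t = years - years.mean()
        for i in range(5):
            for j in range(5):
                ref = (t @ (series[:, i, j] - series[:, i, j].mean())) / (t @ t)
                assert slopes[i, j] == pytest.approx(ref, rel=1e-10)

    def test_too_few_years_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pixel_trend(np.ones((2, 3, 3)), np.array([2010, 2011]))

    def test_pct_change_arithmetic_and_mask(self):
        a = np.array([[10.0, 5.0], [0.0, 2.0]])
        b = np.array([[8.0, 5.0], [1.0, 4.0]])
        out = pct_change(a, b)
        assert out[0, 0] == pytest.approx(-20.0)
        assert out[0, 1] == 0.0
        assert np.isnan(out[1, 0])
        assert out[1, 1] == pytest.approx(100.0)

    def test_trend_and_pct_sign_agree_on_linear_series(self, rng):
        years = np.arange(2010, 2051)
        base = rng.gamma(3.0, 2.0, (4, 4)) + 1.0
        slope_true = rng.standard_normal((4, 4)) * 0.01
        series = base[None] + slope_true[None] * (years - 2010)[:, None, None]
        series = np.maximum(series, 0.01)
        slopes = pixel_trend(series, years)
        pct = pct_change(series[0], series[-1])
        ok = np.abs(slope_true) > 1e-5
        assert np.all(np.sign(slopes[ok]) == np.sign(pct[ok]))


class TestNationalSeries:
    def test_flat_series(self):
        years = np.arange(2010, 2051)
        series = np.ones((41, 4, 4))
        pop = np.full((41, 4, 4), 100.0)
        out = national_series(series, pop, years)
        assert np.allclose(out["pct_change"], 0.0, atol=1e-9)
        assert np.allclose(out["se"].iloc[1:], 0.0, atol=1e-9)

    def test_linear_decline_accumulates(self):
        """A decline of exactly 0.5% of baseline per year reaches -20%
        accumulated by 2050."""
        years = np.arange(2010, 2051)
        base = 0.01
        rate = base * (1 - 0.005 * (years - 2010))
        series = rate[:, None, None] * np.full((41, 1, 1), 100.0)
        pop = np.full((41, 1, 1), 100.0)
        out = national_series(series, pop, years)
        assert out["pct_change"].iloc[-1] == pytest.approx(-20.0, rel=1e-9)

    def test_slope_se_matches_textbook_formula(self, rng):
        years = np.arange(2010, 2031)
        rate = 0.01 + 0.0001 * rng.standard_normal(21)
        series = rate[:, None, None] * 100.0
        pop = np.full((21, 1, 1), 100.0)
        out = national_series(series, pop, years)
        t = years - years.mean()
        slope = (t @ (rate - rate.mean())) / (t @ t)
        resid = rate - rate.mean() - slope * t
        se = np.sqrt(resid @ resid / (21 - 2) / (t @ t))
        base = rate.mean() + slope * (2010 - years.mean())
        assert out["se"].iloc[-1] == pytest.approx(100 * se * 20 / base, rel=1e-9)


class TestConsensusAndDominance:
    def test_all_negative_layers(self, rng):
        layers = [-rng.random((4, 4)) for _ in range(3)]
        cons, frac = rcm_consensus(layers)
        assert np.all(cons == 3)
        assert frac[3] == 1.0
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_zero_slope_counts_as_not_decreasing(self):
        cons, frac = rcm_consensus([np.zeros((3, 3))])
        assert np.all(cons == 0)

    def test_matches_bruteforce_count(self, rng):
        layers = [rng.standard_normal((6, 6)) for _ in range(3)]
        cons, frac = rcm_consensus(layers)
        for i in range(6):
            for j in range(6):
                assert cons[i, j] == sum(lay[i, j] < 0 for lay in layers)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_empty_layer_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rcm_consensus([])

    def test_dominant_species_weighting(self):
        lat = make_lattice(3, 3)
        from envenom.synth import default_params

        params = default_params()
        layers = {s: np.ones(lat.shape) for s in SPECIES}
        S = SpeciesAbundanceSet(lat, layers)
        dom = dominant_species(S, params)
        w = params.c * np.exp(params.b)
        assert np.all(dom == np.argmax(w))

    def test_dominant_two_species_tie_and_order(self):
        lat = make_lattice(3, 3)
        from envenom.model import EnvenomingParams

        params = EnvenomingParams(
            beta0=np.zeros(5), beta1=np.zeros(5),
            c=np.array([2.0, 1.0, 0, 0, 0, 0, 0], dtype=float),
            B0=0.0, B=np.zeros(5), b=np.zeros(7),
        )
        layers = {s: np.ones(lat.shape) for s in SPECIES}
        dom = dominant_species(SpeciesAbundanceSet(lat, layers), params)
        assert np.all(dom == 0)

    def test_bruteforce_argmax_oracle(self, rng):
        lat = make_lattice(4, 4)
        from envenom.synth import default_params

        params = default_params()
        layers = {s: rng.gamma(2.0, 1.0, lat.shape) for s in SPECIES}
        S = SpeciesAbundanceSet(lat, layers)
        dom = dominant_species(S, params)
        stack = np.stack([params.c[i] * np.exp(params.b[i]) * layers[s]
                          for i, s in enumerate(SPECIES)])
        assert np.array_equal(dom, np.argmax(stack, axis=0))


class TestTransitionSummary:
    def test_single_transition_row(self):
        lat = make_lattice(3, 3)
        lc = LandCoverMap(lat, np.zeros(9, dtype=int))
        out = transition_change_summary(lc, lc, np.zeros((3, 3)))
        assert len(out) == 1
        assert out.iloc[0]["from"] == "forest"
        assert out.iloc[0]["median"] == 0.0
        assert out.iloc[0]["n_cells"] == 9

    def test_hand_built_three_transition_map(self):
        lat = make_lattice(3, 3)
        start = LandCoverMap(lat, np.array([0, 0, 0, 1, 1, 1, 2, 2, 2]))
        end = LandCoverMap(lat, np.array([0, 0, 0, 2, 2, 2, 2, 2, 2]))
        pct = np.array([[10.0, 20, 30], [-5, -10, -15], [1, 2, 3]])
        out = transition_change_summary(start, end, pct).set_index(["from", "to"])
        assert out.loc[("forest", "forest"), "median"] == 20.0
        assert out.loc[("degraded_forest", "agriculture"), "median"] == -10.0
        assert out.loc[("agriculture", "agriculture"), "median"] == 2.0
        assert len(out) == 3

    def test_row_count_bounded_by_legend_pairs(self, rng):
        lat = make_lattice(6, 6)
        a = LandCoverMap(lat, rng.integers(0, 5, 36))
        b = LandCoverMap(lat, rng.integers(0, 5, 36))
        out = transition_change_summary(a, b, rng.standard_normal((6, 6)))
        assert len(out) <= 25


class TestScenario:
    def test_valid_pairings(self):
        Scenario("SSP1", "none", "historical-trend")
        Scenario("SSP2", "RCP4.5", "GFDL-CM3")
        Scenario("SSP5", "RCP8.5", "MPI-ESM-LR")

    @pytest.mark.parametrize(
        "ssp,rcp,rcm",
        [
            ("SSP1", "RCP4.5", "historical-trend"),
            ("SSP2", "RCP8.5", "CNRM-CM5"),
            ("SSP5", "RCP8.5", "historical-trend"),
            ("SSP3", "RCP4.5", "CNRM-CM5"),
        ],
    )
    def test_invalid_pairings_rejected(self, ssp, rcp, rcm):
        with pytest.raises(InvalidArgumentError):
            Scenario(ssp, rcp, rcm)


@pytest.fixture(scope="module")
def fixture_truth():
    return make_default_truth(seed=13)


class TestScenarioRun:
    def test_null_run_is_flat_and_reproducible(self, fixture_truth):
        sc = Scenario("SSP1", "none", "historical-trend", population_growth=(1.0,))
        a = run_scenario(sc, fixture_truth.params, fixture_truth, years=range(2010, 2021))
        b = run_scenario(sc, fixture_truth.params, fixture_truth, years=range(2010, 2021))
        assert np.array_equal(a.incidence, b.incidence)
        s = summarize_run(a)
        assert abs(s.national["pct_change"].iloc[-1]) < 1.0

    def test_rcm_run_produces_finite_series(self, fixture_truth):
        sc = Scenario("SSP2", "RCP4.5", "CNRM-CM5", trend=TrendSpec(0.2, 0.98),
                      population_growth=(1.05,))
        run = run_scenario(sc, fixture_truth.params, fixture_truth, years=range(2010, 2021))
        assert np.all(np.isfinite(run.incidence))
        assert np.all(run.incidence >= 0)
        assert np.all(run.incidence <= run.population + 1e-9)
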