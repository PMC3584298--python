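"""The forward cascade: closed forms, the recall link, and the ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memchain as mc
from memchain.chain import POWER, StoreParams, _grid_convolve


class TestStoreIntensity:
    @pytest.mark.parametrize(
        "mu1,a1,mu2,a2,index,t,expected",
        [
            # store 1 keeps its acquired intensity at t = 0
            (2.0, 0.3, None, None, 1, 0.0, 2.0),
            # plain exponential decline of store 1
            (1.50, 0.103, 0.00325, 0.0, 1, 3.5, 1.50 * np.exp(-0.103 * 3.5)),
            # a2 = 0 consolidation: (mu1 mu2 / a1)(1 - e^(-a1 t))
            (2.0, 0.3, 0.1, 0.0, 2, 5.0, (2 * 0.1 / 0.3) * (1 - np.exp(-1.5))),
        ],
    )
    def test_closed_forms(self, mu1, a1, mu2, a2, index, t, expected):
        if mu2 is None:
            params = mc.ChainParams((StoreParams(mu1, a1),))
        else:
            params = mc.two_store(mu1, a1, mu2, a2)
        assert mc.store_intensity(params, index, t) == pytest.approx(expected, rel=1e-12)

    def test_store2_asymptote(self, cho_params):
        # consolidated intensity saturates at mu1 mu2 / a1 when a2 = 0
        limit = 1.50 * 0.00325 / 0.103
        assert mc.store_intensity(cho_params, 2, 1e6) == pytest.approx(limit, rel=1e-9)

    def test_equal_decline_rates_confluent_form(self):
        # a1 = a2 breaks the distinct-rate form; cascade gives mu1 mu2 t e^(-a t)
        params = mc.two_store(1.2, 0.4, 0.3, 0.4)
        t = np.array([0.5, 2.0, 7.0])
        expected = 1.2 * 0.3 * t * np.exp(-0.4 * t)
        np.testing.assert_allclose(mc.store_intensity(params, 2, t), expected,
                                   rtol=1e-8, atol=1e-10)

    def test_both_rates_zero_gives_linear_growth(self):
        params = mc.two_store(1.5, 0.0, 0.2, 0.0)
        assert mc.store_intensity(params, 2, 4.0) == pytest.approx(1.5 * 0.2 * 4.0,
                                                                   rel=1e-8)

    def test_invalid_index_and_negative_time(self, demo_params):
        with pytest.raises(IndexError):
            mc.store_intensity(demo_params, 3, 1.0)
        with pytest.raises(ValueError):
            mc.store_intensity(demo_params, 1, -0.5)


class TestTotalIntensityAndLink:
    def test_initial_total_is_q_mu1(self, demo_params):
        assert mc.total_intensity(demo_params, 0.0) == pytest.approx(2.0)

    def test_two_store_sum(self, demo_params):
        expected = 2 * np.exp(-1.5) + (0.2 / 0.3) * (1 - np.exp(-1.5))
        assert mc.total_intensity(demo_params, 5.0) == pytest.approx(expected, rel=1e-12)

    def test_cue_quality_is_multiplicative(self, demo_params):
        half = mc.ChainParams(demo_params.stores, q=0.5)
        t = np.linspace(0, 20, 9)
        np.testing.assert_allclose(mc.total_intensity(half, t),
                                   0.5 * mc.total_intensity(demo_params, t), rtol=1e-12)

    def test_recall_probability_examples(self, demo_params):
        assert mc.probability_from_intensity(0.0) == 0.0
        assert mc.recall_probability(demo_params, 0.0) == pytest.approx(1 - np.exp(-2))

    def test_guess_floor_bounds(self):
        # 2AFC floor: chance at zero intensity, ceiling 1 at infinite intensity
        assert mc.probability_from_intensity(0.0, g=0.5) == pytest.approx(0.5)
        assert mc.probability_from_intensity(50.0, g=0.5) == pytest.approx(1.0)

    def test_intensity_transform_values(self):
        assert mc.intensity_from_probability(0.0) == 0.0
        assert mc.intensity_from_probability(0.90) == pytest.approx(-np.log(0.1))
        ratio = (mc.intensity_from_probability(0.90)
                 / mc.intensity_from_probability(0.60))
        assert ratio == pytest.approx(np.log(0.1) / np.log(0.4), rel=1e-12)

    @given(st.floats(min_value=1e-6, max_value=12.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_link_round_trip(self, x):
        # above ~12 the double-precision tail of 1 - p limits the inverse
        p = mc.probability_from_intensity(x)
        assert mc.intensity_from_probability(p) == pytest.approx(x, rel=1e-12,
                                                                 abs=1e-12)

    def test_transform_rejects_and_clips(self):
        with pytest.raises(ValueError):
            mc.intensity_from_probability(-0.1)
        with pytest.raises(ValueError):
            mc.intensity_from_probability(1.0, strict=True)
        with pytest.warns(UserWarning):
            val = mc.intensity_from_probability(1.0)
        assert np.isfinite(val)

    def test_guess_floor_correction(self):
        p = mc.probability_from_intensity(0.7, g=0.25)
        assert mc.intensity_from_probability(p, g=0.25) == pytest.approx(0.7)


class TestMonotonicityRegimes:
    """Total intensity falls iff consolidation is slower than store-1 decline."""

    def test_forgetting_regime(self):
        params = mc.two_store(2.0, 0.3, 0.1, 0.0)  # mu2 < a1
        t = np.linspace(0, 30, 301)
        diffs = np.diff(mc.total_intensity(params, t))
        assert np.all(diffs < 0)

    def test_reminiscence_regime(self):
        params = mc.two_store(2.0, 0.1, 0.3, 0.0)  # mu2 > a1
        t = np.linspace(0, 30, 301)
        diffs = np.diff(mc.total_intensity(params, t))
        assert np.all(diffs > 0)


class TestOdeOracle:
    def test_matches_closed_forms_on_random_chains(self, rng):
        for _ in range(10):
            n = rng.integers(2, 4)
            mus = rng.uniform(0.2, 3.0, n)
            rates = rng.uniform(0.02, 1.2, n)
            params = mc.ChainParams(tuple(StoreParams(m, a) for m, a in zip(mus, rates)))
            t = np.sort(rng.uniform(0, 25, 6))
            curve = mc.ode_oracle(params, t)
            closed = mc.intensity_components(params, t)
            np.testing.assert_allclose(curve.per_store, closed, rtol=1e-8, atol=1e-8)

    def test_zero_consolidation_keeps_store2_empty(self):
        params = mc.two_store(1.4, 0.2, 0.0, 0.0)
        curve = mc.ode_oracle(params, np.linspace(0, 10, 5))
        assert np.all(curve.per_store[:, 1] == 0)

    def test_total_is_row_sum(self, demo_params):
        curve = mc.ode_oracle(demo_params, np.linspace(0, 10, 5))
        np.testing.assert_allclose(curve.total, curve.per_store.sum(axis=1))

    def test_rejects_unsorted_times(self, demo_params):
        with pytest.raises(ValueError):
            mc.ode_oracle(demo_params, [3.0, 1.0])


class TestPowerDecline:
    def test_store1_closed_form(self):
        params = mc.ChainParams((StoreParams(2.0, 0.8, POWER),))
        t = np.array([0.0, 1.0, 9.0])
        np.testing.assert_allclose(mc.store_intensity(params, 1, t),
                                   2.0 * (1 + t) ** -0.8, rtol=1e-12)

    def test_store2_quadrature_matches_grid_oracle(self):
        params = mc.ChainParams((StoreParams(2.0, 0.8, POWER),
                                 StoreParams(0.1, 0.0)))
        t = np.array([0.5, 2.0, 8.0])
        quad_vals = mc.store_intensity(params, 2, t)
        grid_vals = _grid_convolve(params, t)[:, 1]
        np.testing.assert_allclose(quad_vals, grid_vals, rtol=1e-5)

    def test_nonnegative_and_zero_at_origin(self):
        params = mc.ChainParams((StoreParams(1.0, 0.5, POWER),
                                 StoreParams(0.2, 0.1, POWER)))
        assert mc.store_intensity(params, 2, 0.0) == 0.0
        assert mc.store_intensity(params, 2, 3.0) > 0


class TestValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            StoreParams(-1.0, 0.1)
        with pytest.raises(ValueError):
            StoreParams(1.0, -0.1)
        with pytest.raises(ValueError):
            mc.ChainParams((), q=1.0)
        with pytest.raises(ValueError):
            mc.ChainParams((StoreParams(1, 0.1),), q=0.0)
        with pytest.raises(ValueError):
            mc.ChainParams((StoreParams(1, 0.1),), g=1.0)
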