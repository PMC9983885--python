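"""Linear adaptation filters: transfer functions, cascades, DC analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import adaptspec as a

F_TINY = np.array([1e-9])
F_HUGE = np.array([1e9])


class TestSFATransfer:
    def test_dc_gain_closed_form(self):
        p = a.SFAParams(gamma=1, c=1, F=0.5, tau=1)
        assert a.sfa_transfer(p, F_TINY)[0].real == pytest.approx(2 / 3, rel=1e-6)

    def test_high_frequency_gain_is_gamma(self):
        p = a.SFAParams(gamma=1, c=1, F=0.5, tau=1)
        assert abs(a.sfa_transfer(p, F_HUGE)[0]) == pytest.approx(1.0, rel=1e-6)

    def test_no_adaptation_reduces_to_gain(self):
        f = np.logspace(-2, 2, 20)
        for p in (a.SFAParams(gamma=2.5, c=1, F=0.0), a.SFAParams(gamma=2.5, c=0.0, F=0.5)):
            assert np.allclose(a.sfa_transfer(p, f), 2.5)

    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.01, 0.95), st.floats(0.01, 10))
    def test_dc_gain_random_params(self, gamma, c, F, tau):
        p = a.SFAParams(gamma=gamma, c=c, F=F, tau=tau)
        h0 = a.sfa_transfer(p, np.array([1e-12]))[0]
        assert abs(h0) == pytest.approx(gamma / (1 + c * F), rel=1e-6)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            a.SFAParams(tau=-1)
        with pytest.raises(ValueError):
            a.SFAParams(gamma=0)


class TestSTDLinearTransfer:
    def test_dc_gain_closed_form(self):
        p = a.STDLinParams(gamma=1, F=0.5, x0=1, tau=1)
        assert a.std_linear_transfer(p, F_TINY)[0].real == pytest.approx(1 / 1.5**2, rel=1e-6)

    def test_zero_input_is_passthrough(self):
        p = a.STDLinParams(gamma=1.7, F=0.5, x0=0.0)
        assert np.allclose(a.std_linear_transfer(p, np.logspace(-2, 2, 20)), 1.7)

    def test_high_frequency_gain_is_gamma_a0(self):
        p = a.STDLinParams(gamma=1, F=0.5, x0=1)
        assert abs(a.std_linear_transfer(p, F_HUGE)[0]) == pytest.approx(1 / 1.5, rel=1e-6)

    def test_negative_x0_rejected(self):
        with pytest.raises(ValueError):
            a.STDLinParams(x0=-0.1)


class TestCascade:
    def test_highpass_dc_gain(self):
        c = a.FilterCascade(highpass=(a.HighPassStage(g=1, tau=1, A=2),))
        assert a.cascade_response(c, F_TINY)[0].real == pytest.approx(0.5, rel=1e-6)

    def test_lowpass_corner_frequency(self):
        c = a.FilterCascade(lowpass=(a.LowPassStage(k=1, tau=1),))
        w1 = np.array([1 / (2 * np.pi)])  # omega = 1 rad/s
        assert abs(a.cascade_response(c, w1)[0]) == pytest.approx(2**-0.5, rel=1e-9)

    def test_multiplicative_composition(self):
        c = a.FilterCascade(
            highpass=(a.HighPassStage(g=1, tau=1, A=2),),
            lowpass=(a.LowPassStage(k=1, tau=1),),
        )
        assert a.cascade_response(c, F_TINY)[0].real == pytest.approx(0.5, rel=1e-6)
        f = np.logspace(-2, 2, 30)
        prod = c.highpass[0].response(f) * c.lowpass[0].response(f)
        assert np.allclose(a.cascade_response(c, f), prod, rtol=1e-12)

    def test_empty_cascade_rejected(self):
        with pytest.raises(ValueError):
            a.FilterCascade()

    @given(st.floats(0.1, 5), st.floats(0.01, 10), st.floats(1.0, 10))
    def test_highpass_magnitude_nondecreasing(self, g, tau, A):
        st_ = a.HighPassStage(g=g, tau=tau, A=A)
        mag = np.abs(st_.response(np.logspace(-3, 3, 100)))
        assert np.all(np.diff(mag) >= -1e-12 * mag[:-1])

    @given(st.floats(0.1, 5), st.floats(0.01, 10))
    def test_lowpass_magnitude_nonincreasing(self, k, tau):
        mag = np.abs(a.LowPassStage(k=k, tau=tau).response(np.logspace(-3, 3, 100)))
        assert np.all(np.diff(mag) <= 1e-12 * mag[:-1])


class TestCascadeMagnitudeSq:
    PARAMS = dict(
        sfa=a.SFAParams(gamma=1, c=1, F=0.5, tau=1),
        std=a.STDLinParams(gamma=1, F=0.5, x0=1, tau=1),
        lp=a.LowPassStage(k=1, tau=1),
    )

    def test_dc_value_three_identical_sigmoids(self):
        m2 = a.cascade_magnitude_sq(f=np.array([1e-12]), **self.PARAMS)
        assert m2[0] == pytest.approx((1 / 2.25) ** 3, rel=1e-9)

    def test_vanishes_at_high_frequency(self):
        m2 = a.cascade_magnitude_sq(f=F_HUGE, **self.PARAMS)
        assert m2[0] < 1e-12

    def test_agrees_with_product_of_stages(self):
        rng = np.random.default_rng(7)
        f = np.logspace(-3, 3, 60)
        for _ in range(100):
            sfa = a.SFAParams(*rng.uniform([0.1, 0.1, 0.05, 0.05], [5, 5, 0.95, 10]))
            std = a.STDLinParams(*rng.uniform([0.1, 0.05, 0.05, 0.0], [5, 0.95, 10, 5]))
            lp = a.LowPassStage(*rng.uniform([0.1, 0.05], [5, 10]))
            direct = a.cascade_magnitude_sq(sfa, std, lp, f)
            prod = np.abs(
                a.sfa_transfer(sfa, f) * a.std_linear_transfer(std, f) * lp.response(f)
            ) ** 2
            assert np.allclose(direct, prod, rtol=1e-10)


class TestDCOutputPower:
    def test_zero_input_gives_zero(self):
        assert a.dc_output_power(1, 0.5, 1.0, 0.0) == 0.0

    def test_monotone_decreasing_beyond_peak(self):
        xpk = a.dc_peak_input(2, 0.5)
        xs = np.linspace(xpk * 1.01, xpk * 10, 50)
        vals = [a.dc_output_power(2, 0.5, 1.0, x) for x in xs]
        assert np.all(np.diff(vals) < 0)

    def test_peak_formula_examples(self):
        assert a.dc_peak_input(1, 0.5) == pytest.approx(2 / 3)
        assert a.dc_peak_input(3, 0.5) == pytest.approx(1 / 5.5)

    def test_grid_search_argmax_matches_formula(self):
        # independent numeric argmax oracle, Fig-style parameters
        x0 = np.arange(1e-4, 5.0001, 1e-4)
        vals = x0 * 2.0 ** (2 * 3) / (1 + x0 * 0.5) ** (4 * 3)
        assert x0[np.argmax(vals)] == pytest.approx(1 / 5.5, abs=1e-3)
        assert a.dc_peak_input(3, 0.5) == pytest.approx(1 / 5.5, abs=1e-12)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            a.dc_output_power(0, 0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            a.dc_peak_input(0, 0.5)


class TestShapedPSD:
    def test_flat_input_through_lowpass_is_lorentzian(self):
        f = np.logspace(-2, 2, 100)
        c = a.FilterCascade(lowpass=(a.LowPassStage(k=1, tau=1),))
        out = a.shaped_psd(c, np.ones_like(f), f)
        w = 2 * np.pi * f
        assert np.allclose(out, 1 / (w**2 + 1), rtol=1e-12)

    def test_identity_cascade_leaves_input_unchanged(self):
        f = np.logspace(-2, 2, 50)
        c = a.FilterCascade(highpass=(a.HighPassStage(g=1, tau=1, A=1),))
        psd = np.abs(np.sin(f)) + 0.5
        assert np.allclose(a.shaped_psd(c, psd, f), psd)

    def test_length_mismatch_rejected(self):
        c = a.FilterCascade(lowpass=(a.LowPassStage(),))
        with pytest.raises(ValueError):
            a.shaped_psd(c, np.ones(3), np.logspace(0, 1, 4))

    def test_stronger_adaptation_lowers_low_frequency_power(self):
        # two printed parameter sets for the three-timescale cascade
        def psd_at(A, g, freq):
            hp = tuple(a.HighPassStage(g=g, tau=t, A=A) for t in (0.05, 0.5, 5.0))
            c = a.FilterCascade(highpass=hp, lowpass=(a.LowPassStage(k=500.0, tau=5.0),))
            return a.shaped_psd(c, np.ones(1), np.array([freq]))[0]

        assert psd_at(1.5, 1.5, 0.1) < psd_at(1.1, 1.3, 0.1)


class TestPSDSlope:
    def test_flat_spectrum_has_zero_slope(self):
        f = np.logspace(-1, 1, 50)
        assert a.psd_slope(np.full_like(f, 2.0), f, (0.2, 5)) == pytest.approx(0.0, abs=1e-12)

    def test_lorentzian_tail_slope_minus_two(self):
        f = np.logspace(-2, 3, 300)
        w = 2 * np.pi * f
        psd = 1 / (w**2 * 1.0 + 1)
        assert a.psd_slope(psd, f, (50, 500)) == pytest.approx(-2.0, abs=0.02)

    def test_band_outside_grid_rejected(self):
        f = np.logspace(-1, 1, 50)
        with pytest.raises(ValueError):
            a.psd_slope(np.ones_like(f), f, (100.0, 200.0))
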