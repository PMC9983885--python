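"""Fractional operators, the superposition identity, and constant-phase fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import adaptspec as a

TAUS = [0.05, 0.5, 5.0]
BAND = (0.05, 5.0)


class TestFracPhase:
    @pytest.mark.parametrize(
        "alpha,expected", [(1.0, math.pi / 2), (0.0, 0.0), (0.3, 0.3 * math.pi / 2)]
    )
    def test_closed_form(self, alpha, expected):
        assert a.frac_phase(alpha) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            a.frac_phase(1.5)


class TestFracTransfer:
    def test_first_derivative_at_unit_omega(self):
        h = a.frac_transfer(1.0, 1.0, np.array([1 / (2 * np.pi)]))[0]
        assert h == pytest.approx(1j, abs=1e-12)

    def test_decade_amplitude_scaling(self):
        for alpha in (0.1, 0.5, 0.9):
            h = a.frac_transfer(alpha, 2.0, np.array([0.7, 7.0]))
            assert abs(h[1]) / abs(h[0]) == pytest.approx(10**alpha, rel=1e-12)

    @given(st.floats(0.01, 1.0))
    def test_phase_constant_across_grid(self, alpha):
        h = a.frac_transfer(alpha, 1.0, np.logspace(-3, 3, 200))
        assert np.allclose(np.angle(h), alpha * np.pi / 2, atol=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            a.frac_transfer(0.5, 1.0, np.array([0.0, 1.0]))


class TestConstantPhaseFit:
    def test_alpha_zero_gives_unit_A_zero_residual(self):
        r = a.fit_gains_constant_phase(TAUS, 0.0, BAND, "shared")
        assert r.A_values == (1.0,)
        assert r.residual == 0.0

    def test_small_alpha_fit_is_tight(self):
        r = a.fit_gains_constant_phase(TAUS, 0.1, BAND, "shared")
        assert r.residual < 0.05
        assert all(A >= 1 for A in r.A_values)

    def test_per_stage_never_worse_than_shared(self):
        for alpha in (0.3, 0.5):
            shared = a.fit_gains_constant_phase(TAUS, alpha, BAND, "shared")
            per = a.fit_gains_constant_phase(TAUS, alpha, BAND, "per-stage")
            assert per.residual <= shared.residual + 1e-12
            assert len(per.A_values) == len(TAUS)

    def test_residual_grows_with_alpha(self):
        r = [a.fit_gains_constant_phase(TAUS, al, BAND, "shared").residual
             for al in (0.1, 0.5, 0.9)]
        assert r[0] < r[1] < r[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            a.fit_gains_constant_phase([0.1, 0.1], 0.3, BAND)
        with pytest.raises(ValueError):
            a.fit_gains_constant_phase(TAUS, 0.3, (5.0, 0.05))

    def test_result_roundtrips_to_json(self):
        import json

        r = a.fit_gains_constant_phase(TAUS, 0.2, BAND, "shared")
        d = json.loads(r.to_json())
        assert d["alpha"] == 0.2 and len(d["A_values"]) == 1


class TestGammaSuperposition:
    @pytest.mark.parametrize(
        "k,t,expected", [(1.0, 3.0, 1 / 3), (0.5, 2.0, 2**-0.5), (0.1, 1.0, 1.0)]
    )
    def test_known_values(self, k, t, expected):
        assert a.gamma_superposition(k, t) == pytest.approx(expected, rel=1e-9)

    def test_reproduces_power_law_over_grid(self):
        for k in np.arange(0.1, 0.95, 0.2):
            for t in (0.1, 1.0, 10.0):
                assert a.gamma_superposition(k, t) == pytest.approx(t**-k, rel=1e-6)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            a.gamma_superposition(0.0, 1.0)


class TestFractionalDerivative:
    def _ramp(self, n=2001, t_end=2.0):
        t = np.linspace(0, t_end, n)
        return a.SampledSignal(t, t.copy())

    def test_order_zero_is_identity(self):
        sig = self._ramp()
        out = a.fractional_derivative(sig, 0.0)
        assert np.array_equal(out.values, sig.values)

    def test_order_one_on_ramp_is_constant(self):
        out = a.fractional_derivative(self._ramp(), 1.0)
        assert np.allclose(out.values[5:], 1.0, atol=1e-9)

    def test_half_derivative_of_ramp_closed_form(self):
        # D^0.5 t = Gamma(2)/Gamma(1.5) * t^0.5 = 2*sqrt(t/pi)
        out = a.fractional_derivative(self._ramp(), 0.5)
        i = 1000  # t = 1
        assert out.values[i] == pytest.approx(2 / math.sqrt(math.pi), abs=2e-3)

    def test_semigroup_on_ramp(self):
        # D^alpha then D^(1-alpha) applied to t gives the first derivative
        for alpha in (0.3, 0.5, 0.7):
            first = a.fractional_derivative(self._ramp(), alpha)
            second = a.fractional_derivative(first, 1.0 - alpha)
            assert np.allclose(second.values[20:], 1.0, atol=5e-3)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.4])
        with pytest.raises(ValueError):
            a.fractional_derivative(a.SampledSignal(t, t), 0.5)


class TestStepResponses:
    def test_highpass_initial_and_final_value(self):
        st_ = a.HighPassStage(g=1, tau=1, A=2)
        r = a.step_response(st_, np.array([0.0, 50.0]))
        assert r.values[0] == pytest.approx(1.0)
        assert r.values[1] == pytest.approx(0.5, abs=1e-9)

    def test_cascade_decays_over_more_decades_than_single_stage(self):
        t = np.logspace(-2, 1.3, 400)
        casc = a.FilterCascade(
            highpass=tuple(a.HighPassStage(g=1, tau=tau, A=1.5) for tau in TAUS)
        )
        resp = a.step_response(casc, t)
        final = np.prod([1 / 1.5] * 3)
        trans = (resp.values - final) / (resp.values[0] - final)
        single = a.step_response(a.HighPassStage(g=1, tau=0.05, A=1.5), t)
        strans = (single.values - 1 / 1.5) / (single.values[0] - 1 / 1.5)
        # cascade transient persists from t=0.01 through t>=5 (>2 decades);
        # the fast single stage is gone within a fraction of a second
        assert trans[0] > 0.5 and np.interp(5.0, t, trans) > 0.02
        assert np.interp(1.0, t, strans) < 1e-9

    def test_fractional_step_is_power_law(self):
        r = a.fractional_step_response(0.1, np.array([0.1, 1.0]))
        assert r.values[0] / r.values[1] == pytest.approx(10**0.1, rel=1e-12)
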