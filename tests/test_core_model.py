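"""Unit and property tests for the membrane model primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pumpneuron.core_model import (
    FARADAY,
    GATING_NAMES,
    CurrentBreakdown,
    GatingState,
    MembraneParameters,
    ModelInputError,
    NeuronState,
    PumpParameters,
    SodiumEnvironment,
    VariantSwitches,
    gating_kinetics,
    membrane_currents,
    nernst_sodium,
    pump_current,
    resting_gating,
    state_derivative,
)

ENV = SodiumEnvironment()
PUMP = PumpParameters()


class TestGatingKinetics:
    @pytest.mark.parametrize(
        "V, name, expected",
        [
            (-48.77, "mNaP", 0.5),  # persistent-sodium half activation
            (-29.13, "mNaT", 0.5),  # transient-sodium half activation
            (-40.0, "hNaT", 0.5),
            (-12.85, "nKs", 0.5),
        ],
    )
    def test_half_activation_midpoints(self, V, name, expected):
        x_inf, _ = gating_kinetics(V)
        assert x_inf[GATING_NAMES.index(name)] == pytest.approx(expected, abs=1e-12)

    def test_voltage_independent_time_constants(self):
        for V in (-100.0, -60.0, 0.0, 50.0):
            _, tau = gating_kinetics(V)
            assert tau[GATING_NAMES.index("mNaP")] == 1.0
            assert tau[GATING_NAMES.index("hKf2")] == 116.0

    def test_steady_states_monotone_and_taus_positive(self):
        """Across a dense grid all x_inf are strictly monotone in V, all
        taus strictly positive, all x_inf within [0, 1]."""
        grid = np.linspace(-100.0, 50.0, 601)
        X = np.array([gating_kinetics(v)[0] for v in grid])
        T = np.array([gating_kinetics(v)[1] for v in grid])
        assert np.all(T > 0)
        assert np.all((X >= 0) & (X <= 1))
        diffs = np.diff(X, axis=0)
        for j, name in enumerate(GATING_NAMES):
            signs = np.sign(diffs[:, j])
            nonzero = signs[signs != 0]  # saturated tails underflow to flat
            assert len(nonzero) > 0.5 * len(signs), f"{name} mostly flat"
            assert np.all(nonzero == nonzero[0]), f"{name} not monotone"

    def test_rejects_non_finite_voltage(self):
        with pytest.raises(ModelInputError):
            gating_kinetics(float("nan"))


class TestPumpCurrent:
    def test_half_activation_at_NaH(self):
        assert pump_current(40.0, PUMP) == pytest.approx(37.5, abs=1e-12)

    def test_saturates_at_maximum(self):
        assert pump_current(1e6, PUMP) == pytest.approx(PUMP.Ipumpmax)

    def test_value_at_default_resting_sodium(self):
        # direct evaluation: 75/(1+exp((40-40.08)/10))
        expected = 75.0 / (1.0 + math.exp((40.0 - 40.08) / 10.0))
        assert pump_current(40.08, PUMP) == pytest.approx(expected, rel=1e-14)
        assert pump_current(40.08, PUMP) == pytest.approx(37.65, abs=0.01)

    def test_resting_pump_approximately_half_activated(self):
        frac = pump_current(ENV.Na_rest, PUMP) / PUMP.Ipumpmax
        assert 0.49 < frac < 0.53

    @given(st.floats(0.5, 200.0), st.floats(0.5, 200.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_sodium(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert pump_current(lo, PUMP) < pump_current(hi, PUMP)
        assert 0.0 < pump_current(a, PUMP) < PUMP.Ipumpmax

    def test_rejects_nonpositive_sodium(self):
        with pytest.raises(ModelInputError):
            pump_current(0.0, PUMP)


class TestNernst:
    def test_zero_at_equal_concentrations(self):
        assert nernst_sodium(ENV.Na_out, ENV) == pytest.approx(0.0, abs=1e-12)

    def test_resting_reversal_matches_reference(self):
        assert nernst_sodium(40.08, ENV) == pytest.approx(31.2, abs=0.05)
        assert nernst_sodium(ENV.Na_rest, ENV) == pytest.approx(ENV.ENa_rest, abs=0.05)

    def test_halving_concentration_adds_RT_over_F_ln2(self):
        shift = nernst_sodium(20.0, ENV) - nernst_sodium(40.0, ENV)
        assert shift == pytest.approx(ENV.RT_over_F * math.log(2.0), rel=1e-12)
        assert shift == pytest.approx(17.8, abs=0.05)

    @given(st.floats(1.0, 300.0), st.floats(1.0, 300.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert nernst_sodium(lo, ENV) > nernst_sodium(hi, ENV)


class TestMembraneCurrents:
    def _state(self, V, Na=40.08):
        return NeuronState(V=V, gating=resting_gating(V), Na_in=Na)

    def test_zero_sodium_driving_force(self):
        state = self._state(ENV.ENa_rest)
        c = membrane_currents(state, switches=VariantSwitches.from_name("ConCon"))
        assert c.INaT == c.INaP == c.INaleak == 0.0

    def test_zero_potassium_driving_force(self):
        params = MembraneParameters()
        state = self._state(params.EK)
        c = membrane_currents(state)
        assert c.IKf == c.IKs == c.IKleak == 0.0

    def test_resting_leak_and_pump_values(self):
        """Hand evaluation: gNaleak*(V-ENa) and the pump sigmoid at rest."""
        state = self._state(-60.0)
        c = membrane_currents(state, switches=VariantSwitches.from_name("ConCon"))
        assert c.INaleak == pytest.approx(1.2 * (-60.0 - 31.2), rel=1e-12)
        assert c.INaleak == pytest.approx(-109.4, abs=0.1)
        assert c.Ipump == pytest.approx(37.65, abs=0.01)

    def test_reversal_switch_selects_effective_ENa(self):
        state = self._state(-60.0, Na=50.0)
        frozen = membrane_currents(state, switches=VariantSwitches(True, False))
        dynamic = membrane_currents(state, switches=VariantSwitches(True, True))
        assert frozen.ENa_effective == ENV.ENa_rest
        assert dynamic.ENa_effective == pytest.approx(nernst_sodium(50.0, ENV))

    def test_kf_mixes_two_inactivation_components(self):
        gating = GatingState(0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0)
        state = NeuronState(V=-60.0, gating=gating, Na_in=40.08)
        c1 = membrane_currents(state)
        gating2 = GatingState(0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)
        c2 = membrane_currents(NeuronState(V=-60.0, gating=gating2, Na_in=40.08))
        assert c1.IKf / c2.IKf == pytest.approx(0.95 / 0.05, rel=1e-12)


class TestStateDerivative:
    def test_frozen_sodium_has_zero_concentration_derivative(self):
        state = NeuronState(V=-30.0, gating=resting_gating(-30.0), Na_in=40.08)
        d = state_derivative(0.0, state, 20.0, switches=VariantSwitches(False, False))
        assert d[8] == 0.0

    def test_sodium_conversion_constant(self):
        assert 1.0 / (FARADAY * ENV.Vol) == pytest.approx(1.888e-5, rel=1e-3)

    def test_injected_current_depolarizes(self):
        state = NeuronState(V=-60.0, gating=resting_gating(-60.0), Na_in=40.08)
        d0 = state_derivative(0.0, state, 0.0)
        d1 = state_derivative(0.0, state, 50.0)
        assert d1[0] - d0[0] == pytest.approx(50.0 / 4.0, rel=1e-12)  # pA/pF


class TestTypesAndSwitches:
    def test_dynamic_reversal_requires_dynamic_sodium(self):
        with pytest.raises(ModelInputError):
            VariantSwitches(na_dynamic=False, ena_dynamic=True)

    @pytest.mark.parametrize(
        "name, flags",
        [("ConCon", (False, False)), ("DynCon", (True, False)), ("DynDyn", (True, True))],
    )
    def test_variant_presets(self, name, flags):
        sw = VariantSwitches.from_name(name)
        assert (sw.na_dynamic, sw.ena_dynamic) == flags
        assert sw.name == name

    def test_unknown_variant_rejected(self):
        with pytest.raises(ModelInputError):
            VariantSwitches.from_name("DynDynDyn")

    def test_gating_bounds_enforced(self):
        with pytest.raises(ModelInputError):
            GatingState(1.2, 0, 0, 0, 0, 0, 0)

    def test_invalid_physical_parameters_rejected(self):
        with pytest.raises(ModelInputError):
            MembraneParameters(C=-1.0)
        with pytest.raises(ModelInputError):
            PumpParameters(Ipumpmax=0.0)
        with pytest.raises(ModelInputError):
            NeuronState(V=-60.0, gating=resting_gating(-60.0), Na_in=-1.0)

    def test_environment_internally_consistent(self):
        assert nernst_sodium(ENV.Na_rest, ENV) == pytest.approx(ENV.ENa_rest, abs=0.05)
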