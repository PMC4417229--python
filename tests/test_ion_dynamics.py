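import math

import numpy as np
import pytest

from purkinje2c.constants import FARADAY, NA_OUT, RTF_MV
from purkinje2c.ion_dynamics import (
    NaHistory,
    counterbalance_currents,
    dendrite_pump,
    e_k_dendrite,
    na_influx_soma,
    soma_pump,
    step_dend_ca,
    step_k_o,
    step_na_i,
    step_soma_ca,
)
from purkinje2c.params import PumpExchangerSet


class TestSomaPump:
    def test_zero_at_minus_75(self):
        i, ina, ik = soma_pump(-75.0, 40.0)
        assert i == 0.0 and ina == 0.0 and ik == 0.0

    def test_half_gate_at_affinity_constant(self):
        # [Na]_i = K_Na: denominator factor (1 + e^0) = 2
        v = -65.0
        i, _, _ = soma_pump(v, 40.0, d_pump_s=1.0, k_na_mM=40.0)
        expected = 1000.0 * (v + 75.0) / ((v + 80.0) * 2.0)
        assert i == pytest.approx(expected, rel=1e-12)

    def test_stoichiometry_3_to_minus_2(self):
        i, ina, ik = soma_pump(-60.0, 40.0)
        assert i != 0.0
        assert ina / ik == pytest.approx(-1.5)

    def test_singularity_guard_at_minus_80(self):
        i, _, _ = soma_pump(-80.0, 40.0)
        assert math.isfinite(i)
        below = soma_pump(-80.005, 40.0)[0]
        assert math.isfinite(below)

    def test_off_at_resting_na(self):
        i, _, _ = soma_pump(-65.0, 10.0, k_na_mM=40.0)
        assert abs(i) < 1e-8


class TestDendritePump:
    def test_half_activation(self):
        i, _, _ = dendrite_pump(2.245, d_pump_d=0.001)
        assert i == pytest.approx(0.5 * 1000.0 * 0.001)

    def test_saturation_limit(self):
        i, _, _ = dendrite_pump(1e9, d_pump_d=0.001)
        assert i == pytest.approx(1.0, rel=1e-6)

    def test_zero_density(self):
        assert dendrite_pump(2.5, d_pump_d=0.0) == (0.0, 0.0, 0.0)

    def test_stoichiometry(self):
        i, ina, ik = dendrite_pump(2.5, 0.001)
        assert ina == pytest.approx(3.0 * i)
        assert ik == pytest.approx(-2.0 * i)


class TestCounterbalance:
    def test_soma_mismatch_is_net_inward(self):
        ex, pump, comps = counterbalance_currents(PumpExchangerSet(), "soma")
        assert ex + pump == pytest.approx(-11.0)  # uA/cm2, net depolarising
        assert comps["I_ex_Na"] == pytest.approx(-3.0 * 511.0)
        assert comps["I_pump_Na"] == pytest.approx(3.0 * 500.0)

    def test_dendrite_cancels_exactly(self):
        ex, pump, _ = counterbalance_currents(PumpExchangerSet(), "dendrite")
        assert ex + pump == pytest.approx(0.0)

    def test_all_zero_densities(self):
        zero = PumpExchangerSet(g_ex_s=0.0, g_pump_s=0.0, g_ex_d=0.0,
                                g_pump_d=0.0)
        for comp in ("soma", "dendrite"):
            ex, pump, comps = counterbalance_currents(zero, comp)
            assert ex == 0.0 and pump == 0.0

    def test_unknown_compartment(self):
        with pytest.raises(ValueError):
            counterbalance_currents(PumpExchangerSet(), "axon")


class TestSomaCa:
    def test_floor_clamp(self):
        assert step_soma_ca(1e-4, 0.0, 0.025) == 1e-4

    def test_single_step_matches_hand_evaluation(self):
        # influx (1e4-form conversion) minus first-order decay, explicit Euler
        ca, i_ca, dt, depth, beta = 2e-4, -1.0, 0.025, 0.1, 1.0
        expected = ca + dt * (
            10.0 * (-i_ca) / (2.0 * FARADAY * depth) - beta * ca
        )
        assert step_soma_ca(ca, i_ca, dt) == pytest.approx(expected, rel=1e-12)

    def test_decays_monotonically_to_floor(self):
        ca = 5e-3
        for _ in range(2000):
            new = step_soma_ca(ca, 0.0, 0.025)
            assert new <= ca
            ca = new
        assert ca == 1e-4


class TestDendCa:
    def test_outward_current_rectified(self):
        # positive (outward) Ca current must not deplete the shell
        up = step_dend_ca(1e-4, +5.0, 0.025, depth_um=0.616)
        ref = step_dend_ca(1e-4, 0.0, 0.025, depth_um=0.616)
        assert up == ref

    def test_single_step_matches_hand_evaluation(self):
        ca, i_ca, dt, depth = 3e-4, -0.8, 0.025, 0.616
        chan = 10.0 * (-i_ca) / (2.0 * FARADAY * depth)
        expected = ca + dt * (
            chan - 4e-5 * ca / (ca + 4e-5) + (4e-5 - ca) / 2.0
        )
        assert step_dend_ca(ca, i_ca, dt, depth) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rest_equilibrium_matches_root_oracle(self):
        from scipy.optimize import brentq

        f = lambda c: -4e-5 * c / (c + 4e-5) + (4e-5 - c) / 2.0
        root = brentq(f, 1e-9, 4e-5, xtol=1e-15)
        ca = 4e-5
        for _ in range(400000):
            ca = step_dend_ca(ca, 0.0, 0.025, 0.616)
        assert ca == pytest.approx(root, abs=1e-9)


class TestNaHistory:
    def test_exact_delay(self):
        hist = NaHistory(tau_ms=5000.0, dt_ms=0.025)
        assert hist.capacity == 200000
        # impulse injected now returns after exactly tau
        out_at = None
        for k in range(2 * hist.capacity):
            val = 1.0 if k == 10 else 0.0
            lagged = hist.push(val)
            if lagged != 0.0 and out_at is None:
                out_at = k
        assert out_at == 10 + hist.capacity

    def test_prefilled_with_zeros(self):
        hist = NaHistory(tau_ms=1.0, dt_ms=0.25)
        assert all(hist.push(9.9) == 0.0 for _ in range(4))
        assert hist.push(0.0) == 9.9

    def test_too_short_tau_rejected(self):
        with pytest.raises(ValueError):
            NaHistory(tau_ms=0.001, dt_ms=0.025)


class TestNaI:
    def test_floor(self):
        na, e_na = step_na_i(10.0, 0.0, 0.025)
        assert na == 10.0
        na, _ = step_na_i(10.0, -1e6, 0.025)
        assert na == 10.0

    def test_constant_influx_growth_matches_closed_form(self):
        # d[Na]/dt = 4*I/(diam*F) in consistent units; 1000 steps of constant
        # influx integrate exactly linearly
        influx, dt, diam = 100.0, 0.025, 22.0
        na = 10.0
        for _ in range(1000):
            na, _ = step_na_i(na, influx, dt, soma_diam_um=diam)
        expected = 10.0 + 1000 * dt * 40.0 * influx / (diam * FARADAY)
        assert na == pytest.approx(expected, rel=1e-12)

    def test_e_na_nernst_then_floor(self):
        na, e_na = step_na_i(12.0, 0.0, 0.025)
        assert e_na == pytest.approx(max(RTF_MV * math.log(NA_OUT / 12.0), 70.0))
        _, e_na_high = step_na_i(80.0, 0.0, 0.025)
        assert e_na_high == 70.0  # catch: E_Na never below +70

    def test_influx_bookkeeping(self):
        pumps = PumpExchangerSet()
        # at rest: no NaR, no saturating pump -> 3*(g_ex - g_pump) net in
        assert na_influx_soma(0.0, 0.0, pumps) == pytest.approx(3.0 * 11.0)
        # inward NaR current (negative) adds influx
        assert na_influx_soma(-10.0, 0.0, pumps) == pytest.approx(
            10.0 + 33.0
        )


class TestKo:
    def test_unchanged_with_zero_net(self):
        assert step_k_o(2.5, 10.0, 10.0, 0.025) == 2.5

    def test_clamps(self):
        assert step_k_o(3.02, 1e9, 0.0, 0.025) == 3.03
        assert step_k_o(2.01, 0.0, 1e9, 0.025) == 2.0

    def test_single_step_matches_hand_evaluation(self):
        k_o, out, inn, dt = 2.4, 50.0, 5.0, 0.025
        expected = k_o + dt * 0.0119 * (out - inn) / (FARADAY * 0.07)
        assert step_k_o(k_o, out, inn, dt) == pytest.approx(expected, rel=1e-12)

    def test_e_k_anchor(self):
        # default closure: K_i = 45 mM
        assert e_k_dendrite(2.0) == pytest.approx(RTF_MV * math.log(2.0 / 45.0))
        assert e_k_dendrite(3.03) - e_k_dendrite(2.0) == pytest.approx(
            RTF_MV * math.log(3.03 / 2.0)
        )
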