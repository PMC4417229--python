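import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from purkinje2c import kinetics as K
from purkinje2c.constants import FT_36, MT_37
from purkinje2c.mechanisms import (
    GATE_TABLE,
    CurrentSpec,
    MarkovNaState,
    default_current_specs,
    eval_current,
    gate_inf_tau,
    ghk_flux,
    markov_rates,
)

V_GRID = np.linspace(-120.0, 60.0, 361)

#: expected monotonic direction of each steady state in V ("+" increasing)
GATE_DIRECTION = {
    ("soma", "kfast", "m"): "+", ("soma", "kfast", "h"): "-",
    ("soma", "kmid", "m"): "+", ("soma", "kslow", "m"): "+",
    ("soma", "cap", "m"): "+", ("soma", "h", "m"): "-",
    ("soma", "bk", "m"): "+", ("soma", "bk", "h"): "-",
    ("dendrite", "cat", "m"): "+", ("dendrite", "cat", "h"): "-",
    ("dendrite", "cae", "m"): "+", ("dendrite", "cae", "h"): "-",
    ("dendrite", "cap", "m"): "+", ("dendrite", "h", "m"): "-",
    ("dendrite", "kv12", "m"): "+",
    ("dendrite", "ka", "m"): "+", ("dendrite", "ka", "h"): "-",
    ("dendrite", "km", "m"): "+",
    ("dendrite", "kd", "m"): "+", ("dendrite", "kd", "h"): "-",
    ("dendrite", "dr", "m"): "+", ("dendrite", "bk", "m"): "+",
    ("dendrite", "k2", "m"): "+",
    ("dendrite", "erg", "m"): "+", ("dendrite", "erg", "h"): "-",
}


class TestGateCurves:
    @pytest.mark.parametrize("key", sorted(GATE_DIRECTION))
    def test_bounded_monotone_with_positive_tau(self, key):
        comp, cur, gate = key
        infs, taus = [], []
        for v in V_GRID:
            inf, tau = gate_inf_tau(cur, gate, v, compartment=comp)
            infs.append(inf)
            taus.append(tau)
        infs = np.array(infs)
        assert np.all((infs >= 0.0) & (infs <= 1.0))
        assert np.all(np.array(taus) > 0.0)
        d = np.diff(infs)
        if GATE_DIRECTION[key] == "+":
            assert np.all(d >= -1e-12)
        else:
            assert np.all(d <= 1e-12)

    @pytest.mark.parametrize(
        "cur,gate,vhalf",
        [("kfast", "m", -24.0), ("kmid", "m", -24.0), ("kslow", "m", -16.5),
         ("cap", "m", -19.0), ("bk", "m", -28.9), ("erg", "m", -5.0)],
    )
    def test_boltzmann_midpoint(self, cur, gate, vhalf):
        inf, _ = gate_inf_tau(cur, gate, vhalf)
        assert inf == pytest.approx(0.5, abs=1e-12)

    def test_ca_gated_z_midpoints(self):
        # BK z half-activates at 1 uM; SK z at 190 nM (Hill n = 4)
        inf, tau = gate_inf_tau("bk", "z", 0.0, ca_mm=0.001, compartment="soma")
        assert inf == pytest.approx(0.5)
        assert tau == 1.0
        from purkinje2c.mechanisms import sk_z

        assert sk_z(0.00019) == pytest.approx(0.5)

    def test_ca_required_for_z_gates(self):
        with pytest.raises(ValueError, match="requires a Ca"):
            gate_inf_tau("bk", "z", 0.0, compartment="soma")

    def test_unknown_gate_rejected(self):
        with pytest.raises(KeyError):
            gate_inf_tau("kfast", "q", -60.0)

    def test_dr_singularity_caught(self):
        # the linearised branch at V = -55 gives alpha_m = 0.1*10*(1-0/2) = 1
        assert K.dr_vtrap(-55.0) == pytest.approx(10.0)
        a = 0.1 * K.dr_vtrap(-55.0)
        assert a == pytest.approx(1.0)
        # continuity across the catch branch
        assert K.dr_vtrap(-55.0 + 1e-7) == pytest.approx(K.dr_vtrap(-55.0), rel=1e-6)

    def test_temperature_factors(self):
        assert MT_37 == pytest.approx(3.0 ** (-0.1))
        assert FT_36 == pytest.approx(1.0)

    def test_literal_sigmoid_audit_mode(self):
        # printed 1/exp form exceeds 1 above V_half - exactly why the
        # Boltzmann reading is the default
        lit, _ = gate_inf_tau("kfast", "m", 0.0, literal=True)
        assert lit > 1.0
        bol, _ = gate_inf_tau("kfast", "m", 0.0)
        assert bol < 1.0
        with pytest.raises(ValueError, match="literal"):
            gate_inf_tau("cat", "m", 0.0, compartment="dendrite", literal=True)


class TestMarkov:
    def test_rates_at_zero_mv(self):
        r = markov_rates(0.0)
        assert r["alpha"] == pytest.approx(150.0)
        assert r["beta"] == pytest.approx(3.0)
        assert r["zeta"] == pytest.approx(0.03)
        assert r["gamma"] == 150.0 and r["delta"] == 40.0
        assert r["a"] == pytest.approx((0.75 / 0.005) ** 0.25)
        assert r["b"] == pytest.approx((0.005 / 0.5) ** 0.25)

    def test_rates_nonnegative_everywhere(self):
        for v in V_GRID:
            assert all(x >= 0.0 for x in K.markov_rates(v))

    def test_generator_columns_sum_to_zero(self):
        a = np.empty((13, 13))
        for v in (-80.0, -40.0, 0.0, 30.0):
            K.markov_generator(v, a)
            assert np.allclose(a.sum(axis=0), 0.0, atol=1e-10)
            off = a - np.diag(np.diag(a))
            assert np.all(off >= 0.0)

    def test_zero_dt_is_identity(self):
        s = MarkovNaState.steady(-65.0)
        s2 = s.step(-65.0, 0.0)
        assert np.array_equal(s.occ, s2.occ)

    def test_step_conserves_occupancy(self):
        s = MarkovNaState.steady(-65.0)
        for v in (-70.0, -20.0, 30.0):
            for _ in range(100):
                s = s.step(v, 0.025)
                assert abs(s.occ.sum() - 1.0) < 1e-10
                assert np.all(s.occ >= 0.0)

    def test_steady_state_matches_nullspace_oracle(self):
        from scipy.linalg import null_space

        for v in (-80.0, -65.0, -40.0, 0.0):
            a = np.empty((13, 13))
            K.markov_generator(v, a)
            ns = null_space(a)
            assert ns.shape[1] == 1
            oracle = ns[:, 0] / ns[:, 0].sum()
            mine = K.markov_steady_state(v)
            assert np.allclose(mine, oracle, atol=1e-6)

    def test_relaxation_reaches_steady_state(self):
        v = -50.0
        s = MarkovNaState.steady(-90.0)
        for _ in range(400000):  # 10 s at dt = 25 us
            K.markov_backward_euler(s.occ, v, 0.025, np.empty((13, 13)),
                                    np.empty((13, 14)))
        assert np.allclose(s.occ, K.markov_steady_state(v), atol=1e-5)

    def test_resurgent_block_relief(self):
        # depolarise to open/block the channel, then repolarise: occupancy
        # must transiently pass back through the open state (resurgence)
        s = MarkovNaState.steady(-90.0)
        for _ in range(200):
            s = s.step(30.0, 0.025)
        blocked = s.occ[6]  # OB
        assert blocked > 0.01
        peak_open = 0.0
        for _ in range(400):
            s = s.step(-40.0, 0.025)
            peak_open = max(peak_open, s.open_fraction)
        assert peak_open > s.open_fraction  # transient maximum
        assert peak_open > 0.005


class TestGhk:
    def test_zero_permeability(self):
        assert ghk_flux(-60.0, p_ca=0.0) == 0.0

    def test_limit_at_zero_matches_series_oracle(self):
        # L'Hopital limit: 2*P*F*([Ca]_i - [Ca]_o)
        F = 96485.33212
        limit = 5e-5 * 2.0 * F * (1e-4 - 2.0)
        assert ghk_flux(0.0) == pytest.approx(limit, rel=1e-9)
        # continuity on both sides of the singularity
        assert ghk_flux(1e-7) == pytest.approx(limit, rel=1e-5)
        assert ghk_flux(-1e-7) == pytest.approx(limit, rel=1e-5)

    def test_inward_at_hyperpolarised_v(self):
        assert ghk_flux(-60.0) < 0.0

    @given(v=st.floats(-120.0, 60.0))
    @settings(max_examples=200, deadline=None)
    def test_flux_is_finite_and_inward_below_reversal(self, v):
        f = ghk_flux(v)
        assert math.isfinite(f)
        if v < 100.0:  # far below the Ca Nernst potential
            assert f < 0.0


class TestEvalCurrent:
    def test_zero_gmax_for_every_spec(self):
        for spec in default_current_specs().values():
            zero = CurrentSpec(spec.id, spec.compartment, 0.0, spec.gates,
                               spec.reversal)
            gates = {g: 0.5 for g, _ in spec.gates}
            assert eval_current(zero, gates, -60.0, -88.0) == 0.0

    def test_ohmic_vanishes_at_reversal(self):
        spec = CurrentSpec("bk", "soma", 72.86, (("m", 3), ("z", 2), ("h", 1)),
                           "E_K")
        gates = {"m": 0.4, "z": 0.2, "h": 0.9}
        assert eval_current(spec, gates, -88.0, -88.0) == 0.0

    def test_leak_hand_example(self):
        # g = 0.1 mS/cm2 at V = -60, E_L = -70 -> +1.0 uA/cm2 outward
        spec = CurrentSpec("leak", "soma", 0.1, (), "E_L")
        assert eval_current(spec, {}, -60.0, -70.0) == pytest.approx(1.0)

    def test_missing_gate_raises(self):
        spec = CurrentSpec("kfast", "soma", 41.6, (("m", 3), ("h", 1)), "E_K")
        with pytest.raises(KeyError, match="missing gate"):
            eval_current(spec, {"m": 0.5}, -60.0, -88.0)

    def test_gate_out_of_range_raises(self):
        spec = CurrentSpec("kmid", "soma", 20.8, (("m", 4),), "E_K")
        with pytest.raises(ValueError):
            eval_current(spec, {"m": 1.5}, -60.0, -88.0)

    def test_negative_gmax_rejected(self):
        with pytest.raises(ValueError):
            CurrentSpec("x", "soma", -1.0, (), "E_L")

    def test_table_defaults_roster(self):
        specs = default_current_specs()
        assert specs["soma/naR"].g_max == 15.6
        assert specs["soma/bk"].g_max == 72.86
        assert specs["dendrite/ka"].g_max == pytest.approx(197.12)
        assert specs["dendrite/bk"].g_max == pytest.approx(369.6)
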