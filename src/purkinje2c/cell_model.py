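"""Two-compartment cell assembly and the fixed-step simulation loop.

The soma (22 x 22 um cylinder) and the dendritic equivalent cylinder
(529.29 x 3.22 um) are coupled by the axial resistance R_DS = R_SD built from
half of each compartment's cylindrical core resistance. Voltages are advanced
by a linearised implicit (backward-Euler-style) update at a fixed 25 us step;
gates relax exponentially, the Markov Na scheme takes an implicit step, ion
pools take explicit Euler steps with their catch clamps. Everything is
deterministic: identical configurations give identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as KN
from .constants import NA_OUT, nernst
from .ion_dynamics import IonState, NaHistory, e_k_dendrite
from .kinetics import markov_steady_state
from .mechanisms import GATE_TABLE, MarkovNaState
from .params import ModelParams
from .protocols import AlcoholProtocol
from .trace import Trace

__all__ = [
    "Geometry",
    "CellState",
    "SimConfig",
    "SimulationError",
    "axial_currents",
    "build_geometry",
    "init_state",
    "step",
    "simulate",
]


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class Geometry:
    """Compartment geometry and derived coupling quantities."""

    soma_length_um: float
    soma_diam_um: float
    dend_length_um: float
    dend_diam_um: float
    ra_ohm_cm: float

    @property
    def soma_area_cm2(self) -> float:
        return math.pi * self.soma_diam_um * self.soma_length_um * 1e-8

    @property
    def dend_area_cm2(self) -> float:
        return math.pi * self.dend_diam_um * self.dend_length_um * 1e-8

    @property
    def r_axial_ohm(self) -> float:
        """R_DS = R_SD: half-cylinder core resistances in series, Ohm."""
        def half(length_um, diam_um):
            r_cm = diam_um / 2.0 * 1e-4
            return self.ra_ohm_cm * (length_um / 2.0 * 1e-4) / (math.pi * r_cm**2)

        return half(self.soma_length_um, self.soma_diam_um) + half(
            self.dend_length_um, self.dend_diam_um
        )

    def axial_g_density(self, compartment: str) -> float:
        """Axial coupling conductance as a density (mS/cm^2) referred to one
        compartment's membrane area."""
        area = self.soma_area_cm2 if compartment == "soma" else self.dend_area_cm2
        return 1000.0 / (self.r_axial_ohm * area)


def build_geometry(params: ModelParams) -> Geometry:
    return Geometry(
        soma_length_um=params.soma_length,
        soma_diam_um=params.soma_diam,
        dend_length_um=params.dend_length,
        dend_diam_um=params.dend_diam,
        ra_ohm_cm=params.ra_ohm_cm,
    )


def axial_currents(v_s_mV: float, v_d_mV: float, geom: Geometry):
    """Axial current densities (uA/cm^2) into each compartment.

    Returns (I_DS, I_SD): I_DS = (V_D - V_S)/R_DS referred to the somatic
    area (positive when the dendrite is more depolarised, i.e. the axial
    current depolarises the soma), and symmetrically I_SD for the dendrite.
    The underlying absolute currents are equal and opposite since R_DS = R_SD.
    """
    dv = v_d_mV - v_s_mV
    i_ds = dv * geom.axial_g_density("soma")
    i_sd = -dv * geom.axial_g_density("dendrite")
    return i_ds, i_sd


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

#: kernel state-slot for each (compartment, current, gate) H-H gate
_GATE_SLOTS = {
    ("soma", "kfast", "m"): KN.S_M_KFAST,
    ("soma", "kfast", "h"): KN.S_H_KFAST,
    ("soma", "kmid", "m"): KN.S_M_KMID,
    ("soma", "kslow", "m"): KN.S_M_KSLOW,
    ("soma", "cap", "m"): KN.S_M_CAPS,
    ("soma", "h", "m"): KN.S_M_HS,
    ("soma", "bk", "m"): KN.S_M_BKS,
    ("soma", "bk", "h"): KN.S_H_BKS,
    ("soma", "bk", "z"): KN.S_Z_BKS,
    ("dendrite", "cat", "m"): KN.S_M_CAT,
    ("dendrite", "cat", "h"): KN.S_H_CAT,
    ("dendrite", "cae", "m"): KN.S_M_CAE,
    ("dendrite", "cae", "h"): KN.S_H_CAE,
    ("dendrite", "cap", "m"): KN.S_M_CAPD,
    ("dendrite", "h", "m"): KN.S_M_HD,
    ("dendrite", "kv12", "m"): KN.S_M_KV12,
    ("dendrite", "ka", "m"): KN.S_M_KA,
    ("dendrite", "ka", "h"): KN.S_H_KA,
    ("dendrite", "km", "m"): KN.S_M_KM,
    ("dendrite", "kd", "m"): KN.S_M_KD,
    ("dendrite", "kd", "h"): KN.S_H_KD,
    ("dendrite", "dr", "m"): KN.S_M_DR,
    ("dendrite", "bk", "m"): KN.S_M_BKD,
    ("dendrite", "bk", "z"): KN.S_Z_BKD,
    ("dendrite", "k2", "m"): KN.S_M_K2,
    ("dendrite", "k2", "z"): KN.S_Z_K2,
    ("dendrite", "erg", "m"): KN.S_M_ERG,
    ("dendrite", "erg", "h"): KN.S_H_ERG,
}


@dataclass
class CellState:
    """Full dynamic state at one instant."""

    t_ms: float
    v_soma_mV: float
    v_dend_mV: float
    gates: dict          # (compartment, current, gate) -> value
    markov: MarkovNaState
    ions: IonState
    na_history: NaHistory

    def to_array(self) -> np.ndarray:
        s = np.zeros(KN.NSTATE)
        s[KN.S_V_S] = self.v_soma_mV
        s[KN.S_V_D] = self.v_dend_mV
        for key, slot in _GATE_SLOTS.items():
            s[slot] = self.gates.get(key, 0.0)
        s[KN.S_MK0:KN.S_MK0 + 13] = self.markov.occ
        s[KN.S_CA_S] = self.ions.ca_soma_mM
        s[KN.S_CA_D] = self.ions.ca_dend_mM
        s[KN.S_NA_I] = self.ions.na_i_mM
        s[KN.S_K_O] = self.ions.k_o_mM
        s[KN.S_E_NA] = self.ions.e_na_mV
        s[KN.S_E_K_D] = self.ions.e_k_dend_mV
        return s

    @classmethod
    def from_array(cls, s: np.ndarray, t_ms: float, na_history: NaHistory):
        gates = {key: float(s[slot]) for key, slot in _GATE_SLOTS.items()}
        return cls(
            t_ms=t_ms,
            v_soma_mV=float(s[KN.S_V_S]),
            v_dend_mV=float(s[KN.S_V_D]),
            gates=gates,
            markov=MarkovNaState(occ=s[KN.S_MK0:KN.S_MK0 + 13].copy()),
            ions=IonState(
                ca_soma_mM=float(s[KN.S_CA_S]),
                ca_dend_mM=float(s[KN.S_CA_D]),
                na_i_mM=float(s[KN.S_NA_I]),
                k_o_mM=float(s[KN.S_K_O]),
                e_na_mV=float(s[KN.S_E_NA]),
                e_k_dend_mV=float(s[KN.S_E_K_D]),
            ),
            na_history=na_history,
        )


def init_state(params: ModelParams, dt_ms: float = 0.025) -> CellState:
    """Initial state: voltages at -65 mV, every gate at its steady state for
    the initial voltage/Ca, the Markov chain at its stationary distribution,
    concentrations at their initial values, empty Na-lag history."""
    v = params.v_init
    gates = {}
    for key, (fn, needs_ca, _lit) in GATE_TABLE.items():
        if needs_ca:
            ca = params.ca_soma_init if key[0] == "soma" else params.ca_dend_init
            inf, _tau = fn(ca)
        else:
            inf, _tau = fn(v)
        gates[key] = inf
    ions = IonState(
        ca_soma_mM=params.ca_soma_init,
        ca_dend_mM=params.ca_dend_init,
        na_i_mM=params.na_i_init,
        k_o_mM=params.k_o_init,
        e_na_mV=max(nernst(NA_OUT, params.na_i_init), params.e_na_floor),
        e_k_dend_mV=e_k_dendrite(params.k_o_init, params.k_in_dend),
    )
    return CellState(
        t_ms=0.0,
        v_soma_mV=v,
        v_dend_mV=v,
        gates=gates,
        markov=MarkovNaState.steady(v),
        ions=ions,
        na_history=NaHistory(tau_ms=params.na_lag_s * 1000.0, dt_ms=dt_ms),
    )


# ---------------------------------------------------------------------------
# Configuration and runs
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation settings: fixed step (default 25 us), output stride."""

    params: ModelParams = field(default_factory=ModelParams)
    duration_ms: float = 1000.0
    dt_ms: float = 0.025
    stride: int = 4
    protocol: AlcoholProtocol | None = None

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms < 0:
            raise ValueError("duration must be non-negative")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def pack_params(
    params: ModelParams, protocol: AlcoholProtocol | None = None
) -> np.ndarray:
    geom = build_geometry(params)
    p = np.zeros(KN.NPARAM)
    gs, gd = params.gmax_soma, params.gmax_dend
    p[KN.P_G_NAR] = gs["naR"]
    p[KN.P_G_KFAST] = gs["kfast"]
    p[KN.P_G_KMID] = gs["kmid"]
    p[KN.P_G_KSLOW] = gs["kslow"]
    p[KN.P_G_CAPS] = gs["cap"]
    p[KN.P_G_BKS] = gs["bk"]
    p[KN.P_G_SK] = gs["sk"]
    p[KN.P_G_HS] = gs["h"]
    p[KN.P_G_LEAKS] = gs["leak"]
    p[KN.P_G_CAT] = gd["cat"]
    p[KN.P_G_CAE] = gd["cae"]
    p[KN.P_G_CAPD] = gd["cap"]
    p[KN.P_G_KA] = gd["ka"]
    p[KN.P_G_KD] = gd["kd"]
    p[KN.P_G_KM] = gd["km"]
    p[KN.P_G_DR] = gd["dr"]
    p[KN.P_G_BKD] = gd["bk"]
    p[KN.P_G_K2] = gd["k2"]
    p[KN.P_G_KV12] = gd["kv12"]
    p[KN.P_G_HD] = gd["h"]
    p[KN.P_G_LEAKD] = gd["leak"]
    p[KN.P_G_ERG] = params.g_erg
    p[KN.P_E_K_S] = params.e_k_soma
    p[KN.P_E_L_S] = params.e_l_soma
    p[KN.P_E_H_S] = params.e_h_soma
    p[KN.P_E_L_D] = params.e_l_dend
    p[KN.P_E_H_D] = params.e_h_dend
    p[KN.P_E_CA_D] = params.e_ca_dend
    pump = params.pumps
    p[KN.P_D_PUMP_S] = pump.d_pump_s
    p[KN.P_D_PUMP_D] = pump.d_pump_d
    p[KN.P_GEX_S] = pump.g_ex_s
    p[KN.P_GPUMP_S] = pump.g_pump_s
    p[KN.P_GEX_D] = pump.g_ex_d
    p[KN.P_GPUMP_D] = pump.g_pump_d
    p[KN.P_K_NA] = pump.k_na
    p[KN.P_CM_S] = params.cm_soma
    p[KN.P_CM_D] = params.cm_dend
    p[KN.P_GA_S] = geom.axial_g_density("soma")
    p[KN.P_GA_D] = geom.axial_g_density("dendrite")
    p[KN.P_SOMA_DIAM] = params.soma_diam
    p[KN.P_DEPTH_S] = params.depth_soma_um
    p[KN.P_BETA_CA] = params.beta_ca_soma
    p[KN.P_CA_FLOOR] = params.ca_floor_soma
    p[KN.P_DEPTH_D] = params.depth_dend_um
    p[KN.P_KT] = params.kt_dend
    p[KN.P_KD] = params.kd_dend
    p[KN.P_TAU_R] = params.tau_r_dend
    p[KN.P_CA_REST] = params.ca_rest_dend
    p[KN.P_NA_FLOOR] = params.na_floor
    p[KN.P_E_NA_FLOOR] = params.e_na_floor
    p[KN.P_QK] = params.q_k
    p[KN.P_WID] = params.wid_um
    p[KN.P_KO_MIN] = params.k_o_min
    p[KN.P_KO_MAX] = params.k_o_max
    p[KN.P_K_IN_D] = params.k_in_dend
    if protocol is not None:
        p[KN.P_ALC_ON] = 1.0
        p[KN.P_ALC_Y] = protocol.y_mA_cm2_s
        p[KN.P_ALC_M] = protocol.m_mA_cm2_s
        p[KN.P_ALC_ONSET_S] = protocol.onset_s
    return p


def step(state: CellState, dt_ms: float, params: ModelParams | None = None,
         protocol: AlcoholProtocol | None = None) -> CellState:
    """Advance the full state by one integration step (dt = 0 is a no-op)."""
    if dt_ms < 0:
        raise ValueError("dt must be non-negative")
    if dt_ms == 0.0:
        return state
    if params is None:
        params = ModelParams()
    p = pack_params(params, protocol)
    s = state.to_array()
    hist = state.na_history
    hist_state = np.array([hist.pos], dtype=np.int64)
    out = np.empty((2, KN.NREC))
    status, at = KN.run_kernel(p, s, hist.buf, hist_state, 1, dt_ms, 1, out)
    hist.pos = int(hist_state[0])
    if status != KN.STATUS_OK:
        raise SimulationError(
            f"non-finite state at t = {state.t_ms + at * dt_ms:.3f} ms"
        )
    return CellState.from_array(s, state.t_ms + dt_ms, hist)


_CHANNEL_NAMES = (
    "v_soma", "v_dend", "ca_soma", "ca_dend", "na_i", "k_o", "na_open",
    "i_pump_s",
)


def simulate(config: SimConfig, state: CellState | None = None) -> Trace:
    """Run the model and return the sampled trace.

    Deterministic: no randomness anywhere, so identical configurations give
    identical traces. A zero duration returns the initial state only. A
    non-finite state aborts with the failure time in the exception.
    """
    params = config.params
    dt = config.dt_ms
    if state is None:
        state = init_state(params, dt_ms=dt)
    p = pack_params(params, config.protocol)
    s = state.to_array()
    hist = state.na_history
    hist_state = np.array([hist.pos], dtype=np.int64)
    n_steps = int(round(config.duration_ms / dt))
    n_rec = n_steps // config.stride + 1
    out = np.empty((n_rec, KN.NREC))
    status, at = KN.run_kernel(
        p, s, hist.buf, hist_state, n_steps, dt, config.stride, out
    )
    hist.pos = int(hist_state[0])
    if status != KN.STATUS_OK:
        raise SimulationError(f"non-finite state at t = {at * dt:.3f} ms")
    rows = n_steps // config.stride + 1
    channels = {
        name: out[:rows, i].copy() for i, name in enumerate(_CHANNEL_NAMES)
    }
    return Trace(
        dt_ms=dt * config.stride,
        channels=channels,
        meta={
            "dt_ms": dt,
            "stride": config.stride,
            "duration_ms": config.duration_ms,
            "protocol": "alcohol" if config.protocol else "none",
        },
    )
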