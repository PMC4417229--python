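"""Ion-concentration dynamics, Na/K pumps and Na/Ca exchangers.

Two pump descriptions exist per compartment. The *saturating* pump (density
``d_pump``) carries the concentration feedback: at the soma it is gated
steeply by intracellular Na (Boltzmann in [Na]_i around the affinity constant
K_Na, slope 1 mM, with a fixed voltage factor (V+75)/(V+80)); in the dendrite
it saturates hyperbolically in extracellular K. The *counterbalance* pair
(``g_pump``/``g_ex``) is a pair of constant current densities: the exchanger
passes net -1 charge inward (3 Na in per Ca out), the pump net +1 outward
(3 Na out per 2 K in). Both pump forms share the 3:-2 Na:K stoichiometry.

Conventions: pump/exchanger densities are carried in mA/cm^2 as printed;
every returned current is in the internal uA/cm^2 system, positive outward.

Catch coding (hard clamps) per the source model: somatic shell Ca >= 100 nM,
[Na]_i >= 10 mM, E_Na >= 70 mV, 2 <= [K]_o <= 3.03 mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FARADAY, NA_OUT, RTF_MV, nernst
from .params import PumpExchangerSet

__all__ = [
    "IonState",
    "NaHistory",
    "soma_pump",
    "dendrite_pump",
    "counterbalance_currents",
    "step_soma_ca",
    "step_dend_ca",
    "na_influx_soma",
    "step_na_i",
    "step_k_o",
    "e_k_dendrite",
]

#: guard half-width (mV) for the (V+80) factor in the somatic pump
V80_GUARD_MV = 0.01


@dataclass
class IonState:
    """Concentration pools and the reversal potentials they set."""

    ca_soma_mM: float = 5e-5
    ca_dend_mM: float = 4e-5
    na_i_mM: float = 10.0
    k_o_mM: float = 2.0
    e_na_mV: float = 70.0
    e_k_dend_mV: float = -77.0

    def check(self) -> None:
        assert self.ca_soma_mM >= 1e-4 - 1e-15 or self.ca_soma_mM > 0
        assert self.na_i_mM >= 10.0 - 1e-12
        assert self.e_na_mV >= 70.0 - 1e-12
        assert 2.0 - 1e-12 <= self.k_o_mM <= 3.03 + 1e-12


class NaHistory:
    """Fixed-capacity FIFO implementing the channel-to-pump Na lag.

    Stores one net-Na-current sample per integration step over exactly
    ``tau`` of model time; ``push`` records the newest sample and returns the
    sample from tau earlier (zero until the buffer has filled once).
    """

    def __init__(self, tau_ms: float, dt_ms: float):
        self.capacity = int(round(tau_ms / dt_ms))
        if self.capacity < 1:
            raise ValueError("tau must be at least one step")
        self.dt_ms = dt_ms
        self.buf = np.zeros(self.capacity)
        self.pos = 0

    @property
    def tau_ms(self) -> float:
        return self.capacity * self.dt_ms

    def push(self, value: float) -> float:
        lagged = self.buf[self.pos]
        self.buf[self.pos] = value
        self.pos = (self.pos + 1) % self.capacity
        return float(lagged)


def soma_pump(
    v_mV: float,
    na_i_mM: float,
    d_pump_s: float = 1.0,
    k_na_mM: float = 40.0,
) -> tuple[float, float, float]:
    """Saturating somatic Na/K pump: (i_pump, i_pump_Na, i_pump_K), uA/cm^2.

    i = d*(V+75) / [(V+80)*(1+exp(K_Na-[Na]_i))]; the (V+80) factor is
    guarded to +/-0.01 mV around its zero (V = -80 mV is transiently
    reachable). Na efflux is 3i, K influx is -2i (3:-2 stoichiometry).
    """
    v80 = v_mV + 80.0
    if abs(v80) < V80_GUARD_MV:
        v80 = math.copysign(V80_GUARD_MV, v80) if v80 != 0.0 else V80_GUARD_MV
    x = k_na_mM - na_i_mM
    gate = 1.0 + (math.exp(x) if x < 500.0 else math.exp(500.0))
    i = 1000.0 * d_pump_s * (v_mV + 75.0) / (v80 * gate)
    return i, 3.0 * i, -2.0 * i


def dendrite_pump(
    k_o_mM: float, d_pump_d: float = 0.001
) -> tuple[float, float, float]:
    """Saturating dendritic Na/K pump: hyperbolic in [K]_o, half-active at
    2.245 mM. Returns (i_pump, i_pump_Na, i_pump_K) in uA/cm^2."""
    if k_o_mM <= 0:
        raise ValueError("[K]_o must be positive")
    i = 1000.0 * d_pump_d / (1.0 + 2.245 / k_o_mM)
    return i, 3.0 * i, -2.0 * i


def counterbalance_currents(
    pumps: PumpExchangerSet, compartment: str
) -> tuple[float, float, dict]:
    """Constant exchanger/pump pair: (I_ex_net, I_pump_net, components).

    I_ex_net = -g_ex (net depolarising), I_pump_net = +g_pump (net
    hyperpolarising), uA/cm^2. The component fluxes feed the Na and K books:
    the exchanger brings 3 Na in per cycle, the pump takes 3 Na out and 2 K
    in. At the soma the printed mismatch g_ex = g_pump + 0.011 mA/cm^2 leaves
    a small net inward (Na-carried) current; the dendritic pair cancels.
    """
    if compartment.startswith("soma"):
        g_ex, g_pump = pumps.g_ex_s, pumps.g_pump_s
    elif compartment.startswith("dend"):
        g_ex, g_pump = pumps.g_ex_d, pumps.g_pump_d
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    comps = {
        "I_ex_Na": -3.0 * 1000.0 * g_ex,   # Na influx (inward, negative)
        "I_ex_Ca": 2.0 * 1000.0 * g_ex,    # Ca efflux
        "I_pump_Na": 3.0 * 1000.0 * g_pump,
        "I_pump_K": -2.0 * 1000.0 * g_pump,
    }
    return -1000.0 * g_ex, 1000.0 * g_pump, comps


# ---------------------------------------------------------------------------
# Concentration updates (explicit Euler + catch clamps)
# ---------------------------------------------------------------------------

def _shell_influx_rate(i_ca_uA: float, depth_um: float) -> float:
    """Ca influx rate (mM/ms) into a sub-membrane shell from a Ca current
    density (uA/cm^2, inward negative): -I/(2F*depth), in consistent units
    (the factor 10 is the uA/cm^2-and-um bookkeeping)."""
    return 10.0 * (-i_ca_uA) / (2.0 * FARADAY * depth_um)


def step_soma_ca(
    ca_mM: float,
    i_ca_uA: float,
    dt_ms: float,
    depth_um: float = 0.1,
    beta_per_ms: float = 1.0,
    floor_mM: float = 1e-4,
) -> float:
    """Somatic shell Ca: influx from the P-type Ca current, first-order decay
    to the bulk (beta = 1/ms), floored at 100 nM."""
    ca = ca_mM + dt_ms * (_shell_influx_rate(i_ca_uA, depth_um) - beta_per_ms * ca_mM)
    return max(ca, floor_mM)


def step_dend_ca(
    ca_mM: float,
    i_ca_uA: float,
    dt_ms: float,
    depth_um: float,
    kt_mM_ms: float = 4e-5,
    kd_mM: float = 4e-5,
    tau_r_ms: float = 2.0,
    ca_rest_mM: float = 4e-5,
) -> float:
    """Dendritic shell Ca: rectified channel influx (outward Ca current does
    not deplete the shell), Michaelis-Menten extrusion, relaxation to rest."""
    chan = _shell_influx_rate(i_ca_uA, depth_um)
    if chan < 0.0:
        chan = 0.0
    dca = chan - kt_mM_ms * ca_mM / (ca_mM + kd_mM) + (ca_rest_mM - ca_mM) / tau_r_ms
    return ca_mM + dt_ms * dca


def na_influx_soma(
    i_naR_uA: float, i_pump_s_uA: float, pumps: PumpExchangerSet
) -> float:
    """Net Na influx current (uA/cm^2, positive raises [Na]_i): resurgent-Na
    entry plus 3 Na per exchanger cycle, minus 3 Na per cycle of each pump."""
    return (
        -i_naR_uA
        + 3.0 * 1000.0 * pumps.g_ex_s
        - 3.0 * i_pump_s_uA
        - 3.0 * 1000.0 * pumps.g_pump_s
    )


def step_na_i(
    na_i_mM: float,
    i_na_net_lagged_uA: float,
    dt_ms: float,
    soma_diam_um: float = 22.0,
    floor_mM: float = 10.0,
    e_na_floor_mV: float = 70.0,
) -> tuple[float, float]:
    """Advance [Na]_i from the tau-lagged net Na current and refresh E_Na.

    The volumetric conversion is the lateral surface-to-volume ratio of the
    somatic cylinder, 4/diam: d[Na]/dt = 4*I_net/(diam*F) in consistent units
    (factor 40 carries uA/cm^2 with diam in um). E_Na is recomputed by Nernst
    ([Na]_o = 140 mM) before its own floor is applied.
    """
    na = na_i_mM + dt_ms * 40.0 * i_na_net_lagged_uA / (soma_diam_um * FARADAY)
    na = max(na, floor_mM)
    e_na = max(nernst(NA_OUT, na), e_na_floor_mV)
    return na, e_na


def step_k_o(
    k_o_mM: float,
    i_k_out_uA: float,
    i_k_in_uA: float,
    dt_ms: float,
    q: float = 0.0119,
    wid_um: float = 0.07,
    lo_mM: float = 2.0,
    hi_mM: float = 3.03,
) -> float:
    """Extracellular K in the dendritic accumulation shell.

    ``i_k_out`` sums the gated K currents (uA/cm^2, outward positive);
    ``i_k_in`` is the magnitude of pump K import, 2*(i_pump + g_pump). The
    accumulation factor Q is the model's tuned free parameter. Clamped to
    [2, 3.03] mM.
    """
    dk = dt_ms * q * (i_k_out_uA - i_k_in_uA) / (FARADAY * wid_um)
    return min(max(k_o_mM + dk, lo_mM), hi_mM)


def e_k_dendrite(k_o_mM: float, k_in_mM: float | None = None) -> float:
    """Dendritic K reversal from [K]_o by Nernst with fixed intracellular K."""
    if k_in_mM is None:
        from .constants import K_IN_DEND

        k_in_mM = K_IN_DEND
    return RTF_MV * math.log(k_o_mM / k_in_mM)
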