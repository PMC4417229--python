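"""In-silico experimental protocols.

* Alcohol: a progressive Na/K-pump block, modelled as linear declines of the
  four pump densities (the somatic saturating pump from t = 0, the other
  three from t = 50 s), each floored at zero. The exchanger densities are
  untouched, so the soma loses the hyperpolarising counterweight to the
  depolarising Na/Ca exchanger and eventually enters depolarisation block.
* K_Na switch: lowering the somatic pump's Na affinity constant from 40 to
  12 mM turns the pump on at resting [Na]_i and holds the cell quiescent.
* BK knockout: zero BK density in both compartments (genetic-knockout
  analogue); dendritic Ca spikes then fail to repolarise.
* ERG insertion: adds the ERG K current to the dendrite (activation V_half
  -5 mV), the candidate rescuer of dendritic repolarisation without BK.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams, PumpExchangerSet

__all__ = [
    "AlcoholProtocol",
    "alcohol_ramp",
    "set_kna",
    "bk_knockout",
    "add_erg",
    "DEFAULT_ERG_BASE",
]

#: pre-C_d ERG density, mS/cm^2; the inserted density is this times C_d
DEFAULT_ERG_BASE = 0.5


@dataclass(frozen=True)
class AlcoholProtocol:
    """Pump-density ramp rates (mA cm^-2 s^-1) and the late-ramp onset."""

    y_mA_cm2_s: float = 0.014
    m_mA_cm2_s: float = 0.005
    onset_s: float = 50.0


def alcohol_ramp(
    t_s: float,
    base: PumpExchangerSet,
    protocol: AlcoholProtocol = AlcoholProtocol(),
) -> PumpExchangerSet:
    """Pump densities at protocol time ``t_s`` (seconds).

    d_pump_s declines as d(0) - Y*t from t = 0. After the onset (50 s) the
    dendritic saturating pump and both counterbalance pump densities decline
    continuously as d(0) - M*(t - onset): the block is piecewise linear in
    time, each density clamped at zero; the exchangers are not ramped.
    """
    if t_s < 0:
        raise ValueError("t must be >= 0")
    out = base.copy()
    out.d_pump_s = max(0.0, base.d_pump_s - protocol.y_mA_cm2_s * t_s)
    if t_s > protocol.onset_s:
        m = protocol.m_mA_cm2_s
        t_late = t_s - protocol.onset_s
        out.d_pump_d = max(0.0, base.d_pump_d - m * t_late)
        out.g_pump_s = max(0.0, base.g_pump_s - m * t_late)
        out.g_pump_d = max(0.0, base.g_pump_d - m * t_late)
    return out


def set_kna(params: ModelParams, value_mM: float) -> ModelParams:
    """Return a copy with the somatic pump Na affinity constant replaced."""
    if value_mM <= 0:
        raise ValueError("K_Na must be positive")
    out = params.copy()
    out.pumps.k_na = value_mM
    return out


def bk_knockout(params: ModelParams) -> ModelParams:
    """Return a copy with BK removed from both compartments (idempotent)."""
    out = params.copy()
    out.gmax_soma["bk"] = 0.0
    out.gmax_dend["bk"] = 0.0
    return out


def add_erg(params: ModelParams, gmax_mS_cm2: float | None = None) -> ModelParams:
    """Return a copy with dendritic ERG inserted.

    The default density is 0.5 * C_d mS/cm^2 (the pre-collapse density scaled
    like every other dendritic conductance).
    """
    out = params.copy()
    if gmax_mS_cm2 is None:
        gmax_mS_cm2 = DEFAULT_ERG_BASE * params.cd
    if gmax_mS_cm2 < 0:
        raise ValueError("g_max must be >= 0")
    out.g_erg = gmax_mS_cm2
    return out
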