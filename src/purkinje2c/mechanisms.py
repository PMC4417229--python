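"""Membrane mechanisms: gate kinetics, Markov resurgent Na, current densities.

This is the inspectable front end over :mod:`purkinje2c.kinetics` (the compiled
scalar functions the simulation kernel shares). Gate identities follow the
model's current roster:

soma:      kfast (m3 h), kmid (m4), kslow (m4), cap (m, GHK), h (m),
           bk (m3 z2 h), sk (z, instantaneous), leak, naR (Markov open state)
dendrite:  cat (m h), cae (m h), cap (m), h (m), kv12 (m4), ka (m4 h),
           km (m), kd (m h), dr (m4), bk (m z2), k2 (m z2), leak, erg (m h)

Steady states printed in the source as 1/exp(-(V-Vh)/k) are implemented as
Boltzmann sigmoids 1/(1+exp(-(V-Vh)/k)) - the literal form exceeds one above
Vh and cannot be an occupancy; pass ``literal=True`` to audit the printed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import kinetics as K
from .constants import E_CA_DEND
from .kinetics import (  # noqa: F401  (re-exported)
    MARKOV_OPEN,
    MARKOV_STATES,
    ghk_flux,
    markov_generator,
    markov_steady_state,
)
from .params import SOMA_GMAX, dend_gmax_2c

__all__ = [
    "gate_inf_tau",
    "markov_rates",
    "MarkovNaState",
    "ghk_flux",
    "CurrentSpec",
    "eval_current",
    "default_current_specs",
    "GATE_TABLE",
]

# (compartment, current, gate) -> (kinetics fn, needs_ca, literal sigmoid
# params (base, amp, vhalf, slope) or None)
GATE_TABLE = {
    ("soma", "kfast", "m"): (K.soma_kfast_m, False, (0.0, 1.0, -24.0, 15.4)),
    ("soma", "kfast", "h"): (K.soma_kfast_h, False, (0.31, 0.69, -5.8, -11.2)),
    ("soma", "kmid", "m"): (K.soma_kmid_m, False, (0.0, 1.0, -24.0, 20.4)),
    ("soma", "kslow", "m"): (K.soma_kslow_m, False, (0.0, 1.0, -16.5, 18.4)),
    ("soma", "cap", "m"): (K.soma_cap_m, False, (0.0, 1.0, -19.0, 5.5)),
    ("soma", "h", "m"): (K.soma_h_m, False, (0.0, 1.0, -90.1, -9.9)),
    ("soma", "bk", "m"): (K.soma_bk_m, False, (0.0, 1.0, -28.9, 6.2)),
    ("soma", "bk", "h"): (K.soma_bk_h, False, (0.085, 0.915, -32.0, -5.8)),
    ("soma", "bk", "z"): (K.soma_bk_z, True, None),
    ("dendrite", "cat", "m"): (K.dend_cat_m, False, None),
    ("dendrite", "cat", "h"): (K.dend_cat_h, False, None),
    ("dendrite", "cae", "m"): (K.dend_cae_m, False, None),
    ("dendrite", "cae", "h"): (K.dend_cae_h, False, None),
    ("dendrite", "cap", "m"): (K.dend_cap_m, False, None),
    ("dendrite", "h", "m"): (K.dend_h_m, False, None),
    ("dendrite", "kv12", "m"): (K.dend_kv12_m, False, None),
    ("dendrite", "ka", "m"): (K.dend_ka_m, False, None),
    ("dendrite", "ka", "h"): (K.dend_ka_h, False, None),
    ("dendrite", "km", "m"): (K.dend_km_m, False, None),
    ("dendrite", "kd", "m"): (K.dend_kd_m, False, None),
    ("dendrite", "kd", "h"): (K.dend_kd_h, False, None),
    ("dendrite", "dr", "m"): (K.dend_dr_m, False, None),
    ("dendrite", "bk", "m"): (K.dend_bk_m, False, None),
    ("dendrite", "bk", "z"): (K.dend_bk_z, True, None),
    ("dendrite", "k2", "m"): (K.dend_k2_m, False, None),
    ("dendrite", "k2", "z"): (K.dend_k2_z, True, None),
    ("dendrite", "erg", "m"): (K.erg_m, False, (0.0, 1.0, -5.0, 5.0)),
    ("dendrite", "erg", "h"): (K.erg_h, False, (0.0, 1.0, -70.0, -20.0)),
}


def gate_inf_tau(
    current_id: str,
    gate_id: str,
    v_mv: float,
    ca_mm: float | None = None,
    compartment: str = None,
    literal: bool = False,
):
    """Steady state and time constant (ms) of one gate.

    ``current_id`` may be prefixed with the compartment ("soma/bk") or the
    compartment passed separately; unprefixed ids are resolved soma-first.
    Ca (mM) is required only for the Ca-gated z gates. ``literal=True``
    evaluates the un-corrected printed sigmoid (audit mode; can exceed 1).
    """
    if "/" in current_id:
        compartment, current_id = current_id.split("/", 1)
    if compartment is None:
        for comp in ("soma", "dendrite"):
            if (comp, current_id, gate_id) in GATE_TABLE:
                compartment = comp
                break
    key = (compartment, current_id, gate_id)
    if key not in GATE_TABLE:
        raise KeyError(f"unknown gate {key!r}")
    fn, needs_ca, lit = GATE_TABLE[key]
    if needs_ca:
        if ca_mm is None:
            raise ValueError(f"gate {key!r} requires a Ca concentration")
        return fn(ca_mm)
    inf, tau = fn(v_mv)
    if literal:
        if lit is None:
            raise ValueError(f"gate {key!r} has no printed-sigmoid literal form")
        base, amp, vh, k = lit
        inf = base + amp * math.exp((v_mv - vh) / k)
    return inf, tau


def sk_z(ca_mm: float) -> float:
    """Instantaneous SK activation (Hill n=4, half-activation 190 nM)."""
    return K.soma_sk_z(ca_mm)


def markov_rates(v_mv: float) -> dict:
    """Named voltage-dependent rate constants of the resurgent-Na scheme."""
    names = ("alpha", "beta", "gamma", "delta", "con", "coff", "oon", "ooff",
             "a", "b", "epsilon", "zeta")
    return dict(zip(names, K.markov_rates(v_mv)))


@dataclass
class MarkovNaState:
    """Occupancy vector of the 13-state resurgent Na scheme.

    States C1..C5 (closed), O (open), OB (open-blocked; the state whose
    repolarisation-driven emptying produces the resurgent current), I1..I6
    (inactivated). Occupancies are fractions summing to one.
    """

    occ: np.ndarray

    @classmethod
    def steady(cls, v_mv: float) -> "MarkovNaState":
        return cls(occ=markov_steady_state(v_mv))

    @property
    def open_fraction(self) -> float:
        return float(self.occ[MARKOV_OPEN])

    def check(self, tol: float = 1e-10) -> None:
        if np.any(self.occ < -tol) or np.any(self.occ > 1 + tol):
            raise ValueError("occupancies outside [0, 1]")
        if abs(self.occ.sum() - 1.0) > tol:
            raise ValueError("occupancies do not sum to 1")

    def step(self, v_mv: float, dt_ms: float) -> "MarkovNaState":
        """Advance by one backward-Euler step (conserves total occupancy)."""
        if dt_ms == 0.0:
            return MarkovNaState(occ=self.occ.copy())
        occ = self.occ.astype(float).copy()
        K.markov_backward_euler(
            occ, v_mv, dt_ms, np.empty((13, 13)), np.empty((13, 14))
        )
        return MarkovNaState(occ=occ)


def markov_step(state: MarkovNaState, v_mv: float, dt_ms: float) -> MarkovNaState:
    return state.step(v_mv, dt_ms)


# ---------------------------------------------------------------------------
# Current evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentSpec:
    """One membrane current: gate composition, density, reversal rule."""

    id: str
    compartment: str  # "soma" | "dendrite"
    g_max: float      # mS/cm^2
    gates: Sequence[tuple]  # ((gate_id, exponent), ...)
    reversal: str     # "E_K" | "E_Na" | "E_Ca" | "E_L" | "E_h" | "GHK"

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError(f"{self.id}: g_max must be >= 0")


def eval_current(
    spec: CurrentSpec,
    gate_values: Mapping[str, float],
    v_mv: float,
    e_rev_mv: float | None = None,
) -> float:
    """Instantaneous current density, uA/cm^2, positive outward.

    Ohmic currents are g_max * (product of gates^exp) * (V - E_rev); the GHK
    reversal rule replaces the driving force with the nonlinear flux term.
    Gate values must lie in [0, 1]; a missing gate raises KeyError.
    """
    gprod = 1.0
    for gate_id, exponent in spec.gates:
        if gate_id not in gate_values:
            raise KeyError(f"current {spec.id}: missing gate {gate_id!r}")
        x = gate_values[gate_id]
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"current {spec.id}: gate {gate_id!r}={x} outside [0,1]")
        gprod *= x**exponent
    if spec.reversal == "GHK":
        return spec.g_max * gprod * ghk_flux(v_mv)
    if e_rev_mv is None:
        raise ValueError(f"current {spec.id}: reversal {spec.reversal} needs E_rev")
    return spec.g_max * gprod * (v_mv - e_rev_mv)


def default_current_specs(cd: float = 6.16) -> dict[str, CurrentSpec]:
    """The full current roster at the published densities."""
    gd = dend_gmax_2c(cd)
    specs = [
        CurrentSpec("naR", "soma", SOMA_GMAX["naR"], (("O", 1),), "E_Na"),
        CurrentSpec("kfast", "soma", SOMA_GMAX["kfast"], (("m", 3), ("h", 1)), "E_K"),
        CurrentSpec("kmid", "soma", SOMA_GMAX["kmid"], (("m", 4),), "E_K"),
        CurrentSpec("kslow", "soma", SOMA_GMAX["kslow"], (("m", 4),), "E_K"),
        CurrentSpec("cap", "soma", SOMA_GMAX["cap"], (("m", 1),), "GHK"),
        CurrentSpec("bk", "soma", SOMA_GMAX["bk"], (("m", 3), ("z", 2), ("h", 1)), "E_K"),
        CurrentSpec("sk", "soma", SOMA_GMAX["sk"], (("z", 1),), "E_K"),
        CurrentSpec("h", "soma", SOMA_GMAX["h"], (("m", 1),), "E_h"),
        CurrentSpec("leak", "soma", SOMA_GMAX["leak"], (), "E_L"),
        CurrentSpec("cat", "dendrite", gd["cat"], (("m", 1), ("h", 1)), "E_Ca"),
        CurrentSpec("cae", "dendrite", gd["cae"], (("m", 1), ("h", 1)), "E_Ca"),
        CurrentSpec("cap", "dendrite", gd["cap"], (("m", 1),), "E_Ca"),
        CurrentSpec("h", "dendrite", gd["h"], (("m", 1),), "E_h"),
        CurrentSpec("kv12", "dendrite", gd["kv12"], (("m", 4),), "E_K"),
        CurrentSpec("ka", "dendrite", gd["ka"], (("m", 4), ("h", 1)), "E_K"),
        CurrentSpec("km", "dendrite", gd["km"], (("m", 1),), "E_K"),
        CurrentSpec("kd", "dendrite", gd["kd"], (("m", 1), ("h", 1)), "E_K"),
        CurrentSpec("dr", "dendrite", gd["dr"], (("m", 4),), "E_K"),
        CurrentSpec("bk", "dendrite", gd["bk"], (("m", 1), ("z", 2)), "E_K"),
        CurrentSpec("k2", "dendrite", gd["k2"], (("m", 1), ("z", 2)), "E_K"),
        CurrentSpec("leak", "dendrite", gd["leak"], (), "E_L"),
    ]
    return {f"{s.compartment}/{s.id}": s for s in specs}


#: fixed dendritic Ca reversal, mV (the GHK soma current has no reversal)
E_CA_FIXED = E_CA_DEND
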