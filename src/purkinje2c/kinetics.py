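"""Gating kinetics of every membrane mechanism.

Each gate is reduced to the pair ``(x_inf, tau_eff_ms)`` and advanced by the
exact exponential relaxation ``x += (1 - exp(-dt/tau)) * (x_inf - x)`` with
coefficients frozen over the step. Mechanisms whose source code prescribes an
explicit relaxation factor (the dendritic E-type Ca, D-type K, delayed
rectifier, BK m and K2 m gates, with their extra /4, /10, x1.6 divisors) are
expressed through the equivalent effective time constant, so the update
reproduces the source factors exactly.

Somatic time constants are published in seconds and converted to ms here;
dendritic alpha/beta rates are in 1/ms as published. Voltage in mV, Ca in mM.

All functions are scalar and numba-compiled; they are shared between the
simulation kernel and the public :mod:`purkinje2c.mechanisms` API.
"""

import math

import numpy as np

from ._compat import njit
from .constants import MT_37, MT_22, FT_36

__all__ = [
    "sigmoid",
    "ghk_flux",
    "markov_rates",
    "markov_generator",
    "markov_backward_euler",
    "markov_steady_state",
    "MARKOV_STATES",
    "MARKOV_OPEN",
]


@njit
def sigmoid(x):
    # guarded logistic; |x| beyond 500 saturates instead of overflowing
    if x > 500.0:
        return 1.0
    if x < -500.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Soma: highly / moderately / non TEA-sensitive K currents (m^3 h, m^4, m^4)
# ---------------------------------------------------------------------------

@njit
def soma_kfast_m(v):
    inf = sigmoid((v + 24.0) / 15.4)
    if v < -35.0:
        tau = 0.000103 + 0.0149 * math.exp(0.035 * v)
    else:
        tau = 0.000129 + 1.0 / (
            math.exp((v + 100.7) / 12.9) + math.exp((v - 56.0) / -23.1)
        )
    return inf, 1000.0 * tau


@njit
def soma_kfast_h(v):
    inf = 0.31 + (1.0 - 0.31) * sigmoid(-(v + 5.8) / 11.2)
    if v <= 0.0:
        tau = 1.22e-5 + 0.012 * math.exp(-(((v + 56.3) / 49.6) ** 2))
    else:
        tau = 0.0012 + 0.0023 * math.exp(-0.141 * v)
    return inf, 1000.0 * tau


@njit
def soma_kmid_m(v):
    inf = sigmoid((v + 24.0) / 20.4)
    if v < -20.0:
        tau = 0.000688 + 1.0 / (
            math.exp((v + 64.2) / 6.5) + math.exp((v - 141.5) / -34.8)
        )
    else:
        tau = 0.00016 + 0.0008 * math.exp(-0.0267 * v)
    return inf, 1000.0 * tau


@njit
def soma_kslow_m(v):
    inf = sigmoid((v + 16.5) / 18.4)
    tau = 0.000796 + 1.0 / (
        math.exp((v + 73.2) / 11.7) + math.exp((v - 306.7) / -74.2)
    )
    return inf, 1000.0 * tau


# ---------------------------------------------------------------------------
# Soma: P-type Ca (GHK), HCN, BK, SK
# ---------------------------------------------------------------------------

@njit
def soma_cap_m(v):
    inf = sigmoid((v + 19.0) / 5.5)
    if v <= -50.0:
        tau = 0.000264 + 0.128 * math.exp(0.103 * v)
    else:
        tau = 0.000191 + 0.00376 * math.exp(-(((v + 11.9) / 27.8) ** 2))
    return inf, 1000.0 * tau


@njit
def soma_h_m(v):
    inf = sigmoid(-(v + 90.1) / 9.9)
    tau = 0.19 + 0.72 * math.exp(-(((v + 81.5) / 11.9) ** 2))
    return inf, 1000.0 * tau


@njit
def soma_bk_m(v):
    inf = sigmoid((v + 28.9) / 6.2)
    tau = 0.000505 + 1.0 / (
        math.exp((v + 86.4) / 10.1) + math.exp((v - 33.3) / -10.0)
    )
    return inf, 1000.0 * tau


@njit
def soma_bk_h(v):
    inf = 0.085 + (1.0 - 0.085) * sigmoid(-(v + 32.0) / 5.8)
    tau = 0.0019 + 1.0 / (
        math.exp((v + 48.5) / 5.2) + math.exp((v - 54.2) / -12.9)
    )
    return inf, 1000.0 * tau


@njit
def soma_bk_z(ca):
    # Ca in mM; half-activation at 1 uM. tau printed as 1 (ms).
    inf = 1.0 / (1.0 + 0.001 / ca)
    return inf, 1.0


@njit
def soma_sk_z(ca):
    # instantaneous Hill gate, n=4, half-activation 190 nM
    r = 0.00019 / ca
    return 1.0 / (1.0 + r * r * r * r)


# ---------------------------------------------------------------------------
# GHK flux for the somatic P-type Ca current
# ---------------------------------------------------------------------------

@njit
def ghk_flux(v, p_ca=5e-5, ca_i=1e-4, ca_o=2.0, temp_k=295.0):
    """Goldman-Hodgkin-Katz Ca flux term, uA/cm^2.

    ``p_ca`` in cm/s, concentrations in mM. The concentrations are fixed
    constants of the current description - the changing shell Ca is not seen
    here. The removable singularity at V = 0 is handled by a series branch;
    the V -> 0 limit is 2*P*F*([Ca]_i - [Ca]_o).
    """
    F = 96485.33212
    R = 8.31446261815324
    u = 2.0 * F * (v * 1e-3) / (R * temp_k)  # dimensionless 2FV/RT
    if abs(u) < 1e-4:
        s = 1.0 + u / 2.0 + u * u / 12.0  # u / (1 - exp(-u)) series
        return p_ca * 2.0 * F * (ca_i - ca_o * math.exp(-u)) * s
    return p_ca * 2.0 * F * u * (ca_i - ca_o * math.exp(-u)) / (1.0 - math.exp(-u))


# ---------------------------------------------------------------------------
# Dendrite: Ca currents (fixed E_Ca = +135 mV)
# ---------------------------------------------------------------------------

@njit
def dend_cat_m(v):
    a = 2.6 / (1.0 + math.exp(-(v + 21.0) / 8.0))
    b = 0.18 / (1.0 + math.exp((v + 40.0) / 4.0))
    return a / (a + b), 1.0 / ((a + b) * MT_37)


@njit
def dend_cat_h(v):
    a = 0.0025 / (1.0 + math.exp((v + 40.0) / 8.0))
    b = 0.19 / (1.0 + math.exp(-(v + 50.0) / 10.0))
    return a / (a + b), 1.0 / ((a + b) * MT_37)


@njit
def dend_cae_m(v):
    a = 2.6 / (1.0 + math.exp(-(v + 7.0) / 8.0))
    b = 0.18 / (1.0 + math.exp((v + 26.0) / 4.0))
    # source relaxation factor exp(-dt*mt*(a+b)/4) => tau = 4/(mt*(a+b))
    return a / (a + b), 4.0 / ((a + b) * MT_37)


@njit
def dend_cae_h(v):
    a = 0.0025 / (1.0 + math.exp((v + 32.0) / 8.0))
    b = 0.19 / (1.0 + math.exp(-(v + 42.0) / 10.0))
    return a / (a + b), 10.0 / ((a + b) * MT_37)


@njit
def dend_cap_m(v):
    a = 8.5 / (1.0 + math.exp(-(v - 8.0) / 12.5))
    b = 35.0 / (1.0 + math.exp((v + 74.0) / 14.5))
    return a / (a + b), 1.0 / ((a + b) * MT_37)


# ---------------------------------------------------------------------------
# Dendrite: HCN, Kv1.2, A-, M-, D-type, delayed rectifier, BK, K2, ERG
# ---------------------------------------------------------------------------

@njit
def dend_h_m(v):
    inf = 1.0 / (1.0 + math.exp((v + 84.1) / 10.2))
    tau = 1.0 / (
        math.exp(-17.9 - 0.116 * v) + math.exp(-1.84 + 0.09 * v)
    ) + 100.0
    return inf, tau


@njit
def dend_kv12_m(v):
    a = 0.12899 * math.exp((v + 45.0) / 33.90877)
    b = 0.12899 * math.exp(-(v + 45.0) / 12.42101)
    return a / (a + b), 1.0 / ((a + b) * MT_22)


@njit
def dend_ka_m(v):
    a = 1.4 / (1.0 + math.exp(-(v + 27.0) / 12.0))
    b = 0.49 / (1.0 + math.exp((v + 30.0) / 4.0))
    return a / (a + b), 1.0 / ((a + b) * MT_37)


@njit
def dend_ka_h(v):
    a = 0.00175 / (1.0 + math.exp((v + 50.0) / 8.0))
    b = 0.49 / (1.0 + math.exp(-(v + 13.0) / 10.0))
    return a / (a + b), 1.0 / ((a + b) * MT_37)


@njit
def dend_km_m(v):
    inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    tau = (1000.0 / FT_36) / (
        3.3 * (math.exp((v + 35.0) / 40.0) + math.exp(-(v + 35.0) / 20.0))
    )
    return inf, tau


@njit
def dend_kd_m(v):
    a = 8.5 / (1.0 + math.exp(-(v + 17.0) / 12.5))
    b = 35.0 / (1.0 + math.exp((v + 99.0) / 14.5))
    return a / (a + b), 10.0 / ((a + b) * MT_37)


@njit
def dend_kd_h(v):
    a = 0.0015 / (1.0 + math.exp((v + 89.0) / 8.0))
    b = 0.0055 / (1.0 + math.exp(-(v + 83.0) / 8.0))
    return a / (a + b), 1.0 / (1.6 * (a + b) * MT_37)


@njit
def dr_vtrap(v):
    """Linearised alpha ramp of the delayed rectifier, with the removable
    singularity at V = -55 mV caught by a series branch."""
    x = -(v + 55.0) / 10.0
    if abs(x) < 1e-6:
        return 10.0 * (1.0 - x / 2.0)
    return -(v + 55.0) / (math.exp(x) - 1.0)


@njit
def dend_dr_m(v):
    a = 0.1 * dr_vtrap(v)
    b = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return a / (a + b), 1.0 / ((a + b) * MT_37)


@njit
def dend_bk_m(v):
    a = 7.5
    b = 0.11 * math.exp(-(v - 35.0) / 14.9)
    return a / (a + b), 1.0 / (a + b)


@njit
def dend_bk_z(ca):
    # alpha_z = 1, beta_z = 400/([Ca]*1000) with Ca in mM; tau fixed 10 ms
    inf = 1.0 / (1.0 + 400.0 / (ca * 1000.0))
    return inf, 10.0


@njit
def dend_k2_m(v):
    a = 25.0
    b = 0.075 * math.exp(-(v + 5.0) / 10.0)
    return a / (a + b), 1.0 / (a + b)


@njit
def dend_k2_z(ca):
    inf = 1.0 / (1.0 + 20.0 / (ca * 1000.0))
    return inf, 10.0


@njit
def erg_m(v, v_half=-5.0):
    inf = sigmoid((v - v_half) / 5.0)
    tau = 1.0 / (
        0.00225 * math.exp(0.12 * v) + 0.00004 * math.exp(-0.05 * v)
    )
    return inf, tau


@njit
def erg_h(v):
    inf = sigmoid(-(v + 70.0) / 20.0)
    tau = 1.0 / (0.1 * math.exp(0.02 * v) + 0.003 * math.exp(-0.03 * v))
    return inf, tau


# ---------------------------------------------------------------------------
# Markov resurgent Na channel (13 states)
# ---------------------------------------------------------------------------

MARKOV_STATES = (
    "C1", "C2", "C3", "C4", "C5", "O", "OB",
    "I1", "I2", "I3", "I4", "I5", "I6",
)
#: index of the open state in the occupancy vector
MARKOV_OPEN = 5

_CON = 0.005
_COFF = 0.5
_OON = 0.75
_OOFF = 0.005
_A = (_OON / _CON) ** 0.25
_B = (_OOFF / _COFF) ** 0.25


@njit
def markov_rates(v):
    """Voltage-dependent rate set (1/ms).

    Returns (alpha, beta, gamma, delta, con, coff, oon, ooff, a, b,
    epsilon, zeta). Activation alpha grows and deactivation beta decays with
    depolarisation; the open-channel-block exit rate zeta grows on
    repolarisation, which is what produces the resurgent current.
    """
    alpha = 150.0 * math.exp(v / 20.0)
    beta = 3.0 * math.exp(-v / 20.0)
    zeta = 0.03 * math.exp(-v / 25.0)
    return (alpha, beta, 150.0, 40.0, _CON, _COFF, _OON, _OOFF,
            _A, _B, 1.75, zeta)


@njit
def markov_generator(v, out):
    """Fill ``out`` (13x13) with the transition-rate generator A.

    A[i, j] is the rate from state j to state i for i != j; diagonal entries
    close each column to zero, so d(occ)/dt = A @ occ conserves total
    occupancy. State order: C1..C5, O, OB, I1..I6.
    """
    alpha, beta, gamma, delta, con, coff, oon, ooff, a, b, eps, zeta = \
        markov_rates(v)
    out[:, :] = 0.0
    # closed chain C1..C5 (indices 0..4), multiplicities 4,3,2,1
    for i in range(4):
        out[i + 1, i] += (4.0 - i) * alpha      # C_i -> C_{i+1}
        out[i, i + 1] += (i + 1.0) * beta       # C_{i+1} -> C_i
    out[5, 4] += gamma                          # C5 -> O
    out[4, 5] += delta                          # O -> C5
    out[6, 5] += eps                            # O -> OB
    out[5, 6] += zeta                           # OB -> O
    # inactivation couplings C_i <-> I_i
    for i in range(5):
        out[7 + i, i] += con * a ** i           # C_i -> I_i
        out[i, 7 + i] += coff * b ** i          # I_i -> C_i
    out[12, 5] += oon                           # O -> I6
    out[5, 12] += ooff                          # I6 -> O
    # inactivated chain I1..I6 (indices 7..12)
    for i in range(4):
        out[8 + i, 7 + i] += (4.0 - i) * alpha * a
        out[7 + i, 8 + i] += (i + 1.0) * beta * b
    out[12, 11] += gamma                        # I5 -> I6
    out[11, 12] += delta                        # I6 -> I5
    # close the columns
    for j in range(13):
        s = 0.0
        for i in range(13):
            if i != j:
                s += out[i, j]
        out[j, j] = -s
    return out


@njit
def markov_backward_euler(occ, v, dt, scratch_a, scratch_m):
    """One implicit (backward Euler) step of the occupancy vector.

    Solves (I - dt*A) x_new = x_old by Gaussian elimination. The matrix is
    strictly column diagonally dominant (diag 1 + dt*sum(out-rates)), so
    elimination without pivoting is stable. The left null vector of A is the
    ones vector, hence the step conserves total occupancy exactly up to
    roundoff; a final renormalisation pins the sum to 1.
    """
    markov_generator(v, scratch_a)
    n = 13
    for i in range(n):
        for j in range(n):
            scratch_m[i, j] = -dt * scratch_a[i, j]
        scratch_m[i, i] += 1.0
        scratch_m[i, n] = occ[i]
    # forward elimination
    for k in range(n):
        piv = scratch_m[k, k]
        for i in range(k + 1, n):
            f = scratch_m[i, k] / piv
            if f != 0.0:
                for j in range(k, n + 1):
                    scratch_m[i, j] -= f * scratch_m[k, j]
    # back substitution
    for i in range(n - 1, -1, -1):
        s = scratch_m[i, n]
        for j in range(i + 1, n):
            s -= scratch_m[i, j] * occ[j]
        occ[i] = s / scratch_m[i, i]
    total = 0.0
    for i in range(n):
        if occ[i] < 0.0:
            occ[i] = 0.0
        total += occ[i]
    for i in range(n):
        occ[i] /= total
    return occ


@njit
def markov_conservation_scan(n_steps, seed):
    """Stress the occupancy invariants over random (V, dt) steps.

    Returns (max |sum - 1|, min occupancy) over the walk. Voltages are drawn
    uniformly from [-120, 60] mV and steps from (0, 0.1] ms.
    """
    np.random.seed(seed)
    occ = np.zeros(13)
    occ[0] = 1.0
    scr_a = np.empty((13, 13))
    scr_m = np.empty((13, 14))
    worst_sum = 0.0
    worst_occ = 1.0
    for _ in range(n_steps):
        v = -120.0 + 180.0 * np.random.random()
        dt = 0.1 * np.random.random() + 1e-6
        markov_backward_euler(occ, v, dt, scr_a, scr_m)
        s = 0.0
        for i in range(13):
            if occ[i] < worst_occ:
                worst_occ = occ[i]
            s += occ[i]
        err = abs(s - 1.0)
        if err > worst_sum:
            worst_sum = err
    return worst_sum, worst_occ


def markov_steady_state(v: float) -> np.ndarray:
    """Stationary occupancy at clamped voltage (solves A x = 0, sum x = 1)."""
    a = np.empty((13, 13))
    markov_generator(v, a)
    m = a.copy()
    m[-1, :] = 1.0
    rhs = np.zeros(13)
    rhs[-1] = 1.0
    x = np.linalg.solve(m, rhs)
    x = np.clip(x, 0.0, None)
    return x / x.sum()
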