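"""Non-Markov sarcolemmal currents: HH channels, pumps and exchangers.

All currents are in pA/pF with outward positive.  Gating-rate and
current functions are scalar so the same code serves both standalone
current-voltage scans and the assembled whole-cell right-hand side.
"""

import math

from ._speed import jit as _jit, sexp as _exp
from .constants import f_over_rt


def nernst(z: int, c_in: float, c_out: float, temp_c: float) -> float:
    """Nernst equilibrium potential (mV) for valence ``z``."""
    if z == 0:
        raise ValueError("valence must be non-zero")
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    return math.log(c_out / c_in) / (z * f_over_rt(temp_c))


# ---------------------------------------------------------------------------
# fast and late Na+ currents
# ---------------------------------------------------------------------------

@_jit
def ina_rates(v):
    """(am, bm, ah, bh, aj, bj) in 1/ms; classic cardiac Na+ kinetics."""
    dv = v + 47.13
    if abs(dv) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - _exp(-0.1 * dv))
    bm = 0.08 * _exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + _exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * _exp(-2.535e-7 * v) / (1.0 + _exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * _exp(-(80.0 + v) / 6.8)
        bh = 3.56 * _exp(0.079 * v) + 3.1e5 * _exp(0.35 * v)
        aj = ((-1.2714e5 * _exp(0.2444 * v) - 3.474e-5 * _exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + _exp(0.311 * (v + 79.23))))
        bj = 0.1212 * _exp(-0.01052 * v) / (1.0 + _exp(-0.1378 * (v + 40.14)))
    return am, bm, ah, bh, aj, bj


@_jit
def ina_current(m, h, j, v, e_na, g):
    return g * m * m * m * h * j * (v - e_na)


@_jit
def inal_gates(v):
    """(mL_inf, tau_mL, hL_inf, tau_hL); slow-inactivating component."""
    ml_inf = 1.0 / (1.0 + _exp(-(v + 42.85) / 5.264))
    tau_ml = 0.5 + 1.5 / (1.0 + _exp((v + 35.0) / 8.0))
    hl_inf = 1.0 / (1.0 + _exp((v + 87.61) / 7.488))
    tau_hl = 200.0
    return ml_inf, tau_ml, hl_inf, tau_hl


@_jit
def inal_current(ml, hl, v, e_na, g):
    return g * ml * hl * (v - e_na)


# ---------------------------------------------------------------------------
# steady-state K+ current (single activation gate, no inactivation)
# ---------------------------------------------------------------------------

@_jit
def iss_gate(v, phi_kin):
    """(x_inf, tau_x in ms); slow activation, time constant / Q10 factor."""
    x_inf = 1.0 / (1.0 + _exp(-(v + 12.0) / 10.5))
    tau = (45.0 + 300.0 / (1.0 + _exp((v + 25.0) / 10.0))) / phi_kin
    return x_inf, tau


@_jit
def iss_rectification(v):
    """Mild outward-rectification saturation of the conducting pathway.

    Makes the fully-activated I-V plateau around +30..+40 mV instead of
    growing linearly, matching the measured shape of the current.
    """
    return 1.0 / (1.0 + _exp((v - 45.0) / 40.0))


@_jit
def iss_current(x, v, e_k, g, phi_g):
    return g * phi_g * x * iss_rectification(v) * (v - e_k)


# ---------------------------------------------------------------------------
# inward rectifier and background K+ currents
# ---------------------------------------------------------------------------

@_jit
def ik1_current(v, e_k, k_o, g):
    dv = v - e_k
    a = 1.02 / (1.0 + _exp(0.2385 * (dv - 59.215)))
    b = ((0.49124 * _exp(0.08032 * (dv + 5.476))
          + _exp(0.06175 * (dv - 594.31)))
         / (1.0 + _exp(-0.5143 * (dv + 4.753))))
    k1_inf = a / (a + b)
    return g * math.sqrt(k_o / 5.4) * k1_inf * dv


@_jit
def ikb_current(v, e_k, g):
    """Instantaneous Boltzmann-shaped background K+ current (37 C fit)."""
    act = 0.02 + 0.98 / (1.0 + _exp(-(v + 55.0) / 12.0))
    return g * act * (v - e_k)


@_jit
def ikach_current(v, e_k, ach, g):
    """ACh-activated K+ current; closed at ach = 0 (uM)."""
    if ach <= 0.0:
        return 0.0
    dose = ach / (ach + 0.125)
    rect = 0.055 + 0.40 / (1.0 + _exp((v - e_k + 9.5) / 17.5))
    return g * dose * rect * (v - e_k)


@_jit
def ikca_current(v, e_k, ca_sl, g, km):
    """Small-conductance Ca2+-activated K+ current (Hill 2 on SL Ca2+)."""
    act = 1.0 / (1.0 + (km / ca_sl) ** 2)
    return g * act * (v - e_k)


# ---------------------------------------------------------------------------
# Cl- currents
# ---------------------------------------------------------------------------

@_jit
def iclca_current(v, e_cl, ca_sl, g, kd):
    return g * (v - e_cl) / (1.0 + kd / ca_sl)


@_jit
def iclb_current(v, e_cl, g):
    return g * (v - e_cl)


# ---------------------------------------------------------------------------
# backgrounds
# ---------------------------------------------------------------------------

@_jit
def background_current(v, e_rev, g):
    return g * (v - e_rev)


# ---------------------------------------------------------------------------
# pumps and exchangers
# ---------------------------------------------------------------------------

@_jit
def inak_current(v, na_i, k_o, na_o, imax, km_nai, km_ko, frt):
    """Na+/K+ pump; always outward, saturating in internal Na+."""
    sigma = (_exp(na_o / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * _exp(-0.1 * v * frt)
                   + 0.0365 * sigma * _exp(-v * frt))
    na_term = 1.0 / (1.0 + (km_nai / na_i) ** 4)
    return imax * f_nak * na_term * k_o / (k_o + km_ko)


@_jit
def incx_current(v, na_i, ca_sl, na_o, ca_o, k, eta, ksat, kd_act, frt):
    """Na+/Ca2+ exchanger; positive = reverse mode (Ca2+ entry).

    Simplified electro-diffusive form with allosteric cytosolic-Ca2+
    activation; the denominator normalisation is folded into ``k``.
    """
    x = v * frt
    ka = 1.0 / (1.0 + (kd_act / ca_sl) ** 3)
    num = (_exp(eta * x) * na_i ** 3 * ca_o
           - _exp((eta - 1.0) * x) * na_o ** 3 * ca_sl)
    den = (na_o ** 3 * ca_o) * (1.0 + ksat * _exp((eta - 1.0) * x))
    return k * ka * num / den


@_jit
def ipmca_current(ca_sl, imax, km):
    """Plasma-membrane Ca2+ pump (Hill 1.6), outward."""
    h = ca_sl ** 1.6
    return imax * h / (h + km ** 1.6)
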