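"""Markov-chain gating schemes of the five state-dependent channels.

Each channel exposes a generator-matrix builder ``q_<name>(...)`` returning
the column-generator Q (Q[i, j] is the j -> i transition rate in 1/ms,
diagonal entries are minus the column sums), so occupancies obey
``d occ / dt = Q @ occ`` and probability is conserved by construction.

Schemes and the modifications applied to them:

* L-type Ca2+ channel: 7 states (C2, C1, O, IV1, IV2, ICa, ICaV).  The
  C2<->C1 transition carries the strong voltage dependence and its rates
  are evaluated at V + 4.4 mV (leftward shift of the steady-state
  activation); C1->O is voltage independent.  Ca2+-dependent inactivation
  enters through the O->ICa rate driven by cleft Ca2+.
* transient outward K+ current: 7 states (C3, C2, C1, O, If, Is, CI), a
  three-step activation ladder with fast/slow open-state inactivation and
  one closed-inactivated state.
* ultra-rapid K+ current: 6 states (C1..C4, O, I); the activation ladder
  rates alpha and beta are 1/8 of the parent Kv1.5 values, which slows
  activation to the atrial phenotype; inactivation is very slow.
* rapid delayed rectifier: 5 states (C1, C2, C3, O, I) with slow
  activation and fast, inverted-voltage-dependence inactivation
  (hERG-like); native to 37 C, no temperature rescaling.
* ryanodine receptor: 4 states (R, O, I, RI) gated by cleft Ca2+ with the
  luminal-Ca2+ sensitivity expressed through an SR-Ca EC50 (parent value
  reduced by 10%).

Rate coefficients are frozen after calibration against the voltage-clamp
peak densities and kinetics; see docs/methods.md.
"""

import numpy as np

from ._speed import jit as _jit, sexp as _exp


ICAL_STATES = ("C2", "C1", "O", "IV1", "IV2", "ICa", "ICaV")
ITO_STATES = ("C3", "C2", "C1", "O", "If", "Is", "CI")
IKUR_STATES = ("C1", "C2", "C3", "C4", "O", "I")
IKR_STATES = ("C1", "C2", "C3", "O", "I")
RYR_STATES = ("R", "O", "I", "RI")

ICAL_OPEN = 2
ITO_OPEN = 3
IKUR_OPEN = 4
IKR_OPEN = 3
RYR_OPEN = 1

#: leftward shift applied to the voltage of the C2<->C1 LTCC rates (mV)
ICAL_ACT_SHIFT = 4.4
#: Kv1.5 ladder rates are divided by this factor
IKUR_RATE_DIVISOR = 8.0


@_jit
def _rate(q, i, j, r):
    """Insert the j -> i rate into a column-generator matrix in place."""
    q[i, j] += r
    q[j, j] -= r


@_jit
def q_ical(v, ca_cleft, phi_kin):
    """LTCC generator at voltage ``v`` (mV) and cleft Ca2+ (mM)."""
    q = np.zeros((7, 7))
    vs = v + ICAL_ACT_SHIFT  # shifted voltage, C2<->C1 only
    a_ct = 0.9 / (1.0 + _exp(-(vs - 2.0) / 5.5))
    b_ct = 0.9 / (1.0 + _exp((vs - 2.0) / 5.5))
    kco = 0.25          # C1 -> O, voltage independent
    koc = 0.25
    kov = 0.120 / (1.0 + _exp(-(v + 15.0) / 8.0))     # O -> IV1
    krec = 0.001 + 0.012 / (1.0 + _exp((v + 50.0) / 7.0))  # I* -> C1
    kvv = 0.002                                        # IV1 -> IV2
    kvvb = 0.0008 + 0.010 / (1.0 + _exp((v + 60.0) / 7.0))
    kca = 0.30 * ca_cleft / (ca_cleft + 0.005)         # O -> ICa (CDI)
    _rate(q, 1, 0, a_ct)
    _rate(q, 0, 1, b_ct)
    _rate(q, 2, 1, kco)
    _rate(q, 1, 2, koc)
    _rate(q, 3, 2, kov)      # O -> IV1
    _rate(q, 0, 3, krec)     # IV1 -> C2 (recovery lands deactivated)
    _rate(q, 4, 3, kvv)
    _rate(q, 3, 4, kvvb)
    _rate(q, 5, 2, kca)      # O -> ICa
    _rate(q, 0, 5, krec)     # ICa -> C2
    _rate(q, 6, 5, kov)      # ICa -> ICaV
    _rate(q, 5, 6, krec)     # ICaV -> ICa
    if phi_kin != 1.0:
        for j in range(7):
            for i in range(7):
                q[i, j] *= phi_kin
    return q


@_jit
def q_ito(v, phi_kin):
    """Transient-outward K+ channel generator."""
    q = np.zeros((7, 7))
    a = 0.55 * _exp(v / 40.0)
    b = 0.06 * _exp(-v / 22.0)
    ki_f = 0.018                                   # O -> If
    kr_f = 0.006 + 0.050 / (1.0 + _exp((v + 60.0) / 8.0))
    ki_s = 0.004                                   # If -> Is
    kr_s = 0.0035 + 0.015 / (1.0 + _exp((v + 60.0) / 8.0))
    kci = 0.0037                                   # C1 -> CI
    kic = 0.0002 + 0.020 / (1.0 + _exp((v + 55.0) / 7.0))
    _rate(q, 1, 0, 3.0 * a)
    _rate(q, 0, 1, b)
    _rate(q, 2, 1, 2.0 * a)
    _rate(q, 1, 2, 2.0 * b)
    _rate(q, 3, 2, a)
    _rate(q, 2, 3, 3.0 * b)
    _rate(q, 4, 3, ki_f)
    _rate(q, 3, 4, kr_f)
    _rate(q, 5, 4, ki_s)
    _rate(q, 4, 5, kr_s)
    _rate(q, 6, 2, kci)
    _rate(q, 2, 6, kic)
    if phi_kin != 1.0:
        for j in range(7):
            for i in range(7):
                q[i, j] *= phi_kin
    return q


@_jit
def q_ikur(v, phi_kin):
    """Ultra-rapid K+ channel generator (ladder rates already / 8)."""
    q = np.zeros((6, 6))
    a = 1.60 * _exp(v / 30.0) / IKUR_RATE_DIVISOR
    b = 0.22 * _exp(-v / 25.0) / IKUR_RATE_DIVISOR
    kin = 0.0012                                    # O -> I, slow
    kout = 0.0010 + 0.020 / (1.0 + _exp((v + 70.0) / 8.0))
    _rate(q, 1, 0, 4.0 * a)
    _rate(q, 0, 1, b)
    _rate(q, 2, 1, 3.0 * a)
    _rate(q, 1, 2, 2.0 * b)
    _rate(q, 3, 2, 2.0 * a)
    _rate(q, 2, 3, 3.0 * b)
    _rate(q, 4, 3, a)
    _rate(q, 3, 4, 4.0 * b)
    _rate(q, 5, 4, kin)
    _rate(q, 4, 5, kout)
    if phi_kin != 1.0:
        for j in range(6):
            for i in range(6):
                q[i, j] *= phi_kin
    return q


@_jit
def q_ikr(v, phi_kin):
    """Rapid delayed-rectifier K+ channel generator (hERG-like)."""
    q = np.zeros((5, 5))
    a1 = 0.068 * _exp(0.033 * v)
    b1 = 0.0014 * _exp(-0.058 * v)
    a2 = 0.160
    b2 = 0.044
    a3 = 0.088 * _exp(0.036 * v)
    b3 = 0.0276 * _exp(-0.041 * v)
    ai = 0.110 * _exp(0.0255 * v)     # O -> I, fast at depolarised V
    bi = 0.0065 * _exp(-0.028 * v)
    _rate(q, 1, 0, a1)
    _rate(q, 0, 1, b1)
    _rate(q, 2, 1, a2)
    _rate(q, 1, 2, b2)
    _rate(q, 3, 2, a3)
    _rate(q, 2, 3, b3)
    _rate(q, 4, 3, ai)
    _rate(q, 3, 4, bi)
    if phi_kin != 1.0:
        for j in range(5):
            for i in range(5):
                q[i, j] *= phi_kin
    return q


@_jit
def q_ryr(ca_cleft, ca_sr, open_mult, ko_ca, ki_ca, kom, kim,
          max_sr, min_sr, ec50_sr):
    """Ryanodine-receptor generator gated by cleft and luminal Ca2+.

    ``open_mult`` scales the opening rate (caffeine hook, 1 = none).
    """
    q = np.zeros((4, 4))
    ratio = ec50_sr / ca_sr
    k_ca_sr = max_sr - (max_sr - min_sr) / (1.0 + ratio * ratio * np.sqrt(ratio))
    ko_sr = open_mult * ko_ca / k_ca_sr
    ki_sr = ki_ca * k_ca_sr
    _rate(q, 1, 0, ko_sr * ca_cleft * ca_cleft)   # R -> O
    _rate(q, 0, 1, kom)
    _rate(q, 2, 1, ki_sr * ca_cleft)              # O -> I
    _rate(q, 1, 2, kim)
    _rate(q, 3, 2, kom)                           # I -> RI
    _rate(q, 2, 3, ko_sr * ca_cleft * ca_cleft)
    _rate(q, 0, 3, kim)                           # RI -> R
    _rate(q, 3, 0, ki_sr * ca_cleft)
    return q
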