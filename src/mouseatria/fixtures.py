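"""Analytic test objects with known answers (no external data).

* ``two_state_channel`` — constant rates alpha=2, beta=1 /ms, so the
  stationary open fraction is alpha/(alpha+beta) = 2/3.
* ``triangle_ap`` — instant upstroke from -80 to +20 mV followed by a
  linear 100-ms repolarisation: APD_x = x ms by construction.
* ``exp_cat`` — a 0.1 uM baseline stepping to 0.1 + 0.2 exp(-t/200) uM,
  so the decay fit must recover tau = 200 ms.
* ``detailed_balance_ring`` — a 3-state ring obeying detailed balance,
  whose stationary distribution equals the Boltzmann weights.
"""

from __future__ import annotations

import numpy as np

from .markov import MarkovChainSpec

FIXTURE_KINDS = ("two_state_channel", "triangle_ap", "exp_cat",
                 "detailed_balance_ring")


def _two_state(alpha: float = 2.0, beta: float = 1.0) -> MarkovChainSpec:
    def build_q(v, ligands, phi):
        q = np.array([[-alpha, beta], [alpha, -beta]]) * phi
        return q
    return MarkovChainSpec("two_state", ("C", "O"), build_q, {"O": 1.0},
                           g_max=1.0)


#: Boltzmann energies (units of kT) of the detailed-balance ring states
RING_ENERGIES = (0.0, 1.0, 2.5)


def _ring() -> MarkovChainSpec:
    e = np.array(RING_ENERGIES)

    def build_q(v, ligands, phi):
        q = np.zeros((3, 3))
        for j in range(3):
            for i in range(3):
                if i == j:
                    continue
                # symmetric barrier rule -> detailed balance
                r = np.exp(-(e[i] - e[j]) / 2.0)
                q[i, j] += r
                q[j, j] -= r
        return q * phi
    return MarkovChainSpec("ring", ("A", "B", "C"), build_q, {"A": 1.0})


def ring_boltzmann() -> np.ndarray:
    w = np.exp(-np.array(RING_ENERGIES))
    return w / w.sum()


def _triangle_ap(dt: float = 0.01):
    t = np.arange(0.0, 120.0 + dt / 2, dt)
    v = np.full_like(t, -80.0)
    up = t >= 1.0
    v[up] = np.maximum(20.0 - (t[up] - 1.0), -80.0)
    return t, v


def _exp_cat(dt: float = 1.0, tau: float = 200.0):
    t = np.arange(0.0, 1250.0 + dt / 2, dt)
    ca = np.full_like(t, 1e-4)            # mM, diastolic baseline
    decay = t >= 50.0
    ca[decay] = 1e-4 + 2e-4 * np.exp(-(t[decay] - 50.0) / tau)
    return t, ca


def fixtures(kind: str):
    """Return the named analytic fixture object."""
    if kind == "two_state_channel":
        return _two_state()
    if kind == "triangle_ap":
        return _triangle_ap()
    if kind == "exp_cat":
        return _exp_cat()
    if kind == "detailed_balance_ring":
        return _ring()
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of "
                     f"{FIXTURE_KINDS}")
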