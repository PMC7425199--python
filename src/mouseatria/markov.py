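"""Generic Markov-chain gating engine.

A channel is described by a :class:`MarkovChainSpec`: ordered state labels,
a generator-matrix builder, the conducting states and how the driving force
is obtained.  The engine provides the column-generator matrix (probability
conserving by construction), its stationary distribution, and the per-state
current/flux functions for the five channels of the cell model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import channels as ch
from .constants import f_over_rt, q10_factor


@dataclass(frozen=True)
class TemperatureScaling:
    """Q10 rescaling between an experiment and a simulation temperature."""

    q10_kinetics: float
    q10_conductance: float
    t_exp: float
    t_sim: float

    def __post_init__(self):
        if self.q10_kinetics <= 0 or self.q10_conductance <= 0:
            raise ValueError("Q10 factors must be positive")

    @property
    def kinetics(self) -> float:
        return q10_factor(self.q10_kinetics, self.t_sim, self.t_exp)

    @property
    def conductance(self) -> float:
        return q10_factor(self.q10_conductance, self.t_sim, self.t_exp)


@dataclass(frozen=True)
class MarkovChainSpec:
    """State graph and conduction rule of one Markov channel."""

    name: str
    states: tuple
    #: (V, ligands, phi_kin) -> column-generator matrix (1/ms)
    build_q: Callable
    #: state label -> conductance weight (usually one open state, weight 1)
    conducting: Mapping[str, float]
    g_max: float = 0.0
    #: "nernst:K" | "nernst:Ca" | "fixed:<mV>"
    erev: str = "nernst:K"

    def __post_init__(self):
        unknown = set(self.conducting) - set(self.states)
        if unknown:
            raise ValueError(f"conducting states {unknown} not in state list")

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)

    def open_fraction(self, occ: np.ndarray) -> float:
        return float(sum(w * occ[self.index(s)]
                         for s, w in self.conducting.items()))


def transition_matrix(spec: MarkovChainSpec, v: float,
                      ligands: Mapping[str, float] | None = None,
                      phi_kin: float = 1.0) -> np.ndarray:
    """Column-generator matrix at voltage ``v`` (mV).

    Off-diagonal entries are the (Q10-scaled) transition rates, the
    diagonal holds minus the column sums, so every column sums to zero.
    """
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    q = spec.build_q(v, ligands or {}, phi_kin)
    off = q - np.diag(np.diag(q))
    if np.any(off < -1e-12):
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise ValueError(
            f"negative transition rate {spec.states[j]}->{spec.states[i]} "
            f"({off[i, j]:.3g}/ms) at V={v} mV")
    return q


def steady_state_distribution(spec: MarkovChainSpec, v: float,
                              ligands: Mapping[str, float] | None = None,
                              phi_kin: float = 1.0) -> np.ndarray:
    """Stationary occupancy: the normalised null vector of the generator."""
    q = transition_matrix(spec, v, ligands, phi_kin)
    svals = np.linalg.svd(q, compute_uv=False)
    tol = max(q.shape) * np.finfo(float).eps * svals[0]
    if np.sum(svals < tol) > 1:
        raise np.linalg.LinAlgError(
            f"{spec.name}: generator is singular beyond its nullity at V={v}")
    a = np.vstack([q, np.ones(spec.n)])
    b = np.zeros(spec.n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


# ---------------------------------------------------------------------------
# channel registry
# ---------------------------------------------------------------------------

def _bq_ical(v, ligands, phi):
    return ch.q_ical(v, ligands.get("Ca_cleft", 1e-4), phi)


def _bq_ito(v, ligands, phi):
    return ch.q_ito(v, phi)


def _bq_ikur(v, ligands, phi):
    return ch.q_ikur(v, phi)


def _bq_ikr(v, ligands, phi):
    return ch.q_ikr(v, phi)


def _make_bq_ryr(params):
    pv = params.values

    def bq(v, ligands, phi):
        return ch.q_ryr(ligands.get("Ca_cleft", 1e-4),
                        ligands.get("Ca_SR", 0.55),
                        ligands.get("open_mult", 1.0),
                        pv["koCa_RyR"], pv["kiCa_RyR"], pv["kom_RyR"],
                        pv["kim_RyR"], pv["maxSR_RyR"], pv["minSR_RyR"],
                        params.ec50_SR)
    return bq


def channel_registry(params) -> dict:
    """Name-addressable specs built from a parameter set."""
    return {
        "ICaL": MarkovChainSpec(
            "ICaL", ch.ICAL_STATES, _bq_ical, {"O": 1.0},
            g_max=params.P_CaL * params.keep("ICaL"), erev="ghk:Ca"),
        "Ito": MarkovChainSpec(
            "Ito", ch.ITO_STATES, _bq_ito, {"O": 1.0},
            g_max=params["g_to"] * params.keep("Ito"), erev="nernst:K"),
        "IKur": MarkovChainSpec(
            "IKur", ch.IKUR_STATES, _bq_ikur, {"O": 1.0},
            g_max=params["g_Kur"] * params.keep("IKur"), erev="nernst:K"),
        "IKr": MarkovChainSpec(
            "IKr", ch.IKR_STATES, _bq_ikr, {"O": 1.0},
            g_max=params["g_Kr"] * params.keep("IKr"), erev="nernst:K"),
        "RyR": MarkovChainSpec(
            "RyR", ch.RYR_STATES, _make_bq_ryr(params), {"O": 1.0},
            g_max=params["ks_RyR"], erev="fixed:0"),
    }


def rate_table(spec: MarkovChainSpec, voltages: Sequence[float],
               ligands: Mapping[str, float] | None = None,
               phi_kin: float = 1.0):
    """Off-diagonal rates per voltage, exportable for audit (CSV-friendly)."""
    rows = []
    for v in voltages:
        q = transition_matrix(spec, v, ligands, phi_kin)
        row = {"V_mV": v}
        for j, sj in enumerate(spec.states):
            for i, si in enumerate(spec.states):
                if i != j and q[i, j] != 0.0:
                    row[f"{sj}->{si}"] = q[i, j]
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# currents and fluxes carried by the Markov channels
# ---------------------------------------------------------------------------

def ghk_ca(v: float, ca_in: float, ca_out: float, temp_c: float) -> float:
    """GHK driving term for Ca2+ (per unit permeability, mM scale).

    Returns the factor multiplying P_CaL * P_open; negative = inward.
    """
    frt = f_over_rt(temp_c)
    x = 2.0 * v * frt
    if abs(x) < 1e-6:
        return ca_in - 0.341 * ca_out
    ex = math.exp(x)
    return x * (ca_in * ex - 0.341 * ca_out) / (ex - 1.0)


def ical_current(occ, v, ca_cleft, params):
    """LTCC current (pA/pF) and its unitary (per-open-channel) driving term."""
    if ca_cleft <= 0:
        raise ValueError("cleft Ca2+ must be positive")
    unit = ghk_ca(v, ca_cleft, params["Ca_o"], params.temperature)
    o = occ[ch.ICAL_OPEN]
    return params.P_CaL * params.keep("ICaL") * o * unit, unit


def _k_current(occ, open_idx, v, g, k_i, k_o, temp_c):
    from .membrane import nernst
    e_k = nernst(1, k_i, k_o, temp_c)
    return g * occ[open_idx] * (v - e_k)


def ito_current(occ, v, params, k_i=140.0):
    g = params["g_to"] * params.keep("Ito") * params.phi("to_g")
    return _k_current(occ, ch.ITO_OPEN, v, g, k_i, params["K_o"],
                      params.temperature)


def ikur_current(occ, v, params, k_i=140.0):
    g = params["g_Kur"] * params.keep("IKur") * params.phi("kur_g")
    return _k_current(occ, ch.IKUR_OPEN, v, g, k_i, params["K_o"],
                      params.temperature)


def ikr_current(occ, v, params, k_i=140.0):
    g = params["g_Kr"] * params.keep("IKr")
    return _k_current(occ, ch.IKR_OPEN, v, g, k_i, params["K_o"],
                      params.temperature)


def ryr_flux(occ, ca_sr, ca_cleft, camkii_leak, params,
             leak_enabled: bool = True):
    """SR release and leak, both SR-volume-referenced (mM/ms).

    ``camkii_leak`` is the CaMKII leak-enhancement factor (0 = basal);
    the caffeine hook acts on the opening rate inside the gating scheme.
    """
    grad = ca_sr - ca_cleft
    j_rel = params["ks_RyR"] * occ[ch.RYR_OPEN] * grad
    j_leak = 0.0
    if leak_enabled:
        j_leak = params["k_leak"] * (1.0 + camkii_leak) * grad
    return j_rel, j_leak
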