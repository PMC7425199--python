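"""Declarative experiment engine: pacing, clamps, S1S2, drug block, caffeine.

A :class:`ProtocolSpec` is a plain declarative record (JSON round-trip
safe).  Voltage-clamp families can run either on an isolated channel
(gating ODE with exogenous V and frozen ligands) or on the whole cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from . import core, markov, membrane as mb
from .parameters import ModelParameters

PROTOCOL_KINDS = ("pacing", "vclamp", "s1s2", "caffeine", "ion_clamp",
                  "free")

#: capture criterion for an evoked beat (mV/ms == V/s / 1000... stated in V/s)
CAPTURE_DVDT_V_PER_S = 10.0


@dataclass
class ProtocolSpec:
    """Declarative description of a stimulation experiment."""

    kind: str = "pacing"
    stim_amplitude: float | None = None   # pA/pF, applied inward
    stim_duration: float | None = None    # ms
    cl: float = 1000.0                    # pacing cycle length (ms)
    # voltage-step family
    holding: float = -80.0
    levels: tuple = ()
    step_duration: float = 500.0
    tail_level: float | None = None
    tail_duration: float = 500.0
    pre_duration: float = 50.0
    # S1S2
    s1_count: int = 20
    s1_cl: float = 130.0
    s2_intervals: tuple = ()
    # ion clamp
    clamp_species: str | None = None
    clamp_value: float | None = None
    pre_beats: int = 0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "vclamp" and len(tuple(self.levels)) == 0:
            raise ValueError("voltage-step family must be non-empty")
        if self.kind == "s1s2" and any(s <= 0 for s in self.s2_intervals):
            raise ValueError("S1S2 intervals must be positive")
        self.levels = tuple(self.levels)
        self.s2_intervals = tuple(self.s2_intervals)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        return cls(**json.loads(text))

    def stimulus(self, params: ModelParameters):
        amp = (self.stim_amplitude if self.stim_amplitude is not None
               else params["stim_amplitude"])
        dur = (self.stim_duration if self.stim_duration is not None
               else params["stim_duration"])
        return amp, dur


def pacing(cl: float, **kw) -> ProtocolSpec:
    return ProtocolSpec(kind="pacing", cl=cl, **kw)


def clamp_ion(species: str, value: float) -> ProtocolSpec:
    """Fix one bulk species: its derivative is forced to zero while all
    currents keep reading the clamped value."""
    if species not in ("Na_i", "K_i", "Cl_i", "Ca_i"):
        raise ValueError(f"cannot clamp species {species!r}")
    return ProtocolSpec(kind="ion_clamp", clamp_species=species,
                        clamp_value=value)


def expand_segments(protocol, params: ModelParameters, t_span: float):
    """Translate a protocol into integration segments + runtime base."""
    if protocol is None:
        protocol = ProtocolSpec(kind="free")
    runtime: dict = {}
    if protocol.kind == "free":
        return [(t_span, {})], runtime
    if protocol.kind == "caffeine":
        runtime = {"ryr_open_mult": 7.5, "serca_mult": 0.0,
                   "cab_mult": 0.0}
        return [(t_span, {})], runtime
    if protocol.kind in ("pacing", "ion_clamp"):
        if protocol.kind == "ion_clamp":
            runtime["clamp"] = (protocol.clamp_species,)
        amp, dur = protocol.stimulus(params)
        cl = protocol.cl
        segs = []
        t = 0.0
        while t < t_span - 1e-9:
            on = min(dur, t_span - t)
            segs.append((on, {"stim": -amp}))
            t += on
            if t >= t_span - 1e-9:
                break
            off = min(cl - dur, t_span - t)
            segs.append((off, {"stim": 0.0}))
            t += off
        return segs, runtime
    raise ValueError(f"protocol kind {protocol.kind!r} has no pacing "
                     "expansion; use its dedicated runner")


# ---------------------------------------------------------------------------
# drug-block registry (closed-form lookup, no interpolation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugBlock:
    """Per-current fractional block in [0, 1]."""

    block: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, frac in self.block.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"block fraction for {name} out of range")

    def apply(self, params: ModelParameters) -> ModelParameters:
        return params.with_block(self.block)


_DRUG_REGISTRY = {
    ("4-AP", "50uM"): {"Ito": 0.16, "IKur": 0.70},
    ("4-AP", "100uM"): {"Ito": 0.30, "IKur": 1.00},
    ("E-4031", "5uM"): {"IKr": 1.00},
    ("TEA", "5mM"): {"Iss": 0.55, "IKur": 0.00},
}


def _norm_dose(dose) -> str:
    return str(dose).replace(" ", "").replace("μ", "u")


def drug_to_block(drug: str, dose) -> DrugBlock:
    """Literature-derived block fractions for a registered (drug, dose).

    Unknown combinations are rejected rather than interpolated.
    """
    key = (drug, _norm_dose(dose))
    if key not in _DRUG_REGISTRY:
        supported = ", ".join(f"{d} @ {c}" for d, c in _DRUG_REGISTRY)
        raise KeyError(f"no registered block for {drug} @ {dose}; "
                       f"supported: {supported}")
    return DrugBlock(dict(_DRUG_REGISTRY[key]))


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

@dataclass
class ClampStep:
    level: float
    t: np.ndarray
    i: np.ndarray
    peak: float
    steady: float
    tail: float | None = None


_K_CHANNELS = {"Ito": markov.ito_current, "IKur": markov.ikur_current,
               "IKr": markov.ikr_current}

#: ligand values frozen during isolated-channel clamps
CLAMP_LIGANDS = {"Ca_cleft": 1e-4, "Ca_SR": 0.55, "open_mult": 1.0}
CLAMP_KI = 140.0


def _channel_current(name, spec, occ_t, v, params):
    if name == "ICaL":
        return np.array([markov.ical_current(o, v, CLAMP_LIGANDS["Ca_cleft"],
                                             params)[0] for o in occ_t.T])
    fn = _K_CHANNELS[name]
    return np.array([fn(o, v, params, k_i=CLAMP_KI) for o in occ_t.T])


def _phi_kin(name, params):
    return {"Ito": params.phi("to_kin"), "IKur": params.phi("kur_kin")}.get(
        name, 1.0)


def _integrate_channel(spec, occ0, v, dur, phi, grid=0.5):
    def f(t, occ):
        return spec.build_q(v, CLAMP_LIGANDS, phi) @ occ
    n = max(int(round(dur / grid)), 2)
    sol = solve_ivp(f, (0.0, dur), occ0, method="LSODA",
                    t_eval=np.linspace(0.0, dur, n), rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise core.IntegrationError(f"channel clamp failed at V={v}")
    return sol.t, sol.y


def run_channel_clamp(name: str, protocol: ProtocolSpec,
                      params: ModelParameters, grid: float = 0.5):
    """Voltage-clamp family on one isolated channel.

    Gating evolves under exogenous piecewise-constant voltage with frozen
    ligand concentrations; per-step peak, steady-state and (optional)
    tail currents are extracted.
    """
    if protocol.kind != "vclamp":
        raise ValueError("protocol.kind must be 'vclamp'")
    if name == "Iss":
        return _run_iss_clamp(protocol, params, grid)
    spec = markov.channel_registry(params)[name]
    phi = _phi_kin(name, params)
    hold_occ = markov.steady_state_distribution(
        spec, protocol.holding, CLAMP_LIGANDS, phi)
    steps = []
    for level in protocol.levels:
        occ0 = hold_occ.copy()
        if protocol.pre_duration > 0:
            _, occ_pre = _integrate_channel(spec, occ0, protocol.holding,
                                            protocol.pre_duration, phi, grid)
            occ0 = occ_pre[:, -1]
        t, occ_t = _integrate_channel(spec, occ0, level,
                                      protocol.step_duration, phi, grid)
        i_t = _channel_current(name, spec, occ_t, level, params)
        peak = i_t[np.argmax(np.abs(i_t))]
        tail = None
        if protocol.tail_level is not None:
            t2, occ2 = _integrate_channel(spec, occ_t[:, -1],
                                          protocol.tail_level,
                                          protocol.tail_duration, phi, grid)
            i2 = _channel_current(name, spec, occ2, protocol.tail_level,
                                  params)
            tail = i2[np.argmax(np.abs(i2))]
        steps.append(ClampStep(level=level, t=t, i=i_t, peak=float(peak),
                               steady=float(i_t[-1]),
                               tail=None if tail is None else float(tail)))
    return steps


def _run_iss_clamp(protocol, params, grid=0.5):
    """HH steady-state current under the step family (exact gate solution)."""
    phi = params.phi("ss")
    e_k = mb.nernst(1, CLAMP_KI, params["K_o"], params.temperature)
    g = params["g_ss"] * params.keep("Iss")
    x_hold, _ = mb.iss_gate(protocol.holding, phi)
    steps = []
    for level in protocol.levels:
        x_inf, tau = mb.iss_gate(level, phi)
        t = np.arange(0.0, protocol.step_duration + grid / 2, grid)
        x = x_inf + (x_hold - x_inf) * np.exp(-t / tau)
        i_t = np.array([mb.iss_current(xx, level, e_k, g, phi) for xx in x])
        peak = i_t[np.argmax(np.abs(i_t))]
        steps.append(ClampStep(level=level, t=t, i=i_t, peak=float(peak),
                               steady=float(i_t[-1])))
    return steps


def steady_state_inactivation(name: str, params: ModelParameters,
                              prepulse_levels, prepulse_ms: float = 1000.0,
                              test_level: float = 30.0,
                              test_ms: float = 100.0,
                              holding: float = -80.0):
    """Two-pulse availability curve: prepulse family, fixed test pulse.

    Returns ``(levels, availability)`` with availability normalised to
    its maximum over the family.
    """
    spec = markov.channel_registry(params)[name]
    phi = _phi_kin(name, params)
    hold = markov.steady_state_distribution(spec, holding, CLAMP_LIGANDS, phi)
    peaks = []
    for lvl in prepulse_levels:
        _, occ_pre = _integrate_channel(spec, hold.copy(), lvl,
                                        prepulse_ms, phi)
        t, occ_t = _integrate_channel(spec, occ_pre[:, -1], test_level,
                                      test_ms, phi, grid=0.2)
        i_t = _channel_current(name, spec, occ_t, test_level, params)
        peaks.append(np.abs(i_t).max())
    peaks = np.array(peaks)
    return np.asarray(prepulse_levels, float), peaks / peaks.max()


def recovery_from_inactivation(name: str, params: ModelParameters,
                               intervals, pulse_level: float = 30.0,
                               pulse_ms: float = 200.0,
                               holding: float = -80.0):
    """Two-pulse recovery: P1, variable gap at holding, P2.

    Returns ``(intervals, P2/P1 peak ratio)``; the ratio approaches 1 at
    long gaps.
    """
    spec = markov.channel_registry(params)[name]
    phi = _phi_kin(name, params)
    hold = markov.steady_state_distribution(spec, holding, CLAMP_LIGANDS, phi)
    _, occ_p1 = _integrate_channel(spec, hold.copy(), pulse_level,
                                   pulse_ms, phi, grid=0.2)
    i_p1 = _channel_current(name, spec, occ_p1, pulse_level, params)
    p1 = np.abs(i_p1).max()
    out = []
    for gap in intervals:
        _, occ_gap = _integrate_channel(spec, occ_p1[:, -1], holding,
                                        gap, phi)
        _, occ_p2 = _integrate_channel(spec, occ_gap[:, -1], pulse_level,
                                       pulse_ms, phi, grid=0.2)
        i_p2 = _channel_current(name, spec, occ_p2, pulse_level, params)
        out.append(np.abs(i_p2).max() / p1)
    return np.asarray(intervals, float), np.array(out)


def run_whole_cell_clamp(state0, protocol: ProtocolSpec,
                         params: ModelParameters, grid: float = 0.5):
    """Step family on the full model with V as an exogenous input."""
    if protocol.kind != "vclamp":
        raise ValueError("protocol.kind must be 'vclamp'")
    steps = []
    y_hold = getattr(state0, "y", state0).copy()
    for level in protocol.levels:
        y0 = y_hold.copy()
        y0[core.IV] = protocol.holding
        segs = [(max(protocol.pre_duration, 1.0), {})]
        try:
            t0, ymat0, final0, _ = core.integrate_segments(
                y0, params, segs, grid=grid,
                runtime_base={"vclamp": True})
            y1 = final0.y.copy()
            y1[core.IV] = level
            t, ymat, final, meta = core.integrate_segments(
                y1, params, [(protocol.step_duration, {})], grid=grid,
                runtime_base={"vclamp": True})
        except core.IntegrationError as err:
            raise core.IntegrationError(
                f"whole-cell clamp failed at step {level} mV: {err}")
        out = core._record_outputs(t, ymat, params,
                                   [(protocol.step_duration, {})],
                                   {"vclamp": True})
        res = core.build_result(t, ymat, out, protocol=protocol,
                                final_state=final, meta=meta)
        steps.append((level, res))
    return steps


# ---------------------------------------------------------------------------
# caffeine dump
# ---------------------------------------------------------------------------

def caffeine_transient(state0, params: ModelParameters,
                       duration: float = 10000.0,
                       grid: float = 1.0) -> core.SimulationResult:
    """Caffeine application: RyR opening rate x 7.5, SERCA and the
    background Ca2+ current fully blocked; no pacing."""
    proto = ProtocolSpec(kind="caffeine")
    return core.integrate(state0, params, proto, duration, grid=grid)


# ---------------------------------------------------------------------------
# S1S2 restitution
# ---------------------------------------------------------------------------

def s1s2_restitution(params: ModelParameters, s1_cl: float = 130.0,
                     s2_list=(), s1_count: int = 20, state0=None,
                     rtol: float = 1e-6):
    """APD_30 of a single premature (S2) beat after an S1 train.

    Returns a list of ``(interval, APD_30)``; a sub-threshold S2
    (dV/dt_max below the capture criterion) yields NaN, flagged not
    raised.
    """
    from .analysis import ap_features
    state = state0 if state0 is not None else core.default_initial_state(params)
    train = core.pace_beats(state, params, s1_cl, s1_count, record=False,
                            rtol=rtol)
    base = train.final_state
    amp, dur = params["stim_amplitude"], params["stim_duration"]
    pairs = []
    for s2 in s2_list:
        segs = [(dur, {"stim": -amp}), (s2 - dur, {"stim": 0.0}),
                (dur, {"stim": -amp}),
                (max(s2, 300.0) - dur, {"stim": 0.0})]
        t, ymat, final, meta = core.integrate_segments(
            base.y.copy(), params, segs, rtol=rtol)
        res = core.build_result(t, ymat, np.zeros((core.N_OUT, t.size)),
                                final_state=final)
        feats = ap_features(res, window=(s2, t[-1]), require_beat=False)
        dvdt_ok = (feats.dVdt_max == feats.dVdt_max
                   and feats.dVdt_max >= CAPTURE_DVDT_V_PER_S)
        pairs.append((float(s2),
                      float(feats.APD_30) if dvdt_ok else float("nan")))
    return pairs
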