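"""Feature extraction: AP metrics, Ca2+-transient metrics, I-V summaries,
Ca2+-removal partitioning and rate-dependence sweeps."""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import curve_fit

from . import core
from .parameters import ModelParameters

#: minimal amplitude (mV) for a deflection to count as an evoked beat
MIN_BEAT_AMPLITUDE = 10.0


@dataclass
class APFeatures:
    """Action-potential metrics of one beat (NaN = flagged/not found)."""

    RMP: float = math.nan          # mV, immediately before the stimulus
    OS: float = math.nan           # overshoot = max V (mV)
    APA: float = math.nan          # amplitude = OS - RMP (mV)
    dVdt_max: float = math.nan     # V/s
    APD_20: float = math.nan       # ms
    APD_30: float = math.nan
    APD_50: float = math.nan
    APD_90: float = math.nan
    apd_ratio_50_90: float = math.nan

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CaTFeatures:
    """Ca2+-transient metrics of one beat."""

    diastolic_uM: float = math.nan
    amplitude_ratio: float = math.nan   # peak / diastolic (fold)
    time_to_peak: float = math.nan      # ms from window start
    tau_decay: float = math.nan         # ms, monoexponential fit
    fractional_release: float = math.nan

    def as_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _window_slice(t, window):
    if window is None:
        return slice(None)
    lo, hi = window
    return slice(np.searchsorted(t, lo), np.searchsorted(t, hi, "right"))


def ap_features(trace, window=None, reference: str = "upstroke",
                require_beat: bool = True) -> APFeatures:
    """Extract AP metrics from a voltage trace.

    RMP is the voltage at the start of the window (immediately before
    the stimulus when the window opens at stimulus onset).  APD_x runs
    from the reference instant (time of dV/dt_max by default,
    ``reference='stimulus'`` for window start) to the linearly
    interpolated crossing of RMP + (1 - x/100) * APA on the
    repolarising limb.  A trace with no deflection above
    MIN_BEAT_AMPLITUDE returns flagged (NaN) durations.
    """
    t = np.asarray(trace.t if hasattr(trace, "t") else trace[0], float)
    v = np.asarray(trace.V if hasattr(trace, "V") else trace[1], float)
    sl = _window_slice(t, window)
    t, v = t[sl], v[sl]
    if t.size < 3:
        raise ValueError("window too short for feature extraction")
    feats = APFeatures()
    feats.RMP = float(v[0])
    ipk = int(np.argmax(v))
    feats.OS = float(v[ipk])
    feats.APA = feats.OS - feats.RMP
    dvdt = np.gradient(v, t)
    iup = int(np.argmax(dvdt))
    feats.dVdt_max = float(dvdt[iup])   # mV/ms == V/s
    if feats.APA < MIN_BEAT_AMPLITUDE:
        if require_beat:
            raise ValueError("no beat detected in the window")
        return feats
    t_ref = t[iup] if reference == "upstroke" else t[0]
    for x in (20, 30, 50, 90):
        level = feats.RMP + (1.0 - x / 100.0) * feats.APA
        crossing = math.nan
        for k in range(ipk, t.size - 1):
            if v[k] >= level >= v[k + 1]:
                frac = (v[k] - level) / (v[k] - v[k + 1])
                crossing = t[k] + frac * (t[k + 1] - t[k]) - t_ref
                break
        setattr(feats, f"APD_{x}", crossing)
    if feats.APD_90 == feats.APD_90 and feats.APD_50 == feats.APD_50:
        feats.apd_ratio_50_90 = feats.APD_50 / feats.APD_90
    return feats


def _monoexp(t, base, amp, tau):
    return base + amp * np.exp(-t / tau)


def cat_features(trace, window=None, ca_key: str = "Ca_i",
                 fractional_release: float = math.nan) -> CaTFeatures:
    """Ca2+-transient metrics; decay tau from a monoexponential
    least-squares fit between the peak and 10% above diastole."""
    if hasattr(trace, "concentrations"):
        t = np.asarray(trace.t, float)
        ca = np.asarray(trace.concentrations[ca_key], float)
    else:
        t, ca = (np.asarray(x, float) for x in trace)
    sl = _window_slice(t, window)
    t, ca = t[sl], ca[sl]
    feats = CaTFeatures(fractional_release=fractional_release)
    dia = float(ca[0])
    feats.diastolic_uM = dia * 1e3
    ipk = int(np.argmax(ca))
    peak = float(ca[ipk])
    if peak <= dia * 1.01:
        return feats
    feats.amplitude_ratio = peak / dia
    feats.time_to_peak = float(t[ipk] - t[0])
    cutoff = dia + 0.10 * (peak - dia)
    tail = np.where(ca[ipk:] <= cutoff)[0]
    iend = ipk + (int(tail[0]) + 1 if tail.size else ca.size - ipk)
    td = t[ipk:iend] - t[ipk]
    cd = ca[ipk:iend]
    if td.size < 4:
        return feats
    try:
        popt, _ = curve_fit(_monoexp, td, cd,
                            p0=(dia, peak - dia, max(td[-1] / 3, 1.0)),
                            maxfev=5000)
        if popt[2] > 0:
            feats.tau_decay = float(popt[2])
    except RuntimeError:
        pass
    return feats


def ca_removal_partition(result, window=None) -> dict:
    """Share of cytosolic Ca2+ removal by SERCA, NCX and PMCA (percent).

    Each cytosol-referenced removal flux is integrated over the decay
    phase (Ca peak to window end); percentages of their sum, so they sum
    to 100 exactly.
    """
    t = np.asarray(result.t, float)
    sl = _window_slice(t, window)
    t = t[sl]
    ca = np.asarray(result.concentrations["Ca_i"], float)[sl]
    ipk = int(np.argmax(ca))
    dec = slice(ipk, t.size)
    td = t[dec]

    def removal(name, sign):
        j = np.asarray(result.fluxes[name], float)[sl][dec] * sign
        return float(np.trapezoid(np.clip(j, 0.0, None), td))

    serca = removal("J_up", +1.0)
    ncx = removal("J_NCX", -1.0)     # recorded as influx; efflux removes
    pmca = removal("J_PMCA", -1.0)
    total = serca + ncx + pmca
    if total <= 0:
        raise ValueError("no Ca2+ removal in the selected window")
    return {"SERCA": 100.0 * serca / total, "NCX": 100.0 * ncx / total,
            "PMCA": 100.0 * pmca / total}


def iv_summary(steps, mode: str = "peak", normalize_at=None):
    """Per-step scalar extraction from a clamp family -> (V, I) table.

    ``mode``: 'peak' | 'tail' | 'steady'.  ``normalize_at`` divides by
    the value at that step voltage (rejected if absent or zero).
    """
    if not steps:
        raise ValueError("empty clamp family")
    volts = np.array([s.level for s in steps])
    pick = {"peak": lambda s: s.peak, "steady": lambda s: s.steady,
            "tail": lambda s: s.tail}[mode]
    curr = np.array([pick(s) for s in steps], dtype=float)
    if normalize_at is not None:
        match = np.where(np.isclose(volts, normalize_at))[0]
        if match.size == 0:
            raise ValueError(f"no step at {normalize_at} mV to normalise at")
        ref = curr[match[0]]
        if ref == 0 or not np.isfinite(ref):
            raise ValueError("cannot normalise at a zero/invalid current")
        curr = curr / ref
    return volts, curr


def rate_sweep(params: ModelParameters, cl_list, state0=None,
               max_beats: int = 60, tol: float = 1e-4):
    """Steady-state AP/CaT features and ion concentrations per cycle length.

    Each CL is paced to the beat-to-beat convergence criterion
    independently; non-convergence is flagged in the row.
    """
    import pandas as pd
    rows = []
    for cl in cl_list:
        st, info = core.pace_to_steady_state(params, cl, state0=state0,
                                             max_beats=max_beats, tol=tol)
        res = core.pace_beats(st, params, cl, 1)
        apf = ap_features(res, require_beat=False)
        caf = cat_features(res)
        row = {"CL_ms": cl, "converged": info["converged"],
               "beats": info["beats"],
               "Na_i_mM": res.concentrations["Na_i"][-1],
               "K_i_mM": res.concentrations["K_i"][-1],
               "Cl_i_mM": res.concentrations["Cl_i"][-1]}
        row.update({f"AP_{k}": v for k, v in apf.as_dict().items()})
        row.update({f"CaT_{k}": v for k, v in caf.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
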