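"""Intracellular Ca2+ handling: compartments, buffers, SERCA and CaMKII.

The cell volume is divided into four compartments: dyadic cleft (where
LTCC flux and RyR release meet), sub-sarcolemmal shell (SL), bulk cytosol
and SR.  Ca2+ moves between cleft -> SL -> cytosol down its gradient with
first-order diffusion, and total cell Ca2+ changes only through
sarcolemmal fluxes (LTCC, NCX, PMCA, background).

SERCA uptake uses a reversible pump with its maximal rate scaled up by a
CaMKII-dependent factor K_SERCA, a steep (exponent 12) Hill function of
the phospholamban phosphorylation fraction with midpoint 0.0167.  Because
phosphorylation builds up slowly at fast pacing, this produces the
frequency-dependent acceleration of relaxation (FDAR).

The CaMKII cascade is reduced to one active fraction driven by cleft
Ca2+ plus the slow phospholamban phosphorylation variable; the full
kinase/phosphatase network of the parent framework is represented only
through these two aggregated states.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._speed import jit as _jit

#: midpoint of the K_SERCA factor; exponent of its Hill curve
K_SERCA_MID = 0.0167
K_SERCA_HILL = 12.0
PH_PLB_FLOOR = 1e-6


@_jit
def _k_serca(ph_plb):
    if ph_plb < PH_PLB_FLOOR:
        ph_plb = PH_PLB_FLOOR
    return 1.0 / ((K_SERCA_MID / ph_plb) ** K_SERCA_HILL + 1.0)


def k_serca(ph_plb: float) -> float:
    """CaMKII enhancement factor of SERCA in [0, 1).

    ``ph_plb`` is the phospholamban phosphorylation fraction; the factor
    is 0.5 at 0.0167 and switches steeply around that midpoint.
    """
    if ph_plb < 0:
        raise ValueError("phosphorylation fraction must be >= 0")
    return float(_k_serca(ph_plb))


@_jit
def _serca_flux(ca_i, ca_sr, vmax, kmf, kmr, hill, k):
    fwd = (ca_i / kmf) ** hill
    rev = (ca_sr / kmr) ** hill
    return vmax * (1.0 + k) * (fwd - rev) / (1.0 + fwd + rev)


@dataclass(frozen=True)
class SercaParams:
    """Reversible SERCA pump constants (cytosol-referenced V_max)."""

    v_max: float
    k_mf: float
    k_mr: float
    hill: float

    def __post_init__(self):
        if min(self.v_max, self.k_mf, self.k_mr, self.hill) <= 0:
            raise ValueError("SERCA parameters must be positive")

    @classmethod
    def from_model(cls, params) -> "SercaParams":
        return cls(params.Vmax_SERCA, params.Kmf_SERCA,
                   params["Kmr_SERCA"], params["hill_SERCA"])


def serca_flux(ca_i: float, ca_sr: float, serca: SercaParams,
               k: float) -> float:
    """SR uptake flux J_up (mM/ms, cytosol-referenced).

    Strictly increasing in the CaMKII factor ``k`` at fixed
    concentrations; net uptake when cytosolic Ca2+ is elevated, bounded
    leak-back when the SR term dominates.
    """
    if ca_i <= 0 or ca_sr < 0:
        raise ValueError("concentrations must be positive")
    return float(_serca_flux(ca_i, ca_sr, serca.v_max, serca.k_mf,
                             serca.k_mr, serca.hill, k))


# ---------------------------------------------------------------------------
# buffering
# ---------------------------------------------------------------------------

@_jit
def buffer_rate(ca, bound, bmax, kon, koff):
    """d(bound)/dt of one buffer; the free-Ca2+ ODE receives the negative."""
    return kon * ca * (bmax - bound) - koff * bound


# ---------------------------------------------------------------------------
# CaMKII activation and phospholamban phosphorylation (reduced)
# ---------------------------------------------------------------------------

@_jit
def camk_act_deriv(ca_cleft, act, k_act, km, k_deact):
    """d(active fraction)/dt; steep (Hill-4) drive from cleft Ca2+.

    The fourth-order cooperativity mirrors the four Ca2+ sites of
    calmodulin and makes the mean activation a sensitive reporter of
    pacing rate through the time-averaged cleft Ca2+."""
    c4 = ca_cleft ** 4
    drive = c4 / (c4 + km ** 4)
    return k_act * drive * (1.0 - act) - k_deact * act


@_jit
def plb_deriv(act, ph, k_phos, k_base, k_deph):
    """d(Ph_PLB)/dt; slow build-up at fast pacing drives FDAR."""
    return (k_phos * act + k_base) * (1.0 - ph) - k_deph * ph


@dataclass
class CaMKIIState:
    """Aggregated signalling state: active CaMKII and PLB phosphorylation."""

    act: float = 0.003
    ph_plb: float = 0.012

    def _check(self):
        if not (0.0 <= self.act <= 1.0 and 0.0 <= self.ph_plb <= 1.0):
            raise ValueError("signalling fractions must lie in [0, 1]")


def camkii_activation(ca_cleft: float, state: CaMKIIState, dt: float,
                      params) -> CaMKIIState:
    """Advance the reduced cascade by ``dt`` ms (forward Euler).

    The whole-cell model integrates the same derivatives inside the full
    ODE system; this incremental form is for standalone signalling runs.
    """
    state._check()
    pv = params.values
    da = camk_act_deriv(ca_cleft, state.act, pv["k_act_CaMKII"],
                        pv["Km_CaMKII"], pv["k_deact_CaMKII"])
    dp = plb_deriv(state.act, state.ph_plb, pv["k_phos_PLB"],
                   pv["k_base_PLB"], pv["k_deph_PLB"])
    new = CaMKIIState(act=min(max(state.act + da * dt, 0.0), 1.0),
                      ph_plb=min(max(state.ph_plb + dp * dt, 0.0), 1.0))
    return new


# ---------------------------------------------------------------------------
# compartmental Ca2+ balance
# ---------------------------------------------------------------------------

@_jit
def ca_comp_derivs(ca_i, ca_sl, ca_cleft, ca_sr,
                   j_up, j_rel_sr, j_leak_sr,
                   j_cal_cleft, j_sl_membrane,
                   tau_c_sl, tau_sl_cy,
                   v_cyto, v_sl, v_cleft, v_sr):
    """Free-Ca2+ derivatives of the four compartments (buffers excluded).

    Flux arguments are referenced to the compartment they enter:
    ``j_up`` cytosolic, ``j_rel_sr``/``j_leak_sr`` SR, ``j_cal_cleft``
    cleft (LTCC influx, positive inward), ``j_sl_membrane`` the net
    sarcolemmal transporter flux (NCX + PMCA + background combined)
    entering the sub-sarcolemmal shell, which also provides the local
    Ca2+ read-out for the Ca2+-activated sarcolemmal currents.
    """
    j_c_sl = (ca_cleft - ca_sl) / tau_c_sl          # cleft-referenced
    j_sl_cy = (ca_sl - ca_i) / tau_sl_cy            # SL-referenced
    d_cleft = j_cal_cleft + j_rel_sr * (v_sr / v_cleft) - j_c_sl
    d_sl = j_sl_membrane + j_c_sl * (v_cleft / v_sl) - j_sl_cy
    # the passive leak drains the non-junctional SR into the bulk cytosol
    d_cyto = j_sl_cy * (v_sl / v_cyto) + j_leak_sr * (v_sr / v_cyto) - j_up
    d_sr = j_up * (v_cyto / v_sr) - j_rel_sr - j_leak_sr
    return d_cyto, d_sl, d_cleft, d_sr


def compartment_fluxes(concentrations: dict, fluxes: dict, params) -> dict:
    """Mass-conserving Ca2+ balance (spec-level convenience wrapper).

    ``concentrations``: Ca_i, Ca_SL, Ca_cleft, Ca_SR (mM).
    ``fluxes``: J_up (cytosol-ref), J_rel/J_leak (SR-ref), J_CaL (cleft-ref
    influx), J_SL (net SL membrane influx).  Returns d[Ca]/dt per
    compartment, buffering excluded.
    """
    vols = params.volumes()
    d_cyto, d_sl, d_cleft, d_sr = ca_comp_derivs(
        concentrations["Ca_i"], concentrations["Ca_SL"],
        concentrations["Ca_cleft"], concentrations["Ca_SR"],
        fluxes.get("J_up", 0.0), fluxes.get("J_rel", 0.0),
        fluxes.get("J_leak", 0.0), fluxes.get("J_CaL", 0.0),
        fluxes.get("J_SL", 0.0),
        params["tau_cleft_SL"], params["tau_SL_cyto"],
        vols["cyto"], vols["SL"], vols["cleft"], vols["SR"])
    return {"Ca_i": d_cyto, "Ca_SL": d_sl, "Ca_cleft": d_cleft,
            "Ca_SR": d_sr}
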