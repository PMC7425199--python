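"""Physical constants and unit conventions.

Conventions used throughout the package:

* voltage in mV, time in ms, currents in pA/pF (membrane capacitance
  normalised), concentrations in mM, fluxes in mM/ms referenced to the
  stated compartment volume.
* outward membrane current is positive; an inward stimulus is negative.
"""

import math

R_GAS = 8.314462  # J mol^-1 K^-1
FARADAY = 96485.33  # C mol^-1

CELSIUS_OFFSET = 273.15

#: default simulation temperature (deg C); model rates are native to 37 C
T_BODY_C = 37.0


def rt_over_f(temp_c: float) -> float:
    """RT/F in mV at a temperature in deg C."""
    return R_GAS * (temp_c + CELSIUS_OFFSET) / FARADAY * 1000.0


def f_over_rt(temp_c: float) -> float:
    """F/RT in 1/mV at a temperature in deg C."""
    return 1.0 / rt_over_f(temp_c)


def q10_factor(q10: float, t_sim_c: float, t_ref_c: float) -> float:
    """Fold change of a rate or conductance between two temperatures."""
    if q10 <= 0:
        raise ValueError("Q10 factor must be positive")
    return q10 ** ((t_sim_c - t_ref_c) / 10.0)


def safe_exp(x: float) -> float:
    """exp with clipping; transition-rate args can overflow transiently."""
    if x > 300.0:
        x = 300.0
    elif x < -300.0:
        x = -300.0
    return math.exp(x)
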