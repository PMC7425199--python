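"""Left/right atrial variants.

The left-atrial cell differs from the right-atrial baseline only in two
conductances: I_Kur is 110% larger and I_K1 70% larger; all kinetics and
every other parameter are shared.  (Measured left/right ratios also
exist for I_CaL, I_to and I_Kr but are close to unity and are not
applied; see the commented optional multipliers below.)
"""

from __future__ import annotations

from .parameters import ModelParameters, VARIANTS

# Optional additional left-atrial multipliers (measured ratios near 1),
# intentionally not applied by default:
# _LA_OPTIONAL = {"P_CaL_parent": 0.95, "g_to": 1.05, "g_Kr": 1.10}


def make_variant(base: ModelParameters, name: str) -> ModelParameters:
    """Derive a named variant from the right-atrial baseline."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; expected one of "
                         f"{VARIANTS}")
    if base.variant != "RA":
        raise ValueError("variants are derived from the RA baseline")
    if name == "RA":
        return base.copy()
    p = base.copy()
    p.values["g_Kur"] = base.values["g_Kur"] * base.values["la_scale_Kur"]
    p.values["g_K1"] = base.values["g_K1"] * base.values["la_scale_K1"]
    p.variant = "LA"
    return p
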