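"""Model parameters: loading, provenance, variants and channel block.

All numeric constants of the cell model live in ``data/parameters.json``,
one entry per constant with value, units, a provenance tag
(``paper`` | ``parent-model`` | ``fitted-here``) and a short note, so that
recalibration is a config edit rather than a code change.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

from .constants import T_BODY_C, q10_factor

#: currents that accept a fractional block multiplier
BLOCKABLE = ("INa", "INaL", "ICaL", "Ito", "IKur", "IKr", "Iss", "IK1",
             "IKb", "IKACh", "IKCa", "IClCa", "INaK", "INCX", "IPMCA",
             "ICab", "INab", "IClb")

VARIANTS = ("RA", "LA")


def _load_raw() -> dict:
    with resources.files("mouseatria.data").joinpath("parameters.json").open() as fh:
        return json.load(fh)


@dataclass
class ModelParameters:
    """Parameter set for one simulation.

    Attributes
    ----------
    values : dict
        name -> float, the flat numeric table (annotated source in
        ``data/parameters.json``).
    variant : str
        "RA" (baseline) or "LA" (I_Kur x2.10, I_K1 x1.70).
    block : dict
        current name -> fractional block in [0, 1].
    ach : float
        acetylcholine concentration (uM); 0 closes I_KACh.
    pka : float
        static PKA phosphorylation fraction applied to its ECC targets
        (reduced stand-in for the receptor cascade), in [0, 1].
    """

    values: dict = field(default_factory=dict)
    variant: str = "RA"
    block: dict = field(default_factory=dict)
    ach: float = 0.0
    pka: float = 0.0
    meta: dict = field(default_factory=dict, repr=False)

    @classmethod
    def default(cls, variant: str = "RA") -> "ModelParameters":
        raw = _load_raw()
        values = {k: float(v["value"]) for k, v in raw.items()}
        meta = {k: {kk: vv for kk, vv in v.items() if kk != "value"}
                for k, v in raw.items()}
        p = cls(values=values, meta=meta)
        if variant != "RA":
            from .variants import make_variant
            p = make_variant(p, variant)
        p._validate()
        return p

    def _validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name, frac in self.block.items():
            if name not in BLOCKABLE:
                raise ValueError(f"unknown blockable current {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"block fraction for {name} outside [0, 1]")
        for key in ("frac_cyto", "frac_SL", "frac_cleft", "frac_SR"):
            if self.values[key] <= 0:
                raise ValueError(f"{key} must be positive")

    # -- convenience accessors -------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def with_block(self, block: dict) -> "ModelParameters":
        p = self.copy()
        p.block = dict(self.block)
        p.block.update(block)
        p._validate()
        return p

    def keep(self, frac_of: str) -> float:
        """1 - block for a current name (the conductance multiplier)."""
        return 1.0 - self.block.get(frac_of, 0.0)

    @property
    def temperature(self) -> float:
        return self.values["temperature"]

    # -- derived effective quantities ------------------------------------
    @property
    def g_NaL(self) -> float:
        return self.values["g_NaL_parent"] * self.values["scale_NaL"]

    @property
    def P_CaL(self) -> float:
        return self.values["P_CaL_parent"] * self.values["scale_CaL"]

    @property
    def I_NaK_max(self) -> float:
        return self.values["I_NaK_max_parent"] * self.values["scale_NaK"]

    @property
    def Vmax_SERCA(self) -> float:
        return self.values["Vmax_SERCA_parent"] * self.values["scale_SERCA"]

    @property
    def Kmf_SERCA(self) -> float:
        return self.values["Kmf_parent"] * self.values["scale_Kmf"]

    @property
    def ec50_SR(self) -> float:
        return self.values["ec50SR_parent"] * self.values["scale_ec50SR"]

    def phi(self, which: str) -> float:
        """Q10 temperature factor for a named coefficient set.

        Rates are native to 37 C; the factor is 1 at the default
        temperature (temperature neutrality).
        """
        t = self.temperature
        q10 = {
            "to_kin": self.values["q10_to_kin"],
            "to_g": self.values["q10_to_g"],
            "kur_kin": self.values["q10_kur_kin"],
            "kur_g": self.values["q10_kur_g"],
            "ss": self.values["q10_ss"],
        }[which]
        return q10_factor(q10, t, T_BODY_C)

    def volumes(self) -> dict:
        v = self.values["vol_cell"]
        return {
            "cyto": v * self.values["frac_cyto"],
            "SL": v * self.values["frac_SL"],
            "cleft": v * self.values["frac_cleft"],
            "SR": v * self.values["frac_SR"],
        }

    def digest(self) -> str:
        """Hash of the numeric table + variant + block, for trace metadata."""
        payload = json.dumps(
            {"values": self.values, "variant": self.variant,
             "block": self.block, "ach": self.ach, "pka": self.pka},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
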