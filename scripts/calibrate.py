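#!/usr/bin/env python
"""Recalibrate channel conductances against the target peak densities.

The Markov rate structures carry the published structural modifications
(the -4.4 mV L-type shift, the 1/8 ultra-rapid ladder rates); the free
conductance/permeability scales are then set so the standard clamp
protocols reproduce the target peak current densities.  Peak density is
linear in the conductance, so one clamp run per channel suffices; the
result is written back into the annotated parameter file.

Usage:  python scripts/calibrate.py [--dry-run]
"""

from __future__ import annotations

import argparse
import json
from importlib import resources

import numpy as np

from mouseatria import ModelParameters
from mouseatria.analysis import iv_summary
from mouseatria.protocols import ProtocolSpec, run_channel_clamp

#: (parameter key, channel, clamp protocol, extraction, target pA/pF)
TARGETS = [
    ("P_CaL_parent", "ICaL",
     dict(holding=-90.0, levels=tuple(range(-40, 41, 10)),
          step_duration=250.0),
     "abs_max", 4.76),
    ("g_to", "Ito",
     dict(holding=-75.0, levels=tuple(range(-70, 51, 10)),
          step_duration=500.0),
     "at_plus30", 11.6),
    ("g_Kur", "IKur",
     dict(holding=-80.0, levels=tuple(range(-70, 51, 10)),
          step_duration=500.0),
     "at_plus30", 5.1),
]


def measure(name, proto_kw, extraction, params):
    steps = run_channel_clamp(name, ProtocolSpec(kind="vclamp",
                                                 **proto_kw), params)
    volts, peaks = iv_summary(steps, "peak")
    if extraction == "abs_max":
        return float(np.abs(peaks).max())
    return float(peaks[list(volts).index(30)])


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dry-run", action="store_true")
    args = ap.parse_args()

    params = ModelParameters.default()
    path = resources.files("mouseatria.data").joinpath("parameters.json")
    with path.open() as fh:
        table = json.load(fh)

    for key, channel, proto_kw, extraction, target in TARGETS:
        measured = measure(channel, proto_kw, extraction, params)
        factor = target / measured
        new = table[key]["value"] * factor
        print(f"{channel}: measured {measured:.4f} pA/pF, target {target}"
              f" -> {key} x {factor:.5f} = {new:.6g}")
        table[key]["value"] = new
        params.values[key] = new

    if not args.dry_run:
        with open(str(path), "w") as fh:
            json.dump(table, fh, indent=1)
            fh.write("\n")
        print("parameter file updated")


if __name__ == "__main__":
    main()
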