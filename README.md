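# mouseatria

Electrophysiology of the mouse atrial myocyte: a deterministic ODE model
of the action potential and intracellular Ca²⁺ handling, with a protocol
engine for the standard cellular experiments.

The mouse atrium is a workhorse preparation for studying atrial
arrhythmia mechanisms, but its action potential is very unlike the
human one — a ~25 ms spike repolarised by a battery of K⁺ currents
(I_to, I_Kur, I_Kr, I_ss, I_K1).  The package models the membrane as

    C_m dV/dt = −(Σ I_ion + I_stim)

with Markov-chain gating for the L-type Ca²⁺ channel (7 states), I_to
(7), I_Kur (6), I_Kr (5) and the ryanodine receptor (4), Hodgkin–Huxley
or algebraic forms for the remaining currents and transporters
(I_Na, I_NaL, I_ss, I_K1, I_Kb, I_KACh, I_KCa, I_ClCa, backgrounds,
NKA, NCX, PMCA), and four-compartment Ca²⁺ handling (dyadic cleft,
sub-sarcolemmal shell, cytosol, SR) with dynamic buffers, a reversible
SERCA pump whose maximal rate is boosted by CaMKII-dependent
phospholamban phosphorylation (K_SERCA = 1/((0.0167/Ph_PLB)¹² + 1)),
and luminally gated SR release.  Left- and right-atrial variants differ
in two conductances (LA: I_Kur × 2.10, I_K1 × 1.70).  The model is
fully deterministic — identical inputs reproduce identical traces.

It is intended for cellular electrophysiologists and modellers who want
to run in-silico clamp/pacing/block experiments, and as a cell kernel
for tissue-level studies.

## Worked example

```python
import mouseatria as ma
from mouseatria import core

params = ma.ModelParameters.default()            # right-atrial baseline
state, info = core.pace_to_steady_state(params, cl=500.0)   # 2 Hz
beat = core.pace_beats(state, params, 500.0, 1)
feats = ma.ap_features(beat, require_beat=False)
print(f"converged={info['converged']} after {info['beats']} beats")
print(f"RMP={feats.RMP:.1f} mV  OS={feats.OS:.1f} mV  "
      f"dV/dt_max={feats.dVdt_max:.0f} V/s")
print(f"APD20={feats.APD_20:.1f}  APD50={feats.APD_50:.1f}  "
      f"APD90={feats.APD_90:.1f} ms")
```

prints

```
converged=True after 59 beats
RMP=-85.1 mV  OS=32.5 mV  dV/dt_max=230 V/s
APD20=2.7  APD50=9.5  APD90=26.2 ms
```

i.e. a steady 2-Hz right-atrial beat resting near −86 mV with a ~230 V/s
upstroke and 90%-repolarisation duration of ~25 ms.  The same objects
drive channel-level voltage clamps, S1S2 restitution, drug block
(4-AP / E-4031 / TEA registry), caffeine dumps and ion-clamp
experiments; see `mouseatria.protocols`.

A command line wraps the library:

```
mouseatria pace --variant RA --cl 1000 --beats 50 --out beat.csv
mouseatria vclamp --channel Ito
mouseatria block --drug 4-AP --dose 100uM --cl 1000
mouseatria s1s2 --s1-cl 130
```

Traces are written as CSV (`t_ms,V_mV,<current>_pA_per_pF,...`) with a
JSON sidecar holding the protocol and a parameter-provenance digest.

All numeric constants live in `src/mouseatria/data/parameters.json`,
annotated with units and provenance; `scripts/calibrate.py` rederives
the conductance scales from the clamp-protocol peak-density targets.
The science and the numerical choices are documented in
`docs/methods.md`.

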