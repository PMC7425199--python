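# Methods

`mouseatria` simulates the electrical activity and Ca²⁺ handling of a
single mouse atrial myocyte.  The membrane potential obeys

    C_m dV/dt = −(Σ I_ion + I_stim),

with currents expressed per unit capacitance (pA/pF), so C_m enters only
when currents are converted to ion fluxes.  The dynamical state has 53
variables: V, six Hodgkin–Huxley gates, five Markov occupancy vectors
(L-type Ca²⁺ channel, I_to, I_Kur, I_Kr, RyR), bulk Na⁺/K⁺/Cl⁻, free
Ca²⁺ in four compartments, eight Ca²⁺ buffers, and a reduced
CaMKII/phospholamban pair.

## Markov-chain channels

Occupancies evolve as `d occ/dt = Q(V, ligands) · occ` with Q a column
generator matrix (columns sum to zero), so probability is conserved by
construction; all N states are integrated and any drift beyond 1e−9 is
renormalised at beat boundaries.  The schemes and their structural
modifications:

* **L-type Ca²⁺ channel (7 states).**  C2↔C1 carries the steep voltage
  dependence and is evaluated at V + 4.4 mV (the leftward shift of the
  steady-state activation between those states); C1↔O is voltage
  independent.  Open channels inactivate by voltage (O→IV1→IV2) or by
  cleft Ca²⁺ (O→ICa→ICaV); inactivated channels recover into the
  deactivated closed state C2, never through O, which keeps the late
  (recovery-phase) window current physiologically small.  The current
  uses a Goldman–Hodgkin–Katz driving term on cleft Ca²⁺ and the
  permeability is the reconstructed ventricular value × 1/4.
* **I_to (7 states).**  A 3-step activation ladder (C3→C2→C1→O) with
  fast/slow open-state inactivation (If, Is) and one closed-inactivated
  state; recovery rates switch on below about −55 mV, giving recovery
  time constants of tens of milliseconds at the holding potentials used
  experimentally.
* **I_Kur (6 states).**  A Kv1.5-style ladder C1…C4→O with very slow
  inactivation; the ladder rates α, β are the reconstructed parent
  values divided by 8, which slows activation into the range seen in
  atrial recordings.
* **I_Kr (5 states).**  hERG-like: slow activation chain, fast
  inactivation with inverted voltage dependence (O↔I), fitted directly
  at 37 °C (no temperature rescaling).  The activation chain is fast
  enough to load appreciably during the brief murine action potential,
  which is what gives the channel its late-repolarisation leverage.
* **RyR (4 states, R/O/I/RI).**  Opening ∝ [Ca]_cleft² with a luminal
  sensitivity factor (EC50 on SR Ca²⁺ = parent value × 0.9): as the SR
  depletes during release the opening rate falls and inactivation
  rises, which terminates release.  Caffeine acts as a ×7.5 multiplier
  on the opening rate.

Rate-shape coefficients are frozen in `channels.py`; conductances,
permeabilities and all Ca²⁺-handling constants live in the annotated
parameter file `data/parameters.json` (value, units, provenance tag
`paper` / `parent-model` / `fitted-here`).  `scripts/calibrate.py`
re-derives the conductance scales from the clamp-protocol targets (peak
density is linear in conductance, so a single run per channel suffices).

## Temperature

Model rates are native to 37 °C.  Q10 factors (kinetics 1.8 and
conductance 1.1 for I_to; 1.9 and 1.37 for I_Kur; 2.4 for both the time
constant and conductance of I_ss) are exposed through a
`TemperatureScaling` utility and applied as `q10^((T−37)/10)`, so at the
default temperature every factor is exactly 1.

## I_ss and the background K⁺ current

I_ss is a single slow activation gate (no inactivation) with conductance
0.049 nS/pF.  A mild outward-rectification saturation factor makes the
fully activated I–V plateau near +30…+40 mV; without it a purely ohmic
form could not make ~3.3 pA/pF the *peak* of a protocol that reaches
+60 mV.  I_Kb is an instantaneous Boltzmann conductance centred at
−55 mV with a 2% conductance floor: the floor keeps the I–V monotone
below E_K, and the positive activation midpoint keeps the current out of
the sub-threshold voltage range so the excitation threshold stays below
80% of the standard stimulus (10 pA/pF × 4 ms, applied inward and booked
as a K⁺ influx so the potassium budget closes).

## Ca²⁺ handling

Four compartments: dyadic cleft (0.05% of cell volume), sub-sarcolemmal
shell (2%), bulk cytosol (70%) and SR (1.56%, making the SR↔cytosol
flux conversion ≈ 44.9×).  LTCC flux enters the cleft; RyR release
enters the cleft; the passive SR leak drains into the bulk cytosol
(non-junctional SR); NCX, PMCA and the Ca²⁺ background sense and feed
the sub-sarcolemmal shell; diffusion couples cleft→SL (τ = 0.05 ms,
cleft-referenced) and SL→cytosol (τ = 0.5 ms).  Buffers (troponin C,
calmodulin, SR-membrane sites, low/high-affinity sarcolemmal sites,
calsequestrin) are dynamic ODEs referenced to their own compartment
volumes.  With every sarcolemmal Ca²⁺ pathway blocked, total cell Ca²⁺
is conserved to solver tolerance (tested).

SERCA is a reversible Hill pump; its maximal rate is the reconstructed
parent value × 0.5 and the forward affinity K_mf is the parent value
× 1.13.  CaMKII enhances uptake through

    K_SERCA = 1 / ((0.0167 / Ph_PLB)^12 + 1),      V_max,eff = V_max (1 + K_SERCA)

where Ph_PLB is the phospholamban phosphorylation *fraction* (the
midpoint constant 0.0167 only makes sense on the fractional scale, so
that interpretation is used throughout).  An important structural
property of the reversible pump: at diastole it equilibrates, pinning
[Ca]_SR ≈ K_mr · [Ca]_i,dia / K_mf.  Diastolic Ca²⁺ and SR load are
therefore one degree of freedom, set jointly by total cell Ca²⁺; K_mr
(a reconstructed constant) places the pair so that diastolic [Ca]_i is
0.11 µM at the SR load the cell actually sustains.

## CaMKII / phosphorylation (reduced)

The full kinase cascade is represented by two aggregated states: an
active CaMKII fraction driven by cleft Ca²⁺ through a steep Hill-4
function (mirroring calmodulin's four Ca²⁺ sites; the time-averaged
cleft Ca²⁺ roughly doubles from 0.5- to 4-Hz pacing, so the steepness
converts that into a severalfold activation contrast), and a slow
Ph_PLB variable (phosphatase time constant ≈ 30 s).  Retained CaMKII
targets: SERCA via K_SERCA, LTCC facilitation (permeability × (1+act)),
and RyR sensitisation (opening rate and leak × (1+act)).  β-adrenergic
signalling is a static PKA fraction applied to the LTCC, the Na⁺/K⁺
pump affinity and Ph_PLB; it defaults to 0.

## Numerics

LSODA with rtol 1e−6 and per-state absolute tolerances (1e−10 mM for
cytosolic/cleft Ca²⁺, 1e−8 for SR Ca²⁺, 1e−6 elsewhere); every protocol
discontinuity (stimulus edge, clamp step) restarts the integration.
Output is sampled on a uniform 0.1-ms grid by default; halving either
the tolerances or the grid changes APD₉₀ by well under 0.1 ms (tested).
The right-hand side is compiled with numba when available; the Python
path is identical and is exercised automatically when numba is absent.
On-disk JIT caching is disabled deliberately (numba does not invalidate
a caller's cache when an inlined callee changes).

Steady pacing uses two devices: `pace_to_steady_state` (beat-to-beat
convergence of APD₉₀, diastolic Ca²⁺, Na⁺ and K⁺ below a relative 1e−4,
the package's operational definition of steady state) and
`refine_periodic_state`, a guarded componentwise Aitken extrapolation of
the one-beat return map that converges to the periodic orbit in a few
rounds; candidates that do not reduce the beat-to-beat residual are
rejected in favour of plain relaxation.  On the periodic orbit the net
transmembrane flux of each ion species over a cycle, measured exactly
from the conserved-state change, is below 0.1% of the gross flux.
Warm-start snapshots (paced-in 1-Hz end-diastolic states for both
variants) ship as JSON package data.

## Feature conventions

APD_x runs from the instant of dV/dt_max (configurable to stimulus
onset) to the linearly interpolated crossing of RMP + (1 − x/100)·APA on
the repolarising limb, with RMP and APA taken per beat so
rate-dependent RMP elevation is handled.  CaT decay τ is a
monoexponential least-squares fit from the peak to 10% above diastole.
The Ca²⁺-removal partition integrates each cytosol-referenced removal
flux over the decay phase and normalises to their sum.

## Problem sizes used in the shipped checks

Channel-level clamp families integrate 9–15 steps of 250–1000 ms.
Whole-cell quantities use the periodic-orbit refiner (equivalent to
roughly 40–130 beats per condition) starting from the shipped 1-Hz
snapshot; the stability check runs 30 s at an 80-ms cycle length; the
rate-dependence checks pace 25–160 beats per cycle length.

## Known limitations

* The Ca²⁺ transient degrades more steeply with pacing frequency than
  in the reference data: at 4 Hz the RyR pool is largely refractory and
  the transient is too small for a meaningful decay-constant fit, so
  the frequency-dependent acceleration of relaxation can only be
  demonstrated through its mechanism (higher Ph_PLB and K_SERCA at fast
  rates) rather than as a fitted τ ordering between 0.5 and 4 Hz.
* Fractional SR release during a twitch (~6%) is below experimental
  estimates; the store (calsequestrin-buffered) is large relative to
  the per-beat release in this parameterisation.
* The cell is spatially clamped: no Ca²⁺ sparks or waves, no
  caveolar/junctional SR subdivision, no tissue coupling.
* Supplementary parameter tables of the reference models were not
  available; every such constant was reconstructed in the parent
  models' functional forms and calibrated to the printed protocol
  outputs, with provenance recorded per constant in the parameter file.
  Quantities not printed anywhere (e.g. I_Kb density) are constrained
  only indirectly.
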