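# cardioem

Desk-scale simulator of failing-heart electromechanics under left
ventricular assist device (LVAD) support.

Heart failure with systolic dysfunction prolongs the electromechanical
delay (EMD) — the interval between local electrical depolarization and
the onset of myofiber shortening — and an LVAD, by mechanically
unloading the ventricle, is expected to shorten it. `cardioem` lets a
computational physiologist quantify that chain at the single-cell and
lumped-circulation level:

1. **ionic** — a human ventricular myocyte ODE model (ten Tusscher
   family, 2004 and 2006 formulations, epicardial default) paced at a
   basic cycle length of 600 ms produces the transmembrane potential and
   the intracellular Ca²⁺ transient.
2. **ca_scaling** — HF severity is graded phenomenologically by scaling
   the Ca²⁺-transient magnitude about its diastolic baseline:
   HF1..HF4 ↔ 1.0, 0.9, 0.8, 0.7.
3. **myofilament** — a cooperative cross-bridge model (Ca²⁺–troponin
   binding, tropomyosin switching with Hill coefficient 15, pre/post
   power-stroke cycling with mean-strain dynamics, filament-overlap
   force–length) converts the transient into active tension T(t),
   sarcomere shortening and contractile ATP consumption
   A(t) = g_xb·XB_postR·SOVF_thick under isometric ("infinite load") or
   afterloaded-isotonic (30 / 50 kPa) conditions.
4. **metrics / experiments** — EAT (first upward 0-mV crossing),
   MAT (10% of maximal shortening), EMD = MAT − EAT, and the
   severity × load experiment grid.
5. **circulation_lvad** — an eight-compartment closed loop whose
   ventricles are driven by the twitch tension,
   P(V,t) = k_act·T(t)·(V − V₀)₊ + 5·B·(e^{a(V−V₀)} − 1),
   with diode valves and a constant-flow LVAD (50 mL/s = 3 L/min)
   shunting LV → aorta; it yields EDV/ESV/SV/EF, stroke work ∮P dV,
   full-assist detection and per-scenario EMD/ATP.

## Worked example

```python
from cardioem import (baseline_transient, scale_transient, HFSeverity,
                      LoadCondition, run_twitch)

ca = baseline_transient()                 # 20 paced beats, steady state
hf4 = scale_transient(ca, HFSeverity("HF4"))
rec = run_twitch(hf4, LoadCondition.isotonic(30.0))   # 20 cycles
print(round(rec.shortening_amplitude_pct, 2), round(rec.peak_tension_kpa, 1))
```

prints `5.4 30.0`: the severely failing cell shortens by 5.4% of its
rest length against a 30 kPa afterload, its borne tension pinned at the
afterload throughout the shortening phase. The full grid, from the command line:

```
cardioem cellgrid
```

```
Peak times (ms), isotonic load 30 kPa:
          ca_isometric_ms  ca_isotonic_ms  tension_isometric_ms  tension_isotonic_ms length_isometric_ms  length_isotonic_ms  atp_isometric_ms  atp_isotonic_ms
severity
HF1                    27              27                    91                   33                None                 131                91              185
HF2                    27              27                    93                   33                None                 132                93              187
HF3                    27              27                    96                   34                None                 134                96              189
HF4                    27              27                   100                  46                None                 136               100              193
```

Reading the table: the Ca²⁺ time-to-peak is identical in every row
(scaling preserves timing), while the isometric tension and ATP peaks
and the isotonic shortening peak all arrive progressively later as
severity grows — the weaker transient activates the thin filament more
slowly. Isotonic shortening amplitudes at this load are 15.28 / 12.48 /
9.27 / 5.40% of rest length (HF1→HF4), i.e. reductions of 18.3 / 39.3 /
64.7% relative to HF1, and the cell-level EMD lengthens from 28.2 ms
(HF1) to 49.3 ms (HF4).

The eight-condition hemodynamic sweep (HF1..HF4 × control/LVAD, 42 s
each):

```
cardioem sweep --plots
```

reproduces, as orderings: ejection fraction falling with severity in the
control group; PV loops shifting right with severity and back left under
LVAD; full assist (aortic valve shut all cycle) in HF3/HF4 but only
partial assist in HF1/HF2 at 3 L/min; and stroke work, contractile ATP
and EMD all reduced by the LVAD at every severity, with the largest
relative reductions in the most severe failure.

## Scope

Single material point + lumped circulation only: tissue-level electrical
propagation, finite-element ventricular mechanics and spatial EMD maps
are out of scope, and chamber-level outputs are reduced-order orderings
rather than image-based-model values. See `docs/methods.md` for the model
equations' provenance, every tunable constant with units and defaults,
and known limitations.
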