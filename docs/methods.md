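# Methods

`cardioem` simulates the excitation–contraction–circulation chain of a
failing human ventricle at desk scale: a ventricular myocyte ionic ODE
model supplies the Ca²⁺ transient; scaling its magnitude grades heart
failure (HF) severity; a cross-bridge myofilament model converts Ca²⁺ to
tension, shortening and contractile ATP consumption under controlled
mechanical load; and a lumped closed-loop circulation with tension-driven
chambers and a constant-flow left-ventricular assist device (LVAD)
produces hemodynamics and electromechanical delay (EMD). The cell-level
models are reimplementations of published formulations; the chamber
coupling is an explicit reduced-order surrogate for a finite-element
ventricle, so chamber-level claims are qualitative orderings, not
node-resolved values.

## Ionic model

Two generations of the ten Tusscher-family human ventricular model are
implemented behind a `variant` string: the 2004 formulation (17 states;
SR release with a Ca-dependent inactivation gate) and the revised 2006
formulation (19 states; dyadic subspace, four-state RyR adaptation).
Epicardial parameters are the default (`tt2006-epi`); endo/M parameter
sets of the 2006 model are included. Both variants reproduce their
published action-potential characteristics at BCL 600 ms (APD₉₀ ≈ 297 ms
and Cai amplitude ≈ 1.2 µM for 2006-epi; ≈ 267 ms and ≈ 1.0 µM for
2004-epi).

Pacing uses a rectangular 1-ms stimulus. The default amplitude is the
standard −52 pA/pF; `default_stim_amplitude` instead returns twice the
diastolic threshold found once by bisection. Integration is LSODA with a
0.1-ms step cap during the stimulus and per-state absolute tolerances;
output is sampled at 1 ms, matching the integer-millisecond convention of
the timing tables. Initial states are the published steady-paced values
(2006) or the published values relaxed for 20 s without stimulation and
frozen (2004), so the resting state is a fixed point to solver tolerance.

The steady-state criterion is a beat-to-beat change in peak Cai below 1%
at 20 beats. The Ca²⁺ transient of the final beat, aligned to its
stimulus, is the one-way coupling signal; electrical activation time
(EAT) is the first upward 0-mV crossing, linearly interpolated.

A caveat that matters for comparisons with reported timing tables: the
ten Tusscher transients peak ~27 ms (2006) or ~11 ms (2004) after the
stimulus, whereas the myofilament model's own published biexponential
input transient (τ₁ = 20 ms, τ₂ = 110 ms, exposed here as
`approximate_ca_transient`) peaks at 41.6 ms. Studies that tabulate a
41-ms Ca²⁺ time-to-peak used the latter waveform; this package keeps the
ionic-model transient as the default driver and provides the
biexponential as a configuration alternative.

## HF severity scaling

Severity is phenomenological: the transient is scaled by 1.0 / 0.9 /
0.8 / 0.7 (HF1..HF4) about the diastolic baseline, preserving resting
Ca²⁺, timing and period exactly; absolute scaling is available via
`scale_mode`. No mechanistic SERCA/RyR remodelling is attempted.

## Myofilament model

The cross-bridge model follows the approximate cooperative-activation
formulation of cardiac myofilament dynamics: Ca²⁺ binds low/high-affinity
troponin states; permissiveness is a steep Hill-type function (nperm =
15, perm50 = 0.5) of the overlap-weighted bound-troponin fraction; the
attached cycle is permissive → pre-power-stroke → post-power-stroke with
strain-dependent rates; mean distortions xXBprer/xXBpostr carry
force–velocity behaviour; and single-overlap fractions of thick/thin
filaments carry force–length behaviour. Normalized active force is
SOVF_thick · (XBpostr·xXBpostr + XBprer·xXBprer)/(x₀·XBpostr_ss).

Configuration constants the source publication of the study leaves
unstated, chosen once and frozen:

- temperature 37 °C (in-vivo human; the published Q10s are applied
  relative to 37 °C, so base rates are used unchanged);
- species cross-bridge rate modifier 0.2 (the large-mammal setting of
  the published model; the rodent setting of 1.0 gives unphysiologically
  fast human twitches);
- rest sarcomere length 2.2 µm (typical loaded end-diastolic length);
- tension calibration 100 kPa per unit normalized force — the single
  constant mapping model force to kPa. It puts peak isometric HF1
  tension at ≈ 87 kPa, in the range typical of human myocardium models,
  and places the HF4 cell just above the 50 kPa afterload, the
  near-threshold regime the reported shortening pattern implies.

Load protocols:

- isometric: sarcomere length fixed ("infinite load");
- afterloaded isotonic: length clamped at rest until *active* tension
  reaches the afterload; on the constraint the length rate is obtained
  by solving dF/dt = −β (F − F_afterload) for dSL/dt (an index-1
  differential-algebraic constraint with Baumgarte stabilization,
  β = 2000 s⁻¹), so the borne tension genuinely rides the afterload and
  the shortening velocity is set by the cross-bridge kinetics, not by a
  penalty gain. The velocity is bounded at 20 µm/s — about the model's
  maximal shortening velocity; while the bound binds (the initial
  activation surge of the strongest cell at the lightest load), tension
  transiently exceeds the afterload, the massless-load limit of the
  protocol. Relengthening and the geometric floor (1.4 µm) use short
  tapers so the right-hand side stays continuous at the clamps. Passive
  (titin/collagen) tension is not part of the load balance; the
  alternative isometric reading (fixed total cell length with series
  compliance) is not implemented.
- prescribed length: the sarcomere follows a given periodic waveform;
  used by the circulation module (below).

Contractile ATP consumption rate is the product of the post-power-stroke
detachment flux (strain-dependent gxb × XBpostr) and the thick-filament
single-overlap fraction; "ATP per beat" is its cycle integral.

Twitches run 20 cycles by default; the final cycle is analysed.
Integration is LSODA at rtol 1e-7; state occupancies are conserved by
construction (the permissive fraction is implicit).

### What the single-cell chain reproduces, and what it does not

With the defaults above, the load/severity relations of steady-state
shortening emerge quantitatively: the HF4 amplitude is 64.7% below HF1
at 30 kPa and 83.8% below at 50 kPa (HF4 sits just above threshold
there); shortening decreases with afterload at every severity; and the
lighter-loaded cell reaches peak shortening *earlier* (11.5% faster for
HF1, 4.3% for HF3), because the deeper constant-tension shortening
engages overlap-mediated deactivation — this sign depends on the
isotonic constraint being enforced exactly, not by a soft penalty.

Two published observations do not emerge under prescribed-Ca one-way
coupling, in any surveyed configuration (both ionic variants, 24–37 °C,
rate modifiers 0.2–1, calibrations 80–300 kPa):

1. the isometric tension time-to-peak spread with severity is ~9 ms
   (91 → 100 ms) rather than ~46 ms (115 → 161 ms) — in this model
   family the twitch peak is pinned to the collapse of the Ca²⁺
   transient, which severity scaling does not move (the *ordering*, a
   strict increase with severity, is reproduced);
2. the mid-severity shortening reductions at the 50 kPa load are larger
   here (33/54% for HF2/HF3) than reported (11/36%): the model's
   force–Ca relation at this operating point drops more steeply between
   severities than the source ventricle's.

These are structural properties of the reduced chain, documented rather
than tuned around.

## Timing metrics

EAT: first upward 0-mV crossing (interpolated). MAT: first time the
shortening signal rest_length − L(t) reaches 10% of its beat maximum (an
early-activation marker; scale-invariant). EMD = MAT − EAT. All times
are relative to the cycle's stimulus; extractor accuracy on analytic
fixtures is < 0.01 ms, and halving the sampling interval moves EAT/MAT
by < 0.5 ms. Percent comparisons are (x_ref − x)/x_ref × 100 with HF1
(or the higher load) as reference.

## Circulation and LVAD

Eight stressed-volume compartments (LV, systemic arteries/veins, RA, RV,
pulmonary arteries/veins, LA) form a closed loop; valves are ideal
diodes in series with linear resistances; atria and vascular beds are
passive compliances (P = V/C). Each ventricle's pressure is

    P(V, t) = k_act · T(t) · max(V − V₀, 0) + s · B · (e^{a(V−V₀p)} − 1)

with T(t) the severity's isometric twitch-tension waveform (one-way
coupling, precomputed per severity) and s = 5 the failing-myocardium
passive-stiffness multiplier; the HF vascular state also applies a 1.2×
resistance rise and a 0.9× compliance drop. The active term is a
tension-driven time-varying-elastance surrogate (monotone in V, as a
stable reduced-order chamber requires); wall stress is read out
separately with a thick-sphere Laplace relation
σ = P·(1/3 + V/V_wall), which is the physically appropriate afterload
measure for the cell (volume unloading lowers σ even where cavity
pressure rises).

The LVAD is a constant-flow generator (50 mL/s = 3 L/min by default)
from the LV to the systemic-artery compartment, bypassing the aortic
valve; a suction guard caps the pump at the volume available above a
5-mL LV floor and counts engagements. The update is midpoint (RK2) at
dt = 0.25 ms and conservative by construction: every flow leaves one
compartment and enters another, so total blood volume drifts only at
round-off (≪ 0.1 mL over 42 s). Scenarios run 42 s (70 beats) to a
periodic state; the final beat is analysed (EDV, ESV, SV, EF, stroke
work as the enclosed PV-loop area, pressure extrema, full-assist flag).

Baseline R/C values are not printed in the study this package follows;
they are this package's own choice, informed by the lumped-circulation
literature and scaled to the small dilated ventricle, then fixed by a
systematic feasibility scan so the reduced model sits in the reported
qualitative regime (EF falling with severity; PV loops shifting right
with severity and left under LVAD; full assist in HF3/HF4 but partial
assist in HF1/HF2 at 50 mL/s; stroke work, ATP and EMD falling under
LVAD with the largest relative drops at HF4). They are config fields,
not asserted against any publication.

Cell-level feedback per scenario:

- EMD: the afterloaded isotonic twitch is rerun at the scenario's peak
  systolic wall stress (single feedback pass); EMD = MAT − EAT with EAT
  from the ionic run.
- total contractile ATP: a prescribed-length twitch whose sarcomere
  length follows the cube root of the simulated LV volume
  (SL = SL_rest·(V/V_ref)^{1/3}, V_ref = 75 mL). Afterload feedback
  alone cannot reproduce the reported LVAD ATP savings: the measured
  ATP-versus-afterload slope has opposite signs for HF1 and HF4 cells,
  whereas volume unloading shortens sarcomeres and lowers the
  overlap-weighted detachment flux at every severity, which is the
  mechanism the ventricle-level result reflects.

## Numerical choices and degenerate inputs

- All times reported at 1-ms resolution with linear interpolation for
  threshold crossings; table outputs round to integer ms.
- The strain-dependent rate exponents are capped at ±8: the published
  exponentials overflow for the large transient distortions a fast
  length change can produce, and the rates saturate physically anyway.
  A brief detachment-rate burst during the post-twitch snap-back is a
  visible artifact of this regime in the ATP-rate trace of strongly
  shortening cells; per-beat ATP integrals are insensitive to it.
- The L-type current's GHK-type factor uses the z/(e^z − 1) form with a
  series limit at |z| < 1e-7 (removable singularity at V = 15 mV /
  0 mV).
- Isotonic twitches in which tension never reaches the afterload are
  flagged `no_isotonic_shortening`; MAT/EMD are undefined (NaN/absent)
  rather than extrapolated.
- A Vm trace that never crosses 0 mV, a length trace with zero
  shortening, MAT < EAT, non-positive resistances, scales outside
  (0, 1], dt > 1 ms and non-finite states all raise errors.
- Compiled kernels (numba) are bit-deterministic; the package has no
  stochastic component, and manifests carry a reserved seed slot only.

## What the synthetic fixtures emulate

The analytic fixtures (ramp, gaussian twitch, biphasic shortening) have
closed-form EAT/MAT/time-to-peak and exist to test the metric extractors
independently of the ODE models. They do not emulate measurement noise,
beat-to-beat variability, or pathological waveform shapes, so passing
them shows extractor correctness on clean periodic signals only.

## Known limitations

- Single material point: no tissue propagation, Purkinje network, or
  spatial EAT/MAT/EMD maps; EMD magnitudes (~28–38 ms in the scenario
  sweep here) are not
  comparable to ventricle-averaged values from 3D models.
- One-way coupling throughout: no mechano-electric feedback, no
  Ca–troponin feedback onto the ionic model.
- The chamber surrogate compresses the severity contrast of peak LV
  pressure relative to finite-element ventricles; hemodynamic claims
  are orderings and regime splits, not absolute pressures/volumes.
- No coronary circulation, baroreflex, pulsatile LVAD modes, or
  long-term reverse remodelling.

## Problem sizes

Default runs: 20 paced beats (12 s) for the ionic model, 20 cycles per
twitch, 42 s per circulation scenario, 8 scenarios per sweep. On one CPU
the full test suite (including the sweep) completes in about a minute
plus one-time kernel compilation.
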