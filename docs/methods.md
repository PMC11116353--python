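# Methods

This note documents the models and numerical choices behind `refit`: the
closed-loop resuscitation controller, the in-silico porcine hemorrhage model
it is tested against, and what the test bench does and does not demonstrate.

## Signal features

The controller reads only quantities derivable from an arterial pressure
line (plus the stroke volumes a clinical monitor would report).

**Beat detection.** Systolic peaks are found first (scipy `find_peaks` with a
0.25-s refractory distance and a prominence of half the flatness threshold),
the diastolic trough between successive peaks defines the cycle boundary,
and each beat takes its systolic from the cycle maximum and its diastolic
from the *opening* trough.  Using the opening trough rather than the segment
minimum matters: when pulse pressure rises beat-to-beat, the following
cycle's deeper trough would otherwise bleed into the current beat and bias
PPV low by 2–3 % absolute.  A record whose pulsatility never reaches
5 mmHg is treated as flat (no beats) rather than an error, because absent
beats are exactly what the validity logic consumes.  Artifact rejection for
real clinical waveforms is out of scope; the detector is designed for clean
simulated pressure traces.

**PPV and SVV.** `PPV = 100·(PPmax − PPmin)/PPmean` over the beats in a 20-s
trailing window, requiring at least 5 beats; SVV is the identical statistic
on stroke volume, which makes `Ea_dyn = PPV/SVV` a plain ratio.  The
20-s window is also used for MAP (mean of per-beat `diastolic + PP/3`) and
HR (`(n−1)/span`).  The implementation uses plain max/min/sum arithmetic so
an explicit brute-force loop reproduces it bit-for-bit, and both PPV and SVV
are invariant under scaling of all pressures or volumes.

**Validity.** The signal is invalid once no beat has been seen for 5 s —
long enough to ride over a skipped beat, short against the 5-min phase
structure — or when the window holds fewer than 5 beats.  An invalid
snapshot carries NaN features and routes the controller to its failsafe.

**Hypotension trigger.** The protocol's shock criterion: the earliest time
at which more than 80 % of the MAP samples in the trailing 5-min window lie
strictly below 40 mmHg, evaluated once a full window is covered.  All
threshold comparisons in the package use the strict inequalities as printed
(`MAP < 40`, fraction `> 0.80`, `MAP < 60`, `HR > 110`, `PPV ≥ 10`).

## Controller

A finite-state machine ticked at 1 s (far finer than any 5-min phase, so
phase boundaries are unambiguous): initial whole-blood unit (250 ml / 5 min),
CaCl₂ (1 g / 5 min), one equilibration phase, then a single second-blood
decision — a second unit only if the stopping rules are unmet, after which
the decision is never revisited.  Cycling then proceeds in 15-min cycles
(treat / equilibrate / assess).  The snapshot governing a cycle's treatment
is the last valid snapshot of the preceding assess phase.

Where the protocol description leaves the logic open, the package resolves
it as follows:

- **Initiation is disjunctive, stopping conjunctive.**  Treatment is needed
  while `MAP < target or HR > threshold`; stopping requires both back in
  range.  A conjunctive trigger would ignore profound hypotension with a
  normal heart rate.
- **Both actions may be issued in one treat phase.**  A fluid bolus (when
  PPV ≥ 10 % and treatment is needed) and one norepinephrine step can
  coexist; norepinephrine up-titration is keyed to MAP alone.
- **Norepinephrine eligibility** begins the cycle *after* the first
  Ringer's bolus, matching the sequence "fluid first, then pressor if MAP
  remains low".
- **Wean step equals the up-step** (0.01 µg·kg⁻¹·min⁻¹, one per qualifying
  cycle): the minimal symmetric assumption, since only the up-step
  granularity is specified.
- **Failsafe** freezes the norepinephrine rate and blocks new bolus starts;
  an infusion already running completes (the pump already holds its order).
  Recovery requires a full 15-min observation window before the next
  treatment decision; the observation interval itself counts as the
  qualifying "stable cycle" for a first wean, which is what produces the
  wean-after-reconnection behavior when the subject recovered during the
  outage.
- **End-of-run state** is reported two ways: the strict last-sample check
  (MAP ≥ target and HR ≤ threshold at the final second) and the first
  treatment-free cycle time (`time_to_quiet_min`).  The printed
  stabilization definition is gated on a first crystalloid bolus, so
  `time_to_initial_stabilization` returns none for subjects rescued by
  blood alone; `time_to_quiet_min` is defined for every subject.

## The in-silico pig

The simulator is a deliberately minimal lumped-parameter model — every
relation is the simplest monotone or saturating form that meets the
calibration anchors.  It is a test bench for control logic, not a
physiological research model.

**Circulation.**  Cardiac output follows a saturating Frank–Starling curve
of stressed volume, `CO = Vmax·(1 − e^(−k·e))` with
`e = (x − x_u)/(1 − x_u)`, `x = V/V₀` and unstressed fraction `x_u = 0.35`;
`k` is derived so `CO(V₀)` equals the baseline cardiac output.  A one-pass
baroreflex raises SVR by 0.7 %/mmHg and HR by 1 min⁻¹/mmHg of pressure
deficit; norepinephrine multiplies SVR through an Emax relation
(`E_max = 0.5`, `EC₅₀ = 0.15 µg·kg⁻¹·min⁻¹`, so one 0.01 step moves MAP by
roughly 1–2 mmHg in the titration range); `MAP = CO·SVR` closes the loop.
The baseline state (MAP 68.8 mmHg, HR 82.2, CO 2.75 l/min at 70 ml/kg blood
volume) is an exact fixed point by construction for every sampled animal.

**Hemorrhage and volume.**  Bleeding is
`r₀ · e^(−λt) · (MAP/MAP₀)^α`, multiplied by a packing factor of 0.25 once
the liver is packed; `r₀ = 75 ml/min`, `λ = 0.035 min⁻¹` and `α = 0.81`
were calibrated jointly (with the death rule) so that the mean animal
crosses the MAP-40 trigger in ~21 min and an untreated cohort of 200 shows
≈50 % mortality at one hour, with deaths clustering between ~40 and
~75 min and a fraction of animals persisting in compensated shock — the
printed natural history.  Whole blood is retained fully, crystalloid at
40 % (volume-kinetic studies show hypotension markedly raises crystalloid
retention; the euvolemic figure would be nearer 25 %), and a transcapillary
refill term `0.002 min⁻¹ × (V₀ − V)` slowly restores plasma volume.  The
refill term is what lets a resuscitated animal converge durably above the
MAP target instead of hovering on it; it also reproduces the qualitative
hemodilution seen before resuscitation, though the model's pre-resuscitation
hemoglobin (≈10 g/dl) remains above the measured 9.1 g/dl because
hemorrhage itself removes hemoglobin and plasma together.

**Oxygen and lactate.**  SaO₂ is fixed at 100 %; oxygen delivery is
`1.34·Hgb·10·CO`; extraction is capped at 0.57, which pins baseline SvO₂ at
57 % and the deep-shock SvO₂ at the measured 43 %.  Demand not met under the
extraction cap produces lactate at 0.001 mmol·l⁻¹ per ml O₂ deficit,
clearing first-order at 0.01 min⁻¹ toward a 1 mmol/l resting level.

**Death** is declared after MAP stays below 20 mmHg for 5 min continuously,
and is absorbing.

**PPV, SVV and Ea_dyn.**  True PPV is a piecewise-linear, monotone
decreasing function of normalized volume through (x, PPV) anchors
(1.0, 6 %), (0.65, 30 %), (0.45, 60 %): below 10 % at baseline, above 30 %
in pre-resuscitation hypovolemia, and reaching the top dose band while the
circulation is still viable.  The Ea_dyn surrogate is a *wean-safety index*:
the intrinsic (norepinephrine-free) MAP the circulation would sustain at the
current volume, divided by 95 % of the animal's own baseline MAP.  This
realizes the clinical meaning of the Ea_dyn > 1 gate — pressure will be
maintained when the pressor is withdrawn — and prevents the
reactive-hypotension wean/re-titrate limit cycle that a total-tone surrogate
(SVR/SVR₀) produces.  True SVV is then `PPV_true/Ea_dyn_true`.

**Waveform synthesis.**  Beats are emitted at 60/HR s with pulse pressure
proportional to stroke volume, scaled by vascular tone (vasoconstriction
stiffens the arterial tree, preserving pulse pressure in shock).  Beat
pressures follow a `sin^q` pulse whose exponent is solved so the waveform's
time average is exactly `diastolic + PP/3`, making the windowed MAP estimate
unbiased.  The respiratory modulation of PP and SV is a tanh-saturated
sinusoid at the 0.25-Hz ventilator rate (an inspiratory-plateau analogue,
`k = 5`): a pure sinusoid sampled at the beat rate aliases badly whenever HR
is near an integer multiple of the ventilator rate, while the flattened
extremes keep the beat-sampled max/min within 2 % absolute of the true
modulation depth for any heart rate (measured worst case ≈1.7 % at
PPV ≈ 55 %, the controller's least sensitive region).

**Cohort sampling.**  Weight is Normal(30.8, 0.7) kg truncated positive.
Baseline MAP uses the measured absolute spread (σ = 3.7 mmHg) floored at
63 mmHg — an inclusion criterion, since an animal whose healthy baseline
sits below the resuscitation target would be classified as shocked before
injury.  The remaining jittered parameters (HR₀, CO₀, Starling Vmax, bleed
rate and decay, packing factor, VO₂/kg, crystalloid retention, refill rate)
get independent multiplicative Normal(1, cv) factors with cv = 0.10 by
default; `cv = 0` reproduces the reference animal exactly.  Each sampled
animal's derived quantities (SVR₀, Starling k) are recomputed so its own
baseline is a fixed point.

## Harness and numerics

The scenario driver advances the pig with explicit Euler at 0.1 s (the
dynamics are non-stiff first-order balances; halving dt changes trajectories
imperceptibly), emits beats incrementally, and ticks the controller at 1 Hz.
The timeline is baseline (30 min) → liver laceration → hypotension trigger
→ packing (treated runs) → 30-min delay → controller activation → run end at
180 min post-injury.  Disturbances: `transfer_dip` multiplies SVR by
(1 − magnitude) (default 0.15 for 2 min ≈ a 10-mmHg MAP dip) and
`signal_dropout` suppresses beats so the validity logic, not a scripted
flag, drives the failsafe.  All randomness flows from the scenario seed
through `numpy.random.default_rng`; identical config + seed reproduce trend
and ledger files byte-for-byte (floats are formatted explicitly).  The
1-Hz trend records the *monitored* features (blank during dropouts) next to
simulator truth (volume, SvO₂, lactate).

Cohort scales follow the study design they emulate: 200 untreated subjects
for the mortality estimate (binomial σ ≈ 3.5 % at p = 0.5) and 12 treated
subjects for the rescue demonstration.  The natural-history runs shorten the
pre-injury baseline to 5 min since the baseline is an exact fixed point.

## What passing tests show — and what they do not

The treated-cohort results (12/12 surviving with stopping rules met, all
subjects reaching a treatment-free cycle, times to stabilization of roughly
50–65 min) demonstrate that the *control logic* behaves as specified against
a simulator calibrated to the printed physiology.  They are not a
reproduction of animal experiments: the simulator has no anesthetic
pharmacology, coagulation, temperature or acid–base physiology beyond
lactate, its between-animal variability is a generic 10 % jitter rather than
measured covariance, its transport effects are reduced to an SVR dip and a
signal dropout, and its volume-responsiveness trajectory is constrained only
by the dosing behavior the protocol narrates.  Dose totals and stabilization
times produced here are therefore qualitative analogues, not predictions.
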