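# refit

Physiologically based closed-loop resuscitation of severe hemorrhagic shock,
with an in-silico porcine test bench.

## The problem

Severe uncontrolled hemorrhage (for example a liver laceration) kills quickly
— roughly half of untreated subjects within an hour — and definitive surgical
care is often hours away.  A closed-loop controller that reads only an
arterial pressure line can diagnose circulatory shock, dose fluids in
proportion to measured volume responsiveness, titrate a vasopressor, and stop
treating when targets are met, with no clinician in the loop.  This package
implements such a controller together with a calibrated lumped-parameter pig
simulator, so the controller's diagnosis, dosing, titration, stopping rules
and failsafe behavior can be exercised and verified entirely at desk scale.

## The algorithm

The controller consumes windowed hemodynamic features:

- **MAP** — mean arterial pressure over a 20-s window (mmHg);
- **HR** — heart rate (min⁻¹);
- **PPV** — pulse pressure variation, `100·(PPmax − PPmin)/PPmean` over a
  20-s moving window of beat pulse pressures (%): high values indicate
  volume responsiveness under controlled ventilation;
- **SVV** — stroke volume variation, same construction on beat stroke
  volumes;
- **Ea_dyn** — dynamic arterial elastance, PPV/SVV, a surrogate of vasomotor
  reserve used to gate vasopressor weaning.

Resuscitation is needed while `MAP < 60 mmHg or HR > 110 min⁻¹`; the stopping
rule is both back within limits (both thresholds are operator-settable).
On activation the controller gives 250 ml whole blood over 5 min, 1 g CaCl₂
over 5 min, and — only if the stopping rules are still unmet — a second
250 ml blood unit.  It then runs 15-min cycles of three 5-min phases
(treat / equilibrate / reassess):

| PPV at assessment | lactated Ringer's bolus |
|---|---|
| < 10 % | none |
| 10 – < 30 % | 5 ml/kg |
| 30 – < 50 % | 8 ml/kg |
| ≥ 50 % | 10 ml/kg |

Norepinephrine starts at 0.03 µg·kg⁻¹·min⁻¹ once MAP remains below target
after the first Ringer's bolus, moves in 0.01 µg·kg⁻¹·min⁻¹ steps to a
0.3 µg·kg⁻¹·min⁻¹ cap, and is weaned one step per cycle only when MAP held
above target for the whole cycle, no fluid was needed, and Ea_dyn > 1.
If the arterial signal is lost, the controller freezes: the norepinephrine
rate is held, no new boluses start, and after the signal returns a 15-min
observation window elapses before treatment resumes.

The simulator (`refit.pig_sim`) closes the loop: a ~30 kg ventilated pig
with Frank–Starling cardiac output, a one-pass baroreflex, an Emax
norepinephrine response, pressure-dependent decaying hemorrhage, packing,
transcapillary refill, a Fick oxygen balance with lactate kinetics, and a
per-beat arterial waveform with respiratory modulation.  See
`docs/methods.md` for the model, its calibration anchors and limitations.

## Worked example

Run one laboratory-scenario subject (30-min baseline, liver laceration,
hypotension trigger, 30-min delay, ~3-h closed-loop run):

```bash
refit run --seed 11 --out demo/
```

prints the run summary (times in seconds from scenario start):

```json
{
  "injury_at_s": 1800.0,
  "trigger_time_s": 3305.0,
  "resus_start_s": 5105.0,
  "end_time_s": 12600.0,
  "time_to_stabilization_min": 60.0,
  "time_to_quiet_min": 60.0,
  "survived_3h": true,
  "stopping_rules_met_at_end": true,
  "totals_to_stabilization": {
    "ringers_ml_per_kg": 10.0,
    "blood_ml": 500.0,
    "cacl2_g": 1.0,
    "ne_total_ug_per_kg": 0.45,
    "ne_mean_rate_ug_per_kg_min": 0.0075
  },
  "totals_stab_to_2h": {
    "ringers_ml_per_kg": 0.0,
    "blood_ml": 0.0,
    "cacl2_g": 0.0,
    "ne_total_ug_per_kg": 1.9475,
    "ne_mean_rate_ug_per_kg_min": 0.03
  },
  "weight_kg": 30.8
}
```

Reading this: MAP fell below 40 mmHg 25 min after injury (`trigger_time`),
the liver was packed and resuscitation started 30 min later.  The subject
received both blood units, 1 g CaCl₂ and 10 ml/kg of Ringer's plus a small
amount of norepinephrine before reaching initial stabilization (the first
treatment-free 15-min cycle) 60 min into resuscitation, then needed only a
low norepinephrine rate; it survived to the 3-h mark with both stopping
rules met.  The output directory contains `trend.csv` (1-Hz monitored and
simulated physiology), `ledger.csv` (every pump command), `summary.json`,
the resolved `config.json` and a stacked trend plot `trends.png`.

Other entry points:

```bash
refit cohort --n 12 --seed 0          # treated cohort, aggregate table
refit run --no-treatment --seed 1     # natural history (no controller)
refit features waveform.csv           # beat detection + feature snapshot
refit plot demo/trend.csv --ledger demo/ledger.csv
refit config --defaults               # full default JSON configuration
```

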