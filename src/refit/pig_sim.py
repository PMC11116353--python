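"""Lumped-parameter in-silico pig: uncontrolled hemorrhage and resuscitation.

A minimal closed-loop test bench for a ~30 kg mechanically ventilated pig
with a liver-laceration (uncontrolled, pressure-dependent) hemorrhage.  The
model is deliberately the simplest set of monotone/saturating relations that
reproduces the calibration anchors used throughout this package:

* baseline fixed point  MAP 68.8 mmHg, HR 82.2 min^-1, CO 2.75 l/min,
  SvO2 57 %, Hgb 10.6 g/dl at a blood volume of 70 ml/kg;
* a pre-resuscitation shock state near MAP ~49 mmHg / CO ~1.6 l/min;
* hypotension (MAP < 40) reached within 30 min of injury;
* ~50 % one-hour mortality when the injury is left untreated.

Model structure
---------------
Cardiac output follows a Frank-Starling saturating curve of the stressed
blood volume; a one-pass baroreflex raises systemic vascular resistance (SVR)
and heart rate in proportion to the pressure deficit; norepinephrine raises
SVR through a saturating Emax relation; MAP = CO x SVR closes the loop.
Bleeding decays exponentially with time since injury (clot maturation),
scales with the arterial-pressure ratio, and is reduced by a constant factor
once the liver is packed.  Volume lost to hemorrhage is partly replaced by
transcapillary plasma refill; crystalloid is retained at a fixed fraction.
Oxygen transport uses a fixed-SaO2 Fick balance with a maximal extraction
ratio; unmet demand produces lactate which clears first-order.  True pulse
pressure variation (ppv_true) is a piecewise-linear, monotone-decreasing
function of normalized blood volume, and true stroke volume variation is
ppv_true divided by the dynamic arterial elastance surrogate (a wean-safety
index; see :func:`eadyn_true`).

Integration is explicit Euler (default 0.1 s); the arterial waveform is
synthesized per beat, not per ODE step, with pulse pressure proportional to
stroke volume and a respiratory modulation at the ventilator rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from .signal_features import Beat, PressureSample

__all__ = [
    "PigParams",
    "PigState",
    "InfusionInput",
    "derive_hemodynamics",
    "hemorrhage_rate",
    "step",
    "initial_state",
    "BeatClock",
    "emit_waveform",
    "sample_cohort",
]


@dataclass
class PigParams:
    """Physiological parameters of one simulated pig.

    Defaults encode the calibrated ~30 kg animal; :func:`sample_cohort`
    jitters a defined subset of them to create between-animal variability.
    """

    weight: float = 30.8                # kg
    blood_per_kg: float = 70.0          # ml/kg -> V_blood0
    map0: float = 68.8                  # mmHg, baseline MAP (baroreflex setpoint)
    hr0: float = 82.2                   # min^-1
    co0: float = 2.75                   # l/min at V_blood0
    svo2_0: float = 57.0                # %, baseline mixed venous O2 saturation
    hgb0: float = 10.6                  # g/dl
    sao2: float = 100.0                 # %, fixed arterial O2 saturation
    # Frank-Starling: CO = vmax * (1 - exp(-k * e)), e = stressed-volume fraction
    starling_vmax: float = 4.2          # l/min
    starling_k: Optional[float] = None  # None -> derived so CO(V_blood0) = co0
    unstressed_fraction: float = 0.35   # volume fraction generating no output
    # Baroreflex (single fixed-point pass) and norepinephrine Emax
    baro_gain_svr: float = 0.007        # fractional SVR rise per mmHg deficit
    baro_gain_hr: float = 1.0           # min^-1 per mmHg deficit
    hr_max: float = 200.0               # min^-1
    ne_emax: float = 0.5                # max fractional SVR increase
    ne_ec50: float = 0.15               # ug/kg/min
    # True PPV as a function of x = V_blood / V_blood0: piecewise linear
    # through physiologic anchors (baseline < 10 %, steep rise in shock)
    ppv_curve_x: tuple[float, ...] = (0.30, 0.45, 0.65, 1.0, 1.1)
    ppv_curve: tuple[float, ...] = (80.0, 60.0, 30.0, 6.0, 0.0)
    # Uncontrolled hemorrhage (liver laceration)
    bleed_rate0: float = 75.0           # ml/min at injury, MAP = map0, unpacked
    bleed_decay: float = 0.035          # min^-1 (clot maturation)
    bleed_pressure_exp: float = 0.81    # bleeding ~ (MAP/map0)^exp
    packing_factor: float = 0.25        # bleed multiplier once packed
    # Volume kinetics
    lr_retention: float = 0.4           # crystalloid fraction staying intravascular (raised by hypotension)
    refill_rate: float = 0.002          # min^-1: transcapillary plasma refill per ml of volume deficit
    # Oxygen transport / lactate
    vo2_per_kg: float = 5.455           # ml O2/min/kg (-> baseline extraction 0.43)
    o2er_max: float = 0.57              # maximal O2 extraction ratio
    lactate_gain: float = 0.001         # mmol/l/min per ml O2/min deficit
    lactate_clear: float = 0.01         # min^-1
    lactate_rest: float = 1.0           # mmol/l
    # Death rule
    death_map: float = 20.0             # mmHg
    death_duration: float = 5.0         # min continuously below death_map
    # Waveform synthesis
    eadyn_ref_fraction: float = 0.95    # Ea_dyn crosses 1 when intrinsic MAP reaches this fraction of baseline
    resp_rate_hz: float = 0.25          # ventilator frequency
    resp_shape_k: float = 5.0           # tanh saturation of the respiratory modulation
    pp_per_sv: float = 0.8              # mmHg pulse pressure per ml stroke volume
    map_systolic_fraction: float = 1 / 3  # per-beat mean = dia + frac * PP

    @property
    def V_blood0(self) -> float:
        return self.blood_per_kg * self.weight

    @property
    def vo2(self) -> float:
        """Whole-body O2 consumption, ml/min."""
        return self.vo2_per_kg * self.weight

    @property
    def svr0(self) -> float:
        """Baseline SVR (mmHg.min/l), closing MAP = CO x SVR at baseline."""
        return self.map0 / self.co0

    def starling_k_eff(self) -> float:
        if self.starling_k is not None:
            return self.starling_k
        ratio = self.co0 / self.starling_vmax
        if not 0 < ratio < 1:
            raise ValueError("co0 must lie strictly below starling_vmax")
        return -math.log(1.0 - ratio)


@dataclass
class InfusionInput:
    """Pump rates applied to the pig (all >= 0)."""

    blood_rate: float = 0.0     # ml/min
    ringers_rate: float = 0.0   # ml/min
    ne_rate: float = 0.0        # ug/kg/min
    cacl2_rate: float = 0.0     # g/min (tracked only; no modeled hemodynamic effect)


@dataclass(slots=True)
class PigState:
    """Simulated physiology at time ``t`` (s).  Mutated in place by :func:`step`."""

    t: float
    V_blood: float      # ml
    hgb: float          # g/dl
    co: float           # l/min
    sv: float           # ml
    svr: float          # mmHg.min/l
    map: float          # mmHg
    hr: float           # min^-1
    ppv_true: float     # %
    svo2: float         # %
    lactate: float      # mmol/l
    bleed_rate: float   # ml/min
    packed: bool = False
    alive: bool = True
    injured_at: Optional[float] = None       # s, None before injury
    _below_death_since: Optional[float] = None


def derive_hemodynamics(
    V_blood: float, ne_rate: float, params: PigParams, svr_scale: float = 1.0
) -> tuple[float, float, float, float, float, float]:
    """Static circulation closure: ``(co, sv, hr, svr, map, ppv_true)``.

    ``svr_scale`` multiplies vascular tone (used for the transfer-dip
    disturbance).  The baroreflex is applied in a single fixed-point pass:
    the deficit is measured against the pre-reflex pressure.
    """
    x = V_blood / params.V_blood0
    e = x - params.unstressed_fraction
    if e <= 0.0:
        co = 0.0
    else:
        co = params.starling_vmax * (
            1.0 - math.exp(-params.starling_k_eff() * e / (1.0 - params.unstressed_fraction))
        )
    ne_factor = 1.0 + params.ne_emax * ne_rate / (params.ne_ec50 + ne_rate)
    svr0 = params.svr0
    map_raw = co * svr0 * ne_factor * svr_scale
    deficit_raw = params.map0 - map_raw
    baro = 1.0 + params.baro_gain_svr * deficit_raw if deficit_raw > 0.0 else 1.0
    svr = svr0 * baro * ne_factor * svr_scale
    map_ = co * svr
    deficit = params.map0 - map_
    hr = params.hr0 + (params.baro_gain_hr * deficit if deficit > 0.0 else 0.0)
    if hr > params.hr_max:
        hr = params.hr_max
    sv = co * 1000.0 / hr if hr > 0 else 0.0
    xs = params.ppv_curve_x
    ys = params.ppv_curve
    if x <= xs[0]:
        ppv = ys[0]
    elif x >= xs[-1]:
        ppv = ys[-1]
    else:
        ppv = ys[-1]
        for i in range(len(xs) - 1):
            if x < xs[i + 1]:
                f = (x - xs[i]) / (xs[i + 1] - xs[i])
                ppv = ys[i] + f * (ys[i + 1] - ys[i])
                break
    return co, sv, hr, svr, map_, ppv


def eadyn_true(state: PigState, params: PigParams) -> float:
    """Dynamic-arterial-elastance surrogate (dimensionless, crosses 1).

    Ea_dyn (PPV/SVV) is used clinically to gate vasopressor weaning: values
    above 1 predict that arterial pressure will be maintained when the
    pressor is withdrawn.  The model realizes exactly that semantics: the
    intrinsic (norepinephrine-free) mean pressure the circulation would
    sustain at the current volume, relative to a reference slightly below the
    animal's own baroreflex setpoint.  Pressor-dependent states therefore
    read below 1 (weaning would cause reactive hypotension) and recovered
    states read above 1.
    """
    map_intrinsic = derive_hemodynamics(state.V_blood, 0.0, params)[4]
    return map_intrinsic / (params.eadyn_ref_fraction * params.map0)


def hemorrhage_rate(
    t_since_injury: float, map_: float, packed: bool, params: PigParams
) -> float:
    """Instantaneous bleeding rate (ml/min); ``t_since_injury`` in seconds."""
    if t_since_injury < 0:
        raise ValueError("t_since_injury must be >= 0")
    if map_ <= 0.0:
        return 0.0
    rate = (
        params.bleed_rate0
        * math.exp(-params.bleed_decay * t_since_injury / 60.0)
        * (map_ / params.map0) ** params.bleed_pressure_exp
    )
    if packed:
        rate *= params.packing_factor
    return rate


def initial_state(params: PigParams) -> PigState:
    """Baseline fixed point of the model (uninjured, no infusions)."""
    v0 = params.V_blood0
    co, sv, hr, svr, map_, ppv = derive_hemodynamics(v0, 0.0, params)
    do2 = 1.34 * params.hgb0 * 10.0 * co * (params.sao2 / 100.0)
    er = min(params.vo2 / do2 if do2 > 0 else math.inf, params.o2er_max)
    svo2 = max(0.0, min(100.0, params.sao2 * (1.0 - er)))
    return PigState(
        t=0.0, V_blood=v0, hgb=params.hgb0, co=co, sv=sv, svr=svr, map=map_,
        hr=hr, ppv_true=ppv, svo2=svo2, lactate=params.lactate_rest,
        bleed_rate=0.0,
    )


def step(
    state: PigState,
    infusions: InfusionInput,
    dt: float,
    params: PigParams,
    svr_scale: float = 1.0,
) -> PigState:
    """Advance the pig by ``dt`` seconds (explicit Euler).  Mutates ``state``.

    Volume balance: blood is retained fully, crystalloid at ``lr_retention``;
    hemorrhage removes whole blood.  Hemoglobin follows mass conservation
    (crystalloid carries none, infused blood carries the animal's own
    baseline hemoglobin, as with an exchange transfusion).  Death is declared
    after MAP stays below ``death_map`` for ``death_duration`` minutes and is
    absorbing: afterwards only ``t`` advances.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if dt > 1.0:
        raise ValueError("dt must be <= 1 s")
    if not state.alive:
        state.t += dt
        return state

    dt_min = dt / 60.0
    v = state.V_blood
    if state.injured_at is not None and v > 0.0:
        bleed = hemorrhage_rate(state.t - state.injured_at, state.map, state.packed, params)
    else:
        bleed = 0.0

    refill = params.refill_rate * (params.V_blood0 - v) if v < params.V_blood0 else 0.0
    inflow = infusions.blood_rate + params.lr_retention * infusions.ringers_rate + refill
    v_new = v + (inflow - bleed) * dt_min
    if v_new < 0.0:
        v_new = 0.0

    # Hemoglobin mass balance (g); hgb in g/dl, volumes in ml.
    mass = state.hgb * v / 100.0
    mass += (infusions.blood_rate * params.hgb0 - bleed * state.hgb) / 100.0 * dt_min
    hgb = mass * 100.0 / v_new if v_new > 0.0 else 0.0

    co, sv, hr, svr, map_, ppv = derive_hemodynamics(v_new, infusions.ne_rate, params, svr_scale)

    do2 = 1.34 * hgb * 10.0 * co * (params.sao2 / 100.0)
    vo2 = params.vo2
    er = vo2 / do2 if do2 > 0.0 else math.inf
    if er > params.o2er_max:
        er = params.o2er_max
    svo2 = params.sao2 * (1.0 - er)
    if svo2 < 0.0:
        svo2 = 0.0
    elif svo2 > 100.0:
        svo2 = 100.0

    deficit = vo2 - params.o2er_max * do2
    if deficit < 0.0:
        deficit = 0.0
    lac = state.lactate + (
        params.lactate_gain * deficit - params.lactate_clear * (state.lactate - params.lactate_rest)
    ) * dt_min
    if lac < 0.0:
        lac = 0.0

    t_new = state.t + dt
    if map_ < params.death_map:
        if state._below_death_since is None:
            state._below_death_since = state.t
        if t_new - state._below_death_since >= params.death_duration * 60.0:
            state.alive = False
    else:
        state._below_death_since = None

    state.t = t_new
    state.V_blood = v_new
    state.hgb = hgb
    state.co = co
    state.sv = sv
    state.hr = hr
    state.svr = svr
    state.map = map_
    state.ppv_true = ppv
    state.svo2 = svo2
    state.lactate = lac
    state.bleed_rate = bleed
    return state


# ---------------------------------------------------------------------------
# Waveform / beat synthesis


def _resp_shape(phase: float, k: float) -> float:
    """Saturated respiratory modulation in [-1, 1] at respiratory ``phase`` (rad).

    A tanh-flattened sinusoid: the ventilator holds an inspiratory plateau, so
    pulse pressure dwells near its extremes rather than sweeping through them.
    This also makes the beat-sampled max/min of the modulation insensitive to
    the heart-rate-to-ventilator frequency ratio.
    """
    return math.tanh(k * math.sin(phase)) / math.tanh(k)


def _beat_values(
    t: float,
    map_: float,
    sv: float,
    ppv_true: float,
    eadyn: float,
    params: PigParams,
    tone: float = 1.0,
) -> Beat:
    """One synthetic beat at time ``t`` for the given slow-state values.

    ``tone`` (SVR over baseline SVR) scales pulse pressure per unit stroke
    volume: vasoconstriction stiffens the arterial tree, partly preserving
    pulse pressure as stroke volume falls.
    """
    phase = 2.0 * math.pi * params.resp_rate_hz * t
    mod = _resp_shape(phase, params.resp_shape_k)
    pp_mean = params.pp_per_sv * sv * tone
    svv_true = ppv_true / eadyn if eadyn > 0 else ppv_true
    pp = pp_mean * (1.0 + (ppv_true / 200.0) * mod)
    sv_b = sv * (1.0 + (svv_true / 200.0) * mod)
    dia = map_ - params.map_systolic_fraction * pp
    return Beat(t=t, systolic=dia + pp, diastolic=dia, stroke_volume=sv_b)


class BeatClock:
    """Incremental beat emitter for a running simulation.

    Tracks the next beat fiducial time; each call to :meth:`advance` emits the
    beats that fall in ``(previous, until]`` using the pig's current slow
    state, with beat spacing 60/HR.
    """

    def __init__(self, params: PigParams, t0: float = 0.0):
        self.params = params
        self.next_t = t0

    def advance(self, state: PigState, until: float) -> list[Beat]:
        out: list[Beat] = []
        ea = eadyn_true(state, self.params)
        tone = state.svr / self.params.svr0
        while self.next_t <= until:
            if state.alive and state.sv > 0.0 and state.hr > 0.0:
                out.append(
                    _beat_values(self.next_t, state.map, state.sv, state.ppv_true,
                                 ea, self.params, tone)
                )
                self.next_t += 60.0 / state.hr
            else:
                # pulseless: no beats, but keep the clock moving
                self.next_t += 1.0
        return out


def _pulse_exponent(mean_fraction: float) -> float:
    """Exponent q such that the mean of sin(pi u)^q over a beat equals mean_fraction."""

    def mean_of_power(q: float) -> float:
        return _gamma((q + 1.0) / 2.0) / (math.sqrt(math.pi) * _gamma(q / 2.0 + 1.0))

    return float(brentq(lambda q: mean_of_power(q) - mean_fraction, 0.5, 40.0))


def emit_waveform(
    state: PigState,
    duration: float,
    params: PigParams,
    fs: float = 100.0,
    t0: float = 0.0,
) -> tuple[list[PressureSample], list[Beat]]:
    """Render an arterial waveform (and its per-beat ledger) for a frozen state.

    Each beat is a ``sin^q`` pulse whose temporal mean equals
    ``dia + map_systolic_fraction * PP``, so the waveform's time average
    recovers the state's MAP.  Beat-to-beat pulse pressure and stroke volume
    carry the respiratory modulation described in :func:`_beat_values`.
    """
    if not state.alive:
        raise ValueError("cannot emit a waveform for a dead subject")
    q = _pulse_exponent(params.map_systolic_fraction)
    ea = eadyn_true(state, params)
    tone = state.svr / params.svr0
    beats: list[Beat] = []
    samples: list[PressureSample] = []
    t_beat = t0
    period = 60.0 / state.hr if state.hr > 0 else math.inf
    n_samples = int(round(duration * fs))
    i = 0
    while t_beat < t0 + duration:
        b = _beat_values(t_beat, state.map, state.sv, state.ppv_true, ea, params, tone)
        beats.append(b)
        t_end = t_beat + period
        while i < n_samples and t0 + i / fs < t_end:
            ts = t0 + i / fs
            u = (ts - t_beat) / period
            p = b.diastolic + b.pulse_pressure * math.sin(math.pi * u) ** q
            samples.append(PressureSample(t=ts, p=p))
            i += 1
        t_beat = t_end
    return samples, beats


# ---------------------------------------------------------------------------
# Cohort sampling

#: parameters jittered between animals by :func:`sample_cohort`
JITTERED_FIELDS = (
    "hr0",
    "co0",
    "starling_vmax",
    "bleed_rate0",
    "bleed_decay",
    "packing_factor",
    "vo2_per_kg",
    "lr_retention",
    "refill_rate",
)


def sample_cohort(
    n: int,
    seed: int,
    params0: PigParams | None = None,
    cv: float = 0.10,
    weight_mean: float = 30.8,
    weight_sd: float = 0.7,
    map0_sd: float = 3.7,
    map0_floor: float = 63.0,
) -> list[PigParams]:
    """Draw ``n`` animals around ``params0``.

    Weights are Normal(30.8, 0.7) truncated positive; baseline MAP gets the
    cohort's measured absolute spread (``map0_sd`` mmHg, scaled by ``cv/0.10``
    so ``cv=0`` disables it too); the fields in :data:`JITTERED_FIELDS` get
    independent multiplicative Normal(1, cv) factors (truncated at 0.2).
    ``cv=0`` reproduces ``params0`` exactly (apart from weight).
    Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params0 = params0 or PigParams()
    rng = np.random.default_rng(seed)
    cohort: list[PigParams] = []
    for _ in range(n):
        w = 0.0
        while w <= 0.0:
            w = float(rng.normal(weight_mean, weight_sd))
        kwargs = {"weight": w}
        # inclusion criterion: a study animal is not in shock at baseline, so
        # its baseline MAP must clear the resuscitation target with margin
        map0 = float(rng.normal(params0.map0, map0_sd * cv / 0.10))
        kwargs["map0"] = max(map0, map0_floor if cv > 0 else 0.0)
        for name in JITTERED_FIELDS:
            factor = max(0.2, float(rng.normal(1.0, cv)))
            kwargs[name] = getattr(params0, name) * factor
        p = replace(params0, **kwargs)
        # keep the Starling curve consistent: CO(V0) = co0 needs co0 < vmax
        if p.co0 >= 0.9 * p.starling_vmax:
            p = replace(p, starling_vmax=p.co0 / 0.9)
        if p.packing_factor > 1.0:
            p = replace(p, packing_factor=1.0)
        if p.lr_retention > 1.0:
            p = replace(p, lr_retention=1.0)
        cohort.append(p)
    return cohort
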