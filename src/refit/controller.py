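"""Closed-loop resuscitation decision engine.

The controller implements a physiologically based closed-loop protocol for
severe hemorrhagic shock, driven entirely by windowed hemodynamic features
(MAP, HR, PPV, SVV, Ea_dyn):

* **Initial sequence** — on activation, 250 ml whole blood over 5 min, then
  1 g CaCl2 over 5 min, then one 5-min equilibration; a second 250 ml blood
  unit follows only if the stopping rules (MAP at target and HR at or below
  threshold) are still unmet at that check.
* **15-min cycles** — each cycle is TREAT (5 min: issue at most one
  crystalloid bolus and/or one norepinephrine rate change), EQUILIBRATE
  (5 min: no action) and ASSESS (5 min: the last valid snapshot of this phase
  governs the next cycle's treatment).
* **Proportional fluid dosing** — lactated Ringer's boluses scale with pulse
  pressure variation: no fluid below 10 %, 5 ml/kg for 10-30 %, 8 ml/kg for
  30-50 %, 10 ml/kg at or above 50 %, infused over 5 min.
* **Vasopressor titration** — norepinephrine starts at 0.03 ug/kg/min (only
  after the first Ringer's bolus has been given and MAP remains below
  target), moves in 0.01 ug/kg/min steps, is capped at 0.3, and is weaned one
  step per cycle only when MAP held above target for the whole cycle, no
  fluid was needed, and Ea_dyn > 1 (adequate vasomotor tone).
* **Failsafe** — on loss of a valid signal the controller freezes: the
  norepinephrine rate is held, no new boluses start.  When the signal
  returns, a 15-min observation window elapses before treatment resumes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .signal_features import HemoSnapshot

__all__ = [
    "Channel",
    "CommandKind",
    "Mode",
    "Phase",
    "ControllerConfig",
    "PumpCommand",
    "ControllerState",
    "needs_resuscitation",
    "fluid_dose",
    "ne_adjust",
    "step",
    "time_to_initial_stabilization",
    "summarize_run",
    "write_ledger_csv",
    "read_ledger_csv",
]


class Channel(str, enum.Enum):
    WHOLE_BLOOD = "whole_blood"
    CACL2 = "cacl2"
    RINGERS = "ringers"
    NOREPINEPHRINE = "norepinephrine"


class CommandKind(str, enum.Enum):
    BOLUS = "bolus"
    RATE_SET = "rate_set"


class Mode(str, enum.Enum):
    IDLE = "IDLE"
    INITIAL_BLOOD = "INITIAL_BLOOD"
    CACL2 = "CACL2"
    SECOND_BLOOD = "SECOND_BLOOD"
    CYCLING = "CYCLING"
    FAILSAFE = "FAILSAFE"
    STOPPED = "STOPPED"


class Phase(str, enum.Enum):
    TREAT = "TREAT"
    EQUILIBRATE = "EQUILIBRATE"
    ASSESS = "ASSESS"


class ControllerConfig(BaseModel):
    """Controller thresholds and doses (`controller:` config section).

    ``map_target`` is operator-settable; all other defaults encode the
    protocol as published for a resuscitation target of MAP 60 mmHg.
    """

    map_target: float = Field(default=60.0, gt=0, description="mmHg")
    hr_threshold: float = Field(default=110.0, gt=0, description="min^-1")
    ppv_cuts: tuple[float, float, float] = (10.0, 30.0, 50.0)        # %
    fluid_doses: tuple[float, float, float] = (5.0, 8.0, 10.0)       # ml/kg
    ne_start: float = Field(default=0.03, gt=0, description="ug/kg/min")
    ne_step: float = Field(default=0.01, gt=0, description="ug/kg/min")
    ne_max: float = Field(default=0.3, gt=0, description="ug/kg/min")
    eadyn_wean_threshold: float = Field(default=1.0, description="wean NE only above this Ea_dyn")
    blood_bolus_ml: float = Field(default=250.0, gt=0)
    cacl2_dose_g: float = Field(default=1.0, gt=0)
    bolus_duration_min: float = Field(default=5.0, gt=0)
    phase_length_min: float = Field(default=5.0, gt=0, description="each of TREAT/EQUILIBRATE/ASSESS")
    observation_min: float = Field(default=15.0, gt=0, description="post-failsafe observation window")
    weight_kg: float = Field(default=30.8, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "ControllerConfig":
        if not self.ne_start <= self.ne_max:
            raise ValueError("ne_start must not exceed ne_max")
        if not (self.ppv_cuts[0] < self.ppv_cuts[1] < self.ppv_cuts[2]):
            raise ValueError("ppv_cuts must be strictly increasing")
        if not (self.fluid_doses[0] < self.fluid_doses[1] < self.fluid_doses[2]):
            raise ValueError("fluid_doses must be strictly increasing")
        return self

    @property
    def cycle_length_min(self) -> float:
        return 3 * self.phase_length_min


@dataclass(frozen=True)
class PumpCommand:
    """A single actuation on one of the four pump channels.

    ``amount`` is ml for fluid boluses, g for CaCl2, and ug/kg/min for
    norepinephrine rate settings; ``duration_min`` applies to boluses only.
    """

    t_issued: float
    channel: Channel
    kind: CommandKind
    amount: float
    duration_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("command amount must be >= 0")
        if self.kind is CommandKind.RATE_SET and self.channel is not Channel.NOREPINEPHRINE:
            raise ValueError("rate_set commands are only valid on the norepinephrine channel")


@dataclass
class ControllerState:
    """Mutable controller state; create one per run via ``ControllerState()``."""

    mode: Mode = Mode.IDLE
    phase: Phase = Phase.TREAT
    phase_start: float = 0.0
    cycle_start: float = 0.0
    ne_rate: float = 0.0
    first_lr_given: bool = False
    last_valid_snapshot: Optional[HemoSnapshot] = None
    log: list[PumpCommand] = field(default_factory=list)
    cycle_boundaries: list[float] = field(default_factory=list)
    activated_at: Optional[float] = None
    # cycle accounting
    map_above_all_cycle: bool = True
    prev_cycle_map_above: bool = False
    cycle_had_fluid: bool = False
    prev_cycle_had_fluid: bool = False
    assess_snapshot: Optional[HemoSnapshot] = None
    governing_snapshot: Optional[HemoSnapshot] = None
    observe_until: Optional[float] = None
    second_blood_resolved: bool = False
    _resume_mode: Optional[Mode] = None
    _last_tick: float = -math.inf


def needs_resuscitation(snap: HemoSnapshot, cfg: ControllerConfig) -> bool:
    """True iff the subject still needs treatment (MAP below target OR HR high).

    The stopping condition is the negation: MAP at/above target AND HR
    at/below threshold.  Raises on an invalid snapshot — the caller must
    route signal loss to the failsafe, never here.
    """
    if not snap.valid:
        raise ValueError("needs_resuscitation requires a valid snapshot")
    return snap.map < cfg.map_target or snap.hr > cfg.hr_threshold


def fluid_dose(ppv: float, cfg: ControllerConfig | None = None) -> float:
    """Crystalloid bolus size (ml/kg) for a given PPV (%).

    0 below the first cut, then the graded doses with left-inclusive
    boundaries: PPV in [10, 30) -> 5, [30, 50) -> 8, >= 50 -> 10 ml/kg.
    """
    cfg = cfg or ControllerConfig()
    if ppv < 0 or math.isnan(ppv):
        raise ValueError("ppv must be a non-negative number")
    c1, c2, c3 = cfg.ppv_cuts
    d1, d2, d3 = cfg.fluid_doses
    if ppv < c1:
        return 0.0
    if ppv < c2:
        return d1
    if ppv < c3:
        return d2
    return d3


def ne_adjust(
    snap: HemoSnapshot,
    state: ControllerState,
    cycle_had_fluid: bool,
    cfg: ControllerConfig,
) -> float:
    """New norepinephrine rate given the cycle-end assessment ``snap``.

    Up-titration whenever MAP is below target (start at ``ne_start``, then
    ``ne_step`` increments capped at ``ne_max``); one-step wean only when MAP
    held above target for the whole cycle, no fluid was given, and Ea_dyn
    exceeds the wean threshold.  Norepinephrine may only run after the first
    Ringer's bolus.
    """
    if not state.first_lr_given:
        raise ValueError("norepinephrine may not start before the first Ringer's bolus")
    rate = state.ne_rate
    if snap.map < cfg.map_target:
        if rate == 0.0:
            return cfg.ne_start
        return min(round(rate + cfg.ne_step, 10), cfg.ne_max)
    if (
        state.prev_cycle_map_above
        and not cycle_had_fluid
        and not math.isnan(snap.eadyn)
        and snap.eadyn > cfg.eadyn_wean_threshold
    ):
        return max(round(rate - cfg.ne_step, 10), 0.0)
    return rate


def _bolus(t: float, channel: Channel, amount: float, cfg: ControllerConfig) -> PumpCommand:
    return PumpCommand(
        t_issued=t, channel=channel, kind=CommandKind.BOLUS,
        amount=amount, duration_min=cfg.bolus_duration_min,
    )


def _treat(state: ControllerState, t: float, cfg: ControllerConfig) -> list[PumpCommand]:
    """Cycle-start decision: fluid per the PPV table and one NE adjustment."""
    gov = state.governing_snapshot
    cmds: list[PumpCommand] = []
    if gov is None or not gov.valid:
        return cmds
    fluid_now = False
    first_lr_before = state.first_lr_given
    if needs_resuscitation(gov, cfg):
        dose = fluid_dose(gov.ppv, cfg)
        if dose > 0.0:
            cmds.append(_bolus(t, Channel.RINGERS, dose * cfg.weight_kg, cfg))
            state.first_lr_given = True
            fluid_now = True
    # NE becomes eligible only from the cycle after the first Ringer's bolus.
    if first_lr_before:
        new_rate = ne_adjust(gov, state, state.prev_cycle_had_fluid or fluid_now, cfg)
        if new_rate != state.ne_rate:
            cmds.append(PumpCommand(t_issued=t, channel=Channel.NOREPINEPHRINE,
                                    kind=CommandKind.RATE_SET, amount=new_rate))
            state.ne_rate = new_rate
    state.cycle_had_fluid = fluid_now
    return cmds


def _roll_cycle(state: ControllerState, t: float) -> None:
    state.prev_cycle_map_above = state.map_above_all_cycle
    state.prev_cycle_had_fluid = state.cycle_had_fluid
    state.map_above_all_cycle = True
    state.cycle_had_fluid = False
    state.governing_snapshot = state.assess_snapshot or state.last_valid_snapshot
    state.assess_snapshot = None
    state.cycle_start = t
    state.phase_start = t
    state.cycle_boundaries.append(t)


def step(
    state: ControllerState,
    snap: HemoSnapshot,
    t: float,
    cfg: ControllerConfig,
) -> tuple[ControllerState, list[PumpCommand]]:
    """One control tick (nominally 1 s).  Returns ``(state, new commands)``.

    The first call activates the controller (initial whole-blood bolus).
    Commands are also appended to ``state.log``.  Time must not regress.
    """
    if t < state._last_tick:
        raise ValueError(f"control tick time regressed: {t} < {state._last_tick}")
    state._last_tick = t
    plen = cfg.phase_length_min * 60.0
    cmds: list[PumpCommand] = []

    if state.mode is Mode.STOPPED:
        return state, cmds

    # --- validity / failsafe routing -------------------------------------
    if snap.valid:
        state.last_valid_snapshot = snap
        if not (snap.map > cfg.map_target):
            state.map_above_all_cycle = False
        if state.mode is Mode.CYCLING and state.phase is Phase.ASSESS:
            state.assess_snapshot = snap
        if state.mode is Mode.FAILSAFE:
            # Signal restored: observe for a full window before treating.
            state.mode = Mode.CYCLING
            state.phase = Phase.ASSESS
            state.observe_until = t + cfg.observation_min * 60.0
            state.cycle_start = t
            state.phase_start = t
            state.map_above_all_cycle = snap.map > cfg.map_target
            state.cycle_had_fluid = False
            state.assess_snapshot = snap
    else:
        if state.mode not in (Mode.IDLE, Mode.FAILSAFE, Mode.STOPPED):
            state.mode = Mode.FAILSAFE
        return state, cmds

    if state.mode is Mode.FAILSAFE:
        return state, cmds

    # --- activation -------------------------------------------------------
    if state.mode is Mode.IDLE:
        state.mode = Mode.INITIAL_BLOOD
        state.activated_at = t
        state.phase_start = t
        state.cycle_start = t
        cmd = _bolus(t, Channel.WHOLE_BLOOD, cfg.blood_bolus_ml, cfg)
        cmds.append(cmd)
        state.log.extend(cmds)
        return state, cmds

    elapsed = t - state.phase_start

    if state.mode is Mode.INITIAL_BLOOD:
        if elapsed >= plen:
            state.mode = Mode.CACL2
            state.phase = Phase.TREAT
            state.phase_start = t
            cmds.append(_bolus(t, Channel.CACL2, cfg.cacl2_dose_g, cfg))

    elif state.mode is Mode.CACL2:
        # [0, plen): CaCl2 infusing; [plen, 2*plen): equilibration, then check.
        if elapsed >= 2 * plen:
            ref = state.last_valid_snapshot
            state.second_blood_resolved = True
            if ref is not None and needs_resuscitation(ref, cfg):
                state.mode = Mode.SECOND_BLOOD
                state.phase = Phase.TREAT
                state.phase_start = t
                cmds.append(_bolus(t, Channel.WHOLE_BLOOD, cfg.blood_bolus_ml, cfg))
            else:
                state.mode = Mode.CYCLING
                _roll_cycle(state, t)
                state.phase = Phase.TREAT
                cmds.extend(_treat(state, t, cfg))
        elif elapsed >= plen:
            state.phase = Phase.EQUILIBRATE

    elif state.mode is Mode.SECOND_BLOOD:
        # A full cycle-shaped block: infuse, equilibrate, assess.
        if elapsed >= 3 * plen:
            state.mode = Mode.CYCLING
            _roll_cycle(state, t)
            state.phase = Phase.TREAT
            cmds.extend(_treat(state, t, cfg))
        elif elapsed >= 2 * plen:
            if state.phase is not Phase.ASSESS:
                state.phase = Phase.ASSESS
            if snap.valid:
                state.assess_snapshot = snap
        elif elapsed >= plen:
            state.phase = Phase.EQUILIBRATE

    elif state.mode is Mode.CYCLING:
        if state.observe_until is not None:
            if t >= state.observe_until:
                state.observe_until = None
                _roll_cycle(state, t)
                state.phase = Phase.TREAT
                cmds.extend(_treat(state, t, cfg))
            # else: observing — no phase advance, no commands
        else:
            cyc = t - state.cycle_start
            if cyc >= 3 * plen:
                _roll_cycle(state, t)
                state.phase = Phase.TREAT
                cmds.extend(_treat(state, t, cfg))
            elif cyc >= 2 * plen:
                state.phase = Phase.ASSESS
            elif cyc >= plen:
                state.phase = Phase.EQUILIBRATE

    state.log.extend(cmds)
    return state, cmds


def stop(state: ControllerState) -> ControllerState:
    """Mark the run finished (scenario end)."""
    state.mode = Mode.STOPPED
    return state


# ---------------------------------------------------------------------------
# Run summaries


def time_to_initial_stabilization(
    log: Sequence[PumpCommand],
    cycle_boundaries: Sequence[float],
    start_time: float | None = None,
    cycle_length_s: float = 900.0,
) -> Optional[float]:
    """Minutes from resuscitation start to initial stabilization.

    Initial stabilization is the start of the first full cycle, beginning at
    or after the first Ringer's bolus, in which no treatment was given or
    changed.  Returns None if a Ringer's bolus never appears or no quiet
    cycle exists.  ``start_time`` defaults to the first cycle boundary.
    """
    lr_times = [c.t_issued for c in log if c.channel is Channel.RINGERS]
    if not lr_times:
        return None
    first_lr = min(lr_times)
    if start_time is None:
        if not cycle_boundaries:
            return None
        start_time = cycle_boundaries[0]
    bounds = sorted(cycle_boundaries)
    for i, b in enumerate(bounds):
        end = bounds[i + 1] if i + 1 < len(bounds) else b + cycle_length_s
        if b < first_lr:
            continue
        if not any(b <= c.t_issued < end for c in log):
            return (b - start_time) / 60.0
    return None


def _rate_trajectory(log: Sequence[PumpCommand]) -> list[tuple[float, float]]:
    """(time, rate) breakpoints of the norepinephrine infusion, rate in ug/kg/min."""
    traj = [(-math.inf, 0.0)]
    for c in sorted(log, key=lambda c: c.t_issued):
        if c.channel is Channel.NOREPINEPHRINE and c.kind is CommandKind.RATE_SET:
            traj.append((c.t_issued, c.amount))
    return traj


def summarize_run(
    log: Sequence[PumpCommand],
    weight: float,
    window: tuple[float, float],
) -> dict[str, float]:
    """Dose totals over ``window = (t_a, t_b)`` in seconds.

    Returns ``ringers_ml_per_kg``, ``blood_ml``, ``cacl2_g`` (bolus volumes
    pro-rated by the fraction of the infusion falling inside the window),
    ``ne_total_ug_per_kg`` (integral of the rate) and ``ne_mean_rate``
    (total over window duration, ug/kg/min).
    """
    t_a, t_b = window
    if not t_a < t_b:
        raise ValueError("window must satisfy t_a < t_b")
    vol = {Channel.RINGERS: 0.0, Channel.WHOLE_BLOOD: 0.0, Channel.CACL2: 0.0}
    for c in log:
        if c.kind is not CommandKind.BOLUS:
            continue
        dur = (c.duration_min or 0.0) * 60.0
        lo = max(c.t_issued, t_a)
        hi = min(c.t_issued + dur, t_b)
        if hi <= lo or dur <= 0.0:
            continue
        vol[c.channel] += c.amount * (hi - lo) / dur
    traj = _rate_trajectory(log)
    ne_total = 0.0
    for (t0, rate), (t1, _) in zip(traj, traj[1:] + [(math.inf, 0.0)]):
        lo = max(t0, t_a)
        hi = min(t1, t_b)
        if hi > lo:
            ne_total += rate * (hi - lo) / 60.0
    duration_min = (t_b - t_a) / 60.0
    return {
        "ringers_ml_per_kg": vol[Channel.RINGERS] / weight,
        "blood_ml": vol[Channel.WHOLE_BLOOD],
        "cacl2_g": vol[Channel.CACL2],
        "ne_total_ug_per_kg": ne_total,
        "ne_mean_rate_ug_per_kg_min": ne_total / duration_min,
    }


# ---------------------------------------------------------------------------
# Ledger CSV


_UNITS = {
    (Channel.WHOLE_BLOOD, CommandKind.BOLUS): "ml",
    (Channel.RINGERS, CommandKind.BOLUS): "ml",
    (Channel.CACL2, CommandKind.BOLUS): "g",
    (Channel.NOREPINEPHRINE, CommandKind.RATE_SET): "ug/kg/min",
}


def write_ledger_csv(log: Sequence[PumpCommand], path) -> None:
    """Write the command ledger: ``t_s,channel,kind,amount,unit,duration_min``."""
    with open(path, "w") as fh:
        fh.write("t_s,channel,kind,amount,unit,duration_min\n")
        for c in log:
            unit = _UNITS.get((c.channel, c.kind), "")
            dur = "" if c.duration_min is None else f"{c.duration_min:.6g}"
            fh.write(f"{c.t_issued:.6g},{c.channel.value},{c.kind.value},{c.amount:.6g},{unit},{dur}\n")


def read_ledger_csv(path) -> list[PumpCommand]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        dur = None if pd.isna(r.duration_min) else float(r.duration_min)
        out.append(PumpCommand(t_issued=float(r.t_s), channel=Channel(r.channel),
                               kind=CommandKind(r.kind), amount=float(r.amount),
                               duration_min=dur))
    return out
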