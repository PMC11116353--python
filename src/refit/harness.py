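"""Scenario orchestration: simulator -> signal features -> controller -> pumps.

Wires the in-silico pig, the feature extractor and the closed-loop controller
together at a 1-s control tick (simulator Euler substeps at 0.1 s), applies
the experimental timeline (baseline, liver laceration, hypotension trigger,
30-min delay, ~3-h closed-loop run) and the transport disturbances (transfer
dip, signal dropout), and writes trend/ledger/summary outputs.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import controller as ctrl
from . import pig_sim, signal_features as sf
from .controller import Channel, CommandKind, ControllerConfig, ControllerState
from .pig_sim import BeatClock, InfusionInput, PigParams
from .signal_features import SignalConfig

logger = logging.getLogger("refit")

__all__ = [
    "Disturbance",
    "ScenarioConfig",
    "RunResult",
    "run_subject",
    "run_scenario",
    "run_cohort",
    "render_trends",
]

TREND_COLUMNS = [
    "t_s", "map", "hr", "ppv", "svv", "eadyn", "valid",
    "svo2", "lactate", "co", "hgb", "V_blood", "ne_rate", "alive",
]


class Disturbance(BaseModel):
    """A scripted perturbation during a run.

    ``transfer_dip`` transiently lowers vascular tone (the physical act of
    moving the animal), producing a ~10 mmHg MAP dip at the default
    magnitude; ``signal_dropout`` suppresses the arterial signal so the
    controller must enter its failsafe.  ``t_start_s`` is measured relative
    to ``relative_to``.
    """

    kind: Literal["transfer_dip", "signal_dropout"]
    t_start_s: float = Field(ge=0)
    duration_s: float = Field(gt=0)
    magnitude: float = Field(default=0.15, ge=0, le=1, description="fractional SVR drop (transfer_dip only)")
    relative_to: Literal["resus_start", "injury", "absolute"] = "resus_start"


class ScenarioConfig(BaseModel):
    """Timeline and orchestration settings (`scenario:` config section)."""

    name: str = "lab"
    seed: int = 0
    baseline_min: float = Field(default=30.0, ge=0)
    post_injury_min: float = Field(default=180.0, gt=0, description="run ends this long after injury")
    trigger_delay_min: float = Field(default=30.0, ge=0, description="hypotension trigger -> resuscitation start")
    treatment_enabled: bool = True
    disturbances: list[Disturbance] = Field(default_factory=list)
    control_tick_s: float = Field(default=1.0, gt=0)
    sim_dt_s: float = Field(default=0.1, gt=0, le=1.0)
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        span = (self.baseline_min + self.post_injury_min) * 60.0
        for d in self.disturbances:
            if d.relative_to == "absolute" and d.t_start_s + d.duration_s > span:
                raise ValueError("disturbance extends past the scenario span")
        return self


@dataclass
class RunResult:
    """Outcome of one subject's run."""

    trend: pd.DataFrame
    log: list[ctrl.PumpCommand]
    params: PigParams
    injury_at: float
    trigger_time: Optional[float]
    resus_start: Optional[float]
    end_time: float
    time_to_stabilization_min: Optional[float]
    time_to_quiet_min: Optional[float]
    survived_3h: bool
    stopping_rules_met_at_end: bool
    totals_to_stabilization: Optional[dict] = None
    totals_stab_to_2h: Optional[dict] = None
    trend_path: Optional[str] = None
    ledger_path: Optional[str] = None

    def summary(self) -> dict:
        return {
            "injury_at_s": self.injury_at,
            "trigger_time_s": self.trigger_time,
            "resus_start_s": self.resus_start,
            "end_time_s": self.end_time,
            "time_to_stabilization_min": self.time_to_stabilization_min,
            "time_to_quiet_min": self.time_to_quiet_min,
            "survived_3h": self.survived_3h,
            "stopping_rules_met_at_end": self.stopping_rules_met_at_end,
            "totals_to_stabilization": self.totals_to_stabilization,
            "totals_stab_to_2h": self.totals_stab_to_2h,
            "weight_kg": self.params.weight,
        }


class _Pumps:
    """Active infusions: boluses run at amount/duration until their end time."""

    def __init__(self) -> None:
        self.boluses: dict[Channel, tuple[float, float]] = {}  # channel -> (rate/min, end_t)
        self.ne_rate = 0.0

    def apply(self, cmd: ctrl.PumpCommand) -> None:
        if cmd.kind is CommandKind.RATE_SET:
            self.ne_rate = cmd.amount
        else:
            dur_s = (cmd.duration_min or 0.0) * 60.0
            self.boluses[cmd.channel] = (cmd.amount / (cmd.duration_min or 1.0), cmd.t_issued + dur_s)

    def rates(self, t: float) -> InfusionInput:
        def rate(ch: Channel) -> float:
            r = self.boluses.get(ch)
            return r[0] if r is not None and t < r[1] else 0.0

        return InfusionInput(
            blood_rate=rate(Channel.WHOLE_BLOOD),
            ringers_rate=rate(Channel.RINGERS),
            ne_rate=self.ne_rate,
            cacl2_rate=rate(Channel.CACL2),
        )


def run_subject(
    params: PigParams,
    scenario: ScenarioConfig,
    controller_cfg: ControllerConfig | None = None,
    signal_cfg: SignalConfig | None = None,
) -> RunResult:
    """Run one subject through the full timeline; deterministic.

    Baseline -> liver laceration at ``baseline_min`` -> observation until the
    hypotension trigger (MAP < 40 mmHg over > 80 % of a 5-min window) -> if
    treatment is enabled, packing at the trigger and controller activation
    ``trigger_delay_min`` later -> run until ``post_injury_min`` after injury.
    """
    signal_cfg = signal_cfg or SignalConfig()
    controller_cfg = (controller_cfg or ControllerConfig()).model_copy(
        update={"weight_kg": params.weight}
    )
    tick = scenario.control_tick_s
    dt = scenario.sim_dt_s
    substeps = max(1, int(round(tick / dt)))
    dt = tick / substeps

    state = pig_sim.initial_state(params)
    injury_at = scenario.baseline_min * 60.0
    end_time = injury_at + scenario.post_injury_min * 60.0
    treated = scenario.treatment_enabled

    clock = BeatClock(params)
    beats: deque[sf.Beat] = deque()
    cstate = ControllerState()
    pumps = _Pumps()

    trigger_time: Optional[float] = None
    resus_start: Optional[float] = None

    # online hypotension trigger: fraction of the last 5-min of 1-Hz samples < 40
    trig_win = int(round(signal_cfg.trigger_window_s / tick))
    trig_buf: deque[float] = deque(maxlen=trig_win)

    def disturbance_flags(t: float) -> tuple[float, bool]:
        svr_scale = 1.0
        dropout = False
        for d in scenario.disturbances:
            ref = {"injury": injury_at, "absolute": 0.0}.get(d.relative_to)
            if ref is None:
                if resus_start is None:
                    continue
                ref = resus_start
            t0 = ref + d.t_start_s
            if t0 <= t < t0 + d.duration_s:
                if d.kind == "transfer_dip":
                    svr_scale *= 1.0 - d.magnitude
                else:
                    dropout = True
        return svr_scale, dropout

    rows = []
    n_trig_seen = 0
    n_ticks = int(round(end_time / tick))
    for k in range(n_ticks + 1):
        t = k * tick
        # advance physiology over (t - tick, t] with the rates and
        # disturbances in force at the start of that interval
        if k > 0:
            t_prev = t - tick
            if state.injured_at is None and t_prev >= injury_at:
                state.injured_at = state.t  # the sim's own (accumulated) clock
                logger.info("t=%.0fs injury", t_prev)
            svr_scale, _ = disturbance_flags(t_prev)
            inf = pumps.rates(t_prev)
            for _ in range(substeps):
                pig_sim.step(state, inf, dt, params, svr_scale=svr_scale)
        _, dropout = disturbance_flags(t)
        new_beats = clock.advance(state, t)
        if not dropout:
            beats.extend(new_beats)
        while beats and beats[0].t <= t - 2.0 * signal_cfg.feature_window_s:
            beats.popleft()

        snap = sf.snapshot(list(beats), t, signal_cfg) if treated else None

        # hypotension trigger (1-Hz MAP samples, 5-min window, > 80 % below 40)
        if trigger_time is None and t >= injury_at:
            trig_buf.append(state.map)
            n_trig_seen += 1
            if n_trig_seen > trig_win:
                frac = sum(1 for m in trig_buf if m < signal_cfg.trigger_map_mmHg) / trig_win
                if frac > signal_cfg.trigger_fraction:
                    trigger_time = t
                    if treated:
                        state.packed = True
                        resus_start = t + scenario.trigger_delay_min * 60.0
                    logger.info("t=%.0fs hypotension trigger; resus at %s", t, resus_start)

        cmds: list[ctrl.PumpCommand] = []
        if treated and resus_start is not None and t >= resus_start and state.alive:
            prev_mode = cstate.mode
            _, cmds = ctrl.step(cstate, snap, t, controller_cfg)
            if cstate.mode is not prev_mode:
                logger.info("t=%.0fs controller %s -> %s", t, prev_mode.value, cstate.mode.value)
            for c in cmds:
                pumps.apply(c)

        if snap is not None and snap.valid:
            m, h, pv, svv, ea, valid = snap.map, snap.hr, snap.ppv, snap.svv, snap.eadyn, True
        elif snap is not None:
            m = h = pv = svv = ea = math.nan
            valid = False
        else:  # untreated runs log the simulator truth
            m, h, pv = state.map, state.hr, state.ppv_true
            svv = state.ppv_true / pig_sim.eadyn_true(state, params)
            ea = pig_sim.eadyn_true(state, params)
            valid = True
        rows.append((
            t, m, h, pv, svv, ea, valid,
            state.svo2, state.lactate, state.co, state.hgb, state.V_blood,
            pumps.ne_rate, state.alive,
        ))

    ctrl.stop(cstate)
    trend = pd.DataFrame(rows, columns=TREND_COLUMNS)

    stab = None
    quiet = None
    stopping_met = False
    if treated and resus_start is not None:
        cycle_s = controller_cfg.cycle_length_min * 60.0
        stab = ctrl.time_to_initial_stabilization(
            cstate.log, cstate.cycle_boundaries, start_time=resus_start,
            cycle_length_s=cycle_s,
        )
        # first treatment-free cycle regardless of whether crystalloid was
        # ever needed (defined even for subjects rescued by blood alone)
        bounds = sorted(cstate.cycle_boundaries)
        for i, b in enumerate(bounds):
            hi = bounds[i + 1] if i + 1 < len(bounds) else b + cycle_s
            if not any(b <= c.t_issued < hi for c in cstate.log):
                quiet = (b - resus_start) / 60.0
                break
        last = cstate.last_valid_snapshot
        if state.alive and last is not None and last.valid:
            stopping_met = not ctrl.needs_resuscitation(last, controller_cfg)

    result = RunResult(
        trend=trend, log=cstate.log, params=params,
        injury_at=injury_at, trigger_time=trigger_time, resus_start=resus_start,
        end_time=end_time,
        time_to_stabilization_min=stab,
        time_to_quiet_min=quiet,
        survived_3h=state.alive,
        stopping_rules_met_at_end=stopping_met,
    )
    if treated and resus_start is not None and stab is not None:
        t_stab = resus_start + stab * 60.0
        result.totals_to_stabilization = ctrl.summarize_run(
            cstate.log, params.weight, (resus_start, t_stab))
        result.totals_stab_to_2h = ctrl.summarize_run(
            cstate.log, params.weight, (t_stab, min(t_stab + 7200.0, end_time)))
    return result


def _write_outputs(result: RunResult, out_dir: Path, resolved_config: dict, plot: bool = True) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    trend_path = out_dir / "trend.csv"
    _write_trend_csv(result.trend, trend_path)
    ledger_path = out_dir / "ledger.csv"
    ctrl.write_ledger_csv(result.log, ledger_path)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    with open(out_dir / "config.json", "w") as fh:
        json.dump(resolved_config, fh, indent=2, default=str)
    result.trend_path = str(trend_path)
    result.ledger_path = str(ledger_path)
    if plot:
        render_trends(result.trend, result.log, out_dir / "trends.png",
                      injury_at=result.injury_at, resus_start=result.resus_start)


def _write_trend_csv(trend: pd.DataFrame, path) -> None:
    """Deterministic, byte-stable trend CSV at 1 Hz."""
    with open(path, "w") as fh:
        fh.write(",".join(TREND_COLUMNS) + "\n")
        for row in trend.itertuples(index=False):
            cells = []
            for c, v in zip(TREND_COLUMNS, row):
                if c in ("valid", "alive"):
                    cells.append("1" if v else "0")
                elif isinstance(v, float) and math.isnan(v):
                    cells.append("")
                else:
                    cells.append(f"{v:.6g}")
            fh.write(",".join(cells) + "\n")


def run_scenario(
    scenario: ScenarioConfig,
    params: PigParams | None = None,
    controller_cfg: ControllerConfig | None = None,
    signal_cfg: SignalConfig | None = None,
) -> RunResult:
    """Run a single-subject scenario and, if configured, write its outputs."""
    params = params or PigParams()
    result = run_subject(params, scenario, controller_cfg, signal_cfg)
    if scenario.output_dir:
        resolved = {
            "scenario": scenario.model_dump(),
            "controller": (controller_cfg or ControllerConfig()).model_dump(),
            "signal": (signal_cfg or SignalConfig()).model_dump(),
            "pig": dataclass_dict(params),
        }
        _write_outputs(result, Path(scenario.output_dir), resolved)
    return result


def dataclass_dict(params: PigParams) -> dict:
    from dataclasses import asdict

    return asdict(params)


def run_cohort(
    scenario: ScenarioConfig,
    n: int,
    params0: PigParams | None = None,
    cv: float = 0.10,
    controller_cfg: ControllerConfig | None = None,
    signal_cfg: SignalConfig | None = None,
    mortality_horizon_min: Optional[float] = 60.0,
) -> tuple[list[RunResult], dict]:
    """Run ``n`` sampled subjects through the scenario; aggregate outcomes.

    Returns per-subject results and a summary dict with survival counts and
    mean +/- sd of time-to-stabilization and dose totals (treated runs).
    ``mortality_horizon_min`` adds the fraction dead within that many minutes
    of injury (the natural-history endpoint).
    """
    cohort = pig_sim.sample_cohort(n, scenario.seed, params0, cv=cv)
    results = [run_subject(p, scenario, controller_cfg, signal_cfg) for p in cohort]

    agg: dict = {
        "n": n,
        "survived_3h": int(sum(r.survived_3h for r in results)),
        "survival_fraction": float(np.mean([r.survived_3h for r in results])),
    }
    if mortality_horizon_min is not None:
        dead = 0
        for r in results:
            horizon = r.injury_at + mortality_horizon_min * 60.0
            sl = r.trend[r.trend.t_s <= horizon]
            dead += int(not bool(sl.alive.iloc[-1]))
        agg[f"mortality_{int(mortality_horizon_min)}min_pct"] = 100.0 * dead / n

    def mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
        vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if not vals:
            return None, None
        m = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        return m, sd

    if scenario.treatment_enabled:
        m, sd = mean_sd([r.time_to_stabilization_min for r in results])
        agg["time_to_stabilization_min_mean"] = m
        agg["time_to_stabilization_min_sd"] = sd
        agg["stabilized"] = int(sum(r.time_to_stabilization_min is not None for r in results))
        agg["reached_quiet_cycle"] = int(sum(r.time_to_quiet_min is not None for r in results))
        for key in ("ringers_ml_per_kg", "ne_total_ug_per_kg", "ne_mean_rate_ug_per_kg_min"):
            for win, attr in (("to_stab", "totals_to_stabilization"), ("stab_to_2h", "totals_stab_to_2h")):
                vals = [getattr(r, attr)[key] for r in results if getattr(r, attr) is not None]
                m, sd = mean_sd(vals)
                agg[f"{key}_{win}_mean"] = m
                agg[f"{key}_{win}_sd"] = sd
    return results, agg


def render_trends(
    trend: pd.DataFrame | str,
    log: Sequence[ctrl.PumpCommand] | str,
    out_path,
    injury_at: Optional[float] = None,
    resus_start: Optional[float] = None,
) -> str:
    """Stacked physiologic trend panels (NE rate, boluses, MAP, SvO2, HR, lactate).

    Invalid-signal intervals appear as gaps in the MAP panel; the bleed phase
    (injury to resuscitation) and the resuscitation phase are shaded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(trend, (str, Path)):
        trend = pd.read_csv(trend)
    if isinstance(log, (str, Path)):
        log = ctrl.read_ledger_csv(log)
    if len(trend) == 0:
        raise ValueError("empty trend log")

    t_min = trend.t_s / 60.0
    fig, axes = plt.subplots(6, 1, figsize=(10, 12), sharex=True)
    ne, bol, mapax, svo2, hrax, lac = axes
    ne.step(t_min, trend.ne_rate, where="post", color="tab:purple")
    ne.set_ylabel("NE\n(ug/kg/min)")
    for c in log:
        if c.kind is CommandKind.BOLUS:
            color = {"whole_blood": "red", "ringers": "tab:blue", "cacl2": "tab:orange"}[c.channel.value]
            bol.axvline(c.t_issued / 60.0, color=color, lw=2)
    bol.set_ylabel("boluses")
    bol.set_yticks([])
    mapax.plot(t_min, trend["map"], color="k")
    mapax.axhline(60, color="gray", ls="--", lw=0.8)
    mapax.set_ylabel("MAP\n(mmHg)")
    svo2.plot(t_min, trend.svo2, color="tab:green")
    svo2.set_ylabel("SvO2 (%)")
    hrax.plot(t_min, trend.hr, color="tab:red")
    hrax.set_ylabel("HR (min$^{-1}$)")
    lac.plot(t_min, trend.lactate, color="tab:brown")
    lac.set_ylabel("lactate\n(mmol/l)")
    lac.set_xlabel("time (min)")
    end = float(trend.t_s.iloc[-1])
    for ax in axes:
        if injury_at is not None:
            hi = resus_start if resus_start is not None else end
            ax.axvspan(injury_at / 60.0, hi / 60.0, color="salmon", alpha=0.15)
        if resus_start is not None:
            ax.axvspan(resus_start / 60.0, end / 60.0, color="lightblue", alpha=0.15)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)
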