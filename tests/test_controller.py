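"""Decision engine: dose table, NE titration, FSM, failsafe, run summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refit.controller import (
    Channel,
    CommandKind,
    ControllerConfig,
    ControllerState,
    Mode,
    PumpCommand,
    fluid_dose,
    ne_adjust,
    needs_resuscitation,
    step,
    summarize_run,
    time_to_initial_stabilization,
)

from conftest import snap


class TestNeedsResuscitation:
    @pytest.mark.parametrize(
        "map_, hr, expected",
        [
            (55.0, 90.0, True),    # hypotension alone
            (65.0, 100.0, False),  # both within limits
            (65.0, 120.0, True),   # tachycardia alone
            (59.9, 110.0, True),
            (60.0, 110.0, False),  # strict comparisons at both boundaries
            (60.0, 110.1, True),
        ],
    )
    def test_disjunctive_trigger(self, controller_cfg, map_, hr, expected):
        assert needs_resuscitation(snap(map=map_, hr=hr), controller_cfg) is expected

    def test_invalid_snapshot_raises(self, controller_cfg):
        with pytest.raises(ValueError):
            needs_resuscitation(snap(valid=False), controller_cfg)


class TestFluidDose:
    @pytest.mark.parametrize(
        "ppv, dose",
        [
            (5.0, 0.0), (9.99, 0.0),
            (10.0, 5.0), (15.0, 5.0), (29.99, 5.0),
            (30.0, 8.0), (35.0, 8.0), (49.99, 8.0),
            (50.0, 10.0), (55.0, 10.0), (100.0, 10.0),
        ],
    )
    def test_printed_dose_table(self, ppv, dose):
        assert fluid_dose(ppv) == dose

    def test_negative_ppv_raises(self):
        with pytest.raises(ValueError):
            fluid_dose(-1.0)

    @given(a=st.floats(min_value=0, max_value=100), b=st.floats(min_value=0, max_value=100))
    @settings(max_examples=100, deadline=None)
    def test_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert fluid_dose(lo) <= fluid_dose(hi)

    def test_breakpoints_are_exactly_the_cuts(self):
        eps = 1e-9
        for cut in (10.0, 30.0, 50.0):
            assert fluid_dose(cut - eps) < fluid_dose(cut)
        for v in (0, 9, 11, 29, 31, 49, 51, 99):
            assert fluid_dose(v) == fluid_dose(v + 0.5)


def _state(ne=0.0, first_lr=True, prev_above=False, cfg=None):
    s = ControllerState()
    s.ne_rate = ne
    s.first_lr_given = first_lr
    s.prev_cycle_map_above = prev_above
    return s


class TestNeAdjust:
    def test_starts_at_003(self, controller_cfg):
        got = ne_adjust(snap(map=55.0), _state(ne=0.0), False, controller_cfg)
        assert got == pytest.approx(0.03)

    def test_steps_up_by_001(self, controller_cfg):
        got = ne_adjust(snap(map=55.0), _state(ne=0.05), False, controller_cfg)
        assert got == pytest.approx(0.06)

    def test_capped_at_03(self, controller_cfg):
        got = ne_adjust(snap(map=55.0), _state(ne=0.30), False, controller_cfg)
        assert got == pytest.approx(0.30)

    def test_wean_one_step_when_gated_open(self, controller_cfg):
        got = ne_adjust(snap(map=68.0, eadyn=1.2), _state(ne=0.05, prev_above=True),
                        False, controller_cfg)
        assert got == pytest.approx(0.04)

    def test_no_wean_when_eadyn_low(self, controller_cfg):
        got = ne_adjust(snap(map=68.0, eadyn=0.8), _state(ne=0.05, prev_above=True),
                        False, controller_cfg)
        assert got == pytest.approx(0.05)

    def test_no_wean_if_fluid_given(self, controller_cfg):
        got = ne_adjust(snap(map=68.0, eadyn=1.2), _state(ne=0.05, prev_above=True),
                        True, controller_cfg)
        assert got == pytest.approx(0.05)

    def test_no_wean_if_map_dipped_during_cycle(self, controller_cfg):
        got = ne_adjust(snap(map=68.0, eadyn=1.2), _state(ne=0.05, prev_above=False),
                        False, controller_cfg)
        assert got == pytest.approx(0.05)

    def test_wean_floors_at_zero(self, controller_cfg):
        got = ne_adjust(snap(map=68.0, eadyn=1.2), _state(ne=0.0, prev_above=True),
                        False, controller_cfg)
        assert got == 0.0

    def test_requires_first_ringers(self, controller_cfg):
        with pytest.raises(ValueError):
            ne_adjust(snap(map=55.0), _state(first_lr=False), False, controller_cfg)


def run_script(cfg, snapshots, t0=0.0, tick=1.0):
    """Drive the FSM with a scripted snapshot stream; return (state, commands)."""
    state = ControllerState()
    cmds = []
    for i, s in enumerate(snapshots):
        state, new = step(state, s, t0 + i * tick, cfg)
        cmds.extend(new)
    return state, cmds


def shocked(t=0.0, ppv=35.0):
    return snap(t=t, map=50.0, hr=120.0, ppv=ppv, svv=30.0, eadyn=0.9)


def stable(t=0.0, ppv=5.0, eadyn=1.2):
    return snap(t=t, map=68.0, hr=85.0, ppv=ppv, svv=8.0, eadyn=eadyn)


class TestControllerFsm:
    def test_activation_emits_initial_blood(self, controller_cfg):
        state = ControllerState()
        state, cmds = step(state, shocked(), 100.0, controller_cfg)
        assert state.mode is Mode.INITIAL_BLOOD
        assert len(cmds) == 1
        c = cmds[0]
        assert c.channel is Channel.WHOLE_BLOOD and c.kind is CommandKind.BOLUS
        assert c.amount == 250.0 and c.duration_min == 5.0

    def test_initial_sequence_blood_then_cacl2_then_second_blood(self, controller_cfg):
        n = 16 * 60  # through the second-blood decision
        _, cmds = run_script(controller_cfg, [shocked(t=float(i)) for i in range(n)])
        kinds = [(c.t_issued, c.channel) for c in cmds[:3]]
        assert kinds[0] == (0.0, Channel.WHOLE_BLOOD)
        assert kinds[1] == (300.0, Channel.CACL2)
        assert cmds[1].amount == 1.0
        assert kinds[2] == (900.0, Channel.WHOLE_BLOOD)  # unmet stopping rules

    def test_no_second_blood_when_stable(self, controller_cfg):
        # shocked start, stable by the post-CaCl2 assessment
        stream = [shocked(t=float(i)) if i < 600 else stable(t=float(i)) for i in range(3600)]
        _, cmds = run_script(controller_cfg, stream)
        blood = [c for c in cmds if c.channel is Channel.WHOLE_BLOOD]
        assert len(blood) == 1

    def test_treat_phase_fluid_follows_dose_table(self, controller_cfg):
        n = 35 * 60
        _, cmds = run_script(controller_cfg, [shocked(t=float(i), ppv=35.0) for i in range(n)])
        lr = [c for c in cmds if c.channel is Channel.RINGERS]
        assert lr, "expected a Ringer's bolus in the first cycle"
        assert lr[0].t_issued == 1800.0  # first cycle starts after the initial sequence
        assert lr[0].amount == pytest.approx(8.0 * controller_cfg.weight_kg)

    def test_no_fluid_below_ppv_10(self, controller_cfg):
        stream = [snap(t=float(i), map=50.0, hr=120.0, ppv=6.0, svv=8.0, eadyn=0.8)
                  for i in range(90 * 60)]
        _, cmds = run_script(controller_cfg, stream)
        assert not any(c.channel is Channel.RINGERS for c in cmds)

    def test_ne_starts_only_after_first_ringers(self, controller_cfg):
        n = 80 * 60
        _, cmds = run_script(controller_cfg, [shocked(t=float(i)) for i in range(n)])
        lr_t = min(c.t_issued for c in cmds if c.channel is Channel.RINGERS)
        ne = [c for c in cmds if c.channel is Channel.NOREPINEPHRINE]
        assert ne and ne[0].t_issued > lr_t
        assert ne[0].amount == pytest.approx(0.03)
        # subsequent changes step by 0.01
        for a, b in zip(ne, ne[1:]):
            assert abs(b.amount - a.amount) == pytest.approx(0.01)

    def test_ne_rate_never_exceeds_cap(self, controller_cfg):
        state, cmds = run_script(
            controller_cfg, [shocked(t=float(i)) for i in range(8 * 3600)])
        rates = [c.amount for c in cmds if c.channel is Channel.NOREPINEPHRINE]
        assert max(rates) <= 0.3 + 1e-12
        assert state.ne_rate <= 0.3 + 1e-12

    def test_failsafe_holds_ne_and_blocks_commands(self, controller_cfg):
        # drive to NE 0.07, then 25-min dropout, then stable return
        stream = [shocked(t=float(i)) for i in range(75 * 60)]
        state, cmds = run_script(controller_cfg, stream)
        ne_before = state.ne_rate
        assert ne_before > 0
        t0 = 75 * 60
        outage = 25 * 60
        for i in range(outage):
            state, new = step(state, snap(t=t0 + i, valid=False), float(t0 + i), controller_cfg)
            assert new == []
            assert state.mode is Mode.FAILSAFE
            assert state.ne_rate == ne_before
        # reconnection: observation window, no treatment for 15 min
        t1 = t0 + outage
        observed_cmds = []
        for i in range(15 * 60):
            state, new = step(state, stable(t=float(t1 + i)), float(t1 + i), controller_cfg)
            observed_cmds.extend(new)
        assert state.mode is Mode.CYCLING
        assert observed_cmds == []
        # first decision after the observation window: wean (MAP high, Ea_dyn > 1)
        state, new = step(state, stable(t=float(t1 + 900)), float(t1 + 900), controller_cfg)
        assert len(new) == 1
        assert new[0].channel is Channel.NOREPINEPHRINE
        assert new[0].amount == pytest.approx(ne_before - 0.01)

    def test_time_regression_raises(self, controller_cfg):
        state = ControllerState()
        state, _ = step(state, shocked(), 100.0, controller_cfg)
        with pytest.raises(ValueError):
            step(state, shocked(), 99.0, controller_cfg)

    def test_deterministic_replay(self, controller_cfg):
        stream = [shocked(t=float(i)) if i % 900 < 450 else stable(t=float(i))
                  for i in range(2 * 3600)]
        s1, c1 = run_script(controller_cfg, stream)
        s2, c2 = run_script(controller_cfg, stream)
        assert c1 == c2
        assert s1.mode == s2.mode and s1.ne_rate == s2.ne_rate

    def test_treat_commands_start_at_cycle_boundaries(self, controller_cfg):
        state, cmds = run_script(controller_cfg, [shocked(t=float(i)) for i in range(3 * 3600)])
        for c in cmds:
            if c.t_issued >= 1800.0:  # cycling era
                offset = (c.t_issued - 1800.0) % 900.0
                assert offset == 0.0


class TestStabilizationTime:
    def test_first_quiet_cycle_after_first_lr(self):
        bounds = [0.0, 900.0, 1800.0]
        log = [PumpCommand(t_issued=100.0, channel=Channel.RINGERS,
                           kind=CommandKind.BOLUS, amount=150.0, duration_min=5.0)]
        assert time_to_initial_stabilization(log, bounds) == pytest.approx(900.0 / 60.0)

    def test_commands_every_cycle_gives_none(self):
        bounds = [i * 900.0 for i in range(4)]
        log = [PumpCommand(t_issued=b + 1.0, channel=Channel.RINGERS,
                           kind=CommandKind.BOLUS, amount=150.0, duration_min=5.0)
               for b in bounds]
        assert time_to_initial_stabilization(log, bounds) is None

    def test_no_ringers_gives_none(self):
        log = [PumpCommand(t_issued=0.0, channel=Channel.WHOLE_BLOOD,
                           kind=CommandKind.BOLUS, amount=250.0, duration_min=5.0)]
        assert time_to_initial_stabilization(log, [0.0, 900.0]) is None

    def test_twelve_cycle_log_matches_brute_force(self):
        # quiet cycles {4, 7} (0-based 3, 6); first LR in cycle 2 (0-based 1)
        bounds = [i * 900.0 for i in range(12)]
        busy = {0, 1, 2, 4, 5, 7, 8, 9, 10, 11}
        log = []
        for i in sorted(busy):
            ch = Channel.RINGERS if i == 1 else Channel.NOREPINEPHRINE
            kind = CommandKind.BOLUS if i == 1 else CommandKind.RATE_SET
            log.append(PumpCommand(t_issued=bounds[i] + 5.0, channel=ch, kind=kind,
                                   amount=150.0 if i == 1 else 0.05,
                                   duration_min=5.0 if i == 1 else None))
        # brute force: first boundary >= first LR with no command inside
        first_lr = bounds[1] + 5.0
        expect = None
        for i, b in enumerate(bounds):
            end = b + 900.0
            if b >= first_lr and not any(b <= c.t_issued < end for c in log):
                expect = b / 60.0
                break
        got = time_to_initial_stabilization(log, bounds)
        assert got == expect == pytest.approx(bounds[3] / 60.0)


class TestSummarizeRun:
    def test_empty_log(self):
        out = summarize_run([], 30.0, (0.0, 3600.0))
        assert out["ringers_ml_per_kg"] == 0.0
        assert out["ne_total_ug_per_kg"] == 0.0
        assert out["ne_mean_rate_ug_per_kg_min"] == 0.0

    def test_constant_rate_rectangle_integral(self):
        log = [PumpCommand(t_issued=0.0, channel=Channel.NOREPINEPHRINE,
                           kind=CommandKind.RATE_SET, amount=0.05)]
        out = summarize_run(log, 30.0, (0.0, 120 * 60.0))
        assert out["ne_total_ug_per_kg"] == pytest.approx(6.0)
        assert out["ne_mean_rate_ug_per_kg_min"] == pytest.approx(0.05)

    def test_two_boluses_inside_window(self):
        log = [
            PumpCommand(t_issued=600.0, channel=Channel.RINGERS,
                        kind=CommandKind.BOLUS, amount=150.0, duration_min=5.0),
            PumpCommand(t_issued=1800.0, channel=Channel.RINGERS,
                        kind=CommandKind.BOLUS, amount=150.0, duration_min=5.0),
        ]
        out = summarize_run(log, 30.0, (0.0, 3600.0))
        assert out["ringers_ml_per_kg"] == pytest.approx(10.0)

    def test_bolus_prorated_at_window_edge(self):
        log = [PumpCommand(t_issued=0.0, channel=Channel.RINGERS,
                           kind=CommandKind.BOLUS, amount=150.0, duration_min=5.0)]
        out = summarize_run(log, 30.0, (0.0, 150.0))  # half the infusion
        assert out["ringers_ml_per_kg"] == pytest.approx(2.5)

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            summarize_run([], 30.0, (10.0, 10.0))
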