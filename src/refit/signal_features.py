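"""Windowed hemodynamic features from an arterial-pressure record.

This module turns a pressure waveform (or a per-beat series reported by a
monitor/simulator) into the quantities a closed-loop resuscitation controller
reads: mean arterial pressure (MAP), heart rate (HR), pulse pressure
variation (PPV), stroke volume variation (SVV) and their ratio, dynamic
arterial elastance (Ea_dyn = PPV/SVV).  It also implements the protocol's
hypotension trigger (MAP < 40 mmHg over more than 80 % of a 5-min moving
window) and a signal-validity check used to gate the controller's failsafe.

PPV is computed as 100 x (PPmax - PPmin) / PPmean over a 20-s moving window
of beat pulse pressures; SVV is defined identically on beat stroke volumes,
which makes Ea_dyn a plain ratio of the two percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.signal import find_peaks

__all__ = [
    "PressureSample",
    "Beat",
    "HemoSnapshot",
    "SignalConfig",
    "detect_beats",
    "compute_ppv",
    "compute_svv",
    "snapshot",
    "hypotension_trigger",
    "signal_valid",
    "read_waveform_csv",
    "write_beats_csv",
    "read_beats_csv",
]


@dataclass(frozen=True)
class PressureSample:
    """One arterial-pressure sample: time ``t`` (s), pressure ``p`` (mmHg)."""

    t: float
    p: float


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle.

    ``t`` is the beat fiducial time (the opening diastolic trough), ``systolic``
    and ``diastolic`` are the extrema of that cycle (mmHg) and
    ``stroke_volume`` (ml) is optional, supplied by a monitor or simulator.
    """

    t: float
    systolic: float
    diastolic: float
    stroke_volume: Optional[float] = None

    @property
    def pulse_pressure(self) -> float:
        return self.systolic - self.diastolic

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic:
            raise ValueError(
                f"beat at t={self.t}: systolic ({self.systolic}) must exceed "
                f"diastolic ({self.diastolic})"
            )


@dataclass(frozen=True)
class HemoSnapshot:
    """Windowed monitored state driving the controller.

    When ``valid`` is False the feature fields are NaN and must not be used
    for treatment decisions (the controller routes to its failsafe instead).
    ``eadyn`` is NaN whenever SVV is zero or unavailable.
    """

    t: float
    map: float
    hr: float
    ppv: float
    svv: float
    eadyn: float
    valid: bool


class SignalConfig(BaseModel):
    """Feature-extraction parameters (`signal:` section of the JSON config)."""

    feature_window_s: float = Field(default=20.0, gt=0, description="PPV/SVV/MAP/HR window (s)")
    trigger_window_s: float = Field(default=300.0, gt=0, description="hypotension-trigger window (s)")
    trigger_map_mmHg: float = Field(default=40.0, gt=0, description="hypotension threshold (mmHg)")
    trigger_fraction: float = Field(default=0.80, ge=0, le=1, description="window fraction that must be below threshold")
    validity_horizon_s: float = Field(default=5.0, gt=0, description="no beat for this long => signal invalid")
    min_beats: int = Field(default=5, ge=2, description="minimum beats per window for PPV/SVV")
    refractory_s: float = Field(default=0.25, gt=0, description="beat-detection refractory period (s)")
    min_pulse_pressure: float = Field(default=5.0, gt=0, description="below this PP (mmHg) the signal is treated as flat")
    map_systolic_fraction: float = Field(
        default=1 / 3, gt=0, lt=1,
        description="per-beat MAP estimate = diastolic + fraction * pulse pressure",
    )


def detect_beats(record: Sequence[PressureSample], cfg: SignalConfig | None = None) -> list[Beat]:
    """Segment a pressure record into beats (trough-to-trough).

    Systolic peaks are located first (they are sharp and unambiguous), the
    diastolic trough between successive peaks defines the cycle boundary, and
    each beat takes the local max/min between its bounding troughs.  A flat
    or too-short record yields an empty list: absence of beats feeds the
    validity logic rather than raising.
    """
    cfg = cfg or SignalConfig()
    n = len(record)
    if n < 3:
        return []
    t = np.asarray([s.t for s in record], dtype=float)
    p = np.asarray([s.p for s in record], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("pressure record times must be strictly increasing")
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure record contains non-finite values")
    dt = float(np.median(np.diff(t)))
    if dt <= 0 or (t[-1] - t[0]) < 2.0:
        return []
    distance = max(1, int(round(cfg.refractory_s / dt)))
    peaks, _ = find_peaks(p, distance=distance, prominence=cfg.min_pulse_pressure / 2)
    if len(peaks) < 2:
        return []
    # Trough = minimum between successive systolic peaks.
    troughs = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(a + int(np.argmin(p[a:b])))
    beats: list[Beat] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        # systolic: cycle maximum; diastolic: the opening trough, so that a
        # beat-to-beat change in pulse pressure never bleeds the next
        # cycle's deeper trough into this beat
        sys_p = float(p[a : b + 1].max())
        dia_p = float(p[a])
        # artifact floor: half the flat-record threshold
        if sys_p - dia_p < cfg.min_pulse_pressure / 2:
            continue
        beats.append(Beat(t=float(t[a]), systolic=sys_p, diastolic=dia_p))
    # a record whose pulsatility never reaches the threshold is flat
    if beats and max(b.pulse_pressure for b in beats) < cfg.min_pulse_pressure:
        return []
    return beats


def _window_beats(beats: Sequence[Beat], t: float, window: float) -> list[Beat]:
    return [b for b in beats if t - window < b.t <= t]


def _variation_pct(values: Sequence[float]) -> float:
    """100 x (max - min) / mean, plain-arithmetic so tests can brute-force it."""
    vmax = max(values)
    vmin = min(values)
    vmean = sum(values) / len(values)
    if vmean <= 0:
        return math.nan
    return 100.0 * (vmax - vmin) / vmean


def compute_ppv(
    beats: Sequence[Beat], t: float, window: float = 20.0, min_beats: int = 5
) -> float:
    """Pulse pressure variation (%) over the window ``(t - window, t]``.

    Returns ``100 x (PPmax - PPmin) / PPmean``; NaN when fewer than
    ``min_beats`` beats fall in the window (the caller must then mark the
    snapshot invalid).
    """
    win = _window_beats(beats, t, window)
    if len(win) < min_beats:
        return math.nan
    return _variation_pct([b.pulse_pressure for b in win])


def compute_svv(
    beats: Sequence[Beat], t: float, window: float = 20.0, min_beats: int = 5
) -> float:
    """Stroke volume variation (%), same contract as :func:`compute_ppv`.

    Beats lacking a stroke volume are ignored; if fewer than ``min_beats``
    carry one, returns NaN.
    """
    win = [b for b in _window_beats(beats, t, window) if b.stroke_volume is not None]
    if len(win) < min_beats:
        return math.nan
    return _variation_pct([b.stroke_volume for b in win])


def signal_valid(beats: Sequence[Beat], t: float, horizon: float = 5.0) -> bool:
    """False iff no beat was detected in the trailing ``horizon`` seconds.

    A single skipped beat (~1 s gap) keeps the signal valid; a monitor
    disconnect longer than the horizon does not.
    """
    return any(t - horizon < b.t <= t for b in beats)


def snapshot(beats: Sequence[Beat], t: float, cfg: SignalConfig | None = None) -> HemoSnapshot:
    """Aggregate the monitored quantities at time ``t`` into a snapshot.

    MAP is the mean of per-beat pressure estimates
    (diastolic + ``map_systolic_fraction`` x pulse pressure) over the feature
    window; HR uses the beat count over the window span actually covered.
    The snapshot is valid only if beats are current (see :func:`signal_valid`)
    and the window holds enough beats for PPV.
    """
    cfg = cfg or SignalConfig()
    win = _window_beats(beats, t, cfg.feature_window_s)
    valid = signal_valid(beats, t, cfg.validity_horizon_s) and len(win) >= cfg.min_beats
    if not valid:
        nan = math.nan
        return HemoSnapshot(t=t, map=nan, hr=nan, ppv=nan, svv=nan, eadyn=nan, valid=False)
    frac = cfg.map_systolic_fraction
    map_est = sum(b.diastolic + frac * b.pulse_pressure for b in win) / len(win)
    if len(win) >= 2 and win[-1].t > win[0].t:
        hr = 60.0 * (len(win) - 1) / (win[-1].t - win[0].t)
    else:
        hr = math.nan
    ppv = compute_ppv(beats, t, cfg.feature_window_s, cfg.min_beats)
    svv = compute_svv(beats, t, cfg.feature_window_s, cfg.min_beats)
    eadyn = ppv / svv if (not math.isnan(svv) and svv > 0) else math.nan
    return HemoSnapshot(t=t, map=map_est, hr=hr, ppv=ppv, svv=svv, eadyn=eadyn, valid=True)


def hypotension_trigger(
    map_series: Sequence[tuple[float, float]],
    threshold: float = 40.0,
    window: float = 300.0,
    fraction: float = 0.80,
) -> Optional[float]:
    """Earliest time the hypotension criterion is met, or None.

    The criterion: in the ``window`` seconds ending at ``t`` (only evaluated
    once the series has covered a full window), the fraction of samples with
    MAP strictly below ``threshold`` strictly exceeds ``fraction``.
    """
    if len(map_series) == 0:
        raise ValueError("empty MAP series")
    t = np.asarray([s[0] for s in map_series], dtype=float)
    m = np.asarray([s[1] for s in map_series], dtype=float)
    below = (m < threshold).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(below)])
    # window (t_i - window, t_i]: left index via searchsorted on the open edge
    left = np.searchsorted(t, t - window, side="right")
    idx = np.arange(len(t))
    count = idx - left + 1
    frac = (cum[idx + 1] - cum[left]) / count
    covered = (t - t[0]) >= window
    hits = np.nonzero(covered & (frac > fraction))[0]
    if len(hits) == 0:
        return None
    return float(t[hits[0]])


# ---------------------------------------------------------------------------
# CSV interfaces


def read_waveform_csv(path) -> list[PressureSample]:
    """Read a waveform CSV with header ``t_s,p_mmHg``."""
    df = pd.read_csv(path)
    return [PressureSample(t=float(r.t_s), p=float(r.p_mmHg)) for r in df.itertuples()]


def write_beats_csv(beats: Sequence[Beat], path) -> None:
    """Write a beat CSV with header ``t_s,sys_mmHg,dia_mmHg,sv_ml``."""
    with open(path, "w") as fh:
        fh.write("t_s,sys_mmHg,dia_mmHg,sv_ml\n")
        for b in beats:
            sv = "" if b.stroke_volume is None else f"{b.stroke_volume:.6g}"
            fh.write(f"{b.t:.6g},{b.systolic:.6g},{b.diastolic:.6g},{sv}\n")


def read_beats_csv(path) -> list[Beat]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        sv = None if pd.isna(r.sv_ml) else float(r.sv_ml)
        out.append(Beat(t=float(r.t_s), systolic=float(r.sys_mmHg), diastolic=float(r.dia_mmHg), stroke_volume=sv))
    return out
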