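import math

import pytest

from refit.controller import ControllerConfig
from refit.pig_sim import PigParams
from refit.signal_features import Beat, HemoSnapshot, PressureSample, SignalConfig


@pytest.fixture
def signal_cfg() -> SignalConfig:
    return SignalConfig()


@pytest.fixture
def controller_cfg() -> ControllerConfig:
    return ControllerConfig(weight_kg=30.0)


@pytest.fixture
def pig_params() -> PigParams:
    return PigParams()


def make_pulse_wave(
    n_beats: int = 10,
    period: float = 1.0,
    systolic: float = 120.0,
    diastolic: float = 80.0,
    fs: float = 100.0,
    t0: float = 0.0,
):
    """Constructed waveform of identical beats: dia + PP * sin^2(pi u)."""
    samples = []
    n = int(round(n_beats * period * fs))
    pp = systolic - diastolic
    for i in range(n):
        t = t0 + i / fs
        u = (t % period) / period
        samples.append(PressureSample(t=t, p=diastolic + pp * math.sin(math.pi * u) ** 2))
    return samples


def make_beats(pulse_pressures, dt: float = 1.0, t0: float = 0.0, dia: float = 70.0, svs=None):
    """Beat list with prescribed pulse pressures (and optionally stroke volumes)."""
    out = []
    for i, pp in enumerate(pulse_pressures):
        sv = None if svs is None else svs[i]
        out.append(Beat(t=t0 + i * dt, systolic=dia + pp, diastolic=dia, stroke_volume=sv))
    return out


def snap(t=0.0, map=65.0, hr=90.0, ppv=20.0, svv=20.0, eadyn=1.0, valid=True) -> HemoSnapshot:
    return HemoSnapshot(t=t, map=map, hr=hr, ppv=ppv, svv=svv, eadyn=eadyn, valid=valid)
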