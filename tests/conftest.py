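import numpy as np
import pytest
from hypothesis import settings

from empredict.calibration import AdditionEvent, FluorescenceTrace, IonicContext

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def context() -> IonicContext:
    return IonicContext()  # HTF: 5 mM K+ out, 120 mM in, 37 C


def make_step_trace(
    levels,
    event_kinds=None,
    segment_s: float = 60.0,
    sample_rate: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    kcl_volume_ul: float = 10.0,
    kcl_mM: float = 1000.0,
):
    """Piecewise-constant trace: levels[0] before the first event, then one
    level per event.  Events default to valinomycin followed by KCl."""
    levels = list(levels)
    n_events = len(levels) - 1
    if event_kinds is None:
        event_kinds = ["valinomycin"] + ["KCl"] * (n_events - 1)
    duration = segment_s * (n_events + 1)
    n = int(duration * sample_rate) + 1
    time = np.arange(n) / sample_rate
    fl = np.empty(n)
    event_times = [segment_s * (i + 1) for i in range(n_events)]
    bounds = [0.0] + event_times + [np.inf]
    for i, lvl in enumerate(levels):
        mask = (time >= bounds[i]) & (time < bounds[i + 1])
        fl[mask] = lvl
    if noise_sd > 0:
        fl = fl + np.random.default_rng(seed).normal(0, noise_sd, n)
    events = [
        AdditionEvent(
            time=t,
            kind=k,
            aliquot_volume=0.0 if k == "valinomycin" else kcl_volume_ul,
            aliquot_concentration=0.0 if k == "valinomycin" else kcl_mM,
        )
        for t, k in zip(event_times, event_kinds)
    ]
    return FluorescenceTrace(time=time, fluorescence=fl, events=events,
                             initial_volume=2.0)


@pytest.fixture
def step_trace_factory():
    return make_step_trace
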