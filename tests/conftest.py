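"""Shared fixtures: simulated beats are expensive enough to build once."""

from __future__ import annotations

import numpy as np
import pytest

from pvbeat.signal import resample_uniform, segment_beats
from pvbeat.simulator import SimulatorParams, simulate_beat


@pytest.fixture(scope="session")
def sim_beat():
    """Severe-AS preset beat with default (1 mmHg) noise, seed 42."""
    return simulate_beat(SimulatorParams(seed=42))


@pytest.fixture(scope="session")
def sim_beat_clean():
    """Noiseless severe-AS beat for deterministic landmark checks."""
    return simulate_beat(SimulatorParams(seed=42, noise_sd=0.0))


@pytest.fixture(scope="session")
def trace500(sim_beat):
    """The noisy beat resampled to the 500 Hz working rate."""
    return resample_uniform(sim_beat.trace, 500.0)


@pytest.fixture(scope="session")
def beats500(trace500):
    return segment_beats(trace500)


def beat_frame_truth(sim, trace, beat):
    """True valve/end-systole times mapped into a beat's local time frame."""
    t = sim.truth
    cyc = t["cycle_duration"]
    phase = float(trace.time[beat.start_index]) % cyc
    return {
        "open": (t["valve_open_time"] - phase) % cyc,
        "close": (t["valve_close_time"] - phase) % cyc,
        "t_es": (t["t_es"] - phase) % cyc,
    }
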