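import numpy as np
import pytest

from hfoloc import SimConfig, simulate_hfo_recording, detect_hfos


def band_of(event) -> str:
    return "ripple" if event.kind == "ripple-burst" else "fast-ripple"


def match_events(retained, truth_bursts, slack: float = 0.02):
    """(recall, precision) of retained events against planted bursts."""
    hits = 0
    for e in truth_bursts:
        m = retained[(retained.channel == e.channel)
                     & (retained.band == band_of(e))
                     & (retained.start_s < e.onset + e.duration)
                     & (retained.end_s > e.onset)]
        if len(m):
            hits += 1
    tp = 0
    for r in retained.itertuples():
        if any(e.channel == r.channel and band_of(e) == r.band
               and r.start_s < e.onset + e.duration + slack
               and r.end_s > e.onset - slack
               for e in truth_bursts):
            tp += 1
    recall = hits / len(truth_bursts) if truth_bursts else 1.0
    precision = tp / len(retained) if len(retained) else 1.0
    return recall, precision


@pytest.fixture(scope="session")
def small_detection():
    """4-channel, 60-s seeded recording with planted events, detected."""
    config = SimConfig(n_channels=4, duration=60.0, seed=3)
    rec, truth = simulate_hfo_recording(config, n_ripples=8, n_frs=4,
                                        n_spikes=6)
    events = detect_hfos(rec)
    return rec, truth, events


@pytest.fixture(scope="session")
def study_scale_detection():
    """10-channel, 5-min recording with 40 ripples, 20 fast ripples and
    30 spike transients at 10-15x background SD, detected."""
    config = SimConfig(n_channels=10, duration=300.0, seed=1)
    rec, truth = simulate_hfo_recording(config, n_ripples=40, n_frs=20,
                                        n_spikes=30)
    events = detect_hfos(rec)
    return rec, truth, events
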