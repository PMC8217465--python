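"""Synthetic iEEG and cohort generation with known ground truth.

The generator emulates the features the detector must separate: a 1/f^alpha
Gaussian background, band-limited oscillatory bursts in the ripple
(80-200 Hz) and fast-ripple (200-500 Hz) bands with at least four cycles,
and sharp non-oscillatory spike transients whose filter ringing mimics an
HFO (the false-positive generator the Gibbs discriminator must reject).
Burst amplitudes are expressed in multiples of the local background standard
deviation so detector thresholds map directly onto ground truth.

Randomness: one integer master seed; independent sub-streams are derived per
channel and per stochastic decision through ``numpy.random.SeedSequence``
spawning, so simulations are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import IEEGRecording

RIPPLE_BAND = (80.0, 200.0)
FR_BAND = (200.0, 500.0)

TABLE1_COLUMNS = ["Patient", "Sex/Age", "Onset/Fre", "Electrode", "PET-MRI",
                  "FLAWS", "HFOs", "Overlapped", "Removing", "Outcome"]


@dataclass
class SimConfig:
    """Background-simulation configuration.

    ``noise_exponent`` is the spectral slope alpha of the 1/f^alpha
    background (alpha=1, "pink", is the standard EEG approximation);
    ``noise_sigma`` is the per-channel standard deviation in signal units
    (microvolts by convention).
    """

    n_channels: int = 10
    duration: float = 300.0
    sample_rate: float = 4096.0
    noise_sigma: float = 20.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 1000:
            raise ValueError("sample_rate must exceed 1000 Hz "
                             "(must resolve 500 Hz)")


@dataclass
class GroundTruthEvent:
    """A planted burst or spike transient.

    ``amplitude`` is in multiples of the local background SD; ``frequency``
    and ``n_cycles`` apply to bursts only. Detectable bursts carry at least
    four cycles.
    """

    channel: str
    kind: Literal["ripple-burst", "fr-burst", "spike-transient"]
    onset: float
    duration: float
    amplitude: float
    frequency: float | None = None
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.kind in ("ripple-burst", "fr-burst"):
            band = RIPPLE_BAND if self.kind == "ripple-burst" else FR_BAND
            if self.frequency is None or not (band[0] <= self.frequency
                                              <= band[1]):
                raise ValueError(
                    f"{self.kind} frequency {self.frequency} outside "
                    f"{band[0]}-{band[1]} Hz")

    @property
    def band(self) -> str | None:
        return {"ripple-burst": "ripple",
                "fr-burst": "fast-ripple"}.get(self.kind)


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic surgical cohort table.

    The structure mirrors a clinical cohort summary: per-patient region sets
    marked by three modalities (PET-MRI, FLAWS, HFOs), the resected set, and
    an Engel outcome. Complete removal of the HFO-marked set is made to
    correlate with outcome through the two conditional probabilities.
    """

    n_patients: int = 15
    p_seizure_free: float = 1 / 3
    region_vocabulary: Sequence[str] = ("LF", "LT", "LP", "LH", "RF", "RT",
                                        "RP", "RH", "RA", "RCR")
    p_complete_removal_given_good: float = 0.9
    p_complete_removal_given_poor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_seizure_free, self.p_complete_removal_given_good,
                  self.p_complete_removal_given_poor):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not self.region_vocabulary:
            raise ValueError("region_vocabulary must be non-empty")


# ---------------------------------------------------------------------------
# Background + event insertion
# ---------------------------------------------------------------------------

def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^alpha noise of unit SD via spectral shaping."""
    nf = n // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros(nf)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    spec[0] = 0.0                       # zero mean
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_background(config: SimConfig) -> IEEGRecording:
    """1/f^alpha Gaussian background, per-channel independent.

    Each channel is normalized to exactly ``noise_sigma`` SD. Deterministic
    given ``config.seed``; channel i uses the i-th spawned sub-stream of the
    master seed.
    """
    n = int(round(config.duration * config.sample_rate))
    streams = np.random.SeedSequence(config.seed).spawn(config.n_channels)
    samples = np.empty((config.n_channels, n))
    for ch, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        samples[ch] = _pink_noise(n, config.noise_exponent, rng) \
            * config.noise_sigma
    labels = [f"S{ch + 1}" for ch in range(config.n_channels)]
    return IEEGRecording(samples, config.sample_rate, labels)


def _local_sd(recording: IEEGRecording, ch: int, onset: float,
              duration: float, margin: float = 0.5) -> float:
    fs = recording.sample_rate
    i0 = max(0, int((onset - margin) * fs))
    i1 = min(recording.n_samples, int((onset + duration + margin) * fs))
    return float(recording.samples[ch, i0:i1].std())


def insert_oscillation(recording: IEEGRecording,
                       event: GroundTruthEvent) -> IEEGRecording:
    """Add a Hann-tapered sinusoidal burst; returns a new recording.

    The burst has ``event.n_cycles`` cycles at ``event.frequency`` (its
    duration is therefore ``n_cycles / frequency``) and peak amplitude
    ``event.amplitude`` times the local background SD. All other samples
    are unchanged.
    """
    if event.kind not in ("ripple-burst", "fr-burst"):
        raise ValueError(f"insert_oscillation got kind {event.kind!r}")
    fs = recording.sample_rate
    if not 0 < event.frequency < fs / 2:
        raise ValueError(f"burst frequency {event.frequency} Hz outside "
                         f"(0, {fs / 2}) Hz")
    if event.onset + event.duration > recording.duration + 1e-9:
        raise ValueError("event does not fit inside the recording")
    ch = recording.channel_labels.index(event.channel)
    out = recording.copy()
    i0 = int(round(event.onset * fs))
    n = int(round(event.duration * fs))
    if n < 1:
        return out
    t = np.arange(n) / fs
    envelope = np.hanning(n)
    amp = event.amplitude * _local_sd(recording, ch, event.onset,
                                      event.duration)
    out.samples[ch, i0:i0 + n] += (
        amp * envelope * np.sin(2 * np.pi * event.frequency * t))
    return out


def insert_transient(recording: IEEGRecording,
                     event: GroundTruthEvent) -> IEEGRecording:
    """Add a Gaussian-envelope monophasic deflection (a sharp spike).

    The spike carries no oscillatory component: its raw spectrum is monotone
    decreasing across the ripple band, but the bandpass filter rings on the
    sharp edge, producing a false-HFO candidate. ``event.duration`` is the
    full width of the deflection (+- 3 sigma of the Gaussian envelope) and
    must not exceed 80 ms.
    """
    if event.kind != "spike-transient":
        raise ValueError(f"insert_transient got kind {event.kind!r}")
    if event.duration > 0.080 + 1e-9:
        raise ValueError("spike width must be <= 80 ms")
    if event.onset + event.duration > recording.duration + 1e-9:
        raise ValueError("event does not fit inside the recording")
    fs = recording.sample_rate
    ch = recording.channel_labels.index(event.channel)
    out = recording.copy()
    center = event.onset + event.duration / 2.0
    sigma = event.duration / 6.0
    i0 = int(round(event.onset * fs))
    n = int(round(event.duration * fs))
    if n < 1:
        return out
    t = np.arange(i0, i0 + n) / fs
    amp = event.amplitude * _local_sd(recording, ch, event.onset,
                                      event.duration)
    out.samples[ch, i0:i0 + n] += amp * np.exp(-((t - center) ** 2)
                                               / (2 * sigma ** 2))
    return out


def insert_event(recording: IEEGRecording,
                 event: GroundTruthEvent) -> IEEGRecording:
    if event.kind == "spike-transient":
        return insert_transient(recording, event)
    return insert_oscillation(recording, event)


def write_ground_truth(events: Sequence[GroundTruthEvent], path) -> None:
    """Ground-truth ledger as JSON; times in seconds from recording start."""
    with open(path, "w") as fh:
        json.dump([asdict(e) for e in events], fh, indent=1)


def read_ground_truth(path) -> list[GroundTruthEvent]:
    with open(path) as fh:
        return [GroundTruthEvent(**d) for d in json.load(fh)]


def simulate_hfo_recording(
    config: SimConfig,
    n_ripples: int = 40,
    n_frs: int = 20,
    n_spikes: int = 30,
    amplitude_range: tuple[float, float] = (10.0, 15.0),
) -> tuple[IEEGRecording, list[GroundTruthEvent]]:
    """Background plus randomly placed bursts and spikes, non-overlapping.

    Events are spread uniformly over channels and time with a 0.5-s
    exclusion margin between events on the same channel. Ripple bursts draw
    frequencies from 90-190 Hz, fast-ripple bursts from 220-450 Hz, both
    with 8-16 cycles; spikes are 15-40 ms wide. Returns the recording and
    the complete ground-truth ledger (one entry per insertion).
    """
    rec = generate_background(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(config.n_channels + 1)[-1])
    events: list[GroundTruthEvent] = []
    occupied: dict[str, list[tuple[float, float]]] = {
        lab: [] for lab in rec.channel_labels}

    def place(duration: float) -> tuple[str, float] | None:
        for _ in range(200):
            lab = rec.channel_labels[rng.integers(rec.n_channels)]
            onset = rng.uniform(1.0, config.duration - duration - 1.0)
            if all(onset + duration + 0.5 < a or b + 0.5 < onset
                   for a, b in occupied[lab]):
                occupied[lab].append((onset, onset + duration))
                return lab, onset
        return None

    kinds = (["ripple-burst"] * n_ripples + ["fr-burst"] * n_frs
             + ["spike-transient"] * n_spikes)
    for kind in kinds:
        if kind == "spike-transient":
            duration = float(rng.uniform(0.015, 0.040))
            freq = n_cycles = None
        else:
            freq = float(rng.uniform(*(
                (90.0, 190.0) if kind == "ripple-burst" else (220.0, 450.0))))
            n_cycles = int(rng.integers(8, 17))
            duration = n_cycles / freq
        spot = place(duration)
        if spot is None:        # channel-time budget exhausted
            continue
        lab, onset = spot
        ev = GroundTruthEvent(
            channel=lab, kind=kind, onset=onset, duration=duration,
            amplitude=float(rng.uniform(*amplitude_range)),
            frequency=freq, n_cycles=n_cycles)
        rec = insert_event(rec, ev)
        events.append(ev)
    return rec, events


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Synthetic cohort table in the clinical summary-table schema.

    Columns are the printed clinical-table names plus machine-readable
    auxiliary columns (``HFOComplete``, ``ElectrodesCoverImaging``,
    ``ChannRem_HFOs``, ``ChannNonRem_HFOs``, ``Good``) used by the
    evaluation layer. Complete removal of the HFO-marked regions is drawn
    conditionally on outcome per the spec probabilities, so an association
    between complete removal and seizure freedom is built in.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    vocab = list(spec.region_vocabulary)
    rows = []
    for pid in range(1, spec.n_patients + 1):
        good = bool(rng.random() < spec.p_seizure_free)
        outcome = "I" if good else rng.choice(["II", "III"])
        p_complete = (spec.p_complete_removal_given_good if good
                      else spec.p_complete_removal_given_poor)
        complete = bool(rng.random() < p_complete)

        n_hfo = int(rng.integers(1, min(3, len(vocab)) + 1))
        hfo = set(rng.choice(vocab, size=n_hfo, replace=False))
        # imaging modalities overlap the HFO set partially
        def jitter(base: set) -> set:
            s = set(base)
            if len(s) > 1 and rng.random() < 0.3:
                s.discard(sorted(s)[int(rng.integers(len(s)))])
            if rng.random() < 0.4:
                s.add(vocab[int(rng.integers(len(vocab)))])
            return s
        pet, flaws = jitter(hfo), jitter(hfo)

        if complete:
            removed = set(hfo)
        else:
            removed = set(hfo)
            removed.discard(sorted(removed)[int(rng.integers(len(removed)))])
        sets = [pet, flaws, hfo]
        overlapped = set()
        for i in range(3):
            for j in range(i + 1, 3):
                overlapped |= sets[i] & sets[j]

        n_marked = int(rng.integers(4, 13))
        n_rem = n_marked if complete else int(rng.integers(0, n_marked))
        rows.append({
            "Patient": pid,
            "Sex/Age": f"{rng.choice(['M', 'F'])}/{rng.integers(10, 50)}",
            "Onset/Fre": f"{rng.integers(1, 20)}/{rng.choice(['d', 'w', 'm'])}",
            "Electrode": "SEEG",
            "PET-MRI": ",".join(sorted(pet)) if pet else "Normal",
            "FLAWS": ",".join(sorted(flaws)) if flaws else "Normal",
            "HFOs": ",".join(sorted(hfo)),
            "Overlapped": ",".join(sorted(overlapped)) if overlapped
                          else "Normal",
            "Removing": ",".join(sorted(removed)) if removed else "Normal",
            "Outcome": outcome,
            "HFOComplete": complete,
            "ElectrodesCoverImaging": bool(rng.random() < 0.8),
            "ChannRem_HFOs": n_rem,
            "ChannNonRem_HFOs": n_marked - n_rem,
            "Good": good,
        })
    columns = TABLE1_COLUMNS + ["HFOComplete", "ElectrodesCoverImaging",
                                "ChannRem_HFOs", "ChannNonRem_HFOs", "Good"]
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Cohort table as CSV with the clinical-table column names first."""
    cohort.to_csv(path, index=False)
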