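"""Automated ripple / fast-ripple detection.

The detector follows a five-stage pipeline per channel and per band:

1. zero-phase FIR bandpass (80-200 Hz ripples, 200-500 Hz fast ripples);
2. extraction of all peaks of the absolute filtered signal;
3. baseline estimation from the peak point distribution curve (PPDC): peak
   amplitudes within each 5-s window are sorted ascending and the curve's
   turning point — the index of maximum perpendicular distance to the chord
   joining the curve's endpoints — separates baseline peaks (before it)
   from event peaks; the baseline mean and SD are taken over the baseline
   peaks;
4. candidate events: at least eight consecutive peaks above mean + 3 SD
   containing at least six consecutive peaks above mean + 10 SD (ripples)
   or mean + 9.5 SD (fast ripples);
5. rejection of false HFOs caused by filter ringing on sharp transients
   (Gibbs effect): the raw-segment spectrum of a genuine oscillation has a
   local peak inside the detection band, whereas spike ringing rides on a
   monotone-decreasing spectrum, so the power at the in-band spectral peak
   minus the power at a frequency offset below it is positive only for
   genuine events.

Eight absolute peaks correspond to four oscillation cycles, the conventional
minimum for an HFO. Thresholds are relative to the per-window baseline, so
detection is invariant to rescaling a channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

from .io import IEEGRecording

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["channel", "band", "start_s", "end_s", "center_s",
                 "n_peaks_long", "n_peaks_short", "peak_amp_uv",
                 "gibbs_delta", "retained"]


class DegenerateBaselineError(RuntimeError):
    """A channel produced no peaks; no baseline can be estimated."""


@dataclass
class DetectionParams:
    """All detector thresholds, with clinical defaults.

    ``long_run_peaks`` peaks above ``long_run_sd`` SD define a candidate
    run; it must contain ``short_run_peaks`` consecutive peaks above the
    band-specific high threshold (``ripple_short_run_sd`` /
    ``fr_short_run_sd``). ``baseline_window`` is the span of the moving
    baseline window in seconds. ``gibbs_offset_fraction`` sets the spectral
    comparison offset as a fraction of the band width (clipped to
    >= 30 Hz). ``sliding_baseline`` switches the 5-s windows from
    contiguous to a 1-s-hop sliding scheme.
    """

    ripple_band: tuple[float, float] = (80.0, 200.0)
    fr_band: tuple[float, float] = (200.0, 500.0)
    long_run_peaks: int = 8
    long_run_sd: float = 3.0
    short_run_peaks: int = 6
    ripple_short_run_sd: float = 10.0
    fr_short_run_sd: float = 9.5
    baseline_window: float = 5.0
    merge_gap: float = 0.010
    gibbs_offset_fraction: float = 0.5
    gibbs_margin: float = 0.050
    min_window_peaks: int = 20
    sliding_baseline: bool = False

    def __post_init__(self) -> None:
        if not (self.ripple_band[0] < self.ripple_band[1]
                <= self.fr_band[0] < self.fr_band[1]):
            raise ValueError(
                f"bands must be ordered and non-overlapping, got ripple "
                f"{self.ripple_band} and fast-ripple {self.fr_band}")
        if self.short_run_peaks > self.long_run_peaks:
            raise ValueError("short_run_peaks must be <= long_run_peaks")
        for v in (self.long_run_sd, self.ripple_short_run_sd,
                  self.fr_short_run_sd):
            if v <= 0:
                raise ValueError("SD multipliers must be > 0")

    def band(self, name: str) -> tuple[float, float]:
        return self.ripple_band if name == "ripple" else self.fr_band

    def short_run_sd(self, name: str) -> float:
        return (self.ripple_short_run_sd if name == "ripple"
                else self.fr_short_run_sd)


@dataclass
class PeakSeries:
    """Strict local maxima of the absolute filtered signal."""

    times: np.ndarray        # sample indices, strictly increasing
    amplitudes: np.ndarray   # absolute filtered amplitude at each peak

    def __len__(self) -> int:
        return self.times.size


@dataclass
class BaselineWindow:
    """Baseline statistics for one 5-s window of a channel."""

    start: int               # sample index, inclusive
    end: int                 # sample index, exclusive
    mean: float
    sd: float
    turning_index: int       # rank position of the PPDC turning point
    n_peaks: int
    whole_channel: bool = False   # True when the <20-peak fallback fired


# ---------------------------------------------------------------------------
# Filtering and peaks
# ---------------------------------------------------------------------------

def design_fir(band: tuple[float, float], sample_rate: float) -> np.ndarray:
    """Symmetric (linear-phase) bandpass FIR for the given band."""
    transition = float(np.clip(0.25 * band[0], 15.0, 60.0))
    numtaps = int(np.ceil(3.3 * sample_rate / transition))
    numtaps += 1 - numtaps % 2           # odd length -> integer group delay
    return sps.firwin(numtaps, list(band), pass_zero=False, fs=sample_rate)


def bandpass_zero_phase(x: np.ndarray, sample_rate: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Zero-phase bandpass; output has the input's length.

    Uses a symmetric FIR whose group delay is compensated exactly
    (convolution mode ``same`` with an odd-length symmetric kernel), so the
    net phase shift is zero at every frequency.
    """
    if not 0 < band[0] < band[1] < sample_rate / 2:
        raise ValueError(f"band {band} outside (0, {sample_rate / 2}) Hz")
    x = np.asarray(x, dtype=float)
    b = design_fir(band, sample_rate)
    return sps.fftconvolve(x, b, mode="same")


def extract_peaks(filtered: np.ndarray) -> PeakSeries:
    """All strict local maxima of ``|filtered|``; plateaus take the first
    index."""
    a = np.abs(np.asarray(filtered, dtype=float))
    idx, props = sps.find_peaks(a, plateau_size=1)
    left = props.get("left_edges")
    times = left if left is not None and left.size else idx
    return PeakSeries(times=times.astype(np.int64), amplitudes=a[times])


# ---------------------------------------------------------------------------
# PPDC baseline
# ---------------------------------------------------------------------------

def ppdc_turning_point(sorted_amps: np.ndarray) -> int:
    """Turning point of the peak point distribution curve.

    ``sorted_amps`` is the ascending-sorted peak amplitudes. The turning
    point is the index of maximum perpendicular distance from the curve to
    the chord joining its endpoints (knee detection). A flat curve has no
    knee; the last index is returned so that all peaks count as baseline.
    """
    y = np.asarray(sorted_amps, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("empty peak series")
    if n == 1:
        return 0
    x = np.arange(n, dtype=float)
    dx, dy = float(n - 1), float(y[-1] - y[0])
    dist = np.abs(dy * x - dx * (y - y[0])) / np.hypot(dx, dy)
    if dist.max() <= 1e-12 * max(1.0, abs(float(y[-1]))):
        return n - 1
    return int(np.argmax(dist))


def _baseline_stats(amps: np.ndarray) -> tuple[float, float, int]:
    order = np.sort(np.asarray(amps, dtype=float))
    k = ppdc_turning_point(order)
    base = order[:k] if k > 0 else order[:1]
    mean = float(base.mean())
    sd = float(base.std(ddof=0))
    if sd == 0.0:
        sd = 0.05 * mean            # degenerate window: nominal spread
    return mean, sd, k


def ppdc_baseline(peaks: PeakSeries, sample_rate: float, n_samples: int,
                  params: DetectionParams | None = None
                  ) -> list[BaselineWindow]:
    """Per-5-s-window baseline mean/SD from the PPDC turning point.

    Windows are contiguous and non-overlapping (a 1-s-hop sliding variant is
    available via ``params.sliding_baseline``); a window with fewer than
    ``min_window_peaks`` peaks falls back to the whole-channel PPDC.
    """
    params = params or DetectionParams()
    if len(peaks) == 0:
        raise DegenerateBaselineError("channel has no peaks")
    n_samples = int(n_samples)
    win = int(round(params.baseline_window * sample_rate))
    hop = int(round(sample_rate)) if params.sliding_baseline else win
    global_stats: tuple[float, float, int] | None = None
    out: list[BaselineWindow] = []
    for start in range(0, max(n_samples, 1), hop):
        end = min(start + win, n_samples)
        sel = (peaks.times >= start) & (peaks.times < end)
        amps = peaks.amplitudes[sel]
        if amps.size >= params.min_window_peaks:
            mean, sd, k = _baseline_stats(amps)
            whole = False
        else:
            if global_stats is None:
                global_stats = _baseline_stats(peaks.amplitudes)
                logger.debug("window %d-%d has %d peaks; whole-channel "
                             "PPDC fallback", start, end, amps.size)
            mean, sd, k = global_stats
            whole = True
        out.append(BaselineWindow(start=start, end=end, mean=mean, sd=sd,
                                  turning_index=k, n_peaks=amps.size,
                                  whole_channel=whole))
        if end >= n_samples:
            break
    return out


def _window_for(baselines: Sequence[BaselineWindow],
                t: int) -> BaselineWindow:
    for w in baselines:
        if w.start <= t < w.end:
            return w
    return baselines[-1]


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------

def _max_consecutive(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def detect_candidates(filtered: np.ndarray, baselines: Sequence[BaselineWindow],
                      band_name: str, sample_rate: float,
                      params: DetectionParams | None = None,
                      channel: str = "") -> pd.DataFrame:
    """Candidate events for one channel and band (retention undecided).

    A candidate is a maximal run of at least ``long_run_peaks`` consecutive
    peaks above mean + 3 SD (each peak judged against its own window's
    baseline) that contains at least ``short_run_peaks`` consecutive peaks
    above the band's high threshold, with both statistics of the short run
    drawn from the window holding the run's first peak. Candidates closer
    than ``merge_gap`` are merged.
    """
    params = params or DetectionParams()
    peaks = extract_peaks(filtered)
    rows: list[dict] = []
    if len(peaks) == 0:
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    long_thr = np.empty(len(peaks))
    for i, t in enumerate(peaks.times):
        w = _window_for(baselines, int(t))
        long_thr[i] = w.mean + params.long_run_sd * w.sd
    above = peaks.amplitudes > long_thr

    # maximal runs of consecutive above-threshold peaks
    i = 0
    n = len(peaks)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run = slice(i, j + 1)
        run_len = j - i + 1
        if run_len >= params.long_run_peaks:
            w0 = _window_for(baselines, int(peaks.times[i]))
            high = w0.mean + params.short_run_sd(band_name) * w0.sd
            n_short = _max_consecutive(peaks.amplitudes[run] > high)
            if n_short >= params.short_run_peaks:
                amps = peaks.amplitudes[run]
                # amplitude-weighted center: the event midpoint, insensitive
                # to which marginal edge peak happens to clear the threshold
                center = float((peaks.times[run] * amps).sum()
                               / amps.sum()) / sample_rate
                rows.append({
                    "channel": channel,
                    "band": band_name,
                    "start_s": peaks.times[i] / sample_rate,
                    "end_s": peaks.times[j] / sample_rate,
                    "center_s": center,
                    "n_peaks_long": run_len,
                    "n_peaks_short": int(n_short),
                    "peak_amp_uv": float(peaks.amplitudes[run].max()),
                    "gibbs_delta": np.nan,
                    "retained": pd.NA,
                })
        i = j + 1

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return merge_events(events, params.merge_gap)


def merge_events(events: pd.DataFrame, merge_gap: float) -> pd.DataFrame:
    """Fuse same-channel same-band events separated by less than
    ``merge_gap`` seconds."""
    if events.empty:
        return events
    merged: list[dict] = []
    for (_, _), grp in events.groupby(["channel", "band"], sort=False):
        grp = grp.sort_values("start_s")
        cur = None
        for row in grp.to_dict("records"):
            if cur is not None and row["start_s"] - cur["end_s"] < merge_gap:
                cur["end_s"] = max(cur["end_s"], row["end_s"])
                w1, w2 = cur["n_peaks_long"], row["n_peaks_long"]
                cur["center_s"] = (cur["center_s"] * w1
                                   + row["center_s"] * w2) / (w1 + w2)
                cur["n_peaks_long"] += row["n_peaks_long"]
                cur["n_peaks_short"] = max(cur["n_peaks_short"],
                                           row["n_peaks_short"])
                cur["peak_amp_uv"] = max(cur["peak_amp_uv"],
                                         row["peak_amp_uv"])
            else:
                if cur is not None:
                    merged.append(cur)
                cur = dict(row)
        if cur is not None:
            merged.append(cur)
    return pd.DataFrame(merged, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Gibbs-ringing rejection
# ---------------------------------------------------------------------------

def gibbs_power_difference(raw_segment: np.ndarray,
                           band: tuple[float, float], sample_rate: float,
                           params: DetectionParams | None = None
                           ) -> tuple[float, bool]:
    """Spectral-peak-versus-offset power difference on the raw segment.

    Let ``f*`` be the frequency of maximum raw-segment power inside the
    detection band (power locally averaged over +-10 Hz). The discriminator
    is ``delta = P(f*) - P(f* - offset)`` with ``offset`` equal to
    ``gibbs_offset_fraction`` of the band width, clipped to >= 30 Hz. A
    genuine oscillation concentrates power at its frequency, so delta > 0;
    filter ringing on a sharp transient rides on a monotone-decreasing
    spectrum, so delta <= 0 and the event is rejected.
    """
    params = params or DetectionParams()
    x = np.asarray(raw_segment, dtype=float)
    if x.size < sample_rate / 10:
        raise ValueError(
            f"segment of {x.size} samples too short for 10 Hz resolution "
            f"at fs={sample_rate:g}")
    nfft = next_fast_len(max(x.size, int(sample_rate)))
    freqs, psd = sps.periodogram(x, fs=sample_rate, nfft=nfft,
                                 detrend="constant")

    df = freqs[1] - freqs[0]
    half = max(1, int(round(10.0 / df)))
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    smooth = np.convolve(psd, kernel, mode="same")

    in_band = (freqs >= band[0]) & (freqs <= band[1])
    k_star = np.flatnonzero(in_band)[int(np.argmax(smooth[in_band]))]
    offset_hz = max(params.gibbs_offset_fraction * (band[1] - band[0]), 30.0)
    k_off = k_star - int(round(offset_hz / df))
    k_off = max(k_off, 0)
    delta = float(smooth[k_star] - smooth[k_off])
    return delta, delta > 0


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_hfos(recording: IEEGRecording,
                params: DetectionParams | None = None) -> pd.DataFrame:
    """Run the full detector on an already-bipolar, segment-selected
    recording.

    Returns the event table (one row per candidate, ``retained`` True only
    for events passing the Gibbs check). Channels whose filtered signal
    yields no peaks are skipped and logged.
    """
    params = params or DetectionParams()
    fs = recording.sample_rate
    margin = int(round(params.gibbs_margin * fs))
    min_seg = int(np.ceil(fs / 10))
    tables: list[pd.DataFrame] = []
    for ch, label in enumerate(recording.channel_labels):
        raw = recording.samples[ch]
        for band_name in ("ripple", "fast-ripple"):
            band = params.band(band_name)
            if band[1] >= fs / 2:
                logger.warning("band %s exceeds Nyquist at fs=%g; skipped",
                               band_name, fs)
                continue
            filtered = bandpass_zero_phase(raw, fs, band)
            peaks = extract_peaks(filtered)
            if len(peaks) == 0:
                logger.warning("channel %s: no peaks in %s band; skipped",
                               label, band_name)
                continue
            baselines = ppdc_baseline(peaks, fs, recording.n_samples, params)
            cands = detect_candidates(filtered, baselines, band_name, fs,
                                      params, channel=label)
            if cands.empty:
                continue
            deltas, keeps = [], []
            for row in cands.itertuples():
                i0 = int(row.start_s * fs) - margin
                i1 = int(row.end_s * fs) + margin
                # widen symmetrically to the minimum spectral length
                if i1 - i0 < min_seg:
                    pad = (min_seg - (i1 - i0) + 1) // 2
                    i0, i1 = i0 - pad, i1 + pad
                i0 = max(0, i0)
                i1 = min(recording.n_samples, i1)
                delta, keep = gibbs_power_difference(raw[i0:i1], band, fs,
                                                     params)
                deltas.append(delta)
                keeps.append(keep)
            cands = cands.assign(gibbs_delta=deltas, retained=keeps)
            tables.append(cands)
    if not tables:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def channel_rates(events: pd.DataFrame, duration_s: float,
                  channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Retained-event rate (events/min) per channel and band.

    ``channels`` lists all analyzed channels so that silent ones appear
    with rate 0 (needed for ranking).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    minutes = duration_s / 60.0
    if channels is None:
        channels = sorted(events["channel"].unique()) if not events.empty \
            else []
    rows = []
    retained = events[events["retained"] == True] if not events.empty \
        else events  # noqa: E712  (pandas boolean column)
    for ch in channels:
        for band in ("ripple", "fast-ripple"):
            if retained.empty:
                n = 0
            else:
                n = int(((retained["channel"] == ch)
                         & (retained["band"] == band)).sum())
            rows.append({"channel": ch, "band": band, "n_events": n,
                         "rate_per_min": n / minutes})
    return pd.DataFrame(rows, columns=["channel", "band", "n_events",
                                       "rate_per_min"])


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "retained" in df:
        df["retained"] = df["retained"].astype(bool)
    return df
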