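"""Recording container, EDF / delimited-text I/O, bipolar montage, and
slow-wave-sleep segment selection.

The analysis operates on interictal intracranial EEG. Recordings are held as
a channel × time matrix in microvolts together with the sampling rate and
channel labels; depth-electrode labels of the form ``A1``, ``A2``, ``B1`` are
parsed into shaft/contact structure so the bipolar montage (differences of
adjacent contacts on the same shaft) can be built without extra metadata.
"""

from __future__ import annotations

import json
import logging
import re
import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


class FormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


class NoSlowWaveSegmentError(RuntimeError):
    """No contiguous run of qualifying slow-wave epochs was found."""


@dataclass
class IEEGRecording:
    """Multichannel sampled iEEG signal.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array in microvolts.
    sample_rate
        Sampling rate in Hz.
    channel_labels
        One label per channel, e.g. ``["A1", "A2", "B1", ...]``.
    """

    samples: np.ndarray
    sample_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channel x time matrix")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def shaft_of(self) -> dict[str, tuple[str, int]]:
        """Map channel label -> (shaft id, contact index).

        Labels that do not match ``<letters><number>`` form their own
        single-contact shaft (they are skipped by the bipolar montage).
        """
        out: dict[str, tuple[str, int]] = {}
        for lab in self.channel_labels:
            m = _LABEL_RE.match(lab.strip())
            if m:
                out[lab] = (m.group(1), int(m.group(2)))
            else:
                out[lab] = (lab, 1)
        return out

    def copy(self) -> "IEEGRecording":
        return replace(self, samples=self.samples.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass
class EpochSelectionParams:
    """Parameters of the slow-wave-sleep segment rule.

    A segment qualifies when, in every consecutive 30-s epoch, delta-band
    power (0.5-4 Hz) exceeds ``delta_threshold`` of broadband power
    (0.5-45 Hz); ``segment_length`` seconds of such epochs are required.
    """

    epoch_length: float = 30.0
    delta_threshold: float = 0.25
    segment_length: float = 300.0
    delta_band: tuple[float, float] = (0.5, 4.0)
    total_band: tuple[float, float] = (0.5, 45.0)

    def __post_init__(self) -> None:
        if not 0 < self.delta_threshold < 1:
            raise ValueError("delta_threshold must be in (0, 1)")
        n = self.segment_length / self.epoch_length
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError(
                "segment_length must be an integer multiple of epoch_length")


# ---------------------------------------------------------------------------
# EDF + delimited text I/O
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: IEEGRecording, path) -> None:
    """Write a recording as 16-bit EDF (physical dimension microvolts).

    One data record per second; a trailing partial second is dropped (EDF
    records must be full). Channels are scaled independently to their own
    physical range, so the quantization step is ``range / 65535`` per
    channel.
    """
    fs = recording.sample_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise FormatError("EDF writer requires an integer sample rate")
    n_rec = recording.n_samples // spr
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    data = recording.samples[:, : n_rec * spr]
    ns = recording.n_channels

    phys_min, phys_max = [], []
    for ch in range(ns):
        lo, hi = float(np.min(data[ch])), float(np.max(data[ch]))
        if hi - lo < 1e-6:          # flat channel: avoid zero range
            hi, lo = hi + 1.0, lo - 1.0
        phys_min.append(lo)
        phys_max.append(hi)

    now = datetime(2000, 1, 1)
    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate 01-JAN-2000 X X X", 80),
        _edf_ascii(now.strftime("%d.%m.%y"), 8),
        _edf_ascii(now.strftime("%H.%M.%S"), 8),
        _edf_ascii(256 * (ns + 1), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_rec, 8),
        _edf_ascii("1", 8),
        _edf_ascii(ns, 4),
    ])

    def fmt8(x: float) -> str:
        for p in (2, 1, 0):
            s = f"{x:.{p}f}"
            if len(s) <= 8:
                return s
        return f"{x:.0e}"[:8]

    sig_fields = [
        [lab for lab in recording.channel_labels],          # label
        ["" for _ in range(ns)],                            # transducer
        ["uV"] * ns,                                        # physical dim
        [fmt8(v) for v in phys_min],
        [fmt8(v) for v in phys_max],
        ["-32768"] * ns,
        ["32767"] * ns,
        ["" for _ in range(ns)],                            # prefiltering
        [str(spr)] * ns,
        ["" for _ in range(ns)],                            # reserved
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    sig_header = b"".join(
        b"".join(_edf_ascii(v, w) for v in vals)
        for vals, w in zip(sig_fields, widths)
    )

    # re-read the formatted physical bounds so digital scaling matches the
    # header exactly (string round-trip is what any reader will use)
    pmin = np.array([float(fmt8(v)) for v in phys_min])
    pmax = np.array([float(fmt8(v)) for v in phys_max])
    gain = (pmax - pmin) / 65535.0

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            for ch in range(ns):
                seg = data[ch, r * spr:(r + 1) * spr]
                dig = np.round((seg - pmin[ch]) / gain[ch]) - 32768
                dig = np.clip(dig, -32768, 32767).astype("<i2")
                fh.write(struct.pack(f"<{spr}h", *dig))


def _read_edf(path) -> IEEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - error text varies
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    if not raw.info["sfreq"] or raw.info["sfreq"] <= 0:
        raise FormatError(f"EDF file {path}: missing or invalid sample rate")
    data_uv = raw.get_data() * 1e6          # mne returns volts
    return IEEGRecording(data_uv, float(raw.info["sfreq"]),
                         list(raw.ch_names))


def write_delimited(recording: IEEGRecording, path, sep: str = "\t") -> None:
    """Plain numeric matrix, one column per channel, header row of labels.

    The sampling rate is kept in a leading ``#`` comment so the file is
    self-describing.
    """
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={recording.sample_rate:g}\n")
        fh.write(sep.join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.samples.T, delimiter=sep, fmt="%.6f")


def _read_delimited(path, sample_rate: float | None) -> IEEGRecording:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"sample_rate_hz\s*=\s*([\d.eE+-]+)", first)
            if m:
                sample_rate = float(m.group(1))
            header = fh.readline()
        else:
            header = first
        labels = [c.strip() for c in re.split(r"[\t,;]", header.strip())]
        rows = []
        width = None
        for ln, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            vals = re.split(r"[\t,;]", line.strip())
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(
                    f"{path}: line {ln} has {len(vals)} values, "
                    f"expected {width} (channels of unequal length)")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value on line {ln}"
                                  ) from exc
    if sample_rate is None:
        raise FormatError(f"{path}: missing sample rate "
                          "(no '# sample_rate_hz=' comment and no argument)")
    if not rows:
        raise FormatError(f"{path}: no samples")
    mat = np.asarray(rows).T
    if mat.shape[0] != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} header labels but {mat.shape[0]} columns")
    return IEEGRecording(mat, sample_rate, labels)


def read_recording(path, format: str = "edf",
                   sample_rate: float | None = None) -> IEEGRecording:
    """Read a recording from EDF or delimited text.

    Shaft grouping is inferred from labels of the form ``<shaft><contact>``
    (A1, A2, B1, ...). ``sample_rate`` is only needed for delimited files
    lacking the ``# sample_rate_hz=`` comment.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path, sample_rate)
    raise ValueError(f"unknown format {format!r} (use 'edf' or 'delimited')")


def write_recording(recording: IEEGRecording, path,
                    format: str = "edf") -> None:
    if format == "edf":
        write_edf(recording, path)
    elif format == "delimited":
        write_delimited(recording, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Bipolar montage
# ---------------------------------------------------------------------------

def to_bipolar(recording: IEEGRecording) -> IEEGRecording:
    """Re-reference to a bipolar montage of adjacent contacts.

    For each shaft with k contacts, emits k-1 channels ``contact_i -
    contact_{i+1}`` labelled ``"<shaft>i-<shaft>(i+1)"``; shafts appear in
    input order, contacts ascending. A shaft with a single contact is
    skipped with a warning.
    """
    shaft_of = recording.shaft_of()
    shafts: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for idx, lab in enumerate(recording.channel_labels):
        shaft, contact = shaft_of[lab]
        if shaft not in shafts:
            shafts[shaft] = []
            order.append(shaft)
        shafts[shaft].append((contact, idx))

    rows, labels = [], []
    for shaft in order:
        contacts = sorted(shafts[shaft])
        if len(contacts) < 2:
            logger.warning("shaft %s has a single contact; skipped", shaft)
            continue
        for (c_lo, i_lo), (c_hi, i_hi) in zip(contacts, contacts[1:]):
            rows.append(recording.samples[i_lo] - recording.samples[i_hi])
            labels.append(f"{shaft}{c_lo}-{shaft}{c_hi}")
    mat = (np.asarray(rows) if rows
           else np.empty((0, recording.n_samples)))
    return IEEGRecording(mat, recording.sample_rate, labels)


# ---------------------------------------------------------------------------
# Slow-wave segment selection
# ---------------------------------------------------------------------------

def _band_power(freqs: np.ndarray, psd: np.ndarray,
                band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[mask], freqs[mask]))


def delta_proportion(epoch: np.ndarray, sample_rate: float,
                     params: EpochSelectionParams | None = None) -> float:
    """Fraction of broadband power carried by the delta band.

    Computed as averaged-periodogram (Welch) band power in ``delta_band``
    divided by band power in ``total_band``.
    """
    params = params or EpochSelectionParams()
    epoch = np.asarray(epoch, dtype=float)
    min_len = 2.0 / params.total_band[0]
    if epoch.size < min_len * sample_rate:
        raise ValueError(
            f"epoch of {epoch.size / sample_rate:.2f} s too short to resolve "
            f"{params.total_band[0]} Hz (need >= {min_len:.0f} s)")
    nperseg = min(epoch.size, int(round(4.0 * sample_rate)))
    freqs, psd = sps.welch(epoch, fs=sample_rate, nperseg=nperseg)
    total = _band_power(freqs, psd, params.total_band)
    if total <= 0:
        return 0.0
    return _band_power(freqs, psd, params.delta_band) / total


def select_slow_wave_segment(
    recording: IEEGRecording,
    params: EpochSelectionParams | None = None,
    exclusion_intervals: Sequence[tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Earliest 5-min run of consecutive 30-s slow-wave epochs.

    An epoch qualifies when the median across channels of
    :func:`delta_proportion` exceeds ``delta_threshold`` and it does not
    intersect any exclusion interval (e.g. windows around seizures).
    Returns the half-open interval ``[start_s, end_s)``; the start always
    falls on an epoch boundary.
    """
    params = params or EpochSelectionParams()
    if recording.duration < params.segment_length:
        raise ValueError(
            f"recording of {recording.duration:.0f} s shorter than the "
            f"{params.segment_length:.0f} s analysis segment")
    ep_len = int(round(params.epoch_length * recording.sample_rate))
    n_epochs = recording.n_samples // ep_len
    need = int(round(params.segment_length / params.epoch_length))

    ok = np.zeros(n_epochs, dtype=bool)
    props = np.zeros(n_epochs)
    for e in range(n_epochs):
        t0 = e * params.epoch_length
        t1 = t0 + params.epoch_length
        if exclusion_intervals and any(t0 < b and a < t1
                                       for a, b in exclusion_intervals):
            continue
        seg = recording.samples[:, e * ep_len:(e + 1) * ep_len]
        vals = [delta_proportion(seg[ch], recording.sample_rate, params)
                for ch in range(recording.n_channels)]
        props[e] = float(np.median(vals))
        ok[e] = props[e] > params.delta_threshold

    run = 0
    for e in range(n_epochs):
        run = run + 1 if ok[e] else 0
        if run >= need:
            start = (e - need + 1) * params.epoch_length
            return (start, start + params.segment_length)
    raise NoSlowWaveSegmentError(
        "no run of {} consecutive epochs with median delta proportion > {}"
        .format(need, params.delta_threshold))


def segment_report(recording: IEEGRecording,
                   params: EpochSelectionParams | None = None) -> dict:
    """JSON-ready report of the selected segment and per-epoch delta values."""
    params = params or EpochSelectionParams()
    start, end = select_slow_wave_segment(recording, params)
    ep_len = int(round(params.epoch_length * recording.sample_rate))
    n_epochs = recording.n_samples // ep_len
    props = []
    for e in range(n_epochs):
        seg = recording.samples[:, e * ep_len:(e + 1) * ep_len]
        vals = [delta_proportion(seg[ch], recording.sample_rate, params)
                for ch in range(recording.n_channels)]
        props.append(float(np.median(vals)))
    return {"start_s": start, "end_s": end,
            "epoch_delta_proportions": props}


def crop(recording: IEEGRecording, start_s: float,
         end_s: float) -> IEEGRecording:
    """Half-open time crop ``[start_s, end_s)``."""
    i0 = int(round(start_s * recording.sample_rate))
    i1 = int(round(end_s * recording.sample_rate))
    return IEEGRecording(recording.samples[:, i0:i1].copy(),
                         recording.sample_rate,
                         list(recording.channel_labels))
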