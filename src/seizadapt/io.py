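"""EEG I/O: EDF records, annotation tables, and window-sequence cropping.

The pipeline's raw unit is the :class:`EEGRecord` (leads x samples, microvolts);
its network-facing unit is the :class:`WindowSequence` — eight contiguous 2-s
multi-lead windows ending at a reference time, oldest first.

EDF reading is delegated to MNE; EDF writing is implemented here directly
(standard 16-bit EDF: 256-byte fixed header, 256 bytes per signal, int16
little-endian data records), which also documents the quantization bound the
round-trip tests rely on: one digital step of ``(phys_max-phys_min)/65535``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_WINDOWS = 8
WINDOW_SECONDS = 2.0
LOOKBACK_SECONDS = N_WINDOWS * WINDOW_SECONDS  # 16 s of history per sequence

#: channel-name substrings excluded from the EEG lead set on EDF ingest
DEFAULT_EXCLUDE_PATTERNS = ("ecg", "ekg", "emg", "eog", "annotation", "event",
                            "status", "resp", "photic", "ibi", "bursts", "suppr")

NORMAL_LABEL = "normal"


class AnnotationError(ValueError):
    """Malformed annotation table row."""


class InsufficientHistoryError(ValueError):
    """Reference time has less than the required lookback of signal."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class EEGRecord:
    """Multi-lead EEG signal matrix.

    signal : ``[n_leads, n_samples]`` in microvolts
    """

    signal: np.ndarray
    sampling_rate: float
    lead_names: list[str]
    record_id: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a [n_leads, n_samples] matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError(f"{len(self.lead_names)} lead names for "
                             f"{self.signal.shape[0]} signal rows")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def select_leads(self, names: list[str]) -> "EEGRecord":
        """Subset (and reorder) leads by name; missing leads are an error."""
        missing = [n for n in names if n not in self.lead_names]
        if missing:
            raise ValueError(f"record {self.record_id} lacks leads: {missing}")
        idx = [self.lead_names.index(n) for n in names]
        return EEGRecord(self.signal[idx], self.sampling_rate, list(names), self.record_id)


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated event: [onset, offset) in seconds from record start."""

    record_id: str
    onset: float
    offset: float
    label: str
    flagged: bool = False  # label outside the configured class set

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise AnnotationError(f"event {self.record_id} [{self.label}]: "
                                  f"need 0 <= onset < offset, got "
                                  f"[{self.onset}, {self.offset})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass
class WindowSequence:
    """Eight contiguous 2-s windows ending at ``reference_time``, oldest first.

    windows : ``[8, n_leads, window_samples]``
    domain_index : 0 = source cohort, 1 = target cohort, None = unassigned
    """

    windows: np.ndarray
    reference_time: float
    label: str | None = None
    domain_index: int | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[0] != N_WINDOWS:
            raise ValueError(f"expected [{N_WINDOWS}, n_leads, window_samples] "
                             f"windows, got shape {self.windows.shape}")
        if self.domain_index not in (None, 0, 1):
            raise ValueError("domain_index must be 0 (source), 1 (target) or None")


@dataclass(frozen=True)
class CropPolicy:
    """How window sequences are cut from annotated records.

    normalization: 'per-window' z-scores each lead within each 2-s window,
    'per-record' uses whole-record lead statistics, 'off' keeps raw microvolts.
    """

    window_seconds: float = WINDOW_SECONDS
    normal_stride: float = 16.0
    peri_ictal_margin: float = 60.0
    normalization: str = "per-window"
    normal_label: str = NORMAL_LABEL

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.normal_stride <= 0:
            raise ValueError("window_seconds and normal_stride must be positive")
        if self.normalization not in ("off", "per-window", "per-record"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def lookback(self) -> float:
        return N_WINDOWS * self.window_seconds


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def _normalize(windows: np.ndarray, record: EEGRecord, policy: CropPolicy) -> np.ndarray:
    eps = 1e-8
    if policy.normalization == "per-window":
        mu = windows.mean(axis=2, keepdims=True)
        sd = windows.std(axis=2, keepdims=True)
        return (windows - mu) / (sd + eps)
    if policy.normalization == "per-record":
        mu = record.signal.mean(axis=1)[None, :, None]
        sd = record.signal.std(axis=1)[None, :, None]
        return (windows - mu) / (sd + eps)
    return windows


def crop_sequence_at(record: EEGRecord, reference_time: float,
                     policy: CropPolicy = CropPolicy(), label: str | None = None,
                     domain_index: int | None = None) -> WindowSequence:
    """Cut the 8-window sequence ending exactly at ``reference_time``."""
    fs = record.sampling_rate
    win_samples = round(policy.window_seconds * fs)
    total = N_WINDOWS * win_samples
    end = round(reference_time * fs)
    if end > record.n_samples:
        raise InsufficientHistoryError(
            f"record {record.record_id}: reference {reference_time:.2f}s beyond "
            f"record end {record.duration:.2f}s")
    start = end - total
    if start < 0:
        raise InsufficientHistoryError(
            f"record {record.record_id}: reference {reference_time:.2f}s has less "
            f"than the required {policy.lookback:.0f}s of history")
    seg = record.signal[:, start:end]
    windows = seg.reshape(record.n_leads, N_WINDOWS, win_samples).transpose(1, 0, 2)
    windows = _normalize(windows, record, policy)
    return WindowSequence(windows, reference_time, label=label,
                          domain_index=domain_index, record_id=record.record_id)


def crop_sequences(record: EEGRecord, events: list[SeizureEvent],
                   policy: CropPolicy = CropPolicy(),
                   domain_index: int | None = None) -> list[WindowSequence]:
    """Crop training sequences from one annotated record.

    Per seizure event, two sequences are cut: one referenced at the event
    midpoint, one at the event onset.  Interictal (normal) sequences are
    sampled on a regular stride, excluding a peri-ictal margin around every
    event.  Reference points with insufficient history are skipped with a
    warning, not an error.
    """
    out: list[WindowSequence] = []
    own = [e for e in events if e.record_id == record.record_id]
    for ev in own:
        if ev.offset > record.duration + 1e-9:
            raise AnnotationError(f"event [{ev.onset}, {ev.offset}) exceeds record "
                                  f"{record.record_id} duration {record.duration:.2f}s")
        for ref in (ev.midpoint, ev.onset):
            try:
                out.append(crop_sequence_at(record, ref, policy, label=ev.label,
                                            domain_index=domain_index))
            except InsufficientHistoryError as err:
                logger.warning("skipping sequence: %s", err)
    # interictal sampling on a stride, away from every event
    t = policy.lookback
    while t <= record.duration + 1e-9:
        near_event = any(ev.onset - policy.peri_ictal_margin <= t
                         <= ev.offset + policy.peri_ictal_margin for ev in own)
        if not near_event:
            out.append(crop_sequence_at(record, t, policy, label=policy.normal_label,
                                        domain_index=domain_index))
        t += policy.normal_stride
    return out


# ---------------------------------------------------------------------------
# annotation tables (CSV: record_id, onset_s, offset_s, label)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["record_id", "onset_s", "offset_s", "label"]


def save_annotations(events: list[SeizureEvent], path: str | Path) -> None:
    df = pd.DataFrame([(e.record_id, e.onset, e.offset, e.label) for e in events],
                      columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)


def load_annotations(path: str | Path, records: dict[str, EEGRecord] | None = None,
                     known_labels: set[str] | None = None) -> list[SeizureEvent]:
    """Read an annotation CSV.

    Events are validated against record durations when ``records`` is given;
    labels outside ``known_labels`` are retained but ``flagged``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    events: list[SeizureEvent] = []
    for i, row in df.iterrows():
        onset, offset = float(row.onset_s), float(row.offset_s)
        if not (0 <= onset < offset):
            raise AnnotationError(f"{path} row {i}: need 0 <= onset < offset, "
                                  f"got [{onset}, {offset})")
        label = str(row.label)
        flagged = known_labels is not None and label not in known_labels
        if flagged:
            logger.warning("%s row %d: label %r outside the configured class set",
                           path, i, label)
        rid = str(row.record_id)
        if records is not None and rid in records:
            dur = records[rid].duration
            if offset > dur + 1e-9:
                raise AnnotationError(f"{path} row {i}: offset {offset} exceeds "
                                      f"record {rid} duration {dur:.2f}s")
        events.append(SeizureEvent(rid, onset, offset, label, flagged=flagged))
    return events


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | Path,
              sampling_rates: list[float] | None = None) -> None:
    """Write a record as 16-bit EDF.

    One data record per second; the record must span an integer number of
    seconds.  ``sampling_rates`` optionally overrides the per-signal rate (for
    producing mixed-rate test files); by default every signal uses the
    record's rate.  Quantization error is at most one digital step,
    ``(phys_max - phys_min) / 65535`` per channel.
    """
    fs = record.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_sec = record.n_samples / fs
    if abs(n_sec - round(n_sec)) > 1e-9:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_sec = round(n_sec)
    ns = record.n_leads
    rates = [fs] * ns if sampling_rates is None else list(sampling_rates)
    if len(rates) != ns:
        raise ValueError("one sampling rate per signal required")

    chan_data, spr, pmins, pmaxs = [], [], [], []
    for i, rate in enumerate(rates):
        x = record.signal[i]
        if rate != fs:  # decimate/interpolate onto the per-signal rate
            n_new = round(n_sec * rate)
            t_old = np.arange(record.n_samples) / fs
            t_new = np.arange(n_new) / rate
            x = np.interp(t_new, t_old, x)
        amp = max(np.max(np.abs(x)), 1e-6)
        pmin, pmax = -amp, amp
        dig = np.clip(np.round((x - pmin) / (pmax - pmin) * 65535.0 - 32768.0),
                      -32768, 32767).astype("<i2")
        chan_data.append(dig)
        spr.append(round(rate))
        pmins.append(pmin)
        pmaxs.append(pmax)

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(record.record_id, 80),
        _ascii_field("Startdate 01-JAN-2000", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (1 + ns), 8),
        _ascii_field("", 44),
        _ascii_field(n_sec, 8),
        _ascii_field(1, 8),
        _ascii_field(ns, 4),
    ])
    sig_header = b"".join([
        b"".join(_ascii_field(name, 16) for name in record.lead_names),
        b"".join(_ascii_field("", 80) for _ in range(ns)),
        b"".join(_ascii_field("uV", 8) for _ in range(ns)),
        b"".join(_ascii_field(f"{p:.6g}"[:8], 8) for p in pmins),
        b"".join(_ascii_field(f"{p:.6g}"[:8], 8) for p in pmaxs),
        b"".join(_ascii_field(-32768, 8) for _ in range(ns)),
        b"".join(_ascii_field(32767, 8) for _ in range(ns)),
        b"".join(_ascii_field("", 80) for _ in range(ns)),
        b"".join(_ascii_field(s, 8) for s in spr),
        b"".join(_ascii_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec_i in range(n_sec):
            for i in range(ns):
                fh.write(chan_data[i][rec_i * spr[i]:(rec_i + 1) * spr[i]].tobytes())


def edf_resolution(path: str | Path) -> np.ndarray:
    """Per-channel digital step (uV) of an EDF file, from its signal headers."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256].decode())
        sig = fh.read(256 * ns)
    off = 16 * ns + 80 * ns + 8 * ns
    pmin = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
    off += 8 * ns
    pmax = np.array([float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)])
    return (pmax - pmin) / 65535.0


def read_edf(path: str | Path,
             exclude_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS,
             record_id: str | None = None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts).

    Non-EEG channels are dropped by case-insensitive name-substring match
    against ``exclude_patterns``.  MNE resamples mixed-rate channels onto one
    uniform rate on load, so the all-leads-share-one-rate invariant holds by
    construction.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:
        raise IOError(f"unreadable EDF file {path}: {err}") from err
    keep = [name for name in raw.ch_names
            if not any(pat.lower() in name.lower() for pat in exclude_patterns)]
    if not keep:
        raise ValueError(f"{path}: no EEG channels left after name filtering")
    raw.pick(keep)
    data = raw.get_data() * 1e6  # MNE loads in volts
    return EEGRecord(signal=data, sampling_rate=float(raw.info["sfreq"]),
                     lead_names=list(raw.ch_names),
                     record_id=record_id or path.stem)


# ---------------------------------------------------------------------------
# dataset assembly for training
# ---------------------------------------------------------------------------

def stack_sequences(sequences: list[WindowSequence],
                    label_names: list[str] | None = None
                    ) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Stack sequences into ``X [N, 8, n_leads, S]`` and integer labels.

    ``label_names`` fixes the class index order; by default classes are
    sorted, with the normal class first when present.
    """
    if not sequences:
        raise ValueError("no sequences to stack")
    X = np.stack([s.windows for s in sequences])
    labels = [s.label for s in sequences]
    if any(lab is None for lab in labels):
        return X, None, label_names or []
    if label_names is None:
        uniq = sorted(set(labels))
        if NORMAL_LABEL in uniq:
            uniq.remove(NORMAL_LABEL)
            uniq = [NORMAL_LABEL] + uniq
        label_names = uniq
    lut = {name: i for i, name in enumerate(label_names)}
    unknown = sorted(set(labels) - set(lut))
    if unknown:
        raise ValueError(f"labels {unknown} not in label set {label_names}")
    y = np.array([lut[lab] for lab in labels], dtype=int)
    return X, y, label_names
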