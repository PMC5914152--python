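"""Recordings, event markers, epoching and file round-trips.

Continuous EEG comes in as a ``Recording`` (channels x samples, microvolts)
plus an ``EventList`` of cue-onset sample indices.  Each retained event
yields exactly two 1.5 s trials: the *pre-event* window immediately before
the cue onset and the *event-related* window starting at the onset.  The
onset sample itself belongs to the event-related window (the cue is already
on screen at that sample); windows are half-open.

Supported formats: EDF and delimited text (one column per channel, header
row of labels) for recordings; two-column text (event index, onset sample)
for markers.  EDF reading goes through :func:`mne.io.read_raw_edf`; writing
uses a minimal EDF encoder implemented here (16-bit, one-second records).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PRE_EVENT",
    "EVENT_RELATED",
    "Recording",
    "EventList",
    "EpochedTrials",
    "read_recording",
    "read_markers",
    "write_text",
    "write_edf",
    "write_markers",
    "extract_trials",
    "screen_artifacts",
]

PRE_EVENT = "pre-event"
EVENT_RELATED = "event-related"

#: Analysis window length in seconds (one window per class per event).
WINDOW_S = 1.5


@dataclass
class Recording:
    """Continuous multichannel signal: channels x samples in microvolts."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] < 1:
            raise ValueError("recording needs at least one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventList:
    """Cue-onset sample indices, strictly increasing."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EpochedTrials:
    """Trials x channels x samples tensor with class labels.

    Every retained event contributes one trial of each class, so labels are
    balanced by construction and trials come in consecutive (pre, post)
    pairs ordered chronologically by event.
    """

    data: np.ndarray
    labels: np.ndarray
    event_index: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.event_index = np.asarray(self.event_index, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not (len(self.labels) == len(self.event_index) == self.data.shape[0]):
            raise ValueError("labels / event_index length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def window_samples(self) -> int:
        return self.data.shape[2]

    @property
    def events(self) -> np.ndarray:
        """Distinct event indices, in chronological order."""
        return np.unique(self.event_index)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def subset(self, trial_mask: np.ndarray) -> "EpochedTrials":
        return EpochedTrials(
            data=self.data[trial_mask],
            labels=self.labels[trial_mask],
            event_index=self.event_index[trial_mask],
            fs=self.fs,
        )

    def split_event(self, event: int) -> tuple["EpochedTrials", "EpochedTrials"]:
        """(train, test) split leaving out the two trials of one event."""
        mask = self.event_index == event
        if not mask.any():
            raise KeyError(f"no trials for event {event}")
        return self.subset(~mask), self.subset(mask)

    def class_data(self, label: str) -> np.ndarray:
        return self.data[self.labels == label]


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(path, fmt: str | None = None, fs: float | None = None,
                   expected_channels: int | None = None) -> Recording:
    """Read a continuous recording from EDF or delimited text.

    ``fmt`` is ``"edf"`` or ``"text"``; when omitted it is inferred from the
    file extension.  Text files carry no sampling-rate metadata, so ``fs``
    is required for them; for EDF it is read from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "text":
        if fs is None:
            raise ValueError("fs is required when reading delimited text")
        rec = _read_text(path, fs)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if expected_channels is not None and rec.n_channels != expected_channels:
        raise ValueError(
            f"expected {expected_channels} channels, file has {rec.n_channels}"
        )
    return rec


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne scales EEG channels to volts; the package works in microvolts
    return Recording(
        samples=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _read_text(path: Path, fs: float) -> Recording:
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path} holds no samples")
    return Recording(
        samples=frame.to_numpy(dtype=float).T,
        fs=fs,
        channel_labels=[str(c) for c in frame.columns],
    )


def write_text(recording: Recording, path) -> None:
    """One column per channel, header row of channel labels, CSV."""
    frame = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    frame.to_csv(path, index=False)


def write_markers(events: EventList, path) -> None:
    """Two-column text: event index, onset sample."""
    with open(path, "w") as fh:
        fh.write("event\tonset_sample\n")
        for i, onset in enumerate(events.onsets):
            fh.write(f"{i}\t{int(onset)}\n")


def read_markers(path) -> EventList:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (event, onset sample)")
    return EventList(onsets=frame.iloc[:, 1].to_numpy(dtype=int))


def write_edf(recording: Recording, path) -> None:
    """Write an EDF file (16-bit, microvolt physical units, 1 s records).

    Minimal encoder covering continuous unannotated signals; readable by
    standard EDF tools including ``mne.io.read_raw_edf``.
    """
    x = recording.samples
    n_ch = recording.n_channels
    spr = int(round(recording.fs))  # samples per 1 s data record
    if abs(spr - recording.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(x.shape[1] / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : x.shape[1]] = x

    pmin = np.floor(padded.min(axis=1))
    pmax = np.ceil(padded.max(axis=1))
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1
    dmin, dmax = -32768, 32767

    def f(value, width):
        s = f"{value}"[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    header += b"".join(f(lbl, 16) for lbl in recording.channel_labels)
    header += b"".join(f("", 80) for _ in range(n_ch))          # transducer
    header += b"".join(f("uV", 8) for _ in range(n_ch))          # physical dim
    header += b"".join(f(f"{v:g}", 8) for v in pmin)
    header += b"".join(f(f"{v:g}", 8) for v in pmax)
    header += b"".join(f(str(dmin), 8) for _ in range(n_ch))
    header += b"".join(f(str(dmax), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))           # prefiltering
    header += b"".join(f(str(spr), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))           # reserved

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = padded[:, r * spr : (r + 1) * spr]
            digital = np.round((chunk - pmin[:, None]) * scale[:, None] + dmin)
            fh.write(digital.astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# epoching


def extract_trials(rec: Recording, events: EventList,
                   window_s: float = WINDOW_S) -> EpochedTrials:
    """Cut one pre-event and one event-related trial per cue onset.

    The pre-event trial covers samples ``[onset - M, onset)`` and the
    event-related trial ``[onset, onset + M)`` with ``M = round(window_s *
    fs)``.  Events whose windows would cross the recording bounds are
    dropped with a warning; if none remain this is an error.
    """
    m = int(round(window_s * rec.fs))
    data, labels, event_ids = [], [], []
    for i, onset in enumerate(events.onsets):
        if onset - m < 0 or onset + m > rec.n_samples:
            warnings.warn(
                f"event {i} at sample {onset} dropped: windows of {m} samples "
                f"exceed recording bounds [0, {rec.n_samples})",
                stacklevel=2,
            )
            continue
        data.append(rec.samples[:, onset - m : onset])
        labels.append(PRE_EVENT)
        data.append(rec.samples[:, onset : onset + m])
        labels.append(EVENT_RELATED)
        event_ids.extend([i, i])
    if not data:
        raise ValueError("no event admits both analysis windows")
    return EpochedTrials(
        data=np.stack(data),
        labels=np.array(labels),
        event_index=np.array(event_ids),
        fs=rec.fs,
    )


def screen_artifacts(trials: EpochedTrials,
                     peak_threshold: float | None = None
                     ) -> tuple[EpochedTrials, list[int]]:
    """Amplitude-threshold artifact screening preserving class pairing.

    If either trial of an event exceeds ``peak_threshold`` (microvolts, peak
    absolute amplitude), BOTH trials of that event are dropped so the class
    balance and the event pairing survive.  Disabled (``None``) by default,
    mirroring that real screening is a manual judgement this package does
    not attempt to model.  Returns the screened trials and the list of
    dropped event indices.
    """
    if peak_threshold is None:
        return trials, []
    if peak_threshold <= 0:
        raise ValueError("peak_threshold must be positive (or None to disable)")
    peaks = np.abs(trials.data).max(axis=(1, 2))
    bad_events = sorted(set(trials.event_index[peaks > peak_threshold].tolist()))
    if not bad_events:
        return trials, []
    keep = ~np.isin(trials.event_index, bad_events)
    logger.info("artifact screening dropped events %s", bad_events)
    if not keep.any():
        # callers requiring events will raise; return the empty container
        return EpochedTrials(
            data=trials.data[:0], labels=trials.labels[:0],
            event_index=trials.event_index[:0], fs=trials.fs,
        ), bad_events
    return trials.subset(keep), bad_events
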