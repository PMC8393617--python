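"""CAP annotation handling and Terzano-rule temporal logic.

Cyclic alternating pattern (CAP) scoring works on expert-annotated phase-A
events inside NREM sleep.  The temporal rules implemented here:

* two successive A phases separated by less than 2 s merge into one;
* phase durations (A and the intervening B) must lie within 2-60 s;
* absence of CAP for more than 60 s terminates a sequence;
* a CAP sequence needs at least three A phases (A-B-A-B-A); an A phase
  without a companion B is an isolated phase A and counts as non-CAP;
* CAP rate = CAP time / NREM time.

For classifier training the dichotomy is coarser, following common
practice: every expert-labelled A interval is phase A, all remaining NREM
time is phase B, and each interval is tiled with non-overlapping 1 s or 2 s
epochs from its onset (trailing partial windows dropped).  Strict Terzano B
phases are used only for CAP parameters; the two notions are kept separate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocess import TimeSeries

__all__ = [
    "AnnotationEvent",
    "CAPSequence",
    "CAPParameters",
    "EpochSet",
    "A_PHASE_LABELS",
    "NREM_LABELS",
    "parse_annotations",
    "merge_phase_a",
    "build_cap_sequences",
    "compute_cap_parameters",
    "cap_parameters_from_times",
    "label_and_segment",
    "balance_classes",
]

A_PHASE_LABELS = frozenset({"A", "A1", "A2", "A3"})
NREM_LABELS = frozenset({"NREM1", "NREM2", "NREM3"})
CANONICAL_LABELS = A_PHASE_LABELS | NREM_LABELS | {"B", "REM", "W"}

# PhysioNet CAP event-file vocabulary -> canonical labels
_PHYSIONET_LABELS = {
    "MCAP-A1": "A1",
    "MCAP-A2": "A2",
    "MCAP-A3": "A3",
    "SLEEP-S0": "W",
    "SLEEP-S1": "NREM1",
    "SLEEP-S2": "NREM2",
    "SLEEP-S3": "NREM3",
    "SLEEP-S4": "NREM3",
    "SLEEP-REM": "REM",
}


@dataclass(frozen=True, order=True)
class AnnotationEvent:
    """One scored event: onset and duration in seconds from recording start."""

    onset: float
    duration: float
    label: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"non-positive duration {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def is_a_phase(self) -> bool:
        return self.label in A_PHASE_LABELS


@dataclass
class CAPSequence:
    """Alternating A-B-...-A chain with at least three A phases."""

    events: list[AnnotationEvent]

    @property
    def n_a(self) -> int:
        return sum(1 for e in self.events if e.is_a_phase())

    @property
    def start(self) -> float:
        return self.events[0].onset

    @property
    def end(self) -> float:
        return self.events[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    def validate(self) -> None:
        if self.n_a < 3:
            raise ValueError(f"CAP sequence needs >= 3 A phases, has {self.n_a}")
        for i, e in enumerate(self.events):
            want_a = i % 2 == 0
            if e.is_a_phase() != want_a:
                raise ValueError("events must alternate A, B, A, ...")
            if not 2.0 <= e.duration <= 60.0:
                raise ValueError(f"phase duration {e.duration} s outside [2, 60] s")
        if self.events[-1].label == "B":
            raise ValueError("sequence must end with an A phase")


@dataclass(frozen=True)
class CAPParameters:
    """CAP time, NREM time (minutes) and their ratio, the CAP rate."""

    cap_time: float
    nrem_time: float

    @property
    def cap_rate(self) -> float:
        return self.cap_time / self.nrem_time


def cap_parameters_from_times(cap_time: float, nrem_time: float) -> CAPParameters:
    if nrem_time <= 0:
        raise ValueError("NREM time must be positive")
    if cap_time > nrem_time:
        raise ValueError(
            f"CAP time {cap_time} min exceeds NREM time {nrem_time} min: "
            "inconsistent annotations"
        )
    return CAPParameters(cap_time=cap_time, nrem_time=nrem_time)


def compute_cap_parameters(
    sequences: Sequence[CAPSequence], nrem_time: float
) -> CAPParameters:
    """Sum sequence durations into CAP time (minutes) and form the CAP rate."""
    cap_time = sum(s.duration for s in sequences) / 60.0
    return cap_parameters_from_times(cap_time, nrem_time)


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, Path) or p.exists():
            return p.read_text().splitlines()
        return str(source).splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return list(source)


def _check_a_overlap(events: list[AnnotationEvent]) -> None:
    a_sorted = sorted(e for e in events if e.is_a_phase())
    for prev, cur in zip(a_sorted, a_sorted[1:]):
        if cur.onset < prev.end:
            raise ValueError(
                f"overlapping phase-A events at onsets {prev.onset} s and {cur.onset} s"
            )


def _parse_simple_tsv(lines: Iterable[str]) -> list[AnnotationEvent]:
    events = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 'onset<TAB>duration<TAB>label'")
        try:
            onset, duration = float(parts[0]), float(parts[1])
        except ValueError as exc:
            if lineno == 1:  # tolerate a header row
                continue
            raise ValueError(f"line {lineno}: unparseable numbers in {line!r}") from exc
        label = parts[2].strip()
        if label not in CANONICAL_LABELS:
            warnings.warn(f"line {lineno}: unknown label {label!r}, skipped")
            continue
        events.append(AnnotationEvent(onset=onset, duration=duration, label=label))
    return events


def _hhmmss_to_seconds(text: str) -> float:
    parts = text.replace(".", ":").split(":")
    if len(parts) != 3:
        raise ValueError(f"bad time-of-day {text!r}")
    h, m, s = (float(v) for v in parts)
    return 3600 * h + 60 * m + s


def _parse_physionet(lines: Iterable[str]) -> list[AnnotationEvent]:
    """Reader for the PhysioNet CAP database event-list dialect.

    Files carry free-form header lines, then a column-header line naming at
    least ``Time [hh:mm:ss]``, ``Event`` and ``Duration[s]``, then
    tab-separated rows.  Onsets are made relative to the first listed event;
    clock times that step backwards are assumed to cross midnight.
    """
    lines = list(lines)
    header_idx = None
    for i, line in enumerate(lines):
        if "Event" in line and "Duration" in line:
            header_idx = i
            break
    if header_idx is None:
        raise ValueError("no column header line ('Event', 'Duration') found")
    cols = [c.strip() for c in lines[header_idx].split("\t")]
    try:
        time_col = next(i for i, c in enumerate(cols) if c.lower().startswith("time"))
        event_col = next(i for i, c in enumerate(cols) if c.lower() == "event")
        dur_col = next(i for i, c in enumerate(cols) if c.lower().startswith("duration"))
    except StopIteration as exc:
        raise ValueError(f"missing required column in header {cols!r}") from exc
    events = []
    t0 = None
    prev_clock = None
    day_offset = 0.0
    for lineno, raw in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) <= max(time_col, event_col, dur_col):
            raise ValueError(f"line {lineno}: too few columns in {line!r}")
        try:
            clock = _hhmmss_to_seconds(parts[time_col].strip())
            duration = float(parts[dur_col].strip())
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if prev_clock is not None and clock < prev_clock:
            day_offset += 86400.0
        prev_clock = clock
        onset_abs = clock + day_offset
        if t0 is None:
            t0 = onset_abs
        raw_label = parts[event_col].strip()
        label = _PHYSIONET_LABELS.get(raw_label.upper())
        if label is None:
            warnings.warn(f"line {lineno}: unknown event {raw_label!r}, skipped")
            continue
        if duration <= 0:
            warnings.warn(f"line {lineno}: non-positive duration, skipped")
            continue
        events.append(AnnotationEvent(onset=onset_abs - t0, duration=duration, label=label))
    return events


def parse_annotations(source, dialect: str = "simple-tsv") -> list[AnnotationEvent]:
    """Parse an annotation stream into sorted, canonical events.

    Parameters
    ----------
    source : path, string, file-like or iterable of lines.
    dialect : ``"simple-tsv"`` (onset, duration, label per line) or
        ``"physionet-cap"`` (sleep-stage + MCAP event lists).
    """
    lines = _as_lines(source)
    if dialect == "simple-tsv":
        events = _parse_simple_tsv(lines)
    elif dialect == "physionet-cap":
        events = _parse_physionet(lines)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    events.sort()
    _check_a_overlap(events)
    return events


# ---------------------------------------------------------------------------
# Terzano temporal rules
# ---------------------------------------------------------------------------

MERGE_GAP = 2.0       # s; successive A phases closer than this are one event
MIN_PHASE = 2.0       # s
MAX_PHASE = 60.0      # s
NON_CAP_GAP = 60.0    # s; absence of CAP longer than this breaks a sequence


def merge_phase_a(events: Sequence[AnnotationEvent]) -> list[AnnotationEvent]:
    """Merge successive A phases separated by less than 2 s (to fixed point)."""
    a_events = sorted(e for e in events if e.is_a_phase())
    if not a_events:
        return []
    merged = [a_events[0]]
    for ev in a_events[1:]:
        prev = merged[-1]
        if ev.onset - prev.end < MERGE_GAP:
            label = prev.label if prev.label == ev.label else "A"
            end = max(prev.end, ev.end)
            merged[-1] = AnnotationEvent(
                onset=prev.onset, duration=end - prev.onset, label=label
            )
        else:
            merged.append(ev)
    return merged


def _clip_to_intervals(
    events: Sequence[AnnotationEvent], intervals: Sequence[tuple[float, float]] | None
) -> list[AnnotationEvent]:
    if intervals is None:
        return list(events)
    out = []
    for e in events:
        if any(e.onset < hi and e.end > lo for lo, hi in intervals):
            out.append(e)
    return out


def build_cap_sequences(
    events: Sequence[AnnotationEvent],
    nrem_intervals: Sequence[tuple[float, float]] | None = None,
) -> list[CAPSequence]:
    """Chain merged A phases into CAP sequences under the Terzano rules.

    Inter-A intervals become B phases; a chain breaks when the inter-A gap
    exceeds 60 s or a phase duration falls outside [2, 60] s.  Chains with
    at least three A phases become sequences, running from the first A's
    onset to the terminal A's end; shorter chains (isolated A phases) are
    non-CAP and dropped.
    """
    a_events = merge_phase_a(_clip_to_intervals(events, nrem_intervals))
    sequences: list[CAPSequence] = []
    chain: list[AnnotationEvent] = []

    def flush() -> None:
        nonlocal chain
        if sum(1 for e in chain if e.is_a_phase()) >= 3:
            while chain and chain[-1].label == "B":
                chain.pop()
            sequences.append(CAPSequence(events=chain))
        chain = []

    for ev in a_events:
        if not MIN_PHASE <= ev.duration <= MAX_PHASE:
            flush()  # atypical A duration: acts as a chain breaker
            continue
        if chain:
            gap = ev.onset - chain[-1].end
            if MIN_PHASE <= gap <= NON_CAP_GAP:
                chain.append(
                    AnnotationEvent(onset=chain[-1].end, duration=gap, label="B")
                )
            else:
                flush()
        chain.append(ev)
    flush()
    for s in sequences:
        s.validate()
    return sequences


# ---------------------------------------------------------------------------
# Segmentation and balancing for classification
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Fixed-length labelled epochs per channel.

    ``channels`` maps channel name to an ``(n_epochs, n_samples)`` array;
    ``labels`` holds ``"A"``/``"B"`` per epoch.
    """

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    epoch_len: float
    fs: float
    subject: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n_samp = self.epoch_len * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_len * fs must be an integer sample count")
        for name, arr in self.channels.items():
            if arr.shape != (len(self.labels), int(round(n_samp))):
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} inconsistent with "
                    f"{len(self.labels)} epochs x {int(round(n_samp))} samples"
                )

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def select(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            channels={k: v[idx] for k, v in self.channels.items()},
            labels=self.labels[idx],
            epoch_len=self.epoch_len,
            fs=self.fs,
            subject=self.subject,
        )

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]):
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return _union(out)


def _subtract(universe: list[tuple[float, float]], holes: list[tuple[float, float]]):
    out = []
    for lo, hi in universe:
        cur = lo
        for hlo, hhi in holes:
            if hhi <= cur or hlo >= hi:
                continue
            if hlo > cur:
                out.append((cur, hlo))
            cur = max(cur, hhi)
        if cur < hi:
            out.append((cur, hi))
    return out


def nrem_intervals_from_events(
    events: Sequence[AnnotationEvent], total_duration: float | None = None
) -> list[tuple[float, float]]:
    """NREM sleep intervals from stage events; whole span if none are scored."""
    stages = [(e.onset, e.end) for e in events if e.label in NREM_LABELS]
    if stages:
        return _union(stages)
    if total_duration is None:
        raise ValueError("no NREM stage events and no total duration given")
    return [(0.0, total_duration)]


def label_and_segment(
    channels: dict[str, TimeSeries] | TimeSeries,
    events: Sequence[AnnotationEvent],
    epoch_len: float = 2.0,
) -> EpochSet:
    """Cut phase-A and phase-B intervals into fixed-length labelled epochs.

    Merged expert A intervals (clipped to NREM) are labelled A; all
    remaining NREM time is labelled B; REM and wake are excluded.  Each
    interval is tiled with non-overlapping windows of ``epoch_len`` seconds
    starting at the interval onset; trailing partial windows are discarded.
    """
    if epoch_len not in (1.0, 2.0, 1, 2):
        raise ValueError("epoch_len must be 1 or 2 seconds")
    if isinstance(channels, TimeSeries):
        channels = {channels.label or "ch0": channels}
    names = list(channels)
    fs = channels[names[0]].fs
    n_total = len(channels[names[0]].samples)
    for name in names:
        if channels[name].fs != fs or len(channels[name].samples) != n_total:
            raise ValueError("all channels must share sampling rate and length")
    total = n_total / fs

    nrem = nrem_intervals_from_events(events, total_duration=total)
    a_merged = merge_phase_a(events)
    a_intervals = _intersect([(e.onset, e.end) for e in a_merged], nrem)
    b_intervals = _subtract(nrem, a_intervals)

    n_samp = int(round(epoch_len * fs))
    starts: list[int] = []
    labels: list[str] = []
    for label, intervals in (("A", a_intervals), ("B", b_intervals)):
        for lo, hi in intervals:
            n_ep = int(np.floor((hi - lo) / epoch_len + 1e-9))
            for i in range(n_ep):
                s = int(round((lo + i * epoch_len) * fs))
                if s + n_samp <= n_total:
                    starts.append(s)
                    labels.append(label)
    order = np.argsort(starts, kind="stable")
    starts_arr = np.asarray(starts)[order]
    labels_arr = np.asarray(labels)[order]
    data = {
        name: np.stack([channels[name].samples[s : s + n_samp] for s in starts_arr])
        if len(starts_arr)
        else np.empty((0, n_samp))
        for name in names
    }
    return EpochSet(channels=data, labels=labels_arr, epoch_len=float(epoch_len), fs=fs)


def balance_classes(e: EpochSet, seed: int) -> EpochSet:
    """Randomly undersample the majority class to the minority count."""
    counts = e.class_counts()
    if len(counts) < 2:
        raise ValueError(f"both classes required, got labels {sorted(counts)}")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in sorted(counts):
        idx = np.flatnonzero(e.labels == label)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    idx_all = np.sort(np.concatenate(keep))
    return e.select(idx_all)
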