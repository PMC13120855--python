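"""Courtship-song event refinement and train segmentation.

Male flies sing during courtship by wing vibration; recordings contain
two event types here — brief biphasic "pulse" events and "clack" events.
Coarse manual annotations are refined to the true waveform peak within a
short centered window, and refined events of the same type are chained
into trains when consecutive gaps fall strictly below a type-specific
threshold (200 ms for pulse, 400 ms for clack).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

EVENT_TYPES = ("pulse", "clack")
DEFAULT_THRESHOLDS = {"pulse": 0.2, "clack": 0.4}


@dataclass(frozen=True)
class SongEvent:
    type: str
    time_s: float
    amplitude: float = 0.0


@dataclass(frozen=True)
class Train:
    type: str
    member_indices: tuple[int, ...]


@dataclass(frozen=True)
class SongEvents:
    """Typed song events (sorted by time) and their train memberships."""

    events: tuple[SongEvent, ...] = ()
    trains: tuple[Train, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted by time")
        seen: set[int] = set()
        for tr in self.trains:
            for i in tr.member_indices:
                if i in seen:
                    raise ValueError(f"event {i} belongs to multiple trains")
                seen.add(i)

    def of_type(self, kind: str) -> list[tuple[int, SongEvent]]:
        return [(i, e) for i, e in enumerate(self.events) if e.type == kind]

    def to_csv(self, path: Union[str, Path]) -> None:
        train_of = {}
        for t_idx, tr in enumerate(self.trains):
            for i in tr.member_indices:
                train_of[i] = t_idx
        pd.DataFrame(
            {
                "type": [e.type for e in self.events],
                "time_s": [e.time_s for e in self.events],
                "amplitude": [e.amplitude for e in self.events],
                "train": [train_of.get(i, -1) for i in range(len(self.events))],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SongEvents":
        df = pd.read_csv(path)
        events = tuple(
            SongEvent(r.type, float(r.time_s), float(getattr(r, "amplitude", 0.0)))
            for r in df.itertuples(index=False)
        )
        trains: tuple[Train, ...] = ()
        if "train" in df.columns and (df["train"] >= 0).any():
            groups: dict[tuple[str, int], list[int]] = {}
            for i, r in enumerate(df.itertuples(index=False)):
                if r.train >= 0:
                    groups.setdefault((r.type, int(r.train)), []).append(i)
            trains = tuple(
                Train(k[0], tuple(v)) for k, v in sorted(groups.items(), key=lambda kv: kv[1][0])
            )
        return cls(events, trains)


def refine_peak(
    waveform: np.ndarray,
    sample_rate: float,
    annotation_time: float,
    window_ms: float = 20.0,
    mode: str = "abs",
) -> tuple[float, float]:
    """Locate the signal peak near a coarse annotation.

    Searches a ``window_ms`` window centered on the annotation (truncated
    at the waveform edges) for the maximum absolute amplitude (song
    pulses are biphasic; ``mode="signed"`` uses the raw maximum). If the
    annotation sample itself attains the window maximum it is returned
    unchanged; otherwise the earliest maximizing sample wins. Returns
    ``(time_s, amplitude)`` with the signed sample value as amplitude.
    """
    x = np.asarray(waveform, dtype=float)
    n = x.size
    c = int(round(annotation_time * sample_rate))
    if not 0 <= c < n:
        raise ValueError(f"annotation at {annotation_time} s outside waveform")
    half = int(round(window_ms / 1000.0 * sample_rate / 2))
    lo, hi = max(0, c - half), min(n, c + half + 1)
    seg = np.abs(x[lo:hi]) if mode == "abs" else x[lo:hi]
    m = seg.max()
    if seg[c - lo] == m:
        idx = c
    else:
        idx = lo + int(np.argmax(seg))
    return idx / sample_rate, float(x[idx])


def segment_trains(
    events: Union[SongEvents, Sequence[SongEvent]],
    thresholds: Optional[dict[str, float]] = None,
) -> SongEvents:
    """Chain same-type events into trains by consecutive-gap linkage.

    Consecutive events of one type share a train when their gap is
    strictly below that type's threshold (single linkage — chains may
    span more than the threshold end to end). Types segment
    independently; singletons form singleton trains. Unsorted input is
    sorted internally.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    evs = list(events.events if isinstance(events, SongEvents) else events)
    evs.sort(key=lambda e: e.time_s)
    trains: list[Train] = []
    for kind in sorted({e.type for e in evs}):
        idx = [i for i, e in enumerate(evs) if e.type == kind]
        thr = thresholds.get(kind)
        if thr is None:
            raise ValueError(f"no threshold for event type {kind!r}")
        current = [idx[0]]
        for prev, cur in zip(idx, idx[1:]):
            gap = evs[cur].time_s - evs[prev].time_s
            if gap < thr:
                current.append(cur)
            else:
                trains.append(Train(kind, tuple(current)))
                current = [cur]
        trains.append(Train(kind, tuple(current)))
    trains.sort(key=lambda t: t.member_indices[0])
    return SongEvents(tuple(evs), tuple(trains))


def train_stats(songevents: SongEvents) -> pd.DataFrame:
    """Tidy per-type summary of segmented song events.

    Columns: event count, train count, mean/median train size, and
    within-train inter-event-interval statistics in seconds.
    """
    rows = []
    for kind in EVENT_TYPES:
        trs = [t for t in songevents.trains if t.type == kind]
        n_events = sum(len(t.member_indices) for t in trs)
        sizes = [len(t.member_indices) for t in trs]
        ieis: list[float] = []
        for t in trs:
            times = [songevents.events[i].time_s for i in t.member_indices]
            ieis.extend(np.diff(sorted(times)).tolist())
        rows.append(
            {
                "type": kind,
                "n_events": n_events,
                "n_trains": len(trs),
                "mean_train_size": float(np.mean(sizes)) if sizes else 0.0,
                "max_train_size": max(sizes) if sizes else 0,
                "n_ieis": len(ieis),
                "mean_iei_s": float(np.mean(ieis)) if ieis else float("nan"),
                "median_iei_s": float(np.median(ieis)) if ieis else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def read_waveform(path: Union[str, Path]) -> tuple[np.ndarray, float]:
    """Read a waveform from WAV or single-column float text.

    Text files carry the sample rate on a ``# sample_rate: <Hz>`` first
    line; WAV files carry it in the header.
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        x = np.asarray(data, dtype=float)
        if np.issubdtype(data.dtype, np.integer):
            x = x / np.abs(np.iinfo(data.dtype).min)
        return x, float(rate)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# sample_rate:"):
        raise ValueError("text waveform must start with '# sample_rate: <Hz>'")
    rate = float(lines[0].split(":", 1)[1])
    return np.array([float(v) for v in lines[1:] if v.strip()]), rate


def write_waveform(
    path: Union[str, Path], waveform: np.ndarray, sample_rate: float
) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        from scipy.io import wavfile

        wavfile.write(path, int(sample_rate), waveform.astype(np.float32))
        return
    body = "\n".join(f"{v:.8g}" for v in waveform)
    path.write_text(f"# sample_rate: {sample_rate}\n{body}\n")
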