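"""Photostimulation (PS) protocols and PS-locked behavioral analyses.

A protocol is an ordered list of light-ON blocks (onset, duration, pulse
frequency, pulse width, intensity) preceded by a baseline period. The
canonical ramp protocol used for central-circuit activation is six 30 s
blocks of fixed intensity and monotonically increasing pulse frequency,
after a 2 min baseline and separated by 1 min inter-block intervals
(IBIs). Analyses treat ON blocks as plain intervals; pulse width and duty
cycle are carried through serialization only.

Segment conventions: "PS−" is the baseline
period before the first block; "PS+" pools the six ON blocks when scoring
courtship but the five IBIs plus the post-final period when scoring
aggression, because optogenetically evoked attack occurs mostly after
light offset while courtship is time-locked to the light.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import BoutTable, seconds_to_frames
from .metrics import sliding_fraction, group_trace

#: Default frequency ladder for the six-block ramp (Hz). The exact ladder
#: is configurable; these six values span the 1-40 Hz stimulation range.
DEFAULT_FREQUENCIES = (1.0, 2.0, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class PSBlock:
    onset_s: float
    duration_s: float
    freq_hz: float
    pulse_ms: float = 10.0
    intensity: float = 0.0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class PSProtocol:
    blocks: tuple[PSBlock, ...] = ()
    baseline_s: float = 120.0
    sham: bool = False
    protocol_id: str = "ps"

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for b in self.blocks:
            if b.onset_s < prev_off:
                raise ValueError("PS blocks overlap or are out of order")
            if not 0 < b.freq_hz <= 40 + 1e-9 or b.freq_hz < 1 - 1e-9:
                raise ValueError(f"pulse frequency {b.freq_hz} outside [1, 40] Hz")
            prev_off = b.offset_s

    @property
    def end_s(self) -> float:
        return self.blocks[-1].offset_s if self.blocks else self.baseline_s

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {
            "protocol_id": self.protocol_id,
            "baseline_s": self.baseline_s,
            "sham": self.sham,
            "blocks": [
                {
                    "onset_s": b.onset_s,
                    "duration_s": b.duration_s,
                    "freq_hz": b.freq_hz,
                    "pulse_ms": b.pulse_ms,
                    "intensity": b.intensity,
                }
                for b in self.blocks
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PSProtocol":
        doc = json.loads(Path(path).read_text())
        return cls(
            blocks=tuple(PSBlock(**b) for b in doc["blocks"]),
            baseline_s=doc.get("baseline_s", 120.0),
            sham=doc.get("sham", False),
            protocol_id=doc.get("protocol_id", "ps"),
        )


def make_ramp_protocol(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    block_s: float = 30.0,
    baseline_s: float = 120.0,
    ibi_s: float = 60.0,
    intensity: float = 120.0,
    pulse_ms: float = 10.0,
    sham: bool = False,
) -> PSProtocol:
    """Build the canonical frequency-ramp protocol.

    With the defaults the six block onsets fall at 120, 210, 300, 390,
    480 and 570 s. An empty frequency list yields a baseline-only sham.
    """
    freqs = list(frequencies)
    if any(b >= a for a, b in zip(freqs[1:], freqs[:-1])):
        raise ValueError("ramp frequencies must be strictly increasing")
    blocks = tuple(
        PSBlock(
            onset_s=baseline_s + k * (block_s + ibi_s),
            duration_s=block_s,
            freq_hz=f,
            pulse_ms=pulse_ms,
            intensity=intensity,
        )
        for k, f in enumerate(freqs)
    )
    return PSProtocol(
        blocks=blocks,
        baseline_s=baseline_s,
        sham=sham or not blocks,
        protocol_id="ramp-sham" if sham else "ramp",
    )


@dataclass(frozen=True)
class SegmentMasks:
    """Boolean frame masks partitioning a trial into PS segments."""

    baseline: np.ndarray
    on_blocks: tuple[np.ndarray, ...]
    ibis: tuple[np.ndarray, ...]
    post: np.ndarray

    def all_segments(self) -> dict[str, np.ndarray]:
        out = {"baseline": self.baseline}
        out.update({f"on_{i}": m for i, m in enumerate(self.on_blocks)})
        out.update({f"ibi_{i}": m for i, m in enumerate(self.ibis)})
        out["post"] = self.post
        return out

    def assert_partition(self) -> None:
        total = sum(m.astype(int) for m in self.all_segments().values())
        if not np.all(total == 1):
            raise AssertionError("segment masks do not partition the trial")


def segment_masks(
    protocol: PSProtocol, trial_duration: int, frame_rate: float
) -> SegmentMasks:
    """Partition ``trial_duration`` frames into baseline / ON / IBI / post."""
    n = trial_duration
    if protocol.blocks and protocol.end_s * frame_rate > n + 1e-9:
        raise ValueError("protocol exceeds trial duration")
    covered = np.zeros(n, dtype=bool)

    def span(a_s: float, b_s: float) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        a = seconds_to_frames(a_s, frame_rate)
        b = min(seconds_to_frames(b_s, frame_rate), n)
        m[a:b] = True
        return m

    baseline = span(0.0, protocol.blocks[0].onset_s if protocol.blocks else n / frame_rate)
    covered |= baseline
    on, ibis = [], []
    for i, b in enumerate(protocol.blocks):
        m = span(b.onset_s, b.offset_s)
        on.append(m)
        covered |= m
        if i + 1 < len(protocol.blocks):
            g = span(b.offset_s, protocol.blocks[i + 1].onset_s)
            ibis.append(g)
            covered |= g
    post = ~covered
    return SegmentMasks(baseline, tuple(on), tuple(ibis), post)


def aggregate_by_segment(
    bouts: BoutTable,
    masks: SegmentMasks,
    action: str,
    frame_rate: float,
) -> pd.DataFrame:
    """Per-segment bout counts and time fractions, plus PS−/PS+ pools.

    Rows: every individual segment, then ``PS-`` (baseline), ``PS+on``
    (all ON blocks pooled) and ``PS+off`` (IBIs plus post-final pooled).
    Counts assign a bout to the segment containing its start frame; the
    time fraction is action-frames within the segment over segment length.
    """
    segs = masks.all_segments()
    n = len(masks.baseline)
    ind = np.zeros(n, dtype=bool)
    starts = []
    for b in bouts.for_action(action):
        ind[b.start : min(b.end, n)] = True
        if b.start < n:
            starts.append(b.start)
    starts = np.asarray(starts, dtype=int)

    pooled = {
        "PS-": masks.baseline,
        "PS+on": (
            np.logical_or.reduce(masks.on_blocks)
            if masks.on_blocks
            else np.zeros(n, dtype=bool)
        ),
        "PS+off": np.logical_or.reduce(
            list(masks.ibis) + [masks.post]
        )
        if (masks.ibis or masks.post.any())
        else np.zeros(n, dtype=bool),
    }
    rows = []
    for name, m in {**segs, **pooled}.items():
        frames = int(m.sum())
        count = int(m[starts].sum()) if starts.size else 0
        frac = float(ind[m].sum() / frames) if frames else float("nan")
        rows.append(
            {
                "segment": name,
                "frames": frames,
                "seconds": frames / frame_rate,
                "count": count,
                "time_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LockedCurve:
    """Onset-aligned average indicator of an action around PS blocks."""

    times_s: np.ndarray
    fraction: np.ndarray
    n_events: int
    empty: bool = False


def _bout_indicator(bouts: BoutTable, action: str, fly_id: str, n: int) -> np.ndarray:
    ind = np.zeros(n, dtype=bool)
    for b in bouts.for_action(action):
        if b.fly_id == fly_id:
            ind[b.start : min(b.end, n)] = True
    return ind


def ps_locked_fraction(
    trials: Sequence[tuple[BoutTable, Sequence[str]]],
    protocol: PSProtocol,
    n_frames: int,
    frame_rate: float,
    action: str = "UWE",
    window_s: tuple[float, float] = (-1.0, 5.0),
    onset_filter_s: float = 0.5,
) -> LockedCurve:
    """Fraction of qualifying flies performing ``action`` around PS onsets.

    ``trials`` is a list of ``(bout_table, tester_fly_ids)``. A (fly,
    block) event qualifies when one of the fly's action bouts overlaps
    ``[onset - onset_filter_s, onset + onset_filter_s]`` — i.e. the fly
    was already performing the action around light onset. For every
    qualifying event the binary action indicator is aligned to the block
    onset and averaged over the window (default −1 s to +5 s, covering
    the 6 s window surrounding each block).
    """
    lo = seconds_to_frames(window_s[0], frame_rate) if window_s[0] >= 0 else -seconds_to_frames(-window_s[0], frame_rate)
    hi = seconds_to_frames(window_s[1], frame_rate)
    filt = seconds_to_frames(onset_filter_s, frame_rate)
    offsets = np.arange(lo, hi + 1)
    acc = np.zeros(offsets.size, dtype=float)
    n_events = 0
    for table, fly_ids in trials:
        for fly in fly_ids:
            ind = _bout_indicator(table, action, fly, n_frames)
            for blk in protocol.blocks:
                onset = seconds_to_frames(blk.onset_s, frame_rate)
                a, b = max(0, onset - filt), min(n_frames, onset + filt + 1)
                if not ind[a:b].any():
                    continue
                idx = onset + offsets
                valid = (idx >= 0) & (idx < n_frames)
                seg = np.zeros(offsets.size, dtype=float)
                seg[valid] = ind[idx[valid]]
                acc += seg
                n_events += 1
    if n_events == 0:
        return LockedCurve(offsets / frame_rate, acc, 0, empty=True)
    return LockedCurve(offsets / frame_rate, acc / n_events, n_events)


def sham_persistence_baseline(
    sham_tables: Sequence[BoutTable],
    action: str,
    frame_rate: float,
    min_s: float = 2.0,
) -> float:
    """Fraction of spontaneous bouts lasting strictly more than ``min_s``.

    Pooled over sham trials; this is the horizontal-dashed-line baseline
    against which PS-evoked suppression is judged.
    """
    durations = [
        b.duration_s(frame_rate) for t in sham_tables for b in t.for_action(action)
    ]
    if not durations:
        raise ValueError("no bouts of the action in the sham trials")
    return float(np.mean([d > min_s for d in durations]))


def suppression_summary(
    conditions: dict[str, Sequence[tuple[BoutTable, Sequence[str]]]],
    protocol: PSProtocol,
    n_frames: int,
    frame_rate: float,
    baseline: float,
    action: str = "UWE",
    onset_filter_s: float = 0.5,
) -> pd.DataFrame:
    """Per condition, fraction of qualifying bouts persisting through ON.

    A qualifying bout (overlapping the onset ± filter window) "persists"
    when it continues to the block offset. Conditions are typically
    intensity × target-sex labels; the sham baseline is repeated in every
    row for comparison. Monotonicity in intensity is reported, never
    assumed.
    """
    rows = []
    filt = seconds_to_frames(onset_filter_s, frame_rate)
    for label, trials in conditions.items():
        qualifying = persisting = 0
        for table, fly_ids in trials:
            for blk in protocol.blocks:
                onset = seconds_to_frames(blk.onset_s, frame_rate)
                offset = seconds_to_frames(blk.offset_s, frame_rate)
                for b in table.for_action(action):
                    if b.fly_id not in fly_ids:
                        continue
                    if b.start <= onset + filt and b.end >= onset - filt:
                        qualifying += 1
                        if b.end >= offset:
                            persisting += 1
        frac = persisting / qualifying if qualifying else float("nan")
        rows.append(
            {
                "condition": label,
                "n_qualifying": qualifying,
                "persisting_fraction": frac,
                "sham_baseline": baseline,
            }
        )
    return pd.DataFrame(rows)


def penetrance_expressivity(
    fly_tables: Sequence[tuple[BoutTable, str]],
    n_frames: int,
    frame_rate: float,
    action: str = "threat",
    window_s: float = 5.0,
    bin_s: float = 1.0,
):
    """Group penetrance per time bin and mean windowed expressivity.

    Penetrance: fraction of flies with at least one frame of the action
    in each ``bin_s`` bin. Expressivity: group mean (with SEM envelope)
    of each fly's sliding-window action fraction (default 5 s window).
    Returns ``(bin_times_s, penetrance, mean_trace, sem_trace)``.
    """
    if not fly_tables:
        raise ValueError("no flies given")
    bin_frames = max(1, seconds_to_frames(bin_s, frame_rate))
    n_bins = int(np.ceil(n_frames / bin_frames))
    hits = np.zeros((len(fly_tables), n_bins), dtype=bool)
    traces = []
    for i, (table, fly) in enumerate(fly_tables):
        ind = _bout_indicator(table, action, fly, n_frames)
        for j in range(n_bins):
            hits[i, j] = ind[j * bin_frames : (j + 1) * bin_frames].any()
        traces.append(
            sliding_fraction(table, action, window_s, frame_rate, n_frames, fly_id=fly)
        )
    penetrance = hits.mean(axis=0)
    bin_times = (np.arange(n_bins) + 0.5) * bin_frames / frame_rate
    mean_trace, sem_trace = group_trace([t.values for t in traces])
    return bin_times, penetrance, mean_trace, sem_trace
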