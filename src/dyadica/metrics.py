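"""Ethograms, sliding-window expressivity, and scalar behavior metrics.

An ethogram summarizes a trial (or a set of trials) as a graph: nodes are
actions weighted by their bout frequency normalized to all scored bouts,
and a directed edge A→B carries the fraction of A bouts that were followed
by a B bout of the same fly starting within a short window (1 s by
default) of A's end. By default only the earliest successor of each bout
is counted (so per-origin outgoing weights sum to at most 1); counting
every successor within the window is available as a variant.

Expressivity traces give, per frame, the fraction of a sliding window
(10 s for the comparative screen, 5 s for threat induction) annotated as
the action; group traces carry the mean with an SEM envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog import ActionCatalog
from .core import BoutTable, seconds_to_frames


@dataclass(frozen=True)
class Ethogram:
    node_counts: dict[str, int]
    node_freq: dict[str, float]
    edges: dict[tuple[str, str], float]
    window_s: float

    def to_dot(self, name: str = "ethogram") -> str:
        lines = [f"digraph {name} {{"]
        for a, f in self.node_freq.items():
            lines.append(f'  "{a}" [label="{a}\\n{f:.3f}"];')
        for (a, b), w in self.edges.items():
            lines.append(f'  "{a}" -> "{b}" [label="{w:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


def build_ethogram(
    bouts: BoutTable,
    actions: Optional[ActionCatalog] = None,
    window_s: float = 1.0,
    frame_rate: float = 30.0,
    multi_edge: bool = False,
) -> Ethogram:
    """Construct an ethogram from a bout table.

    Node frequencies pool bouts of all flies and are normalized to the
    total scored bout count. Transitions are within-fly: for each bout of
    action A by fly f, the destination is the action of f's earliest
    subsequent bout whose start falls within ``window_s`` of A's end
    (self-transitions allowed). Edge weight = transitions(A→B)/count(A).
    With ``multi_edge=True`` every subsequent bout inside the window
    contributes instead of only the earliest.
    """
    counts: dict[str, int] = {}
    for b in bouts:
        counts[b.action] = counts.get(b.action, 0) + 1
    total = sum(counts.values())
    freq = {a: c / total for a, c in counts.items()} if total else {}

    w = seconds_to_frames(window_s, frame_rate)
    trans: dict[tuple[str, str], int] = {}
    by_fly: dict[str, list] = {}
    for b in bouts:
        by_fly.setdefault(b.fly_id, []).append(b)
    for seq in by_fly.values():
        seq.sort(key=lambda b: (b.start, b.end))
        for i, b in enumerate(seq):
            for nxt in seq[i + 1 :]:
                if nxt.start < b.end:
                    continue  # overlapping other-action bout; not a successor
                if nxt.start - b.end > w:
                    break  # sorted by start: later bouts are farther still
                key = (b.action, nxt.action)
                trans[key] = trans.get(key, 0) + 1
                if not multi_edge:
                    break
    edges = {k: v / counts[k[0]] for k, v in trans.items()}
    return Ethogram(counts, freq, edges, window_s)


@dataclass(frozen=True)
class ExpressivityTrace:
    values: np.ndarray
    window_s: float
    action: str


def _indicator(
    bouts: BoutTable, action: str, n_frames: int, fly_id: Optional[str] = None
) -> np.ndarray:
    ind = np.zeros(n_frames, dtype=bool)
    for b in bouts.for_action(action):
        if fly_id is None or b.fly_id == fly_id:
            ind[b.start : min(b.end, n_frames)] = True
    return ind


def sliding_fraction(
    bouts: BoutTable,
    action: str,
    window_s: float,
    frame_rate: float,
    n_frames: int,
    fly_id: Optional[str] = None,
    edge: str = "truncate",
) -> ExpressivityTrace:
    """Per-frame fraction of a centered sliding window in the action.

    The indicator pools all flies unless ``fly_id`` is given. At trial
    edges the window is truncated and the fraction renormalized to the
    frames actually available (``edge="truncate"``, the default, which
    avoids artificial ramp-down); ``edge="clamp"`` instead slides the
    full-length window inside the trial. A window longer than the trial
    degenerates to the whole-trial fraction at every frame.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    ind = _indicator(bouts, action, n_frames, fly_id)
    w = max(1, seconds_to_frames(window_s, frame_rate))
    half = w // 2
    csum = np.concatenate([[0], np.cumsum(ind)])
    t = np.arange(n_frames)
    if edge == "truncate":
        lo = np.maximum(0, t - half)
        hi = np.minimum(n_frames, t - half + w)
    elif edge == "clamp":
        lo = np.clip(t - half, 0, max(0, n_frames - w))
        hi = np.minimum(lo + w, n_frames)
    else:
        raise ValueError("edge must be 'truncate' or 'clamp'")
    avail = hi - lo
    vals = (csum[hi] - csum[lo]) / avail
    return ExpressivityTrace(vals, window_s, action)


def group_trace(traces: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean and SEM over per-trial traces of equal length."""
    stack = np.vstack(traces)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def fraction_time(
    bouts: BoutTable,
    action: str,
    effective_duration: int,
    per_fly: bool = False,
    target: Optional[str] = None,
):
    """Fraction of the (possibly truncated) trial spent in the action.

    The union of bout intervals is used, so a pair's pooled fraction never
    exceeds 1; with ``per_fly=True`` a ``{fly_id: fraction}`` dict of
    per-fly unions is returned instead. ``target`` restricts to bouts
    directed at the named target.
    """
    if effective_duration <= 0:
        raise ValueError("effective_duration must be positive")
    sel = [
        b
        for b in bouts.for_action(action)
        if target is None or b.target == target
    ]
    if per_fly:
        out: dict[str, float] = {}
        for fly in {b.fly_id for b in sel}:
            ivs = [(b.start, b.end) for b in sel if b.fly_id == fly]
            out[fly] = _union_length(ivs) / effective_duration
        return out
    return _union_length([(b.start, b.end) for b in sel]) / effective_duration


def event_rate(
    bouts: BoutTable, action: str, effective_duration: int, frame_rate: float
) -> float:
    """Bout count per minute of effective duration (e.g. lunges/min)."""
    if effective_duration <= 0:
        raise ValueError("effective_duration must be positive")
    minutes = effective_duration / frame_rate / 60.0
    return len(bouts.for_action(action)) / minutes


@dataclass(frozen=True)
class Latency:
    time_s: float
    censored: bool


def latency(
    bouts: BoutTable, action: str, effective_duration: int, frame_rate: float
) -> Latency:
    """Seconds to the first onset of the action; censored at trial end."""
    sel = bouts.for_action(action)
    if not sel:
        return Latency(effective_duration / frame_rate, censored=True)
    return Latency(min(b.start for b in sel) / frame_rate, censored=False)


def cumulative_event_curve(
    latencies: Sequence[Latency],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative fraction of individuals having shown the event by time t.

    Returns ``(times_s, fractions, final_rate)`` describing a
    nondecreasing step function; censored entries never increment, so the
    final value is the overall event rate (the binomial-test input).
    """
    n = len(latencies)
    if n == 0:
        return np.array([0.0]), np.array([0.0]), 0.0
    events = sorted(l.time_s for l in latencies if not l.censored)
    times = [0.0]
    fracs = [0.0]
    for k, t in enumerate(events, start=1):
        times.append(t)
        fracs.append(k / n)
    return np.asarray(times), np.asarray(fracs), (len(events) / n)
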