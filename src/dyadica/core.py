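"""Core containers: bouts, bout tables, trials, and universal pre-processing.

Conventions used throughout the package:

* frames are 0-based and bout intervals are half-open ``[start, end)``;
* a bout's duration in seconds is ``(end - start) / frame_rate``;
* seconds-valued thresholds are converted to frames by round-half-up, so
  the conventional "at least 0.5 s" minimum on wing-extension bouts equals
  exactly 15 frames at the 30 Hz video rate;
* copulation is stored on the trial (``copulation_onset``) rather than as
  a bout; when present, all analysis is truncated at that frame and the
  latency to copulation replaces the recording length as the normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .catalog import ActionCatalog

ASSAYS = ("solitary", "dyad", "trio", "group-large-chamber", "ymaze", "song")


def seconds_to_frames(seconds: float, frame_rate: float) -> int:
    """Round-half-up conversion of a duration in seconds to frames."""
    import math

    return int(math.floor(seconds * frame_rate + 0.5))


@dataclass(frozen=True)
class Bout:
    """One contiguous interval of one fly performing one action.

    ``target`` optionally names the individual (or its sex) toward which a
    social action is directed; it is used by trio assays where courtship
    toward each of two targets is scored separately.
    """

    fly_id: str
    action: str
    start: int
    end: int
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"bout end must exceed start: {self.fly_id}/{self.action} "
                f"[{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"negative start frame {self.start}")

    def duration_s(self, frame_rate: float) -> float:
        return (self.end - self.start) / frame_rate

    @property
    def frames(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlyInfo:
    fly_id: str
    sex: str = "male"
    strain: str = "wildtype"
    housing: str = "single"
    genotype: str = "wildtype"
    wing_clipped: bool = False


@dataclass(frozen=True)
class Trial:
    """Metadata for one recording."""

    trial_id: str
    assay: str
    frame_rate: float
    duration: int
    roster: tuple[FlyInfo, ...] = ()
    copulation_onset: Optional[int] = None
    protocol_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; one of {ASSAYS}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.copulation_onset is not None and not (
            0 < self.copulation_onset < self.duration
        ):
            raise ValueError(
                f"copulation_onset {self.copulation_onset} outside "
                f"(0, {self.duration})"
            )

    @property
    def duration_s(self) -> float:
        return self.duration / self.frame_rate

    def fly_ids(self) -> list[str]:
        return [f.fly_id for f in self.roster]


@dataclass(frozen=True)
class BoutTable:
    """Ordered collection of bouts for one trial.

    Bouts are kept sorted by ``(start, fly_id, action)``; for a given
    (fly, action) pair the intervals must be pairwise non-overlapping.
    """

    trial_ref: str
    bouts: tuple[Bout, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.bouts, key=lambda b: (b.start, b.fly_id, b.action, b.end))
        )
        object.__setattr__(self, "bouts", ordered)
        last_end: dict[tuple[str, str], int] = {}
        for b in ordered:
            key = (b.fly_id, b.action)
            if key in last_end and b.start < last_end[key]:
                raise ValueError(
                    f"overlapping bouts for fly {b.fly_id!r} action "
                    f"{b.action!r} at frame {b.start}"
                )
            last_end[key] = max(last_end.get(key, 0), b.end)

    def __iter__(self) -> Iterator[Bout]:
        return iter(self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)

    def for_action(self, action: str) -> tuple[Bout, ...]:
        return tuple(b for b in self.bouts if b.action == action)

    def for_fly(self, fly_id: str) -> tuple[Bout, ...]:
        return tuple(b for b in self.bouts if b.fly_id == fly_id)

    def actions(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bouts:
            seen.setdefault(b.action, None)
        return list(seen)

    def validate_against(
        self, trial: Trial, catalog: Optional[ActionCatalog] = None
    ) -> None:
        """Check bounds against the trial and labels against a catalog."""
        for b in self.bouts:
            if b.end > trial.duration:
                raise ValueError(
                    f"bout {b.fly_id}/{b.action} [{b.start},{b.end}) exceeds "
                    f"trial duration {trial.duration}"
                )
            if catalog is not None and b.action not in catalog:
                raise ValueError(f"unknown action label {b.action!r}")

    def with_bouts(self, bouts: Iterable[Bout]) -> "BoutTable":
        return BoutTable(self.trial_ref, tuple(bouts))


def filter_min_duration(
    bouts: BoutTable,
    action: str,
    min_s: float,
    frame_rate: float,
    catalog: Optional[ActionCatalog] = None,
) -> BoutTable:
    """Drop bouts of ``action`` shorter than ``min_s`` seconds.

    The frame threshold is ``round(min_s * frame_rate)`` (half-up) and the
    comparison is inclusive ("at least"), so a 0.5 s minimum at 30 Hz keeps
    bouts of 15 frames and longer. Bouts of other actions are untouched.
    """
    if min_s < 0:
        raise ValueError("min_s must be non-negative")
    if catalog is not None and action not in catalog:
        raise ValueError(f"unknown action label {action!r}")
    thr = seconds_to_frames(min_s, frame_rate)
    kept = tuple(
        b for b in bouts if b.action != action or b.frames >= thr
    )
    return bouts.with_bouts(kept)


def truncate_at_copulation(
    trial: Trial, bouts: BoutTable
) -> tuple[Trial, BoutTable, int]:
    """Clip a trial at copulation onset, if one occurred.

    Bouts straddling the onset are shortened to end at it; bouts starting
    at or after it are dropped. The returned effective duration (frames) is
    the copulation latency when copulation occurred and the full trial
    duration otherwise; it is the normalizer for every downstream fraction,
    rate and latency. Idempotent.
    """
    onset = trial.copulation_onset
    if onset is None:
        return trial, bouts, trial.duration
    clipped = []
    for b in bouts:
        if b.start >= onset:
            continue
        if b.end > onset:
            b = replace(b, end=onset)
        clipped.append(b)
    new_trial = replace(trial, duration=onset, copulation_onset=None)
    return new_trial, BoutTable(bouts.trial_ref, tuple(clipped)), onset
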