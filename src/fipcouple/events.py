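"""Behavioral event definitions: trial inclusion, lick bouts, digging metrics.

Encodes the behavioral scoring rules of the pipeline:

* digging trials enter photometry analysis only with >= 3 s of digging and
  >= 10 s of non-digging baseline before onset;
* turning trials require a turn >= 90 degrees, >= 4 s since the previous
  turn, and no overlap with digging;
* licks < 1 s apart form a bout; lick initiation is the first lick strictly
  after a cue, within the response window;
* digging performance = mean duration, events per minute, and the fraction
  of digs that retrieved a pellet, within a fixed analysis window.

Exclusions are logged with the first violated rule, evaluated in the
documented order (duration -> baseline -> overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BehaviorEvent",
    "Bout",
    "Exclusion",
    "select_digging_trials",
    "select_turning_trials",
    "segment_lick_bouts",
    "lick_initiation",
    "digging_metrics",
]

EVENT_TYPES = ("digging", "turning", "lick", "cue", "other")


@dataclass
class BehaviorEvent:
    """Typed interval (or point) event on the session clock.

    ``offset == onset`` for point events (licks, cues). Turning events must
    carry ``turn_angle`` (degrees) in ``attributes``; digging events may
    carry ``retrieved_pellet`` (bool).
    """

    event_type: str
    onset: float
    offset: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.offset < self.onset:
            raise ValueError(f"offset {self.offset} < onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def overlaps(self, other: "BehaviorEvent") -> bool:
        return self.onset < other.offset and other.onset < self.offset


@dataclass
class Bout:
    """Maximal run of licks with consecutive inter-lick intervals < 1 s."""

    start: float
    end: float
    n_licks: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("bout end before start")
        if self.n_licks < 1:
            raise ValueError("bout must contain at least one lick")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class Exclusion:
    """Why an event was excluded: the first violated rule."""

    event: BehaviorEvent
    rule: str


def _sorted_of_type(events: list[BehaviorEvent], event_type: str) -> list[BehaviorEvent]:
    return sorted((e for e in events if e.event_type == event_type), key=lambda e: e.onset)


def select_digging_trials(
    events: list[BehaviorEvent],
    min_duration: float = 3.0,
    min_baseline: float = 10.0,
) -> tuple[list[BehaviorEvent], list[Exclusion]]:
    """Apply the digging-trial inclusion rules.

    A digging event is included iff its duration is >= ``min_duration``
    (3 s) and no digging occurs in the ``min_baseline`` (10 s) before its
    onset. Every exclusion is returned with the violated rule.

    Raises ``ValueError`` on overlapping digging events (annotation error).
    """
    digs = _sorted_of_type(events, "digging")
    for prev, cur in zip(digs, digs[1:]):
        if cur.onset < prev.offset:
            raise ValueError(
                f"overlapping digging events at {prev.onset:.3f}-{prev.offset:.3f} "
                f"and {cur.onset:.3f}-{cur.offset:.3f} s"
            )
    included: list[BehaviorEvent] = []
    excluded: list[Exclusion] = []
    for ev in digs:
        if ev.duration < min_duration:
            excluded.append(Exclusion(ev, f"duration {ev.duration:.2f} s < {min_duration} s"))
            continue
        # non-digging baseline: no other dig intersects (onset - 10 s, onset)
        dirty = any(
            o is not ev and o.offset > ev.onset - min_baseline and o.onset < ev.onset
            for o in digs
        )
        if dirty:
            excluded.append(Exclusion(ev, f"digging within {min_baseline} s before onset"))
            continue
        included.append(ev)
    return included, excluded


def select_turning_trials(
    events: list[BehaviorEvent],
    min_angle: float = 90.0,
    min_iti: float = 4.0,
) -> tuple[list[BehaviorEvent], list[Exclusion]]:
    """Apply the turning-trial inclusion rules.

    Included iff turn angle >= ``min_angle`` degrees, >= ``min_iti``
    seconds since the previous turning event's onset, and no temporal
    overlap with any digging event.
    """
    turns = _sorted_of_type(events, "turning")
    digs = _sorted_of_type(events, "digging")
    for ev in turns:
        if "turn_angle" not in ev.attributes:
            raise ValueError(f"turning event at {ev.onset:.3f} s lacks turn_angle")
    included: list[BehaviorEvent] = []
    excluded: list[Exclusion] = []
    prev_onset: float | None = None
    for ev in turns:
        angle = float(ev.attributes["turn_angle"])
        reason = None
        if angle < min_angle:
            reason = f"turn angle {angle:.1f} deg < {min_angle} deg"
        elif prev_onset is not None and ev.onset - prev_onset < min_iti:
            reason = f"inter-trial interval {ev.onset - prev_onset:.2f} s < {min_iti} s"
        elif any(ev.overlaps(d) for d in digs):
            reason = "overlaps a digging event"
        if reason is None:
            included.append(ev)
        else:
            excluded.append(Exclusion(ev, reason))
        prev_onset = ev.onset
    return included, excluded


def segment_lick_bouts(lick_times, max_ili: float = 1.0) -> list[Bout]:
    """Partition licks into bouts: maximal runs with gaps strictly < ``max_ili``.

    A gap of exactly ``max_ili`` splits (the bout rule is "interval less
    than 1 s"). Bout length = last lick - first lick, so a lone lick forms
    a zero-length bout.
    """
    t = np.asarray(lick_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise ValueError("lick timestamps must be strictly increasing")
    bouts: list[Bout] = []
    start = 0
    for i in range(1, t.size):
        if t[i] - t[i - 1] >= max_ili:
            bouts.append(Bout(float(t[start]), float(t[i - 1]), i - start))
            start = i
    bouts.append(Bout(float(t[start]), float(t[-1]), t.size - start))
    return bouts


def lick_initiation(
    lick_times, cue_times, response_window: float = 3.0
) -> list[float | None]:
    """First lick strictly after each cue, within the response window.

    Returns one entry per cue: the initiation time, or ``None`` if no lick
    lands in ``(cue, cue + response_window]`` (trial unrewarded). A lick
    exactly at the cue time is not counted.
    """
    licks = np.asarray(lick_times, dtype=float)
    out: list[float | None] = []
    for cue in np.asarray(cue_times, dtype=float):
        in_win = licks[(licks > cue) & (licks <= cue + response_window)]
        out.append(float(in_win[0]) if in_win.size else None)
    return out


def digging_metrics(
    events: list[BehaviorEvent],
    analysis_window: tuple[float, float],
) -> tuple[float | None, float, float | None]:
    """Digging performance within an analysis window.

    The window is anchored by the caller (conventionally the first 10 min
    after the center pellet is acquired). Returns
    ``(mean_duration_s, frequency_per_min, success_rate)``; with no digs
    inside the window, duration and success rate are ``None`` and the
    frequency is 0. A dig counts as inside if its onset falls in the window.
    """
    lo, hi = analysis_window
    if hi <= lo:
        raise ValueError("empty analysis window")
    digs = [e for e in _sorted_of_type(events, "digging") if lo <= e.onset < hi]
    minutes = (hi - lo) / 60.0
    if not digs:
        return None, 0.0, None
    mean_dur = float(np.mean([d.duration for d in digs]))
    freq = len(digs) / minutes
    n_success = sum(bool(d.attributes.get("retrieved_pellet", False)) for d in digs)
    return mean_dur, freq, n_success / len(digs)
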