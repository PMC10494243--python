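"""Stimulation protocols.

A protocol is an ordered, contiguous sequence of named segments, each either
inactive (substimulatory glucose) or active (stimulatory glucose, optionally
with an adenylyl-cyclase activator such as forskolin).  Active segments carry
the oscillation frequency and mean oscillation duration the stimulus is
expected to evoke, and optionally a per-segment synchrony override used by the
synthetic generator.

Consecutive active segments form a *stimulation episode*: a cell activates
once at the start of an episode (after its activation delay) and deactivates
once after the episode ends (after its deactivation delay), while oscillation
parameters may switch at internal segment boundaries (e.g. glucose ->
glucose + forskolin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class Segment:
    """One contiguous stretch of a stimulation protocol.

    Parameters
    ----------
    name : condition label, e.g. ``"12mM glucose"``.
    start, end : segment boundaries in seconds; ``start < end``.
    active : whether the condition drives oscillatory activity.
    freq_hz : target oscillation frequency for active segments (Hz).
    duration_s : target mean oscillation duration for active segments (s).
    sync : optional synchrony override in [0, 1] for the synthetic
        generator; ``None`` falls back to the islet-level value.
    """

    name: str
    start: float
    end: float
    active: bool = False
    freq_hz: float = 0.0
    duration_s: float = 0.0
    sync: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment {self.name!r}: start must be < end")
        if self.freq_hz < 0:
            raise ValueError(f"segment {self.name!r}: frequency must be >= 0")
        if self.active:
            if self.freq_hz <= 0:
                raise ValueError(f"active segment {self.name!r} needs freq_hz > 0")
            if self.duration_s <= 0:
                raise ValueError(f"active segment {self.name!r} needs duration_s > 0")
            if self.duration_s > 1.0 / self.freq_hz:
                raise ValueError(
                    f"active segment {self.name!r}: duration exceeds the "
                    f"oscillation period 1/freq"
                )
        if self.sync is not None and not 0.0 <= self.sync <= 1.0:
            raise ValueError("sync must lie in [0, 1]")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Protocol:
    """Ordered, contiguous, non-overlapping stimulation segments."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Sequence[Segment]):
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError(
                    f"segments {a.name!r} and {b.name!r} are not contiguous"
                )

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def active_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.active)

    def episodes(self) -> list[tuple[Segment, ...]]:
        """Maximal runs of consecutive active segments."""
        runs: list[list[Segment]] = []
        for seg in self.segments:
            if seg.active:
                if runs and runs[-1] and runs[-1][-1].end == seg.start:
                    runs[-1].append(seg)
                else:
                    runs.append([seg])
        return [tuple(r) for r in runs]

    @property
    def stim_onset(self) -> float:
        """Start of the first active segment (activation reference)."""
        act = self.active_segments
        if not act:
            raise ValueError("protocol has no active segment")
        return act[0].start

    @property
    def stim_offset(self) -> float:
        """End of the last active segment (deactivation reference)."""
        act = self.active_segments
        if not act:
            raise ValueError("protocol has no active segment")
        return act[-1].end

    def segment_at(self, t: float) -> Segment:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg
        if t == self.end:
            return self.segments[-1]
        raise ValueError(f"time {t} s outside protocol [{self.start}, {self.end}]")

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        return json.dumps([asdict(s) for s in self.segments])

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        return cls([Segment(**d) for d in json.loads(text)])


def glucose_control_protocol(
    pre_s: float = 300.0,
    stim_s: float = 1500.0,
    post_s: float = 900.0,
    freq_hz: float = 0.033,
    duration_s: float = 10.7,
    sync: float | None = None,
    sync_late: float | None = None,
    split_s: float | None = None,
) -> Protocol:
    """Square-pulse glucose protocol: 6 mM -> 12 mM (25 min) -> 6 mM.

    With ``split_s`` the stimulatory plateau is split into an early and a late
    segment at ``split_s`` seconds after stimulus onset, so the late part can
    carry its own synchrony (``sync_late``) — this mirrors the progressive
    desynchronization seen under prolonged glucose stimulation.
    """
    t0, t1 = pre_s, pre_s + stim_s
    segs = [Segment("6mM glucose", 0.0, t0)]
    if split_s is None:
        segs.append(
            Segment("12mM glucose", t0, t1, True, freq_hz, duration_s, sync)
        )
    else:
        ts = t0 + split_s
        segs.append(Segment("12mM glucose", t0, ts, True, freq_hz, duration_s, sync))
        segs.append(
            Segment("12mM glucose late", ts, t1, True, freq_hz, duration_s, sync_late)
        )
    segs.append(Segment("6mM glucose washout", t1, t1 + post_s))
    return Protocol(segs)


def glucose_forskolin_protocol(
    pre_s: float = 300.0,
    glucose_s: float = 900.0,
    forskolin_s: float = 600.0,
    post_s: float = 900.0,
    freq_hz: float = 0.033,
    duration_s: float = 10.7,
    fsk_freq_hz: float = 0.058,
    fsk_duration_s: float = 8.5,
    sync: float | None = None,
    fsk_sync: float | None = None,
) -> Protocol:
    """6 mM -> 12 mM glucose (15 min) -> 12 mM + 10 uM forskolin (10 min) -> 6 mM.

    Forskolin raises the oscillation frequency and shortens oscillations;
    the defaults encode that condition shift.
    """
    t0 = pre_s
    t1 = t0 + glucose_s
    t2 = t1 + forskolin_s
    return Protocol(
        [
            Segment("6mM glucose", 0.0, t0),
            Segment("12mM glucose", t0, t1, True, freq_hz, duration_s, sync),
            Segment(
                "12mM glucose + forskolin", t1, t2, True, fsk_freq_hz,
                fsk_duration_s, fsk_sync,
            ),
            Segment("6mM glucose washout", t2, t2 + post_s),
        ]
    )
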