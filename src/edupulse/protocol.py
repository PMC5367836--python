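"""Labelling protocols: injection schedules to pulse/chase windows.

An in-vivo EdU/BrdU injection keeps the label bioavailable for a limited
time (modelled as a square 1-hour window by default).  A schedule of
injections therefore induces a partition of the experiment into contiguous
label-on (pulse) and label-off (chase) windows.  The half-open convention
``[start, end)`` is used throughout: an event at a boundary belongs to the
later window, and instant-labelling transfers fire at pulse starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "InjectionSchedule",
    "Protocol",
    "InvalidScheduleError",
    "build_protocol",
    "default_study_protocol",
    "single_pulse_protocol",
]


class InvalidScheduleError(ValueError):
    """Injection schedule violates its ordering/positivity invariants."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection times, label bioavailability and sacrifice time (hours)."""

    injection_times_h: tuple[float, ...]
    availability_h: float = 1.0
    sacrifice_h: float = 16.5

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.injection_times_h)
        object.__setattr__(self, "injection_times_h", times)
        if not times:
            raise InvalidScheduleError("at least one injection is required")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidScheduleError("injection times must be strictly increasing")
        if self.availability_h <= 0:
            raise InvalidScheduleError("availability_h must be > 0")
        if self.sacrifice_h < times[-1]:
            raise InvalidScheduleError("sacrifice_h must be >= the last injection time")
        if self.sacrifice_h <= 0:
            raise InvalidScheduleError("sacrifice_h must be > 0")


@dataclass(frozen=True)
class Protocol:
    """Contiguous, alternating pulse/chase windows covering [0, sacrifice]."""

    windows: tuple[tuple[float, float, bool], ...]

    def __post_init__(self) -> None:
        w = tuple((float(a), float(b), bool(on)) for a, b, on in self.windows)
        object.__setattr__(self, "windows", w)
        if not w:
            raise InvalidScheduleError("a protocol needs at least one window")
        for a, b, _ in w:
            if b <= a:
                raise InvalidScheduleError(f"empty or inverted window ({a}, {b})")
        for (a0, b0, on0), (a1, b1, on1) in zip(w, w[1:]):
            if a1 != b0:
                raise InvalidScheduleError("windows must be contiguous")
            if on1 == on0:
                raise InvalidScheduleError("adjacent windows must alternate label state")

    @property
    def sacrifice_h(self) -> float:
        return self.windows[-1][1]

    @property
    def total_on_h(self) -> float:
        return sum(b - a for a, b, on in self.windows if on)

    @property
    def total_off_h(self) -> float:
        return sum(b - a for a, b, on in self.windows if not on)

    def label_on_at(self, t: float) -> bool:
        """Label state at time ``t`` under the [start, end) convention."""
        for a, b, on in self.windows:
            if a <= t < b:
                return on
        return self.windows[-1][2] if t == self.sacrifice_h else False


def build_protocol(schedule: InjectionSchedule) -> Protocol:
    """Convert an injection schedule to merged pulse/chase windows.

    Each injection opens a label-on interval of ``availability_h`` hours;
    overlapping intervals merge, intervals truncate at ``sacrifice_h`` and
    the gaps are chase windows.
    """
    end = schedule.sacrifice_h
    # merge overlapping/adjacent availability intervals
    merged: list[list[float]] = []
    for t in schedule.injection_times_h:
        lo, hi = t, min(t + schedule.availability_h, end)
        if hi <= lo:
            continue
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    windows: list[tuple[float, float, bool]] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            windows.append((cursor, lo, False))
        windows.append((lo, hi, True))
        cursor = hi
    if cursor < end:
        windows.append((cursor, end, False))
    return Protocol(tuple(windows))


def default_study_protocol(
    injection_times_h: Sequence[float] = (0.0, 1.0, 16.0),
    availability_h: float = 1.0,
    sacrifice_h: float = 16.5,
) -> Protocol:
    """The pulse-chase-pulse design: injections at 0, 1 and 16 h, sacrifice 16.5 h.

    Yields a 2-h initial pulse (the first two injections merge), a 14-h chase
    and a final 30-min pulse.
    """
    return build_protocol(
        InjectionSchedule(tuple(injection_times_h), availability_h, sacrifice_h)
    )


def single_pulse_protocol(pulse_h: float = 1.0, chase_h: float = 19.0) -> Protocol:
    """A single injection followed by a chase (the classic BrdU validation design)."""
    return build_protocol(
        InjectionSchedule((0.0,), availability_h=pulse_h, sacrifice_h=pulse_h + chase_h)
    )
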