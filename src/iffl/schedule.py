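"""Piecewise-constant input protocols: timed additions of activator A and inhibitor I.

The circuit input ``u`` is the running total activator concentration
[A_tot].  Additions of A increase it stepwise; additions of the inhibitor
strand I (a perfect complement of A) neutralize A stoichiometrically.
Strand displacement is fast relative to circuit timescales, so each I
addition is applied as an instantaneous reduction, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple


@dataclass(frozen=True)
class InputEvent:
    time: float          # min (or scaled time for dimensionless runs)
    species: str         # "A" or "I"
    amount: float        # nM, strictly positive

    def __post_init__(self) -> None:
        if self.species not in ("A", "I"):
            raise ValueError(f"species must be 'A' or 'I', got {self.species!r}")
        if self.amount <= 0:
            raise ValueError("event amount must be strictly positive")
        if self.time < 0:
            raise ValueError("event time must be nonnegative")


@dataclass(frozen=True)
class InputSchedule:
    """Ordered list of timed A/I additions."""

    events: Tuple[InputEvent, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, InputEvent) else InputEvent(*e)
            for e in self.events
        )
        times = [e.time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")
        object.__setattr__(self, "events", events)

    @classmethod
    def from_totals(cls, times: Iterable[float], totals: Iterable[float],
                    description: str = "") -> "InputSchedule":
        """Build a schedule from target running totals of [A_tot].

        Each step adds (or, via I, removes) exactly the difference between
        consecutive targets.
        """
        events: List[InputEvent] = []
        running = 0.0
        for t, target in zip(times, totals):
            delta = target - running
            if delta > 0:
                events.append(InputEvent(t, "A", delta))
            elif delta < 0:
                events.append(InputEvent(t, "I", -delta))
            running = target
        return cls(tuple(events), description)

    @property
    def event_times(self) -> Tuple[float, ...]:
        return tuple(e.time for e in self.events)

    def u(self, t: float) -> float:
        """Running [A_tot] at time ``t`` (events at exactly ``t`` included)."""
        return input_u(self, t)


def input_u(schedule: InputSchedule, t: float) -> float:
    """Evaluate the running activator total at time ``t``.

    A additions accumulate; each I addition neutralizes an equal amount of
    activator instantaneously, floored at zero.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    running = 0.0
    for e in schedule.events:
        if e.time > t:
            break
        if e.species == "A":
            running += e.amount
        else:
            running = max(running - e.amount, 0.0)
    return running


def doubling_schedule(u0: float = 10.0, t_first: float = 120.0,
                      interval: float = 60.0, n_doublings: int = 4) -> InputSchedule:
    """Two-fold input staircase: ``u0`` at t=0, then doubling every ``interval``.

    With the defaults this is the fold-change-detection protocol:
    [A_tot] = 10 nM at time 0, 20 nM at 2 h, 40 nM at 3 h, 80 nM at 4 h
    and 160 nM at 5 h.
    """
    events = [InputEvent(0.0, "A", u0)]
    total = u0
    for i in range(n_doublings):
        events.append(InputEvent(t_first + i * interval, "A", total))
        total *= 2
    return InputSchedule(tuple(events),
                         description=f"doubling staircase from {u0} nM")
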