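"""Dosing regimens: named schedules expanded to timed IV-infusion events.

A regimen is an ordered list of blocks ``(amount_mg, interval_days,
n_doses)``.  The paper's study regimens give 7 doses (cycles) each: the
standard 1200 mg q3w arm and three extended-interval arms with two loading
doses followed by 840 mg q6w maintenance.  When the schedule crosses a
block boundary, the gap before the first dose of the new block equals the
NEW block's interval — i.e. "two loading doses followed by q6w" means the
first maintenance dose comes 42 days after the second loading dose.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DoseEvent",
    "RegimenBlock",
    "Regimen",
    "CycleWindow",
    "expand_regimen",
    "builtin_regimens",
    "DEFAULT_INFUSION_DAYS",
]

#: default IV infusion length: 1 hour, in days
DEFAULT_INFUSION_DAYS = 1.0 / 24.0


@dataclass(frozen=True)
class DoseEvent:
    """One IV administration: start time (days), amount (mg), infusion duration (days, 0 = bolus)."""

    time: float
    amount: float
    duration: float = DEFAULT_INFUSION_DAYS

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"infusion duration must be >= 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/day (inf for a bolus)."""
        return self.amount / self.duration if self.duration > 0 else float("inf")


@dataclass(frozen=True)
class RegimenBlock:
    amount: float        # mg
    interval: float      # days
    n_doses: int

    def __post_init__(self) -> None:
        if self.amount <= 0 or self.interval <= 0 or self.n_doses < 1:
            raise ValueError(f"invalid regimen block {self!r}")


@dataclass(frozen=True)
class Regimen:
    """A named dosing schedule."""

    name: str
    blocks: tuple

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("regimen must have at least one block")
        object.__setattr__(self, "blocks", tuple(
            b if isinstance(b, RegimenBlock) else RegimenBlock(*b) for b in self.blocks))

    @property
    def total_doses(self) -> int:
        return sum(b.n_doses for b in self.blocks)


@dataclass(frozen=True)
class CycleWindow:
    """Cycle k spans from dose k to the time of dose k+1 (final cycle: one interval)."""

    index: int
    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


def expand_regimen(regimen: Regimen, infusion_duration: float = DEFAULT_INFUSION_DAYS):
    """Expand a regimen into (dose events, cycle windows).

    Dose k+1 occurs one interval of *its own* block after dose k; the last
    cycle window extends one final interval past the last dose.  Windows
    are contiguous and partition [0, last_end).
    """
    times: list[float] = []
    amounts: list[float] = []
    intervals: list[float] = []
    t = 0.0
    for bi, block in enumerate(regimen.blocks):
        for di in range(block.n_doses):
            if times:
                t = times[-1] + block.interval
            times.append(t)
            amounts.append(block.amount)
            intervals.append(block.interval)
    events = [DoseEvent(time=ti, amount=ai, duration=infusion_duration)
              for ti, ai in zip(times, amounts)]
    windows = []
    for k in range(len(times)):
        end = times[k + 1] if k + 1 < len(times) else times[k] + intervals[k]
        windows.append(CycleWindow(index=k + 1, start=times[k], end=end))
    return events, windows


def builtin_regimens() -> dict:
    """The four study regimens, keyed by their table labels.

    Standard-of-care 1200 mg q3w, plus three 7-cycle extended-interval
    arms: two loading doses (840 q2w / 1200 q3w / 1680 q4w) followed by
    five 840 mg q6w maintenance doses.
    """
    regs = [
        Regimen("1200 mg q3w", ((1200.0, 21.0, 7),)),
        Regimen("840 mg q2w x2, 840 mg q6w x5", ((840.0, 14.0, 2), (840.0, 42.0, 5))),
        Regimen("1200 mg q3w x2, 840 mg q6w x5", ((1200.0, 21.0, 2), (840.0, 42.0, 5))),
        Regimen("1680 mg q4w x2, 840 mg q6w x5", ((1680.0, 28.0, 2), (840.0, 42.0, 5))),
    ]
    return {r.name: r for r in regs}
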