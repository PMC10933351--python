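"""Dependent-variable computation for the four motor assays.

Rotarod: latency to fall (s), 4 trials x 4 days, ceiling 300 s.
ErasmusLadder: percent correct steps per run, 42 runs x 5 days; a correct
step is a front-paw step landing on a high rung whose previous front-paw
placement was also on a high rung; touching a low rung is a misstep.
Balance beam: crossing time (s) on 6 and 12 mm beams, 2 crossings each.
Grip strength: peak force, 2 trials x 4 days (values passed through in the
unit the force gauge reports).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import (
    Assay,
    AssayRecord,
    Group,
    ROTAROD_MAX_S,
    assay_records_to_frame,
)

__all__ = [
    "Paw",
    "RungHeight",
    "LadderRun",
    "score_ladder_run",
    "ladder_table",
    "rotarod_table",
    "beam_table",
    "grip_table",
]

#: design cardinalities (days, trials-or-runs per day)
DESIGN = {
    Assay.ROTAROD: (4, 4),
    Assay.LADDER: (5, 42),
    Assay.GRIP: (4, 2),
}
BEAM_CROSSINGS_PER_WIDTH = 2


class Paw(str, enum.Enum):
    FRONT_LEFT = "front_left"
    FRONT_RIGHT = "front_right"
    HIND_LEFT = "hind_left"
    HIND_RIGHT = "hind_right"

    @property
    def is_front(self) -> bool:
        return self in (Paw.FRONT_LEFT, Paw.FRONT_RIGHT)


class RungHeight(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


@dataclass(frozen=True)
class LadderRun:
    """One ErasmusLadder crossing as a time-ordered rung-touch sequence."""

    mouse_id: str
    group: Group
    day: int
    run_index: int
    steps: tuple[tuple[Paw, RungHeight], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        steps = tuple(
            (Paw(p), RungHeight(h)) for p, h in self.steps
        )
        object.__setattr__(self, "steps", steps)
        if not 1 <= self.run_index <= DESIGN[Assay.LADDER][1]:
            raise ValueError(f"run_index out of range: {self.run_index}")
        if not any(p.is_front for p, _ in steps):
            raise ValueError("a ladder run needs at least one front-paw step")


def score_ladder_run(run: LadderRun, rule: str = "landing") -> float:
    """Percent correct steps over the run's front-paw transitions.

    Only front-paw placements are scored, in temporal order; hind-paw steps
    are recorded but never scored, and the first front-paw placement has no
    predecessor so it is excluded from the transition count. Touching a low
    rung is a misstep. Under the default ``"landing"`` rule a transition is
    correct when the landing rung is high (the landing rung decides, the
    step length never matters); the stricter ``"pair"`` rule additionally
    requires the previous front-paw placement to have been high. A run with
    a single front-paw step has no transitions and scores ``nan``.
    """
    heights = [h for p, h in run.steps if p.is_front]
    n_trans = len(heights) - 1
    if n_trans == 0:
        return float("nan")
    if rule == "landing":
        correct = sum(1 for cur in heights[1:] if cur is RungHeight.HIGH)
    elif rule == "pair":
        correct = sum(
            1
            for prev, cur in zip(heights, heights[1:])
            if prev is RungHeight.HIGH and cur is RungHeight.HIGH
        )
    else:
        raise ValueError(f"unknown scoring rule: {rule!r}")
    return 100.0 * correct / n_trans


def ladder_table(runs: Sequence[LadderRun]) -> pd.DataFrame:
    """Score runs and assemble the tidy ladder analysis table."""
    records = []
    for r in runs:
        pct = score_ladder_run(r)
        if pct != pct:  # nan: single-step run, nothing to score
            warnings.warn(
                f"{r.mouse_id} day {r.day} run {r.run_index}: single "
                "front-paw step, no transitions to score",
                stacklevel=2,
            )
            continue
        records.append(
            AssayRecord(
                assay=Assay.LADDER,
                mouse_id=r.mouse_id,
                group=r.group,
                day=r.day,
                trial_or_run=r.run_index,
                value=pct,
            )
        )
    frame = assay_records_to_frame(records)
    _check_cardinality(frame, Assay.LADDER)
    return frame


def _check_cardinality(frame: pd.DataFrame, assay: Assay) -> None:
    days, per_day = DESIGN[assay]
    expected = days * per_day
    counts = frame.groupby("mouse_id").size()
    short = counts[counts != expected]
    if len(short):
        warnings.warn(
            f"{assay.value}: expected {expected} values per mouse "
            f"({days} days x {per_day}), got deviations for "
            f"{dict(short)}; missingness is handled downstream",
            stacklevel=3,
        )
    dup = frame.duplicated(subset=["mouse_id", "day", "trial_or_run"])
    if dup.any():
        raise ValueError(
            f"duplicate (mouse, day, trial) rows in {assay.value} table: "
            f"{frame.loc[dup, ['mouse_id', 'day', 'trial_or_run']].to_dict('records')}"
        )


def rotarod_table(records: Sequence[AssayRecord]) -> pd.DataFrame:
    """Validated tidy rotarod table (latency to fall, s).

    Latencies outside (0, 300] are rejected at record construction; here the
    4 x 4 design cardinality and (mouse, day, trial) uniqueness are checked.
    Missing trials produce a warning, not an error.
    """
    for r in records:
        if r.assay is not Assay.ROTAROD:
            raise ValueError(f"expected rotarod records, got {r.assay.value}")
        if not 0 < r.value <= ROTAROD_MAX_S:
            raise ValueError(f"rotarod latency out of range: {r.value}")
    frame = assay_records_to_frame(records)
    _check_cardinality(frame, Assay.ROTAROD)
    return frame


def beam_table(records: Sequence[AssayRecord]) -> pd.DataFrame:
    """Validated tidy balance-beam table (crossing time, s).

    Two crossings per beam width (6 and 12 mm), four values per mouse.
    """
    for r in records:
        if r.assay is not Assay.BEAM:
            raise ValueError(f"expected beam records, got {r.assay.value}")
    frame = assay_records_to_frame(records)
    counts = frame.groupby(["mouse_id", "beam_width_mm"]).size()
    off = counts[counts != BEAM_CROSSINGS_PER_WIDTH]
    if len(off):
        warnings.warn(
            f"beam: expected {BEAM_CROSSINGS_PER_WIDTH} crossings per width "
            f"per mouse, deviations: {dict(off)}",
            stacklevel=2,
        )
    dup = frame.duplicated(subset=["mouse_id", "beam_width_mm", "trial_or_run"])
    if dup.any():
        raise ValueError("duplicate (mouse, width, crossing) rows in beam table")
    return frame


def grip_table(records: Sequence[AssayRecord]) -> pd.DataFrame:
    """Validated tidy grip-strength table (peak force, 2 x 4 design)."""
    for r in records:
        if r.assay is not Assay.GRIP:
            raise ValueError(f"expected grip records, got {r.assay.value}")
    frame = assay_records_to_frame(records)
    _check_cardinality(frame, Assay.GRIP)
    return frame
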