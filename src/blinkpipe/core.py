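"""Shared data model for eyeblink-conditioning trials, sessions and motor assays.

The experiment this package analyses is a 20-day delay eyeblink-conditioning
protocol in head-fixed mice: each daily session delivers 240 trials in 20
blocks, every block holding 1 CS-only, 1 US-only and 10 paired CS–US trials in
semi-random order. Days 1–10 use a 250 ms interstimulus interval (ISI) with a
280 ms light CS; days 11–20 use a 500 ms ISI with a 530 ms CS. Mice belong to
one of two housing groups (standard or enriched). Four motor assays (rotarod,
ErasmusLadder, balance beam, grip strength) are recorded as tidy tables.

All latencies are expressed in milliseconds relative to CS onset. Analysis
windows are closed intervals, and ms-to-sample mapping uses
``floor(latency_ms * rate / 1000)`` so that window edges land on deterministic
samples at any sample rate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, fields, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "TrialType",
    "RejectionReason",
    "Assay",
    "TrialMeta",
    "RawTrial",
    "NormalizedTrial",
    "SessionNormalization",
    "CRDetection",
    "SessionOutcome",
    "AssayRecord",
    "build_experiment_schedule",
    "ms_to_offset",
    "pre_cs_slice",
    "window_slice",
    "outcomes_to_frame",
    "assay_records_to_frame",
    "assay_records_from_frame",
]

PRE_CS_MS = 500.0
POST_CS_MS = 1000.0
TRIALS_PER_DAY = 240
BLOCKS_PER_DAY = 20
PAIRED_PER_BLOCK = 10
N_DAYS = 20
ISI_SWITCH_DAY = 11  # first day of the 500 ms ISI phase
CS_US_GAP_MS = 30.0  # CS outlasts US onset by 30 ms in both phases


class Group(str, enum.Enum):
    """Housing group."""

    STANDARD = "standard"
    ENRICHED = "enriched"


class TrialType(str, enum.Enum):
    CS_ONLY = "cs_only"
    US_ONLY = "us_only"
    PAIRED = "paired"


class RejectionReason(str, enum.Enum):
    PRE_CS_ACTIVITY = "pre_cs_activity"


class Assay(str, enum.Enum):
    ROTAROD = "rotarod"
    LADDER = "ladder"
    BEAM = "beam"
    GRIP = "grip"


def isi_for_day(day: int) -> int:
    """ISI in ms for a training day: 250 on days 1-10, 500 on days 11-20."""
    if not 1 <= day <= N_DAYS:
        raise ValueError(f"day must be in 1..{N_DAYS}, got {day}")
    return 250 if day < ISI_SWITCH_DAY else 500


@dataclass(frozen=True)
class TrialMeta:
    """Identity and design metadata of a single trial."""

    mouse_id: str
    group: Group
    day: int
    block: int
    trial_index: int
    trial_type: TrialType
    isi_ms: int
    cs_duration_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "trial_type", TrialType(self.trial_type))
        if not 1 <= self.day <= N_DAYS:
            raise ValueError(f"day out of range: {self.day}")
        if not 1 <= self.block <= BLOCKS_PER_DAY:
            raise ValueError(f"block out of range: {self.block}")
        if self.isi_ms not in (250, 500):
            raise ValueError(f"isi_ms must be 250 or 500, got {self.isi_ms}")
        if self.isi_ms != isi_for_day(self.day):
            raise ValueError(
                f"isi_ms {self.isi_ms} inconsistent with day {self.day}"
            )
        if self.cs_duration_ms != self.isi_ms + CS_US_GAP_MS:
            raise ValueError(
                f"cs_duration_ms must be isi_ms + {CS_US_GAP_MS:g}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group"] = self.group.value
        d["trial_type"] = self.trial_type.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def ms_to_offset(latency_ms: float, sample_rate_hz: float) -> int:
    """Map a latency in ms (relative to CS onset) to a sample offset.

    Uses ``floor`` so that closed windows ``[lo, hi]`` include every sample
    whose time stamp lies inside the interval.
    """
    return int(np.floor(latency_ms * sample_rate_hz / 1000.0))


@dataclass
class RawTrial:
    """One raw eyelid-position time series.

    ``samples`` are raw sensor units (larger = eye more closed); at least
    500 ms of baseline must precede ``cs_onset_index`` and at least 1000 ms
    must follow it, so the pre-CS artifact filter and the 100-1000 ms response
    window are always fully sampled.
    """

    meta: TrialMeta
    samples: np.ndarray
    sample_rate_hz: float
    cs_onset_index: int
    pre_cs_ms: float = PRE_CS_MS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.pre_cs_ms < PRE_CS_MS:
            raise ValueError(f"pre_cs_ms must be >= {PRE_CS_MS:g} ms")
        n_pre = ms_to_offset(PRE_CS_MS, self.sample_rate_hz)
        if self.cs_onset_index < n_pre:
            raise ValueError(
                f"need >= {PRE_CS_MS:g} ms of pre-CS samples, have "
                f"{self.cs_onset_index / self.sample_rate_hz * 1000:.0f} ms"
            )
        n_post = self.samples.size - self.cs_onset_index
        if n_post < ms_to_offset(POST_CS_MS, self.sample_rate_hz) + 1:
            raise ValueError(
                f"need >= {POST_CS_MS:g} ms of post-CS samples, have "
                f"{n_post / self.sample_rate_hz * 1000:.0f} ms"
            )

    def times_ms(self) -> np.ndarray:
        """Time stamp of every sample in ms relative to CS onset."""
        idx = np.arange(self.samples.size) - self.cs_onset_index
        return idx * 1000.0 / self.sample_rate_hz


@dataclass
class NormalizedTrial:
    """Baseline-aligned trace on the normalized eyelid-closure scale.

    0 = eye fully open, 1 = eye fully closed; the scale is set per mouse-day
    by the peak of the averaged unconditioned response (UR).
    """

    meta: TrialMeta
    samples: np.ndarray
    sample_rate_hz: float
    cs_onset_index: int
    valid: bool = True
    rejection_reason: Optional[RejectionReason] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rejection_reason is not None:
            self.rejection_reason = RejectionReason(self.rejection_reason)
        if not self.valid and self.rejection_reason is None:
            raise ValueError("invalid trial must carry a rejection_reason")

    def times_ms(self) -> np.ndarray:
        idx = np.arange(self.samples.size) - self.cs_onset_index
        return idx * 1000.0 / self.sample_rate_hz


@dataclass(frozen=True)
class SessionNormalization:
    """Per-mouse-day normalization reference.

    ``ur_peak_raw`` is the maximum of the day's averaged UR (baseline-aligned
    raw units); dividing every trace of the day by it puts a full reflexive
    blink at 1.
    """

    mouse_id: str
    day: int
    ur_peak_raw: float
    n_ur_trials: int

    def __post_init__(self) -> None:
        if self.ur_peak_raw <= 0:
            raise ValueError("ur_peak_raw must be strictly positive")
        if self.n_ur_trials < 1:
            raise ValueError("need at least one UR trial")


@dataclass(frozen=True)
class CRDetection:
    """Per-trial conditioned-response classification.

    A CR requires a normalized peak amplitude > 0.1 in the 100-1000 ms
    window, onset latency in [50, 500] ms and peak latency in [100, 1000] ms.
    ``perfectly_timed`` is defined only for CR trials.
    """

    meta: TrialMeta
    is_cr: bool
    onset_latency_ms: Optional[float] = None
    peak_latency_ms: Optional[float] = None
    peak_amplitude: Optional[float] = None
    perfectly_timed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.is_cr:
            if self.peak_amplitude is None or self.peak_latency_ms is None:
                raise ValueError("CR must carry peak amplitude and latency")
        elif self.perfectly_timed is not None:
            raise ValueError("perfectly_timed is defined only for CRs")


@dataclass(frozen=True)
class SessionOutcome:
    """The six per-mouse-per-day eyeblink outcomes.

    Fields whose denominator is empty (e.g. latency means on a day without
    CRs) are ``None``, never zero.
    """

    mouse_id: str
    group: Group
    day: int
    n_valid_trials: int
    n_cr_trials: int
    cr_probability: float
    nec_all_trials: float
    nec_cr_trials: Optional[float] = None
    mean_onset_latency_ms: Optional[float] = None
    mean_peak_latency_ms: Optional[float] = None
    pct_perfect: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        if not 0.0 <= self.cr_probability <= 1.0:
            raise ValueError("cr_probability must lie in [0, 1]")


#: closed vocabulary of beam widths (mm)
BEAM_WIDTHS_MM = (6, 12)
ROTAROD_MAX_S = 300.0


@dataclass(frozen=True)
class AssayRecord:
    """One tidy motor-assay measurement."""

    assay: Assay
    mouse_id: str
    group: Group
    trial_or_run: int
    value: float
    day: Optional[int] = None
    beam_width_mm: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        object.__setattr__(self, "group", Group(self.group))
        if self.assay is Assay.ROTAROD and not 0 < self.value <= ROTAROD_MAX_S:
            raise ValueError(
                f"rotarod latency must lie in (0, {ROTAROD_MAX_S:g}] s, "
                f"got {self.value}"
            )
        if self.assay is Assay.LADDER and not 0 <= self.value <= 100:
            raise ValueError("ladder percent correct must lie in [0, 100]")
        if self.assay is Assay.BEAM:
            if self.beam_width_mm not in BEAM_WIDTHS_MM:
                raise ValueError(
                    f"beam width must be one of {BEAM_WIDTHS_MM} mm, "
                    f"got {self.beam_width_mm}"
                )


# ---------------------------------------------------------------------------
# experiment schedule


def build_experiment_schedule(
    n_standard: int,
    n_enriched: int,
    rng: np.random.Generator | int | None = None,
    days: Iterable[int] = range(1, N_DAYS + 1),
) -> list[TrialMeta]:
    """Build the full trial schedule for a two-group experiment.

    Per mouse per day: 240 trials in 20 blocks, each block a seeded uniform
    permutation of 1 CS-only, 1 US-only and 10 paired trials. Mice are named
    ``std01.., enr01..``.

    Parameters
    ----------
    n_standard, n_enriched
        Number of mice per housing group; both must be >= 1.
    rng
        Seed or generator for the within-block permutation.
    days
        Training days to schedule (default all 20).
    """
    if n_standard < 1 or n_enriched < 1:
        raise ValueError("group sizes must be positive")
    rng = np.random.default_rng(rng)
    mice = [(f"std{i + 1:02d}", Group.STANDARD) for i in range(n_standard)]
    mice += [(f"enr{i + 1:02d}", Group.ENRICHED) for i in range(n_enriched)]

    block_types = [TrialType.CS_ONLY, TrialType.US_ONLY] + [
        TrialType.PAIRED
    ] * PAIRED_PER_BLOCK
    schedule: list[TrialMeta] = []
    for mouse_id, group in mice:
        for day in days:
            isi = isi_for_day(day)
            trial_index = 0
            for block in range(1, BLOCKS_PER_DAY + 1):
                order = rng.permutation(len(block_types))
                for k in order:
                    trial_index += 1
                    schedule.append(
                        TrialMeta(
                            mouse_id=mouse_id,
                            group=group,
                            day=day,
                            block=block,
                            trial_index=trial_index,
                            trial_type=block_types[k],
                            isi_ms=isi,
                            cs_duration_ms=isi + CS_US_GAP_MS,
                        )
                    )
    return schedule


# ---------------------------------------------------------------------------
# window helpers shared by preprocess / cr modules


def pre_cs_slice(trial: RawTrial | NormalizedTrial) -> slice:
    """Slice covering the 500 ms pre-CS baseline window [-500, 0) ms."""
    n_pre = ms_to_offset(PRE_CS_MS, trial.sample_rate_hz)
    return slice(trial.cs_onset_index - n_pre, trial.cs_onset_index)


def window_slice(
    trial: RawTrial | NormalizedTrial, lo_ms: float, hi_ms: float
) -> slice:
    """Slice for the closed post-CS window ``[lo_ms, hi_ms]``."""
    lo = trial.cs_onset_index + ms_to_offset(lo_ms, trial.sample_rate_hz)
    hi = trial.cs_onset_index + ms_to_offset(hi_ms, trial.sample_rate_hz)
    return slice(lo, hi + 1)


# ---------------------------------------------------------------------------
# tidy-table conversion


def outcomes_to_frame(outcomes: Sequence[SessionOutcome]) -> pd.DataFrame:
    """Tidy DataFrame with one row per mouse-day outcome."""
    rows = []
    for o in outcomes:
        d = asdict(o)
        d["group"] = o.group.value
        rows.append(d)
    return pd.DataFrame(rows)


def assay_records_to_frame(records: Sequence[AssayRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["assay"] = r.assay.value
        d["group"] = r.group.value
        rows.append(d)
    return pd.DataFrame(rows)


def assay_records_from_frame(frame: pd.DataFrame) -> list[AssayRecord]:
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        for opt in ("day", "beam_width_mm"):
            v = d.get(opt)
            d[opt] = None if v is None or pd.isna(v) else int(v)
        d["trial_or_run"] = int(d["trial_or_run"])
        records.append(AssayRecord(**d))
    return records


def meta_sidecar(metas: Sequence[TrialMeta]) -> str:
    """JSON sidecar text for a sequence of trial metadata records."""
    return json.dumps([m.to_dict() for m in metas], indent=None)
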