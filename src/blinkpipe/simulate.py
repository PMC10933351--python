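"""Synthetic eyeblink-trace and motor-assay generator.

The generator is phenomenological: it emits raw-unit eyelid traces with the
statistical structure the analysis pipeline assumes, not a biomechanical
model of conditioning. Per trial it draws

* whether a CR is present, from a per-group logistic learning curve over
  training days (phase 2, days 11-20, uses a per-group plateau probability);
* CR kinetics — onset latency, peak latency and normalized amplitude. The
  CR waveform is an alpha-function kernel ``A * u * exp(1 - u)`` with
  ``u = (t - onset) / (peak - onset)``: smooth, unimodal, zero before onset
  and peaking exactly at the drawn peak latency. Peak latencies are normal
  around the nominal US onset (the ISI) with a group-specific spread — the
  timing-precision manipulation — truncated *symmetrically* about the ISI so
  the configured mean is preserved;
* an unconditioned response (UR) on US-bearing trials: a fast half-cosine
  rise followed by an exponential decay, with trial-to-trial amplitude
  jitter around the configured raw peak;
* white Gaussian sensor noise and a per-trial baseline offset;
* occasionally, a pre-CS movement artifact (a signed half-sine transient
  placed strictly inside the 500 ms pre-CS window), so the downstream IQR
  filter is the unique detector of these trials.

All randomness derives from ``SimConfig.seed`` through per-session
``numpy.random.SeedSequence`` children, so identical configs produce
byte-identical datasets and sessions can be generated independently in any
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import (
    Group,
    RawTrial,
    TrialMeta,
    TrialType,
    isi_for_day,
    ms_to_offset,
    CS_US_GAP_MS,
    BLOCKS_PER_DAY,
    N_DAYS,
)
from .motor import Assay, AssayRecord, LadderRun, Paw, RungHeight, ladder_table

__all__ = [
    "AcquisitionCurve",
    "CRKinetics",
    "URShape",
    "MotorEffects",
    "SimConfig",
    "MotorData",
    "iter_sessions",
    "simulate_session",
    "simulate_eyeblink_dataset",
    "simulate_motor_assays",
    "alpha_kernel",
    "ur_kernel",
]

PRE_CS_SPAN_MS = 500.0
POST_CS_SPAN_MS = 1100.0


@dataclass(frozen=True)
class AcquisitionCurve:
    """Logistic CR-acquisition curve for one group.

    Phase 1 (days 1-10): ``p(day) = asymptote / (1 + exp(-slope (day - half_day)))``.
    Phase 2 (days 11-20): the learning curve has plateaued; the probability
    is the constant ``phase2_prob``.
    """

    asymptote: float
    half_day: float
    slope: float
    phase2_prob: float

    def prob(self, day: int) -> float:
        if day <= 10:
            return self.asymptote / (1.0 + np.exp(-self.slope * (day - self.half_day)))
        return self.phase2_prob


@dataclass(frozen=True)
class CRKinetics:
    """Per-group CR kinetic distributions.

    ``peak_sd_ms`` maps ISI (ms) to the peak-latency spread around the ISI —
    smaller means tighter adaptive timing. Amplitudes are on the normalized
    closure scale and grow linearly within each training phase.
    """

    onset_mean_ms: float = 150.0
    onset_sd_ms: float = 40.0
    peak_sd_ms: Mapping[int, float] = field(
        default_factory=lambda: {250: 90.0, 500: 180.0}
    )
    amp_day1: float = 0.25
    amp_growth_per_day: float = 0.035
    amp_sd: float = 0.12


@dataclass(frozen=True)
class URShape:
    """Reflexive-blink waveform: half-cosine rise, exponential decay."""

    rise_ms: float = 15.0
    peak_raw: float = 5.0
    decay_ms: float = 80.0
    amp_sd_raw: float = 0.25


@dataclass(frozen=True)
class MotorEffects:
    """Per-group motor-assay means; group effects live entirely here.

    ``*_sd`` are trial-to-trial spreads, ``*_mouse_sd`` the spread of
    per-mouse random intercepts (stable individual differences) — the
    variance the mixed models' mouse random effect is there to absorb.
    """

    rotarod_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "standard": (108.0, 150.0, 170.0, 179.0),
            "enriched": (192.0, 205.0, 210.0, 213.0),
        }
    )
    rotarod_sd: float = 55.0
    rotarod_mouse_sd: float = 40.0
    ladder_pct_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "standard": (50.0, 55.0, 59.0, 62.0, 64.0),
            "enriched": (63.0, 65.0, 66.0, 67.0, 68.0),
        }
    )
    ladder_steps_range: tuple[int, int] = (15, 26)
    ladder_mouse_sd: float = 10.0
    beam_means: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "standard": {6: 8.7, 12: 6.5},
            "enriched": {6: 7.8, 12: 6.0},
        }
    )
    beam_sd: float = 1.8
    beam_mouse_sd: float = 1.6
    grip_means: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 90.0, "enriched": 102.0}
    )
    grip_sd: float = 7.0
    grip_mouse_sd: float = 19.0


def _default_acquisition() -> dict[str, AcquisitionCurve]:
    # standard-housed mice acquire faster and plateau higher; enriched mice
    # are slower learners (group difference in acquisition rate)
    return {
        "standard": AcquisitionCurve(
            asymptote=0.93, half_day=3.0, slope=1.1, phase2_prob=0.74
        ),
        "enriched": AcquisitionCurve(
            asymptote=0.83, half_day=4.5, slope=0.7, phase2_prob=0.62
        ),
    }


def _default_kinetics() -> dict[str, CRKinetics]:
    # enriched mice time their CR peaks more tightly around the expected US
    return {
        "standard": CRKinetics(peak_sd_ms={250: 90.0, 500: 180.0}),
        "enriched": CRKinetics(
            peak_sd_ms={250: 55.0, 500: 110.0},
            amp_day1=0.22,
            amp_growth_per_day=0.028,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration.

    Defaults encode the study design: 12 standard vs 16 enriched mice in the
    eyeblink experiment (11 standard in the motor assays), 20 daily sessions
    of 240 trials, a 1 kHz eyelid signal, and qualitative group effects —
    standard mice acquire CRs faster, enriched mice time them more
    precisely and start higher on rotarod and ladder. Noise and artifact
    levels are generator choices, not measured quantities.
    """

    seed: int = 0
    n_standard: int = 12
    n_enriched: int = 16
    n_standard_motor: int = 11
    n_enriched_motor: int = 16
    sample_rate_hz: float = 1000.0
    acquisition: Mapping[str, AcquisitionCurve] = field(
        default_factory=_default_acquisition
    )
    cr_kinetics: Mapping[str, CRKinetics] = field(default_factory=_default_kinetics)
    ur_shape: URShape = field(default_factory=URShape)
    motor: MotorEffects = field(default_factory=MotorEffects)
    noise_sd: float = 0.08  # raw units
    baseline_offset_raw: float = 10.0
    baseline_offset_sd: float = 0.5
    artifact_rate: float = 0.02
    artifact_amplitude: float = 2.0  # raw units
    artifact_duration_ms: float = 80.0
    iti_range_s: tuple[float, float] = (8.0, 12.0)
    days: tuple[int, ...] = tuple(range(1, N_DAYS + 1))

    def __post_init__(self) -> None:
        if self.n_standard < 1 or self.n_enriched < 1:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for g, acq in self.acquisition.items():
            if not 0.0 <= acq.asymptote <= 1.0 or not 0.0 <= acq.phase2_prob <= 1.0:
                raise ValueError(f"{g}: CR probabilities must lie in [0, 1]")
        for g, kin in self.cr_kinetics.items():
            if kin.onset_sd_ms < 0 or kin.amp_sd < 0:
                raise ValueError(f"{g}: kinetic sds must be non-negative")
            for isi in (250, 500):
                if kin.peak_sd_ms[isi] < 0:
                    raise ValueError(f"{g}: peak sd must be non-negative")
                if isi <= kin.onset_mean_ms:
                    raise ValueError(
                        f"{g}: degenerate kinetics, mean peak latency "
                        f"({isi} ms, the ISI) must exceed mean onset latency "
                        f"({kin.onset_mean_ms} ms)"
                    )

    def mice(self) -> list[tuple[str, Group]]:
        return [
            (f"std{i + 1:02d}", Group.STANDARD) for i in range(self.n_standard)
        ] + [(f"enr{i + 1:02d}", Group.ENRICHED) for i in range(self.n_enriched)]


# ---------------------------------------------------------------------------
# waveform kernels


def alpha_kernel(
    t_ms: np.ndarray, onset_ms: float, peak_ms: float
) -> np.ndarray:
    """Unit-amplitude alpha function rising at ``onset`` and peaking at ``peak``."""
    if peak_ms <= onset_ms:
        raise ValueError("peak latency must exceed onset latency")
    u = (t_ms - onset_ms) / (peak_ms - onset_ms)
    out = np.where(u > 0, u * np.exp(1.0 - u), 0.0)
    return out


def ur_kernel(t_ms: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-amplitude reflexive-blink kernel, peaking at ``rise_ms``."""
    out = np.zeros_like(t_ms, dtype=float)
    rising = (t_ms >= 0) & (t_ms < rise_ms)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t_ms[rising] / rise_ms))
    falling = t_ms >= rise_ms
    out[falling] = np.exp(-(t_ms[falling] - rise_ms) / decay_ms)
    return out


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), mean.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), mean.shape)
    if sd == 0:
        return np.clip(mean, lo, hi)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def _peak_trunc_halfwidth(isi: int) -> float:
    # symmetric truncation about the ISI, kept inside the detection window
    # with margin, so the configured mean peak latency is preserved exactly
    return min(isi - 120.0, 960.0 - isi)


# ---------------------------------------------------------------------------
# eyeblink sessions


def _session_rng(seed: int, mouse_idx: int, day: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, 1, mouse_idx, day))
    )


def simulate_session(
    config: SimConfig, mouse_id: str, group: Group, mouse_idx: int, day: int
) -> tuple[list[RawTrial], pd.DataFrame]:
    """Generate one mouse-day: 240 raw trials plus their ground truth."""
    rng = _session_rng(config.seed, mouse_idx, day)
    rate = config.sample_rate_hz
    isi = isi_for_day(day)
    n_pre = ms_to_offset(PRE_CS_SPAN_MS, rate)
    n_post = ms_to_offset(POST_CS_SPAN_MS, rate) + 1
    t_ms = (np.arange(n_pre + n_post) - n_pre) * 1000.0 / rate

    acq = config.acquisition[group.value]
    kin = config.cr_kinetics[group.value]
    p_cr = acq.prob(day)

    # within-block semi-random trial order
    block_types = [TrialType.CS_ONLY, TrialType.US_ONLY] + [TrialType.PAIRED] * 10
    metas: list[TrialMeta] = []
    for block in range(1, BLOCKS_PER_DAY + 1):
        for k in rng.permutation(len(block_types)):
            metas.append(
                TrialMeta(
                    mouse_id=mouse_id,
                    group=group,
                    day=day,
                    block=block,
                    trial_index=len(metas) + 1,
                    trial_type=block_types[k],
                    isi_ms=isi,
                    cs_duration_ms=isi + CS_US_GAP_MS,
                )
            )
    n = len(metas)
    types = np.array([m.trial_type.value for m in metas])
    has_cs = types != TrialType.US_ONLY.value
    has_us = types != TrialType.CS_ONLY.value

    cr_present = has_cs & (rng.random(n) < p_cr)
    half = _peak_trunc_halfwidth(isi)
    peak = _truncated_normal(
        rng,
        np.full(n, float(isi)),
        kin.peak_sd_ms[isi],
        isi - half,
        isi + half,
    )
    onset = _truncated_normal(
        rng,
        np.full(n, kin.onset_mean_ms),
        kin.onset_sd_ms,
        55.0,
        np.minimum(495.0, peak - 40.0),
    )
    day_in_phase = day if day <= 10 else day - 10
    amp_mean = kin.amp_day1 + kin.amp_growth_per_day * (day_in_phase - 1)
    amp = np.clip(rng.normal(amp_mean, kin.amp_sd, n), 0.12, 0.95)
    peak[~cr_present] = np.nan
    onset[~cr_present] = np.nan
    amp[~cr_present] = np.nan

    ur = config.ur_shape
    ur_amp = np.where(
        has_us, rng.normal(ur.peak_raw, ur.amp_sd_raw, n), np.nan
    )
    artifact = rng.random(n) < config.artifact_rate
    art_dur = config.artifact_duration_ms
    art_start = rng.uniform(-PRE_CS_SPAN_MS + 10.0, -art_dur - 10.0, n)
    art_sign = rng.choice([-1.0, 1.0], n)
    offsets = rng.normal(config.baseline_offset_raw, config.baseline_offset_sd, n)
    iti_s = rng.uniform(*config.iti_range_s, n)

    trials: list[RawTrial] = []
    for i, meta in enumerate(metas):
        y = offsets[i] + rng.normal(0.0, config.noise_sd, t_ms.size)
        if cr_present[i]:
            y += amp[i] * ur.peak_raw * alpha_kernel(t_ms, onset[i], peak[i])
        if has_us[i]:
            y += ur_amp[i] * ur_kernel(t_ms - isi, ur.rise_ms, ur.decay_ms)
        if artifact[i]:
            inside = (t_ms >= art_start[i]) & (t_ms <= art_start[i] + art_dur)
            y[inside] += (
                art_sign[i]
                * config.artifact_amplitude
                * np.sin(np.pi * (t_ms[inside] - art_start[i]) / art_dur)
            )
        trials.append(
            RawTrial(
                meta=meta,
                samples=y,
                sample_rate_hz=rate,
                cs_onset_index=n_pre,
                pre_cs_ms=PRE_CS_SPAN_MS,
            )
        )

    truth = pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "group": group.value,
            "day": day,
            "trial_index": [m.trial_index for m in metas],
            "block": [m.block for m in metas],
            "trial_type": types,
            "cr_present": cr_present,
            "onset_ms": onset,
            "peak_ms": peak,
            "amplitude": amp,
            "artifact": artifact,
            "ur_amp_raw": ur_amp,
            "iti_s": iti_s,
        }
    )
    return trials, truth


def iter_sessions(
    config: SimConfig,
) -> Iterator[tuple[list[RawTrial], pd.DataFrame]]:
    """Yield (trials, ground truth) per mouse-day, in mouse-then-day order.

    Sessions are independently seeded, so streaming consumption never holds
    more than one session (~240 traces) in memory.
    """
    for mouse_idx, (mouse_id, group) in enumerate(config.mice()):
        for day in config.days:
            yield simulate_session(config, mouse_id, group, mouse_idx, day)


def simulate_eyeblink_dataset(
    config: SimConfig,
) -> tuple[list[RawTrial], pd.DataFrame]:
    """Materialize the whole eyeblink dataset (use for small configs).

    For the full 28-mouse, 20-day design prefer :func:`iter_sessions`; the
    materialized dataset holds 134,400 traces.
    """
    all_trials: list[RawTrial] = []
    truths = []
    for trials, truth in iter_sessions(config):
        all_trials.extend(trials)
        truths.append(truth)
    return all_trials, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# motor assays


@dataclass
class MotorData:
    """Tidy motor-assay tables plus the raw ladder step sequences."""

    rotarod: pd.DataFrame
    ladder: pd.DataFrame
    beam: pd.DataFrame
    grip: pd.DataFrame
    ladder_runs: list[LadderRun]

    def records(self) -> pd.DataFrame:
        return pd.concat(
            [self.rotarod, self.ladder, self.beam, self.grip],
            ignore_index=True,
        )


def _motor_mice(config: SimConfig) -> list[tuple[str, Group]]:
    return [
        (f"std{i + 1:02d}", Group.STANDARD)
        for i in range(config.n_standard_motor)
    ] + [
        (f"enr{i + 1:02d}", Group.ENRICHED)
        for i in range(config.n_enriched_motor)
    ]


def simulate_motor_assays(config: SimConfig) -> MotorData:
    """Generate the four motor-assay datasets at their design cardinalities.

    Rotarod latencies are normal around per-group-day means and truncated
    at the 300 s ceiling; ladder runs are emitted as rung-touch sequences
    whose front-paw placements are high with probability ``sqrt(p/100)``, so
    the expected scored percent-correct equals the configured ``p``; beam
    and grip values are truncated normals around per-group means.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    me = config.motor
    mice = _motor_mice(config)

    rotarod = []
    for mouse_id, group in mice:
        mus = me.rotarod_means[group.value]
        mouse_off = rng.normal(0.0, me.rotarod_mouse_sd)
        for day in range(1, 5):
            for trial in range(1, 5):
                v = float(
                    np.clip(
                        rng.normal(mus[day - 1] + mouse_off, me.rotarod_sd),
                        5.0,
                        300.0,
                    )
                )
                rotarod.append(
                    AssayRecord(Assay.ROTAROD, mouse_id, group, trial, v, day=day)
                )

    ladder_runs: list[LadderRun] = []
    lo, hi = me.ladder_steps_range
    for mouse_id, group in mice:
        pcts = me.ladder_pct_means[group.value]
        mouse_off = rng.normal(0.0, me.ladder_mouse_sd)
        for day in range(1, 6):
            # placements land on a high rung with probability p/100, so the
            # expected landing-rule percent correct equals the configured p
            h = float(np.clip(pcts[day - 1] + mouse_off, 0.0, 100.0) / 100.0)
            for run in range(1, 43):
                n_front = int(rng.integers(lo, hi))
                heights = rng.random(n_front) < h
                steps = []
                front = (Paw.FRONT_LEFT, Paw.FRONT_RIGHT)
                for j, high in enumerate(heights):
                    steps.append(
                        (front[j % 2], RungHeight.HIGH if high else RungHeight.LOW)
                    )
                    if rng.random() < 0.3:  # hind-paw touches, never scored
                        steps.append(
                            (
                                Paw.HIND_LEFT if j % 2 else Paw.HIND_RIGHT,
                                RungHeight.HIGH,
                            )
                        )
                ladder_runs.append(
                    LadderRun(mouse_id, group, day, run, tuple(steps))
                )

    beam = []
    for mouse_id, group in mice:
        mouse_off = rng.normal(0.0, me.beam_mouse_sd)
        for width in (12, 6):
            for crossing in (1, 2):
                v = float(
                    max(
                        1.0,
                        rng.normal(
                            me.beam_means[group.value][width] + mouse_off,
                            me.beam_sd,
                        ),
                    )
                )
                beam.append(
                    AssayRecord(
                        Assay.BEAM, mouse_id, group, crossing, v,
                        beam_width_mm=width,
                    )
                )

    grip = []
    for mouse_id, group in mice:
        mouse_off = rng.normal(0.0, me.grip_mouse_sd)
        for day in range(1, 5):
            for trial in (1, 2):
                v = float(
                    max(
                        10.0,
                        rng.normal(
                            me.grip_means[group.value] + mouse_off, me.grip_sd
                        ),
                    )
                )
                grip.append(
                    AssayRecord(Assay.GRIP, mouse_id, group, trial, v, day=day)
                )

    from .motor import beam_table, grip_table, rotarod_table

    return MotorData(
        rotarod=rotarod_table(rotarod),
        ladder=ladder_table(ladder_runs),
        beam=beam_table(beam),
        grip=grip_table(grip),
        ladder_runs=ladder_runs,
    )


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with all group effects removed.

    Both groups share the standard group's parameters; useful for type-I
    error calibration of the statistics layer.
    """
    base = SimConfig(seed=seed)
    acq = {g: base.acquisition["standard"] for g in ("standard", "enriched")}
    kin = {g: base.cr_kinetics["standard"] for g in ("standard", "enriched")}
    me = MotorEffects(
        rotarod_means={g: (108.0, 150.0, 170.0, 179.0) for g in ("standard", "enriched")},
        ladder_pct_means={g: (50.0, 55.0, 59.0, 62.0, 64.0) for g in ("standard", "enriched")},
        beam_means={g: {6: 8.7, 12: 6.5} for g in ("standard", "enriched")},
        grip_means={g: 90.0 for g in ("standard", "enriched")},
    )
    return replace(
        base, seed=seed, acquisition=acq, cr_kinetics=kin, motor=me, **overrides
    )
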