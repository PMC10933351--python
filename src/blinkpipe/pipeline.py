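"""End-to-end analysis: align -> filter -> normalize -> detect -> outcomes -> stats.

The stage order is fixed. Sessions (one mouse-day each) are processed
independently and streamed, so the full 28-mouse, 20-day experiment never
holds more than one session of traces in memory. Every stage's row counts
are logged so trial conservation (trials in = valid + rejected) can be
audited from the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import RawTrial, SessionOutcome, TrialType, outcomes_to_frame
from .cr import (
    CRDetection,
    CRDetector,
    PHASE_DAYS,
    amplitude_matched_subset,
    amplitude_timing_model,
    detections_to_frame,
    group_mean_ci,
    perfect_timing_endpoint,
    session_outcomes,
)
from .preprocess import TrialNormalizer
from .simulate import MotorData, SimConfig, iter_sessions, simulate_motor_assays
from .stats import LMEResult, LMESpec, MixedEffectsComparison, fit_lme

logger = logging.getLogger("blinkpipe")

__all__ = [
    "EyeblinkAnalysis",
    "analyze_sessions",
    "eyeblink_stats",
    "motor_stats",
    "run_study",
    "MOTOR_SPECS",
]

#: per-assay mixed-model specifications (random factors beyond mouse are
#: crossed intercepts, as each assay design states)
MOTOR_SPECS = {
    "rotarod": LMESpec(
        outcome="value",
        fixed_effects=("group", "day", "group:day"),
        random=("mouse_id", "trial_or_run"),
    ),
    "ladder": LMESpec(
        outcome="value",
        fixed_effects=("group", "day", "group:day"),
        random=("mouse_id", "trial_or_run"),
    ),
    "beam": LMESpec(
        outcome="value",
        fixed_effects=("group", "beam_width_mm", "group:beam_width_mm"),
        random=("mouse_id",),
    ),
    "grip": LMESpec(
        outcome="value",
        fixed_effects=("group",),
        random=("mouse_id",),
    ),
}

#: the six per-mouse-day eyeblink outcomes submitted to the stats layer
EYEBLINK_OUTCOMES = (
    "cr_probability",
    "nec_all_trials",
    "nec_cr_trials",
    "mean_onset_latency_ms",
    "mean_peak_latency_ms",
    "pct_perfect",
)


@dataclass
class EyeblinkAnalysis:
    """Everything the eyeblink pipeline produces before the stats layer."""

    outcomes: pd.DataFrame
    detections: pd.DataFrame
    counts: pd.DataFrame
    detection_objects: list[CRDetection] = field(default_factory=list)


def _split_sessions(
    trials: Sequence[RawTrial],
) -> Iterator[list[RawTrial]]:
    by_session: dict[tuple[str, int], list[RawTrial]] = {}
    for t in trials:
        by_session.setdefault((t.meta.mouse_id, t.meta.day), []).append(t)
    for key in sorted(by_session):
        yield by_session[key]


def analyze_sessions(
    sessions: Iterable[Sequence[RawTrial]],
    config: PipelineConfig = PipelineConfig(),
) -> EyeblinkAnalysis:
    """Run preprocessing, CR detection and session outcomes over sessions.

    ``sessions`` yields the trials of one mouse-day at a time (use
    :func:`analyze_trials` for a flat trial list). Invalid trials are
    excluded from every downstream quantity, including the UR average.
    """
    detector = CRDetector(
        amplitude_threshold=config.amplitude_threshold,
        onset_window_ms=config.onset_window_ms,
        peak_window_ms=config.peak_window_ms,
        onset_threshold=config.onset_threshold,
        perfect_windows_ms=config.perfect_windows_ms,
    ).fit()
    outcomes: list[SessionOutcome] = []
    dets_all: list[CRDetection] = []
    count_rows = []
    for sess in sessions:
        normalizer = TrialNormalizer(
            factor=config.filter_factor,
            iqr_scope=config.iqr_scope,
            ur_window_ms=config.ur_window_ms,
        )
        normalized = normalizer.fit_transform(list(sess))
        cs_valid = [
            t
            for t in normalized
            if t.valid and t.meta.trial_type is TrialType.CS_ONLY
        ]
        dets = detector.predict(cs_valid)
        meta = sess[0].meta
        row = {
            "mouse_id": meta.mouse_id,
            "day": meta.day,
            "n_trials": len(sess),
            "n_valid": int(np.sum(~normalizer.invalid_)),
            "n_rejected": int(np.sum(normalizer.invalid_)),
            "n_cs_only_valid": len(cs_valid),
        }
        if dets:
            outcomes.append(session_outcomes(dets))
            dets_all.extend(dets)
            row["n_cr"] = sum(d.is_cr for d in dets)
        else:
            logger.warning(
                "%s day %d: no valid CS-only trials, outcome missing",
                meta.mouse_id,
                meta.day,
            )
            row["n_cr"] = 0
        count_rows.append(row)
        logger.info(
            "%s day %d: %d trials in = %d valid + %d rejected; %d CRs",
            meta.mouse_id,
            meta.day,
            row["n_trials"],
            row["n_valid"],
            row["n_rejected"],
            row["n_cr"],
        )
    return EyeblinkAnalysis(
        outcomes=outcomes_to_frame(outcomes),
        detections=detections_to_frame(dets_all),
        counts=pd.DataFrame(count_rows),
        detection_objects=dets_all,
    )


def analyze_trials(
    trials: Sequence[RawTrial], config: PipelineConfig = PipelineConfig()
) -> EyeblinkAnalysis:
    """Like :func:`analyze_sessions`, for a flat list of trials."""
    return analyze_sessions(_split_sessions(trials), config)


def eyeblink_stats(
    outcomes: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> dict[str, dict[str, LMEResult]]:
    """Phase-wise mixed-model comparison of the six eyeblink outcomes.

    The two ISI phases (days 1-10 and 11-20) are always analyzed
    separately. Each outcome is fit with group, day and their interaction
    as fixed effects and a random intercept per mouse; per-day group
    contrasts carry the configured multiplicity correction.
    """
    results: dict[str, dict[str, LMEResult]] = {}
    for phase, days in PHASE_DAYS.items():
        sub = outcomes[outcomes["day"].isin(days)]
        results[phase] = {}
        for outcome in EYEBLINK_OUTCOMES:
            if outcome not in sub.columns or sub[outcome].dropna().empty:
                continue
            spec = LMESpec(
                outcome=outcome,
                fixed_effects=("group", "day", "group:day"),
                random=("mouse_id",),
                alpha=config.alpha,
                df_method=config.df_method,
                correction=config.correction,
            )
            try:
                results[phase][outcome] = fit_lme(sub, spec)
            except ValueError as exc:
                logger.warning("%s %s: fit skipped (%s)", phase, outcome, exc)
    return results


def motor_stats(
    motor: MotorData, config: PipelineConfig = PipelineConfig()
) -> dict[str, LMEResult]:
    """Fit each motor assay's stated mixed model."""
    tables = {
        "rotarod": motor.rotarod,
        "ladder": motor.ladder,
        "beam": motor.beam,
        "grip": motor.grip,
    }
    out = {}
    for assay, table in tables.items():
        spec = MOTOR_SPECS[assay]
        est = MixedEffectsComparison(
            outcome=spec.outcome,
            fixed_effects=spec.fixed_effects,
            random=spec.random,
            alpha=config.alpha,
            df_method=config.df_method,
            correction=config.correction,
        )
        out[assay] = est.fit(table).result_
    return out


def timing_analyses(
    dets: Sequence[CRDetection], config: PipelineConfig = PipelineConfig()
) -> dict:
    """Adaptive-timing endpoint analyses for both ISI phases.

    Per phase: pooled perfectly-timed percentages with group summaries, the
    peak-latency model with CR amplitude as covariate, and the
    amplitude-matched (enriched-IQR) re-analysis.
    """
    out = {}
    for phase in ("isi250", "isi500"):
        try:
            per_mouse, summary = perfect_timing_endpoint(
                dets, phase, per_day_average=config.per_day_average_perfect
            )
        except ValueError as exc:
            logger.warning("%s endpoint analysis skipped: %s", phase, exc)
            continue
        entry = {"per_mouse": per_mouse, "summary": summary}
        try:
            entry["amplitude_model"] = amplitude_timing_model(dets, phase)
        except ValueError as exc:
            logger.warning("%s amplitude model skipped: %s", phase, exc)
        try:
            subset, bounds = amplitude_matched_subset(dets, phase)
            sub_per_mouse, sub_summary = perfect_timing_endpoint(
                subset, phase, per_day_average=config.per_day_average_perfect
            )
            frame = detections_to_frame(subset)
            frame["perfect"] = frame["perfectly_timed"].astype(float) * 100.0
            matched_fit = fit_lme(
                frame.assign(day=frame["day"]),
                LMESpec(
                    outcome="perfect",
                    fixed_effects=("group",),
                    random=("mouse_id",),
                ),
            )
            entry["amplitude_matched"] = {
                "bounds": bounds,
                "summary": sub_summary,
                "group_test": matched_fit,
            }
        except ValueError as exc:
            logger.warning("%s amplitude-matched subset skipped: %s", phase, exc)
        out[phase] = entry
    return out


def run_study(
    sim_config: SimConfig,
    pipeline_config: Optional[PipelineConfig] = None,
    include_motor: bool = True,
) -> dict:
    """Simulate a full study and run the complete analysis on it.

    Streams the eyeblink sessions, so the full design fits comfortably in
    memory; returns outcomes, per-trial detections, stage counts, the
    phase-wise eyeblink LME results, the timing endpoint analyses and
    (optionally) motor tables with their mixed-model fits.
    """
    config = pipeline_config or PipelineConfig(seed=sim_config.seed)
    analysis = analyze_sessions(
        (trials for trials, _ in iter_sessions(sim_config)), config
    )
    report = {
        "outcomes": analysis.outcomes,
        "detections": analysis.detections,
        "counts": analysis.counts,
        "eyeblink_lme": eyeblink_stats(analysis.outcomes, config),
        "timing": timing_analyses(analysis.detection_objects, config),
    }
    if include_motor:
        motor = simulate_motor_assays(sim_config)
        report["motor"] = motor
        report["motor_lme"] = motor_stats(motor, config)
    return report


def group_day_summary(outcomes: pd.DataFrame, column: str) -> pd.DataFrame:
    """Mean and 95% CI of a per-mouse-day outcome by group and day."""
    rows = []
    for day, sub in outcomes.groupby("day"):
        s = group_mean_ci(sub, column)
        s.insert(0, "day", day)
        rows.append(s)
    return pd.concat(rows, ignore_index=True)
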