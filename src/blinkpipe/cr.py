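"""Conditioned-response detection and adaptive-timing outcomes.

CRs are scored on valid CS-only trials only, because they expose the full
kinetic profile of the learned blink without the reflexive UR on top. A trial
counts as a CR when the normalized closure exceeds 0.1 somewhere in the
100–1000 ms post-CS window, the movement onset falls in [50, 500] ms and the
peak in [100, 1000] ms. The same criteria apply in both ISI phases.

Onset is the first sustained crossing: the earliest post-CS sample above the
onset threshold (default 0.05) from which the trace stays above threshold up
to the peak. A "perfectly timed" CR peaks within ±50 ms of the expected US
for the 250 ms ISI, within ±100 ms for the 500 ms ISI (bounds inclusive).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .core import (
    CRDetection,
    NormalizedTrial,
    SessionOutcome,
    TrialType,
    window_slice,
)

__all__ = [
    "CRDetector",
    "detect_cr",
    "classify_perfect_timing",
    "session_outcomes",
    "detections_to_frame",
    "endpoint_days",
    "perfect_timing_endpoint",
    "amplitude_timing_model",
    "amplitude_matched_subset",
]

#: endpoint days per ISI phase used for the adaptive-timing analyses
ENDPOINT_DAYS = {"isi250": (8, 9, 10), "isi500": (18, 19, 20)}
PHASE_DAYS = {"isi250": tuple(range(1, 11)), "isi500": tuple(range(11, 21))}

DEFAULT_PERFECT_WINDOWS = {250: 50.0, 500: 100.0}


def endpoint_days(phase: str) -> tuple[int, ...]:
    try:
        return ENDPOINT_DAYS[phase]
    except KeyError:
        raise ValueError(
            f"phase must be one of {sorted(ENDPOINT_DAYS)}, got {phase!r}"
        ) from None


class CRDetector(BaseEstimator):
    """Threshold-based CR classifier for valid CS-only trials.

    Parameters default to the field's standard detection constants and are all
    overridable.

    Parameters
    ----------
    amplitude_threshold : float, default 0.1
        Minimum normalized peak closure for a CR (strict inequality).
    onset_window_ms : (float, float), default (50, 500)
        Closed window of acceptable onset latencies.
    peak_window_ms : (float, float), default (100, 1000)
        Closed window searched for the peak; doubles as the NEC window.
    onset_threshold : float, default 0.05
        Closure level whose first sustained crossing defines movement onset.
    perfect_windows_ms : mapping {isi_ms: half_width_ms}
        Half-widths of the perfectly-timed window per ISI,
        default ``{250: 50, 500: 100}``.
    """

    def __init__(
        self,
        amplitude_threshold: float = 0.1,
        onset_window_ms: tuple[float, float] = (50.0, 500.0),
        peak_window_ms: tuple[float, float] = (100.0, 1000.0),
        onset_threshold: float = 0.05,
        perfect_windows_ms: Optional[Mapping[int, float]] = None,
    ):
        self.amplitude_threshold = amplitude_threshold
        self.onset_window_ms = onset_window_ms
        self.peak_window_ms = peak_window_ms
        self.onset_threshold = onset_threshold
        self.perfect_windows_ms = perfect_windows_ms

    def _windows(self) -> Mapping[int, float]:
        if self.perfect_windows_ms is None:
            return DEFAULT_PERFECT_WINDOWS
        return self.perfect_windows_ms

    def fit(self, X=None, y=None) -> "CRDetector":
        """No-op; detection is threshold-based. Present for API symmetry."""
        self.n_features_in_ = 0
        return self

    def predict(self, X: Sequence[NormalizedTrial]) -> list[CRDetection]:
        return [self.detect(t) for t in X]

    def detect(self, trial: NormalizedTrial) -> CRDetection:
        """Classify one valid CS-only trial."""
        if not trial.valid:
            raise ValueError("CR detection is defined on valid trials only")
        if trial.meta.trial_type is not TrialType.CS_ONLY:
            raise ValueError(
                "CR analysis is restricted to CS-only trials, got "
                f"{trial.meta.trial_type.value}"
            )
        lo, hi = self.peak_window_ms
        win = window_slice(trial, lo, hi)
        seg = trial.samples[win]
        k = int(np.argmax(seg))  # earliest sample on ties
        peak_idx = win.start + k
        peak_amp = float(seg[k])
        peak_ms = (peak_idx - trial.cs_onset_index) * 1000.0 / trial.sample_rate_hz

        onset_ms = self._onset_latency(trial, peak_idx)

        on_lo, on_hi = self.onset_window_ms
        is_cr = (
            peak_amp > self.amplitude_threshold
            and onset_ms is not None
            and on_lo <= onset_ms <= on_hi
            and lo <= peak_ms <= hi
        )
        det = CRDetection(
            meta=trial.meta,
            is_cr=is_cr,
            onset_latency_ms=onset_ms,
            peak_latency_ms=peak_ms,
            peak_amplitude=peak_amp,
            perfectly_timed=None,
        )
        if is_cr:
            det = CRDetection(
                meta=det.meta,
                is_cr=True,
                onset_latency_ms=det.onset_latency_ms,
                peak_latency_ms=det.peak_latency_ms,
                peak_amplitude=det.peak_amplitude,
                perfectly_timed=self.classify_perfect_timing(det),
            )
        return det

    def _onset_latency(
        self, trial: NormalizedTrial, peak_idx: int
    ) -> Optional[float]:
        """First sustained crossing of the onset threshold before the peak.

        Returns the latency (ms, relative to CS onset) of the earliest
        post-CS sample above threshold from which the trace never dips back
        to or below threshold before the peak; ``None`` if the trace never
        crosses.
        """
        seg = trial.samples[trial.cs_onset_index : peak_idx + 1]
        above = seg > self.onset_threshold
        if not above[-1]:
            return None
        below = np.flatnonzero(~above)
        onset_off = 0 if below.size == 0 else int(below[-1]) + 1
        return onset_off * 1000.0 / trial.sample_rate_hz

    def classify_perfect_timing(self, det: CRDetection) -> bool:
        """Whether a CR peaks within the expected-US timing window."""
        if not det.is_cr:
            raise ValueError("perfect timing is defined only for CR trials")
        half = self._windows()[det.meta.isi_ms]
        isi = det.meta.isi_ms
        return isi - half <= det.peak_latency_ms <= isi + half


# -- module-level wrappers ---------------------------------------------------


def detect_cr(trial: NormalizedTrial, **params) -> CRDetection:
    """Classify one valid CS-only trial; see :class:`CRDetector`."""
    return CRDetector(**params).detect(trial)


def classify_perfect_timing(
    det: CRDetection, perfect_windows_ms: Optional[Mapping[int, float]] = None
) -> bool:
    return CRDetector(
        perfect_windows_ms=perfect_windows_ms
    ).classify_perfect_timing(det)


# -- session outcomes --------------------------------------------------------


def session_outcomes(dets: Sequence[CRDetection]) -> SessionOutcome:
    """The six per-mouse-per-day outcomes from one session's CR detections.

    ``dets`` must cover every *valid* CS-only trial of one mouse-day. Fields
    with an empty denominator (latencies, NEC over CR trials, percent
    perfectly timed, on days without CRs) are ``None``.
    """
    if len(dets) == 0:
        raise ValueError("no valid CS-only trials in session")
    meta = dets[0].meta
    if any(
        d.meta.mouse_id != meta.mouse_id or d.meta.day != meta.day for d in dets
    ):
        raise ValueError("detections must share one mouse-day")

    crs = [d for d in dets if d.is_cr]
    nec_all = float(np.mean([d.peak_amplitude for d in dets]))
    out = dict(
        mouse_id=meta.mouse_id,
        group=meta.group,
        day=meta.day,
        n_valid_trials=len(dets),
        n_cr_trials=len(crs),
        cr_probability=len(crs) / len(dets),
        nec_all_trials=nec_all,
    )
    if crs:
        out["nec_cr_trials"] = float(np.mean([d.peak_amplitude for d in crs]))
        out["mean_onset_latency_ms"] = float(
            np.mean([d.onset_latency_ms for d in crs])
        )
        out["mean_peak_latency_ms"] = float(
            np.mean([d.peak_latency_ms for d in crs])
        )
        out["pct_perfect"] = 100.0 * sum(d.perfectly_timed for d in crs) / len(crs)
    return SessionOutcome(**out)


def detections_to_frame(dets: Sequence[CRDetection]) -> pd.DataFrame:
    """Tidy per-trial detection table (one row per valid CS-only trial)."""
    return pd.DataFrame(
        {
            "mouse_id": [d.meta.mouse_id for d in dets],
            "group": [d.meta.group.value for d in dets],
            "day": [d.meta.day for d in dets],
            "trial_index": [d.meta.trial_index for d in dets],
            "isi_ms": [d.meta.isi_ms for d in dets],
            "is_cr": [d.is_cr for d in dets],
            "onset_latency_ms": [d.onset_latency_ms for d in dets],
            "peak_latency_ms": [d.peak_latency_ms for d in dets],
            "peak_amplitude": [d.peak_amplitude for d in dets],
            "perfectly_timed": [d.perfectly_timed for d in dets],
        }
    )


# -- adaptive-timing endpoint analyses ---------------------------------------


def _endpoint_crs(dets: Sequence[CRDetection], phase: str) -> list[CRDetection]:
    days = endpoint_days(phase)
    crs = [d for d in dets if d.is_cr and d.meta.day in days]
    present_days = {d.meta.day for d in dets}
    missing = [d for d in days if d not in present_days]
    if missing:
        raise ValueError(f"endpoint days missing from detections: {missing}")
    return crs


def perfect_timing_endpoint(
    dets: Sequence[CRDetection],
    phase: str,
    per_day_average: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of perfectly timed CRs over the endpoint days of a phase.

    Per mouse, CR trials from days 8–10 (ISI 250) or 18–20 (ISI 500) are
    pooled and the perfectly-timed fraction taken over the pool — a
    trial-weighted ratio, not an average of per-day percentages (the
    ``per_day_average`` flag switches to the latter).

    Returns
    -------
    per_mouse : DataFrame with columns mouse_id, group, n_cr, pct_perfect
    summary : DataFrame per group with mean, 95% CI half-width, and n
    """
    crs = _endpoint_crs(dets, phase)
    if not crs:
        raise ValueError(f"no CR trials in the {phase} endpoint days")
    frame = detections_to_frame(crs)
    if per_day_average:
        per_day = frame.groupby(["mouse_id", "group", "day"], as_index=False)[
            "perfectly_timed"
        ].mean()
        per_mouse = per_day.groupby(["mouse_id", "group"], as_index=False).agg(
            pct_perfect=("perfectly_timed", lambda s: 100.0 * s.mean())
        )
        per_mouse["n_cr"] = frame.groupby("mouse_id").size().reindex(
            per_mouse["mouse_id"]
        ).to_numpy()
    else:
        per_mouse = frame.groupby(["mouse_id", "group"], as_index=False).agg(
            n_cr=("perfectly_timed", "size"),
            pct_perfect=("perfectly_timed", lambda s: 100.0 * s.mean()),
        )
    summary = group_mean_ci(per_mouse, "pct_perfect")
    return per_mouse, summary


def group_mean_ci(
    per_mouse: pd.DataFrame, column: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Group mean with t-based 95% CI half-width over per-mouse values."""
    rows = []
    for group, sub in per_mouse.groupby("group"):
        vals = sub[column].dropna().to_numpy(dtype=float)
        n = vals.size
        mean = float(np.mean(vals)) if n else np.nan
        if n > 1:
            half = float(
                sps.t.ppf(1 - alpha / 2, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
            )
        else:
            half = np.nan
        rows.append({"group": group, "mean": mean, "ci95_half": half, "n": n})
    return pd.DataFrame(rows)


def amplitude_timing_model(dets: Sequence[CRDetection], phase: str):
    """Mixed model of peak latency on group with CR amplitude as covariate.

    Fits ``peak_latency_ms ~ group + peak_amplitude`` with a random intercept
    per mouse, on the endpoint-day CR trials of the given phase; separates
    how much of the timing variability is group versus response size.
    """
    from .stats import LMESpec, fit_lme

    crs = _endpoint_crs(dets, phase)
    frame = detections_to_frame(crs)
    if frame["group"].nunique() < 2:
        raise ValueError("need CR trials from both groups")
    spec = LMESpec(
        outcome="peak_latency_ms",
        fixed_effects=("group", "peak_amplitude"),
        random=("mouse_id",),
    )
    return fit_lme(frame, spec)


def amplitude_matched_subset(
    dets: Sequence[CRDetection],
    phase: str,
    bounds: Optional[tuple[float, float]] = None,
) -> tuple[list[CRDetection], tuple[float, float]]:
    """Restrict endpoint CRs to the enriched group's amplitude IQR.

    The benchmark interval is the [Q1, Q3] of CR amplitudes in the enriched
    group (computed from the data unless ``bounds`` is given); CRs of both
    groups with amplitudes inside the closed interval are retained, so the
    perfect-timing comparison can be re-run on amplitude-matched responses.
    """
    crs = _endpoint_crs(dets, phase)
    if bounds is None:
        enr = [
            d.peak_amplitude for d in crs if d.meta.group.value == "enriched"
        ]
        if not enr:
            raise ValueError("no enriched-group CRs to define the benchmark")
        q1, q3 = np.percentile(enr, [25, 75])
        bounds = (float(q1), float(q3))
        if q3 <= q1:
            warnings.warn(
                "zero-width enriched amplitude IQR; subset degenerates to a "
                "single amplitude",
                stacklevel=2,
            )
    lo, hi = bounds
    subset = [d for d in crs if lo <= d.peak_amplitude <= hi]
    if not subset:
        raise ValueError(
            f"amplitude-matched subset is empty for bounds [{lo:g}, {hi:g}]"
        )
    return subset, bounds
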