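"""Trial validity filtering, baseline alignment and UR-referenced normalization.

The preprocessing contract, applied per mouse-day session and always in this
order:

1. **align** — subtract the mean of the 500 ms pre-CS window from every trial,
   so all baselines sit at 0 raw units;
2. **flag** — mark trials with significant pre-CS activity as invalid: a
   trial is rejected when its pre-CS activity statistic (max absolute
   deviation from the trial's pre-CS median) exceeds ``factor`` (default 7)
   times a reference interquartile range;
3. **normalize** — divide every trace by the peak of the day's averaged
   unconditioned response (UR), so a full reflexive blink sits at 1 and the
   open eye at 0.

The reference IQR is, by default, the IQR of the pooled pre-CS sample values
of all trials in the session (``iqr_scope="session"``); a per-trial variant
(``iqr_scope="trial"``) is available since the original computation scope is
not documented. Both the activity statistic and the pooling scope are
scale-free, so validity flags are identical before and after normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import (
    NormalizedTrial,
    RawTrial,
    RejectionReason,
    SessionNormalization,
    TrialType,
    ms_to_offset,
    pre_cs_slice,
)

__all__ = [
    "baseline_align",
    "pre_cs_activity",
    "flag_invalid_trials",
    "compute_session_normalization",
    "normalize_trial",
    "TrialNormalizer",
]


def baseline_align(trial: RawTrial) -> RawTrial:
    """Shift a trial so its 500 ms pre-CS baseline has mean zero.

    Idempotent; the trace shape is unchanged.
    """
    baseline = float(np.mean(trial.samples[pre_cs_slice(trial)]))
    return replace(trial, samples=trial.samples - baseline)


def pre_cs_activity(trial: RawTrial) -> float:
    """Pre-CS activity statistic: max |deviation from the pre-CS median|."""
    pre = trial.samples[pre_cs_slice(trial)]
    return float(np.max(np.abs(pre - np.median(pre))))


def _reference_iqr(trials: Sequence[RawTrial], scope: str) -> np.ndarray:
    """Reference IQR per trial (identical for all trials in session scope)."""
    if scope == "session":
        pooled = np.concatenate([t.samples[pre_cs_slice(t)] for t in trials])
        q1, q3 = np.percentile(pooled, [25, 75])
        return np.full(len(trials), q3 - q1)
    if scope == "trial":
        out = np.empty(len(trials))
        for i, t in enumerate(trials):
            q1, q3 = np.percentile(t.samples[pre_cs_slice(t)], [25, 75])
            out[i] = q3 - q1
        return out
    raise ValueError(f"unknown iqr_scope: {scope!r}")


def flag_invalid_trials(
    trials: Sequence[RawTrial],
    factor: float = 7.0,
    iqr_scope: str = "session",
) -> np.ndarray:
    """Flag trials with significant pre-CS activity.

    Parameters
    ----------
    trials
        Baseline-aligned trials of one session; at least 4 are required for
        a stable IQR estimate.
    factor
        Rejection multiplier: a trial is invalid when its activity statistic
        exceeds ``factor * IQR``. ``factor = inf`` accepts everything.
    iqr_scope
        ``"session"`` pools pre-CS samples across the session's trials
        (default); ``"trial"`` uses each trial's own pre-CS IQR.

    Returns
    -------
    numpy.ndarray of bool
        ``True`` where the trial is **invalid**.

    Notes
    -----
    Degenerate case: if the reference IQR is zero (perfectly flat baselines),
    any trial with nonzero pre-CS activity is invalid — with a zero noise
    scale, any activity is significant.
    """
    if len(trials) == 0:
        raise ValueError("no trials to flag")
    if len(trials) < 4:
        warnings.warn(
            f"only {len(trials)} trials; IQR reference may be unstable",
            stacklevel=2,
        )
    stat = np.array([pre_cs_activity(t) for t in trials])
    if np.isinf(factor):
        return np.zeros(len(trials), dtype=bool)
    iqr = _reference_iqr(trials, iqr_scope)
    return stat > factor * iqr


def compute_session_normalization(
    us_trials: Sequence[RawTrial],
    ur_window_ms: float = 500.0,
) -> SessionNormalization:
    """Normalization reference from a day's baseline-aligned UR trials.

    The US-only (or fallback paired) traces are averaged sample-wise over the
    window [US onset, US onset + ``ur_window_ms``]; the maximum of that
    average is the day's full-blink scale.
    """
    if len(us_trials) == 0:
        raise ValueError(
            "no UR trials for this mouse-day; fall back to paired-trial "
            "post-US segments or the previous day's normalization"
        )
    mouse_id = us_trials[0].meta.mouse_id
    day = us_trials[0].meta.day
    segs = []
    for t in us_trials:
        if t.meta.mouse_id != mouse_id or t.meta.day != day:
            raise ValueError("UR trials must all belong to one mouse-day")
        us_idx = t.cs_onset_index + ms_to_offset(t.meta.isi_ms, t.sample_rate_hz)
        n_win = ms_to_offset(ur_window_ms, t.sample_rate_hz) + 1
        seg = t.samples[us_idx : us_idx + n_win]
        if seg.size < n_win:
            raise ValueError("trial too short for the UR averaging window")
        segs.append(seg)
    averaged = np.mean(segs, axis=0)
    peak = float(np.max(averaged))
    if peak <= 0:
        raise ValueError(
            f"non-positive averaged UR peak ({peak:g}) for "
            f"{mouse_id} day {day}: cannot normalize"
        )
    return SessionNormalization(
        mouse_id=mouse_id, day=day, ur_peak_raw=peak, n_ur_trials=len(us_trials)
    )


def normalize_trial(
    trial: RawTrial,
    norm: SessionNormalization,
    valid: bool = True,
    rejection_reason: Optional[RejectionReason] = None,
) -> NormalizedTrial:
    """Divide a baseline-aligned trace by the day's averaged-UR peak."""
    if trial.meta.mouse_id != norm.mouse_id or trial.meta.day != norm.day:
        raise ValueError(
            f"normalization for {norm.mouse_id} day {norm.day} applied to "
            f"trial of {trial.meta.mouse_id} day {trial.meta.day}"
        )
    return NormalizedTrial(
        meta=trial.meta,
        samples=trial.samples / norm.ur_peak_raw,
        sample_rate_hz=trial.sample_rate_hz,
        cs_onset_index=trial.cs_onset_index,
        valid=valid,
        rejection_reason=rejection_reason,
    )


class TrialNormalizer(BaseEstimator, TransformerMixin):
    """Session-wise preprocessing transformer: align, flag, normalize.

    Operates on a sequence of :class:`~blinkpipe.core.RawTrial`, possibly
    spanning several mouse-days; all per-session state (reference IQR, UR
    normalization) is learned in :meth:`fit` and applied in
    :meth:`transform`.

    Parameters
    ----------
    factor : float, default 7.0
        Pre-CS activity rejection multiplier.
    iqr_scope : {"session", "trial"}, default "session"
        Population over which the reference IQR is computed.
    ur_window_ms : float, default 500.0
        Averaging window after US onset used for the UR reference.
    exclude_invalid_from_ur : bool, default True
        Whether artifact-flagged US-only trials are excluded from the UR
        average.

    Attributes
    ----------
    normalizations_ : dict[(mouse_id, day), SessionNormalization]
        Learned per-session normalization references.
    invalid_ : numpy.ndarray of bool
        Invalidity flags for the trials seen in ``fit``, in input order.
    fallback_sessions_ : list[(mouse_id, day, str)]
        Sessions whose UR reference required a fallback policy, with the
        policy used ("paired" or "previous_day").
    """

    def __init__(
        self,
        factor: float = 7.0,
        iqr_scope: str = "session",
        ur_window_ms: float = 500.0,
        exclude_invalid_from_ur: bool = True,
    ):
        self.factor = factor
        self.iqr_scope = iqr_scope
        self.ur_window_ms = ur_window_ms
        self.exclude_invalid_from_ur = exclude_invalid_from_ur

    @staticmethod
    def _session_key(trial: RawTrial) -> tuple[str, int]:
        return (trial.meta.mouse_id, trial.meta.day)

    def fit(self, X: Sequence[RawTrial], y=None) -> "TrialNormalizer":
        sessions: dict[tuple[str, int], list[int]] = {}
        for i, t in enumerate(X):
            sessions.setdefault(self._session_key(t), []).append(i)

        aligned = [baseline_align(t) for t in X]
        invalid = np.zeros(len(X), dtype=bool)
        norms: dict[tuple[str, int], SessionNormalization] = {}
        fallbacks: list[tuple[str, int, str]] = []

        for key in sorted(sessions, key=lambda k: (k[0], k[1])):
            idx = sessions[key]
            sess = [aligned[i] for i in idx]
            inv = flag_invalid_trials(sess, self.factor, self.iqr_scope)
            invalid[idx] = inv

            def _pick(trial_type: TrialType) -> list[RawTrial]:
                return [
                    t
                    for t, bad in zip(sess, inv)
                    if t.meta.trial_type is trial_type
                    and not (bad and self.exclude_invalid_from_ur)
                ]

            us = _pick(TrialType.US_ONLY)
            if us:
                norms[key] = compute_session_normalization(us, self.ur_window_ms)
                continue
            paired = _pick(TrialType.PAIRED)
            if paired:
                norms[key] = compute_session_normalization(
                    paired, self.ur_window_ms
                )
                fallbacks.append((key[0], key[1], "paired"))
                warnings.warn(
                    f"{key[0]} day {key[1]}: no valid US-only trials; UR "
                    "reference taken from paired-trial post-US segments",
                    stacklevel=2,
                )
                continue
            prev = norms.get((key[0], key[1] - 1))
            if prev is not None:
                norms[key] = SessionNormalization(
                    mouse_id=key[0],
                    day=key[1],
                    ur_peak_raw=prev.ur_peak_raw,
                    n_ur_trials=prev.n_ur_trials,
                )
                fallbacks.append((key[0], key[1], "previous_day"))
                warnings.warn(
                    f"{key[0]} day {key[1]}: no US-bearing trials; "
                    "propagating the previous day's normalization",
                    stacklevel=2,
                )
            else:
                raise ValueError(
                    f"{key[0]} day {key[1]}: no US-bearing trials and no "
                    "previous day to propagate a normalization from"
                )

        self.normalizations_ = norms
        self.invalid_ = invalid
        self.fallback_sessions_ = fallbacks
        self._fit_ids = [id(t) for t in X]
        return self

    def transform(self, X: Sequence[RawTrial]) -> list[NormalizedTrial]:
        if not hasattr(self, "normalizations_"):
            raise ValueError("TrialNormalizer is not fitted")
        # Reuse fit-time flags when transforming the fitted trials; otherwise
        # re-derive per-session flags on the new data.
        if [id(t) for t in X] == self._fit_ids:
            invalid = self.invalid_
            aligned = [baseline_align(t) for t in X]
        else:
            sessions: dict[tuple[str, int], list[int]] = {}
            for i, t in enumerate(X):
                sessions.setdefault(self._session_key(t), []).append(i)
            aligned = [baseline_align(t) for t in X]
            invalid = np.zeros(len(X), dtype=bool)
            for key, idx in sessions.items():
                invalid[idx] = flag_invalid_trials(
                    [aligned[i] for i in idx], self.factor, self.iqr_scope
                )
        out = []
        for t, bad in zip(aligned, invalid):
            key = self._session_key(t)
            norm = self.normalizations_.get(key)
            if norm is None:
                raise ValueError(
                    f"no normalization learned for {key[0]} day {key[1]}"
                )
            out.append(
                normalize_trial(
                    t,
                    norm,
                    valid=not bad,
                    rejection_reason=(
                        RejectionReason.PRE_CS_ACTIVITY if bad else None
                    ),
                )
            )
        return out
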