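import numpy as np
import pytest

from blinkpipe.core import CRDetection, TrialType
from blinkpipe.cr import (
    CRDetector,
    amplitude_matched_subset,
    amplitude_timing_model,
    classify_perfect_timing,
    detect_cr,
    perfect_timing_endpoint,
    session_outcomes,
)
from conftest import N_PRE, cr_trace, make_meta, make_normalized
from oracles import brute_detect, brute_perfect


def det(day=9, perfect=None, is_cr=True, onset=150.0, peak=250.0, amp=0.5,
        mouse="m01", group="standard", idx=1):
    from blinkpipe.core import Group

    return CRDetection(
        meta=make_meta(
            day=day, mouse_id=mouse, group=Group(group), trial_index=idx
        ),
        is_cr=is_cr,
        onset_latency_ms=onset if is_cr else None,
        peak_latency_ms=peak if is_cr else None,
        peak_amplitude=amp,
        perfectly_timed=perfect if is_cr else None,
    )


class TestDetectCR:
    def test_subthreshold_peak_is_not_cr(self):
        t = make_normalized(cr_trace(0.05, 120, 260))
        d = detect_cr(t)
        assert not d.is_cr
        assert d.peak_amplitude == pytest.approx(0.05, abs=1e-3)

    def test_recovers_injected_kinetics(self):
        t = make_normalized(cr_trace(0.5, 120, 260))
        d = detect_cr(t)
        assert d.is_cr
        assert abs(d.peak_latency_ms - 260) <= 5
        assert abs(d.onset_latency_ms - 120) <= 10
        assert d.peak_amplitude == pytest.approx(0.5, abs=0.01)

    def test_early_onset_is_not_cr(self):
        t = make_normalized(cr_trace(0.5, 30, 260))
        d = detect_cr(t)
        assert not d.is_cr
        assert d.onset_latency_ms < 50

    def test_rejects_invalid_and_non_cs_trials(self):
        bad = make_normalized(np.zeros(N_PRE + 1101), valid=False)
        with pytest.raises(ValueError, match="valid"):
            detect_cr(bad)
        us = make_normalized(
            np.zeros(N_PRE + 1101), meta=make_meta(trial_type=TrialType.US_ONLY)
        )
        with pytest.raises(ValueError, match="CS-only"):
            detect_cr(us)

    def test_matches_brute_force_scan(self, rng):
        detector = CRDetector().fit()
        for _ in range(100):
            if rng.random() < 0.7:
                onset = rng.uniform(10, 480)
                peak = onset + rng.uniform(30, 700)
                y = cr_trace(
                    rng.uniform(0.02, 0.9),
                    onset,
                    min(peak, 1050),
                    noise_sd=rng.uniform(0, 0.03),
                    rng=rng,
                )
            else:
                y = rng.normal(0, rng.uniform(0.01, 0.08), N_PRE + 1101)
            t = make_normalized(y)
            d = detector.detect(t)
            b_cr, b_on, b_pk, b_amp = brute_detect(t)
            assert d.is_cr == b_cr
            assert d.peak_latency_ms == b_pk
            assert d.peak_amplitude == b_amp
            assert d.onset_latency_ms == b_on


class TestPerfectTiming:
    @pytest.mark.parametrize(
        "peak,day,expected",
        [
            (250.0, 9, True),
            (300.0, 9, True),  # inclusive upper bound for ISI 250
            (301.0, 9, False),
            (199.0, 9, False),
            (460.0, 19, True),
            (601.0, 19, False),
        ],
    )
    def test_window_membership(self, peak, day, expected):
        d = det(day=day, peak=peak)
        assert classify_perfect_timing(d) is expected
        isi = 250 if day <= 10 else 500
        assert classify_perfect_timing(d) == brute_perfect(peak, isi)

    def test_undefined_for_non_cr(self):
        with pytest.raises(ValueError):
            classify_perfect_timing(det(is_cr=False))


class TestSessionOutcomes:
    def test_probability_and_counts(self):
        dets = [det(idx=i, perfect=i <= 4) for i in range(1, 8)] + [
            det(idx=i, is_cr=False, amp=0.05) for i in range(8, 11)
        ]
        out = session_outcomes(dets)
        assert out.cr_probability == pytest.approx(0.7)
        assert out.n_valid_trials == 10 and out.n_cr_trials == 7
        assert out.pct_perfect == pytest.approx(100 * 4 / 7)

    def test_no_cr_day_has_missing_fields(self):
        dets = [det(idx=i, is_cr=False, amp=0.03) for i in range(1, 6)]
        out = session_outcomes(dets)
        assert out.cr_probability == 0.0
        assert out.nec_cr_trials is None
        assert out.mean_peak_latency_ms is None
        assert out.pct_perfect is None

    def test_nec_cr_at_least_nec_all(self, rng):
        for _ in range(20):
            dets = []
            for i in range(1, 21):
                amp = float(rng.uniform(0.02, 0.9))
                is_cr = amp > 0.1
                dets.append(det(idx=i, is_cr=is_cr, amp=amp, perfect=False))
            out = session_outcomes(dets)
            if out.nec_cr_trials is not None:
                assert out.nec_cr_trials >= out.nec_all_trials

    def test_cr_probability_monotone_in_threshold(self, rng):
        trials = [
            make_normalized(
                cr_trace(rng.uniform(0.05, 0.8), 130, 260), make_meta(trial_index=i)
            )
            for i in range(1, 31)
        ]
        probs = []
        for thr in (0.05, 0.1, 0.3, 0.6):
            dets = CRDetector(amplitude_threshold=thr).fit().predict(trials)
            probs.append(np.mean([d.is_cr for d in dets]))
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestEndpointPooling:
    def _dets_with_counts(self, counts, mouse="m01", group="standard"):
        """counts: {day: (n_perfect, n_cr)}"""
        out = []
        idx = 1
        for day, (k, n) in counts.items():
            for i in range(n):
                out.append(
                    det(
                        day=day, idx=idx, mouse=mouse, group=group,
                        perfect=i < k,
                        peak=250.0 if i < k else 390.0,
                    )
                )
                idx += 1
        return out

    def test_pooled_ratio_not_day_average(self):
        dets = self._dets_with_counts({8: (2, 4), 9: (3, 6), 10: (5, 10)})
        per_mouse, _ = perfect_timing_endpoint(dets, "isi250")
        assert per_mouse.loc[0, "pct_perfect"] == pytest.approx(50.0)
        # day-averaged alternative equals the same here (all days 50%) but
        # differs for unbalanced counts:
        dets2 = self._dets_with_counts({8: (1, 1), 9: (0, 9), 10: (0, 10)})
        pooled, _ = perfect_timing_endpoint(dets2, "isi250")
        assert pooled.loc[0, "pct_perfect"] == pytest.approx(100 * 1 / 20)
        averaged, _ = perfect_timing_endpoint(dets2, "isi250", per_day_average=True)
        assert averaged.loc[0, "pct_perfect"] == pytest.approx(100 / 3)

    def test_all_perfect_is_100(self):
        dets = self._dets_with_counts({8: (4, 4), 9: (6, 6), 10: (10, 10)})
        per_mouse, summary = perfect_timing_endpoint(dets, "isi250")
        assert per_mouse.loc[0, "pct_perfect"] == 100.0

    def test_missing_endpoint_day_raises(self):
        dets = self._dets_with_counts({8: (2, 4), 9: (3, 6)})
        with pytest.raises(ValueError, match="missing"):
            perfect_timing_endpoint(dets, "isi250")


class TestAmplitudeMatchedSubset:
    def _two_group_dets(self, std_amps, enr_amps):
        out = []
        idx = 1
        for day in (8, 9, 10):
            for a in std_amps:
                out.append(det(day=day, idx=idx, amp=a, perfect=True))
                idx += 1
            for a in enr_amps:
                out.append(
                    det(day=day, idx=idx, amp=a, mouse="e01", group="enriched",
                        perfect=True)
                )
                idx += 1
        return out

    def test_forced_full_bounds_is_identity(self):
        dets = self._two_group_dets([0.2, 0.5, 0.8], [0.3, 0.5, 0.7])
        subset, bounds = amplitude_matched_subset(dets, "isi250", bounds=(0.0, 1.0))
        assert len(subset) == len(dets)

    def test_benchmark_is_enriched_iqr(self):
        enr = [0.2, 0.4, 0.6, 0.8]
        dets = self._two_group_dets([0.1, 0.45, 0.95], enr)
        subset, bounds = amplitude_matched_subset(dets, "isi250")
        q1, q3 = np.percentile(enr, [25, 75])
        assert bounds == (pytest.approx(q1), pytest.approx(q3))
        assert all(q1 <= d.peak_amplitude <= q3 for d in subset)
        # standard CRs outside the benchmark interval are excluded
        assert not any(
            d.peak_amplitude in (0.1, 0.95) for d in subset
        )

    def test_degenerate_enriched_amplitudes_warn(self):
        dets = self._two_group_dets([0.2, 0.5], [0.4, 0.4, 0.4])
        with pytest.warns(UserWarning, match="zero-width"):
            subset, bounds = amplitude_matched_subset(dets, "isi250")
        assert bounds == (pytest.approx(0.4), pytest.approx(0.4))
        assert all(d.peak_amplitude == pytest.approx(0.4) for d in subset)

    def test_uniform_amplitudes_retained_fraction(self, rng):
        std = list(rng.uniform(0, 1, 400))
        enr = list(rng.uniform(0, 1, 400))
        dets = self._two_group_dets(std, enr)
        subset, bounds = amplitude_matched_subset(dets, "isi250")
        frac = len(subset) / len(dets)
        # enriched IQR width -> 0.5 for uniform amplitudes; binomial band
        assert frac == pytest.approx(0.5, abs=0.06)


class TestAmplitudeTimingModel:
    def _frame_dets(self, slope, rng, n_mice=8, per_mouse=30):
        dets = []
        idx = 1
        for mi in range(n_mice):
            group = "standard" if mi < n_mice // 2 else "enriched"
            mouse = f"{group[:3]}{mi:02d}"
            mouse_off = rng.normal(0, 20)
            for day in (8, 9, 10):
                for _ in range(per_mouse):
                    amp = float(rng.uniform(0.2, 0.8))
                    peak = 250 + slope * (amp - 0.5) + mouse_off + rng.normal(0, 30)
                    dets.append(
                        det(day=day, idx=idx, mouse=mouse, group=group,
                            amp=amp, peak=peak, perfect=abs(peak - 250) <= 50)
                    )
                    idx += 1
        return dets

    def test_recovers_amplitude_slope(self, rng):
        res = amplitude_timing_model(self._frame_dets(200.0, rng), "isi250")
        slope = res.fe_params["peak_amplitude"]
        assert slope == pytest.approx(200.0, rel=0.2)
        amp_p = res.terms.set_index("term").loc["peak_amplitude", "p"]
        assert amp_p < 0.05

    def test_identical_groups_effect_near_zero(self, rng):
        res = amplitude_timing_model(self._frame_dets(0.0, rng), "isi250")
        term = res.terms.set_index("term")
        assert term.loc["group", "p"] > 0.05
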