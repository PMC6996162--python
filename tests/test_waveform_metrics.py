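"""Wave-1 extraction, threshold estimation and growth functions."""

from dataclasses import replace

import numpy as np
import pytest

from abrkit import synthetic_cochlea as sc
from abrkit.abr_io import AveragedWaveform, ContractError, StimulusSpec
from abrkit.waveform_metrics import (
    default_search_window,
    detect_wave1,
    estimate_threshold,
    growth_function,
    sensation_level,
)


def _wf(samples, stimulus=None):
    return AveragedWaveform(
        mouse_id="m",
        stimulus=stimulus or StimulusSpec(kind="click", level_dB_SPL=70.0),
        samples=samples,
    )


def _click_series(params, rng=None, levels=np.arange(0.0, 100.0, 5.0)):
    return [
        sc.simulate_waveform(
            params, StimulusSpec(kind="click", level_dB_SPL=float(lv)), rng
        )
        for lv in levels
    ]


class TestDetectWave1:
    def test_constructed_biphasic_extrema(self):
        t = np.arange(195) / 9.75
        samples = np.zeros(195)
        samples[np.argmin(abs(t - 1.3))] = 2.0
        samples[np.argmin(abs(t - 1.8))] = -1.5
        m = detect_wave1(_wf(samples))
        assert m.p1n1_amplitude_uV == pytest.approx(3.5)
        assert m.p1_latency_ms == pytest.approx(1.3, abs=0.06)
        assert m.n1_latency_ms > m.p1_latency_ms

    def test_flat_trace_zero_amplitude(self):
        m = detect_wave1(_wf(np.zeros(195)))
        assert m.p1n1_amplitude_uV == 0.0
        assert m.p1_latency_ms == default_search_window(
            StimulusSpec(kind="click", level_dB_SPL=70.0)
        )[0]

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ContractError):
            detect_wave1(_wf(np.zeros(195)), (5.0, 25.0))

    def test_equals_brute_force_scan_oracle(self):
        """On 100 random noisy simulator waveforms the extractor equals an
        exhaustive argmax/argmin scan over the window."""
        rng = np.random.default_rng(17)
        p = sc.MousePhenotypeParams()
        for _ in range(100):
            level = float(rng.integers(0, 20) * 5)
            w = sc.simulate_waveform(
                p, StimulusSpec(kind="click", level_dB_SPL=level), rng
            )
            m = detect_wave1(w)
            lo, hi = default_search_window(w.stimulus)
            t, s = w.times_ms, w.samples
            # oracle: scan every (i, j) pair with t_i in window, t_j in (t_i, t_i+1.5]
            best = None
            for i in np.flatnonzero((t >= lo) & (t <= hi)):
                if s[i] != max(s[(t >= lo) & (t <= hi)]):
                    continue
                js = np.flatnonzero((t > t[i]) & (t <= t[i] + 1.5))
                j = js[np.argmin(s[js])]
                best = (t[i], t[j], s[i] - s[j])
                break
            assert m.p1_latency_ms == best[0]
            assert m.n1_latency_ms == best[1]
            assert m.p1n1_amplitude_uV == pytest.approx(best[2])


class TestEstimateThreshold:
    def test_noiseless_within_one_step(self):
        p = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0)
        p.true_threshold_dB["click"] = 25.0
        est = estimate_threshold(_click_series(p))
        assert not est.censored
        assert abs(est.threshold_dB_SPL - 25.0) <= 5.0

    def test_all_noise_series_censored(self):
        p = sc.MousePhenotypeParams(amp_max_uV=1e-6)
        est = estimate_threshold(_click_series(p, np.random.default_rng(3)))
        assert est.censored
        assert "> 95" in str(est)

    def test_monte_carlo_accuracy_on_cohort(self, wt_threshold_cohort):
        """Median |error| <= 5 dB and no estimate more than 5 dB below the
        true threshold, over a default-noise 20-mouse cohort."""
        archive, truth = wt_threshold_cohort
        errors = []
        by_key = {}
        for w in archive.waveforms:
            by_key.setdefault((w.mouse_id, w.stimulus.family), []).append(w)
        for (mouse_id, family), series in by_key.items():
            series.sort(key=lambda w: w.stimulus.level_dB_SPL)
            est = estimate_threshold(series)
            if not est.censored:
                errors.append(
                    est.threshold_dB_SPL - truth[mouse_id].true_threshold_dB[family]
                )
        errors = np.array(errors)
        assert np.median(np.abs(errors)) <= 5.0
        assert (errors < -5.0).sum() == 0

    def test_monotone_under_uniform_threshold_shift(self):
        """Raising all true thresholds by 10 dB raises noiseless estimates
        by 10 +/- 5 dB."""
        base = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0)
        shifted = replace(
            base,
            true_threshold_dB={k: v + 10.0 for k, v in base.true_threshold_dB.items()},
        )
        e0 = estimate_threshold(_click_series(base))
        e1 = estimate_threshold(_click_series(shifted))
        assert abs((e1.threshold_dB_SPL - e0.threshold_dB_SPL) - 10.0) <= 5.0

    def test_contract_errors(self):
        p = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0)
        series = _click_series(p)
        with pytest.raises(ContractError):
            estimate_threshold(series[:3])  # too few levels
        with pytest.raises(ContractError):
            estimate_threshold(series[::-1])  # unsorted
        tone = sc.simulate_waveform(
            p, StimulusSpec(kind="tone", frequency_kHz=12.0, level_dB_SPL=99.0,
                            duration_ms=5.0, ramp_ms=1.0)
        )
        with pytest.raises(ContractError):
            estimate_threshold(series[:-1] + [tone])  # mixed families


class TestGrowthFunction:
    def test_click_series_enumeration(self, quiet_params):
        g = growth_function(_click_series(quiet_params))
        assert len(g.points) == 20
        assert list(g.levels) == list(np.arange(0.0, 100.0, 5.0))

    def test_noiseless_matches_sigmoid_within_tolerance(self, quiet_params):
        p = quiet_params
        series = [
            sc.simulate_waveform(
                p, StimulusSpec(kind="click", level_dB_SPL=float(lv), rate_per_s=10.65)
            )
            for lv in np.arange(0.0, 100.0, 5.0)
        ]
        g = growth_function(series)
        for level, amp in g.points:
            expected = sc.wave1_amplitude(p, "click", level)
            assert amp == pytest.approx(expected, rel=0.02, abs=1e-9)

    def test_randomised_presentation_order_resorted(self, quiet_params):
        series = _click_series(quiet_params)
        rng = np.random.default_rng(0)
        shuffled = list(series)
        rng.shuffle(shuffled)
        assert growth_function(shuffled) == growth_function(series)

    def test_monotone_for_noiseless_input(self, quiet_params):
        amps = growth_function(_click_series(quiet_params)).amplitudes
        assert np.all(np.diff(amps) >= -1e-9)

    def test_duplicate_level_rejected(self, quiet_params):
        series = _click_series(quiet_params)
        with pytest.raises(ContractError):
            growth_function(series + [series[0]])


class TestSensationLevel:
    def test_identities(self, quiet_params):
        est = estimate_threshold(_click_series(quiet_params))
        thr = est.threshold_dB_SPL
        assert sensation_level(thr + 50.0, est) == pytest.approx(50.0)
        assert sensation_level(thr, est) == 0.0
        for sl in (20.0, 50.0):
            assert sensation_level(thr + sl, est) == pytest.approx(sl)

    def test_censored_threshold_rejected(self):
        from abrkit.waveform_metrics import ThresholdEstimate

        est = ThresholdEstimate("click", None, 95.0)
        with pytest.raises(ContractError):
            sensation_level(70.0, est)
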