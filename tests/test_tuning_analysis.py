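"""Masking functions, masked-threshold crossing, tuning-curve assembly."""

import math

import numpy as np
import pytest

from abrkit import synthetic_cochlea as sc
from abrkit.abr_io import ContractError, MaskerSpec, StimulusSpec
from abrkit.tuning_analysis import (
    MaskingFunction,
    build_tuning_curve,
    masked_threshold,
    masking_function,
    mean_tuning_curve,
)

PROBE = StimulusSpec(kind="tone", frequency_kHz=12.0, level_dB_SPL=40.0,
                     duration_ms=5.0, ramp_ms=1.0)


def _fn(points, usable=True):
    return MaskingFunction(PROBE, 12.0, tuple(points), usable=usable)


from oracles import pava_crossing as _oracle_crossing


class TestMaskedThreshold:
    def test_step_function_midpoint(self):
        points = [(lv, 1.0 if lv <= 40 else 0.0) for lv in range(0, 100, 10)]
        assert masked_threshold(_fn(points)).value == pytest.approx(45.0)

    def test_linear_decline_analytic_crossing(self):
        points = [(lv, 1.0 - lv / 90.0) for lv in range(0, 100, 10)]
        assert masked_threshold(_fn(points)).value == pytest.approx(45.0)

    def test_censoring_above_and_below(self):
        flat_high = [(lv, 0.9) for lv in range(0, 100, 10)]
        assert masked_threshold(_fn(flat_high)).censor == "above"
        flat_low = [(lv, 0.2) for lv in range(0, 100, 10)]
        assert masked_threshold(_fn(flat_low)).censor == "below"
        assert masked_threshold(_fn(flat_low, usable=False)).censor == "unusable"

    def test_criterion_out_of_range_rejected(self):
        points = [(lv, 1.0 - lv / 90.0) for lv in range(0, 100, 10)]
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ContractError):
                masked_threshold(_fn(points), bad)

    def test_random_monotone_functions_match_scan_oracle(self):
        """500 random monotone (noisily perturbed) step functions agree with
        the brute-force PAVA + adjacent-pair scan oracle."""
        rng = np.random.default_rng(23)
        levels = np.arange(0.0, 100.0, 10.0)
        for _ in range(500):
            base = np.sort(rng.uniform(0.0, 1.2, 10))[::-1]
            amps = np.clip(base + rng.normal(0, 0.05, 10), 0.0, None)
            got = masked_threshold(_fn(list(zip(levels, amps))))
            expected_value, expected_censor = _oracle_crossing(levels, amps, 0.5)
            assert got.censor == expected_censor
            if expected_censor is None:
                assert got.value == pytest.approx(expected_value, abs=1e-9)

    def test_invariant_to_monotone_relabelling(self):
        """The crossing depends only on the two bracketing points, so any
        strictly monotone relabelling preserving them leaves it unchanged."""
        points = [(lv, 1.0 if lv <= 40 else 0.0) for lv in range(0, 100, 10)]
        relabelled = [
            (lv, 0.9 if a > 0.5 else 0.1) for lv, a in points
        ]
        t1 = masked_threshold(_fn(points))
        t2 = masked_threshold(_fn(relabelled))
        assert t1.value == pytest.approx(t2.value)


class TestMaskingFunction:
    def test_no_masking_all_points_one(self, quiet_params):
        unmasked = sc.simulate_waveform(quiet_params, PROBE)
        masked = [
            sc.simulate_waveform(
                quiet_params,
                StimulusSpec(
                    kind="tone", frequency_kHz=12.0, level_dB_SPL=40.0,
                    duration_ms=5.0, ramp_ms=1.0,
                    masker=MaskerSpec(kind="tone", frequency_kHz=12.0,
                                      level_dB_SPL=float(lv), gap_ms=4.0),
                ),
            )
            for lv in range(0, 100, 10)
        ]
        # masker at probe frequency but the function normalises correctly:
        # check closed form within 3%
        fn = masking_function(masked, unmasked)
        assert fn.usable
        p = quiet_params
        for level, amp in fn.points:
            eff = level - sc.tuning_filter_db(p, 12.0, 12.0)
            s0 = 1.0 / (1.0 + math.exp(-(eff - sc.MASK_E50_DB) / sc.MASK_K_DB))
            expected = max(
                0.0, 1.0 - s0 * p.adaptation_depth * math.exp(-4.0 / p.recovery_tau_ms)
            )
            assert amp == pytest.approx(expected, abs=0.03)

    def test_identical_masked_and_unmasked_gives_ones(self, quiet_params):
        unmasked = sc.simulate_waveform(quiet_params, PROBE)
        clones = []
        for lv in range(0, 30, 10):
            stim = StimulusSpec(
                kind="tone", frequency_kHz=12.0, level_dB_SPL=40.0,
                duration_ms=5.0, ramp_ms=1.0,
                masker=MaskerSpec(kind="tone", frequency_kHz=6.0,
                                  level_dB_SPL=float(lv), gap_ms=4.0),
            )
            w = sc.simulate_waveform(quiet_params, stim)
            clones.append(w)
        fn = masking_function(clones, unmasked)
        # masker far below the filter at 6 kHz and low level: no suppression
        assert all(a == pytest.approx(1.0, abs=0.01) for _, a in fn.points)

    def test_zero_unmasked_amplitude_flags_unusable(self, quiet_params):
        p = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0)
        sub = StimulusSpec(kind="tone", frequency_kHz=12.0, level_dB_SPL=5.0,
                           duration_ms=5.0, ramp_ms=1.0)
        unmasked = sc.simulate_waveform(p, sub)  # below threshold: flat
        masked_stim = StimulusSpec(
            kind="tone", frequency_kHz=12.0, level_dB_SPL=5.0,
            duration_ms=5.0, ramp_ms=1.0,
            masker=MaskerSpec(kind="tone", frequency_kHz=12.0, level_dB_SPL=50.0),
        )
        fn = masking_function([sc.simulate_waveform(p, masked_stim)], unmasked)
        assert not fn.usable
        assert masked_threshold(fn).censor == "unusable"


class TestTuningCurve:
    def test_tip_at_probe_frequency_group_mean(self, wt_tuning_cohort):
        archive, _ = wt_tuning_cohort
        for probe in (12.0, 18.0, 24.0):
            curves = [
                c
                for m in archive.mouse_ids()
                if (c := build_tuning_curve(archive, m, probe)) is not None
            ]
            assert len(curves) >= 4
            tip_freq, _ = mean_tuning_curve(curves).tip
            assert tip_freq == pytest.approx(probe)

    def test_tip_shift_parameter_recovery(self):
        """Raising tuning_tip_dB by 10 dB raises the on-frequency masked
        threshold by 10 +/- 2 dB (noise off)."""
        thresholds = {}
        for tip in (30.0, 40.0):
            p = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0, tuning_tip_dB=tip)
            arch = sc.simulate_cohort(
                1, {"wt": sc.GenotypeEffect()}, "tuning", seed=2,
                base=p,
            )
            # noise off for clean recovery
            quiet = sc.MousePhenotypeParams(noise_floor_sd_uV=0.0, tuning_tip_dB=tip)
            stims = sc._battery_stimuli("tuning", quiet)
            from abrkit.abr_io import MouseRecord, SessionArchive

            wfs = [sc.simulate_waveform(quiet, s, mouse_id="m0") for s in stims]
            arch = SessionArchive(mice=[MouseRecord("m0", "wt")], waveforms=wfs)
            curve = build_tuning_curve(arch, "m0", 12.0)
            on_freq = dict(curve.points)[12.0]
            assert on_freq.finite
            thresholds[tip] = on_freq.value
        assert thresholds[40.0] - thresholds[30.0] == pytest.approx(10.0, abs=2.0)

    def test_censoring_is_exhaustive(self, wt_tuning_cohort):
        archive, _ = wt_tuning_cohort
        curve = build_tuning_curve(archive, archive.mouse_ids()[0], 18.0)
        for _, thr in curve.points:
            assert (thr.censor is None) == (thr.value is not None)
            assert thr.censor in (None, "above", "below", "unusable")
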