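import numpy as np
import pytest

from accdetect import (
    AveragedResponse,
    EpochSet,
    detect_bootstrap,
    detect_bsa,
    detect_rms,
    simulate_epochs,
)
from accdetect.detect import bsa_statistic_db
from accdetect.synth import acc_template
from accdetect.waveform import find_peaks


def _avg(design, waveform, n_accepted=100):
    return AveragedResponse(waveform=np.asarray(waveform, float),
                            n_accepted=n_accepted, n_rejected=0, design=design)


def _windows_waveform(design, signal_value, noise_value):
    """Waveform with constant values over the signal and noise-floor windows."""
    w = np.zeros(design.n_samples)
    s0, s1 = design.window_indices(design.rms_signal_window_s)
    n0, n1 = design.window_indices(design.rms_noise_window_s)
    w[s0:s1] = signal_value
    w[n0:n1] = noise_value
    return w


class TestRmsMethod:
    def test_boundary_ratio_is_present(self, design):
        """Exactly 1.5x the noise floor counts as present (inclusive rule)."""
        res = detect_rms(_avg(design, _windows_waveform(design, 1.5, 1.0)), design)
        assert res.statistic == pytest.approx(1.5)
        assert res.outcome == "present"

    def test_just_below_boundary_is_absent(self, design):
        res = detect_rms(_avg(design, _windows_waveform(design, 1.49, 1.0)), design)
        assert res.outcome == "absent"

    def test_zero_noise_floor_gives_infinite_statistic(self, design):
        res = detect_rms(_avg(design, _windows_waveform(design, 1.0, 0.0)), design)
        assert np.isinf(res.statistic)
        assert res.outcome == "present"

    def test_invalid_average_is_inconclusive(self, design):
        res = detect_rms(AveragedResponse(None, 0, 120, design), design)
        assert res.outcome == "inconclusive"
        assert np.isnan(res.statistic)

    def test_peak_numerator_mode(self, design):
        w = acc_template(design, 3.0, 2.0) + _windows_waveform(design, 0.0, 1.0)
        res = detect_rms(_avg(design, w), design, numerator="peaks")
        pk = find_peaks(w, design)
        assert res.statistic == pytest.approx(abs(pk.n1p2_amp_uv) / np.sqrt(2.0), rel=1e-9)


class TestBsaMethod:
    @pytest.mark.parametrize(
        "a1, a2, expected_db, outcome",
        [
            (10.0, 2.0, 0.512, "absent"),
            (10.0, 4.0, 4.349, "present"),
        ],
    )
    def test_statistic_arithmetic(self, design, a1, a2, expected_db, outcome):
        """mean/sample-SD of two amplitudes in dB, present iff > 3 dB."""
        assert bsa_statistic_db(a1, a2) == pytest.approx(expected_db, abs=0.005)
        w1 = acc_template(design, 0.6 * a1, 0.4 * a1)
        w2 = acc_template(design, 0.6 * a2, 0.4 * a2)
        res = detect_bsa(_avg(design, w1), _avg(design, w2), design)
        assert res.statistic == pytest.approx(expected_db, abs=0.05)
        assert res.outcome == outcome

    def test_identical_repetitions_present(self, design):
        w = acc_template(design, 3.0, 2.0)
        res = detect_bsa(_avg(design, w), _avg(design, w), design)
        assert np.isinf(res.statistic) and res.statistic > 0
        assert res.outcome == "present"

    def test_negative_mean_amplitude_absent(self, design):
        assert bsa_statistic_db(-2.0, -4.0) == -np.inf

    def test_missing_repetition_inconclusive(self, design):
        w = acc_template(design, 3.0, 2.0)
        res = detect_bsa(_avg(design, w), AveragedResponse(None, 0, 120, design), design)
        assert res.outcome == "inconclusive"

    def test_linear_scale_mode(self, design):
        w1 = acc_template(design, 6.0, 4.0)   # a1 = 10
        w2 = acc_template(design, 2.4, 1.6)   # a2 = 4 -> ratio 1.65 < 3
        res = detect_bsa(_avg(design, w1), _avg(design, w2), design, scale="linear")
        assert res.statistic == pytest.approx(1.65, abs=0.02)
        assert res.outcome == "absent"


class TestBootstrapMethod:
    def test_fixed_seed_reproducible(self, fast_design, noise_only_profile):
        e1 = simulate_epochs(fast_design, noise_only_profile, (1000.0, 15.0, 1),
                             "ipsi", seed=1)
        e2 = simulate_epochs(fast_design, noise_only_profile, (1000.0, 15.0, 1),
                             "contra", seed=2)
        r1 = detect_bootstrap(e1, e2, fast_design, n_boot=199, seed=9)
        r2 = detect_bootstrap(e1, e2, fast_design, n_boot=199, seed=9)
        assert r1.statistic == r2.statistic
        assert r1.ci == r2.ci and r1.outcome == r2.outcome

    def test_large_embedded_response_always_present(self, fast_design, quiet_profile):
        import dataclasses

        prof = dataclasses.replace(quiet_profile, noise_rms_uv=1.0,
                                   latency_jitter_ms=2.0)
        for seed in range(5):
            e1 = simulate_epochs(fast_design, prof, (1000.0, 15.0, 1), "ipsi",
                                 seed=seed)
            e2 = simulate_epochs(fast_design, prof, (1000.0, 15.0, 1), "contra",
                                 seed=seed + 50)
            res = detect_bootstrap(e1, e2, fast_design, n_boot=199, seed=seed)
            assert res.outcome == "present"

    def test_noise_false_present_rate_is_small(self, fast_design, noise_only_profile):
        """Quick type-I check on 60 noise recordings (full calibration elsewhere)."""
        hits = 0
        for i in range(60):
            e1 = simulate_epochs(fast_design, noise_only_profile, (1000.0, 15.0, 1),
                                 "ipsi", seed=2 * i)
            e2 = simulate_epochs(fast_design, noise_only_profile, (1000.0, 15.0, 1),
                                 "contra", seed=2 * i + 1)
            res = detect_bootstrap(e1, e2, fast_design, n_boot=199,
                                   resample_size=80, seed=i)
            hits += res.outcome == "present"
        assert hits <= 8  # ~2.5 % nominal; 8/60 is far outside plausible calibration

    def test_too_few_epochs_inconclusive(self, fast_design):
        e = EpochSet(np.zeros((2, fast_design.n_samples)), fast_design,
                     accepted=np.array([True, False]))
        res = detect_bootstrap(e, None, fast_design, n_boot=99, seed=0)
        assert res.outcome == "inconclusive"

    def test_plain_mode_interval_decision(self, fast_design, quiet_profile):
        import dataclasses

        prof = dataclasses.replace(quiet_profile, noise_rms_uv=1.0)
        e1 = simulate_epochs(fast_design, prof, (1000.0, 15.0, 1), "ipsi", seed=3)
        res = detect_bootstrap(e1, None, fast_design, n_boot=199, seed=4, mode="plain")
        assert res.outcome == "present"
        assert res.ci[0] > 1.0

    def test_observed_statistic_matches_peak_rms_convention(self, fast_design,
                                                            quiet_profile):
        """Bootstrap numerator (N1-P2) and the RMS peak mode (|N1P2|/sqrt2) agree
        up to the sqrt(2) convention factor on the same averaged waveform."""
        import dataclasses

        prof = dataclasses.replace(quiet_profile, noise_rms_uv=2.0)
        e1 = simulate_epochs(fast_design, prof, (1000.0, 15.0, 1), "ipsi", seed=5)
        boot = detect_bootstrap(e1, None, fast_design, n_boot=99, seed=6)
        from accdetect import average

        rms_pk = detect_rms(average(e1), fast_design, numerator="peaks")
        assert boot.statistic == pytest.approx(np.sqrt(2.0) * rms_pk.statistic, rel=1e-9)


def test_all_detectors_refuse_flagged_recordings(design):
    """A recording rejected in preprocessing yields inconclusive, never a guess."""
    bad = AveragedResponse(None, 0, 120, design)
    good = _avg(design, acc_template(design, 3.0, 2.0))
    assert detect_rms(bad, design).outcome == "inconclusive"
    assert detect_bsa(bad, good, design).outcome == "inconclusive"
    assert detect_bsa(good, bad, design).outcome == "inconclusive"
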