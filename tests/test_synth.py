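import dataclasses

import numpy as np
import pytest

from accdetect import (
    ConfigurationError,
    ParticipantProfile,
    acc_template,
    average,
    find_peaks,
    make_design,
    simulate_cohort,
    simulate_epochs,
)


class TestAccTemplate:
    def test_zero_amplitudes_give_zero_waveform(self, design):
        assert not np.any(acc_template(design, 0.0, 0.0))

    def test_peak_to_peak_matches_injected_amplitudes(self, design):
        w = acc_template(design, 3.0, 2.0)
        assert w.max() - w.min() == pytest.approx(5.0, abs=0.05)

    def test_zero_outside_support(self, design):
        w = acc_template(design, 3.0, 2.0)
        t = design.times
        outside = (t < design.tone_onset_s) | (t > design.tone_onset_s + 0.4)
        assert not np.any(w[outside])

    def test_round_trip_latency_recovery(self, design):
        """find_peaks recovers the injected latencies to within one sample."""
        w = acc_template(design, 3.0, 2.0, n1_lat_s=1.095, p2_lat_s=1.210)
        pk = find_peaks(w, design)
        assert pk.n1_latency_s == pytest.approx(1.095, abs=1.0 / design.fs)
        assert pk.p2_latency_s == pytest.approx(1.210, abs=1.0 / design.fs)
        assert pk.n1p2_amp_uv == pytest.approx(5.0, rel=0.01)

    def test_latency_outside_window_rejected(self, design):
        with pytest.raises(ConfigurationError):
            acc_template(design, 1.0, 1.0, n1_lat_s=1.3)


class TestSimulateEpochs:
    def test_noiseless_average_recovers_amplitude(self, design, quiet_profile):
        es = simulate_epochs(design, quiet_profile, (1000.0, 15.0, 1), seed=0)
        pk = find_peaks(average(es), design)
        expected = quiet_profile.acc_amp_at_max_snr_uv[1000.0]
        assert pk.n1p2_amp_uv == pytest.approx(expected, rel=1e-3)

    def test_same_seed_bit_identical(self, design):
        prof = ParticipantProfile()
        a = simulate_epochs(design, prof, (1000.0, 9.0, 1), seed=42)
        b = simulate_epochs(design, prof, (1000.0, 9.0, 1), seed=42)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, design):
        prof = ParticipantProfile()
        a = simulate_epochs(design, prof, (1000.0, 9.0, 1), seed=1)
        b = simulate_epochs(design, prof, (1000.0, 9.0, 1), seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_condition_off_grid_rejected(self, design):
        with pytest.raises(ConfigurationError):
            simulate_epochs(design, ParticipantProfile(), (1000.0, 7.0, 1), seed=0)

    def test_habituation_and_contra_scaling(self, design, quiet_profile):
        rep1 = simulate_epochs(design, quiet_profile, (1000.0, 15.0, 1), seed=0)
        rep2 = simulate_epochs(design, quiet_profile, (1000.0, 15.0, 2), seed=0)
        contra = simulate_epochs(design, quiet_profile, (1000.0, 15.0, 1), "contra", seed=0)
        a1 = find_peaks(average(rep1), design).n1p2_amp_uv
        a2 = find_peaks(average(rep2), design).n1p2_amp_uv
        ac = find_peaks(average(contra), design).n1p2_amp_uv
        assert a2 == pytest.approx(quiet_profile.habituation_factor * a1, rel=1e-6)
        assert ac == pytest.approx(quiet_profile.contra_scale * a1, rel=1e-6)

    def test_dead_region_suppression(self, design, quiet_profile):
        prof = dataclasses.replace(quiet_profile, dr_suppression_snr_db=12.0)
        below = simulate_epochs(design, prof, (1000.0, 9.0, 1), seed=0)
        at = simulate_epochs(design, prof, (1000.0, 12.0, 1), seed=0)
        assert not np.any(below.data)
        assert np.any(at.data)

    def test_average_noise_shrinks_with_sqrt_n(self, fast_design, noise_only_profile):
        """Mean of independent epochs behaves like template + noise/sqrt(n)."""
        es = simulate_epochs(fast_design, noise_only_profile, (1000.0, 15.0, 1), seed=7)
        epoch_rms = np.sqrt(np.mean(es.data**2))
        avg_rms = np.sqrt(np.mean(es.data.mean(axis=0) ** 2))
        expected = epoch_rms / np.sqrt(es.n_epochs)
        assert avg_rms == pytest.approx(expected, rel=0.35)

    def test_embedded_amplitude_monotone_in_snr(self, fast_design):
        """Monte-Carlo mean N1-P2 is non-decreasing over the SNR grid."""
        prof = ParticipantProfile(noise_rms_uv=4.0, artifact_rate=0.0)
        means = []
        for snr in fast_design.snr_grid_ascending:
            amps = []
            for run in range(25):
                es = simulate_epochs(fast_design, prof, (1000.0, snr, 1),
                                     seed=1000 + run)
                amps.append(find_peaks(average(es), fast_design).n1p2_amp_uv)
            means.append(np.mean(amps))
        diffs = np.diff(means)
        assert np.all(diffs > -0.15)  # non-decreasing up to Monte-Carlo error
        assert means[-1] > means[0]


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"artifact_rate": 1.0},
            {"habituation_factor": 0.0},
            {"habituation_factor": 1.5},
            {"noise_rms_uv": -1.0},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ParticipantProfile(**kwargs)

    def test_amplitude_clamped_at_zero(self):
        prof = ParticipantProfile(amp_growth_slope_uv_per_db=1.0)
        assert prof.n1p2_amplitude_uv(4000.0, 0.0, 1) == 0.0


class TestCohort:
    def test_single_participant_counts(self, fast_design):
        cohort = simulate_cohort(fast_design, 1, seed=0)
        assert len(cohort.manifest) == 24  # 2 freq x 6 SNR x 2 reps
        es = cohort.epochs("p00", 1000.0, 15.0, 1, "ipsi")
        assert es.data.shape == (fast_design.sweeps, fast_design.n_samples)

    def test_epoch_access_is_reproducible(self, fast_design):
        c1 = simulate_cohort(fast_design, 2, seed=5)
        c2 = simulate_cohort(fast_design, 2, seed=5)
        a = c1.epochs("p01", 4000.0, 6.0, 2, "contra")
        b = c2.epochs("p01", 4000.0, 6.0, 2, "contra")
        assert np.array_equal(a.data, b.data)

    def test_attrition_marks_requested_count(self, design):
        cohort = simulate_cohort(design, 23, seed=0, attrition=39)
        assert len(cohort.manifest) == 552
        assert (cohort.manifest.status == "ok").sum() == 513

    def test_dr_spec_applied_to_named_participant(self, fast_design):
        cohort = simulate_cohort(fast_design, 2, dr_spec={"p01": 12.0}, seed=0)
        assert cohort.profile("p01").dr_suppression_snr_db == 12.0
        assert cohort.profile("p00").dr_suppression_snr_db is None

    def test_behavioural_str_within_simulated_range(self, fast_design):
        """Estimated signal-to-TEN ratios track the drawn true values (-6..2 dB)."""
        cohort = simulate_cohort(fast_design, 4, seed=3)
        beh = cohort.behavioural
        assert beh.converged.all()
        err = beh.str_db - beh.true_str_db
        assert np.abs(err).max() < 4.0
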