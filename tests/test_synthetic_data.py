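"""Generator contracts: stationary SD, autocorrelation, determinism,
latent-factor clinical co-generation, and near-fall injection."""

import dataclasses
import math

import numpy as np
import pytest

import vestikin as vk
from vestikin.exceptions import InvalidParameterError
from vestikin.synthetic_data import (
    CLINICAL_MEASURES,
    CohortConfig,
    NearFallParams,
    SwayModelParams,
    calibrate_noise_sd,
    default_clinical_params,
    derive_seed,
    expected_sample_sd,
    generate_clinical_table,
    generate_cohort,
    generate_subject_table,
    generate_trial,
    implied_clinical_correlation,
    inject_near_falls,
)

FIRM_EC_CONTROL = SwayModelParams(per_axis_sd=(23, 18, 14, 0.9, 1.4, 1.2))


class TestSwayModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"per_axis_sd": (1, 1, 1, 1, 1)},              # wrong arity
            {"per_axis_sd": (1, 1, 1, 1, 1, -1)},          # negative SD
            {"per_axis_sd": (1,) * 6, "duration_s": -30},  # bad duration
            {"per_axis_sd": (1,) * 6, "sample_rate_hz": 0},
            {"per_axis_sd": (1,) * 6, "correlation_time_s": 40.0},
            {"per_axis_sd": (1,) * 6, "sample_rate_hz": 0.0317},  # non-integer n
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            SwayModelParams(**kwargs)

    def test_sample_count_and_lag1(self):
        p = FIRM_EC_CONTROL
        assert p.n_samples == 15000
        assert p.lag1_autocorrelation == pytest.approx(math.exp(-1 / 500))


class TestGenerateTrial:
    def test_zero_variance_gives_silent_head(self):
        p = dataclasses.replace(FIRM_EC_CONTROL, per_axis_sd=(0.0,) * 6)
        head = generate_trial(p, seed=7, sensors=("head",))[0]
        assert np.all(head.channels == 0.0)

    def test_fixed_seed_is_bit_reproducible(self):
        a = generate_trial(FIRM_EC_CONTROL, seed=42)
        b = generate_trial(FIRM_EC_CONTROL, seed=42)
        for ra, rb in zip(a, b):
            assert ra.sensor_location == rb.sensor_location
            np.testing.assert_array_equal(ra.channels, rb.channels)

    def test_stationary_sd_recovered_over_50_trials(self):
        """Mean empirical per-axis SD over 50 trials matches the closed-form
        expectation of the mean-subtracted sample SD within 3 SE."""
        sds = np.array([
            np.std(generate_trial(FIRM_EC_CONTROL, seed=s, sensors=("head",))[0]
                   .channels, axis=1, ddof=1)
            for s in range(50)
        ])
        for axis in range(6):
            expect = expected_sample_sd(FIRM_EC_CONTROL, axis)
            se = sds[:, axis].std(ddof=1) / math.sqrt(50)
            assert abs(sds[:, axis].mean() - expect) < 3 * se

    def test_roll_axis_tracks_configured_normative_value(self):
        """Roll SD configured at 0.9 deg/s is recovered to within a few
        percent on average (finite-trial estimation keeps it slightly low)."""
        sds = [
            np.std(generate_trial(FIRM_EC_CONTROL, seed=s, sensors=("head",))[0]
                   .channels[3], ddof=1)
            for s in range(50)
        ]
        assert np.mean(sds) == pytest.approx(0.9, rel=0.08)

    def test_lag1_autocorrelation_matches_closed_form(self):
        p = dataclasses.replace(FIRM_EC_CONTROL, correlation_time_s=0.05)
        rhos = []
        for s in range(5):
            x = generate_trial(p, seed=s, sensors=("head",))[0].channels[0]
            rhos.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert np.mean(rhos) == pytest.approx(p.lag1_autocorrelation, abs=0.01)


class TestInjectNearFalls:
    def test_zero_rate_leaves_recording_unchanged(self):
        wrist = generate_trial(FIRM_EC_CONTROL, seed=3,
                               sensors=("left_wrist",))[0]
        out, events = inject_near_falls(wrist, NearFallParams(), seed=5)
        assert len(events) == 0
        np.testing.assert_array_equal(out.channels, wrist.channels)

    def test_rejects_head_sensor_and_oversized_spike(self):
        head = generate_trial(FIRM_EC_CONTROL, seed=3, sensors=("head",))[0]
        with pytest.raises(InvalidParameterError):
            inject_near_falls(head, NearFallParams(event_rate_per_trial=1), 0)
        wrist = generate_trial(FIRM_EC_CONTROL, seed=3,
                               sensors=("left_wrist",))[0]
        with pytest.raises(InvalidParameterError):
            inject_near_falls(
                wrist,
                NearFallParams(event_rate_per_trial=1, spike_duration_s=31.0),
                0,
            )

    def test_events_disjoint_and_inside_trial(self):
        nf = NearFallParams(event_rate_per_trial=4.0)
        wrist = generate_trial(FIRM_EC_CONTROL, seed=9,
                               sensors=("left_wrist",))[0]
        for s in range(10):
            _, events = inject_near_falls(wrist, nf, seed=s)
            assert np.all(events >= nf.spike_duration_s / 2)
            assert np.all(events <= 30.0 - nf.spike_duration_s / 2)
            assert np.all(np.diff(events) >= nf.spike_duration_s)

    def test_poisson_event_count_mean(self):
        """Expected injected count at rate 0.5 is 0.5 per trial."""
        nf = NearFallParams(event_rate_per_trial=0.5)
        wrist = generate_trial(FIRM_EC_CONTROL, seed=2,
                               sensors=("left_wrist",))[0]
        counts = [
            len(inject_near_falls(wrist, nf, seed=s)[1]) for s in range(1000)
        ]
        # Poisson(0.5): SE of the mean over 1000 trials ~ sqrt(0.5/1000)
        assert np.mean(counts) == pytest.approx(0.5, abs=3 * math.sqrt(0.5 / 1000))

    def test_injected_event_recovered_by_detector(self):
        wrist = generate_trial(FIRM_EC_CONTROL, seed=6,
                               sensors=("left_wrist",))[0]
        nf = NearFallParams(event_rate_per_trial=1.0)
        mod = vk.synthetic_data.add_transient(wrist, 12.0, nf.spike_duration_s,
                                              nf.spike_sd_multiple)
        det = vk.detect_near_falls([mod])
        assert len(det) == 1
        assert abs(det[0] - 12.0) <= nf.spike_duration_s


class TestCohort:
    def test_counts(self):
        cfg = CohortConfig(n_per_group=9, sample_rate_hz=50.0, duration_s=2.0)
        cohort = generate_cohort(cfg)
        assert len(cohort.clinical) == 27
        assert len(cohort.trials) == 270
        assert len(cohort.subjects) == 27

    def test_empty_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortConfig(groups=())
        with pytest.raises(InvalidParameterError):
            CohortConfig(exercises=())

    def test_seed_determinism_bytewise(self):
        cfg = CohortConfig(n_per_group=2, exercises=(6,),
                           sample_rate_hz=50.0, duration_s=2.0, seed=17)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.clinical.to_csv() == b.clinical.to_csv()
        for ta, tb in zip(a.trials, b.trials):
            for ra, rb in zip(ta.recordings, tb.recordings):
                assert ra.channels.tobytes() == rb.channels.tobytes()

    def test_vs_subjects_share_latent_across_time_points(self):
        cfg = CohortConfig(n_per_group=5, exercises=(6,),
                           sample_rate_hz=50.0, duration_s=2.0)
        sub = generate_subject_table(cfg)
        pre = sub[sub.group == "preoperative"].set_index("subject")["z"]
        post = sub[sub.group == "postoperative"].set_index("subject")["z"]
        assert (pre == post).all()

    def test_clinical_measures_respect_bounds(self):
        cfg = CohortConfig(n_per_group=200, exercises=(6,),
                           sample_rate_hz=50.0, duration_s=2.0, seed=5)
        clin = generate_clinical_table(cfg)
        for m in CLINICAL_MEASURES:
            lo, hi = cfg.clinical.bounds[m]
            assert clin[m].between(lo, hi).all()

    def test_noiseless_latent_limit_gives_perfect_correlation(self):
        """With clinical noise -> 0, a positively loaded measure correlates
        perfectly with the latent factor (and hence with log sway SD)."""
        cp = default_clinical_params()
        cp = dataclasses.replace(
            cp, noise_sd={m: 0.0 for m in cp.noise_sd},
            bounds={m: (-1e9, 1e9) for m in cp.bounds},
        )
        cfg = CohortConfig(n_per_group=500, groups=("preoperative",),
                           exercises=(6,), sample_rate_hz=50.0,
                           duration_s=2.0, clinical=cp, seed=8)
        sub = generate_subject_table(cfg)
        clin = generate_clinical_table(cfg)
        df = sub.merge(clin, on=["subject", "group"])
        r = np.corrcoef(np.log(df["sway_multiplier"]), df["dva_ipsi_logmar"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_latent_model_correlation_matches_closed_form(self):
        """Sample correlation between a clinical measure and the true log
        sway SD converges to the loadings' closed-form value (n=2000)."""
        cp = default_clinical_params()
        cfg = CohortConfig(n_per_group=2000, groups=("preoperative",),
                           exercises=(6,), sample_rate_hz=50.0,
                           duration_s=2.0, clinical=cp, seed=21)
        sub = generate_subject_table(cfg)
        clin = generate_clinical_table(cfg)
        df = sub.merge(clin, on=["subject", "group"])
        for m in ("tug_s", "fga", "gait_speed_mps"):
            expect = implied_clinical_correlation(
                cp.latent_loading[m], cp.noise_sd[m], cp.kinematic_loading
            )
            got = np.corrcoef(np.log(df["sway_multiplier"]), df[m])[0, 1]
            assert got == pytest.approx(expect, abs=0.05)


class TestCalibration:
    def test_calibrated_noise_reproduces_target(self):
        lam, loading = 0.5, 0.25
        for target in (0.95, 0.88, -0.75):
            load = loading if target > 0 else -loading
            s = calibrate_noise_sd(target, load, lam, extraction_log_var=0.0167)
            assert implied_clinical_correlation(load, s, lam, 0.0167) == \
                pytest.approx(target, abs=1e-12)

    def test_unattainable_target_raises(self):
        with pytest.raises(InvalidParameterError):
            calibrate_noise_sd(0.99, 0.25, 0.1, extraction_log_var=0.05)

    def test_derive_seed_stable_and_bounded(self):
        s = derive_seed(3, "trial", "control", "HC01", 6)
        assert s == derive_seed(3, "trial", "control", "HC01", 6)
        assert 0 <= s < 2**31
        assert s != derive_seed(4, "trial", "control", "HC01", 6)
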