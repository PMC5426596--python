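import numpy as np
import pytest

from vgrfgait.features import (DegenerateFeatureError, FEATURE_NAMES,
                               FeatureConfig, coefficient_of_variation,
                               cop_point, cop_summary, cycle_shape_stats,
                               extract_features, feature_table,
                               peak_phase_force, peak_psd_power_db,
                               swing_stride_cv)
from vgrfgait.preprocess import GaitCycle, floor_noise, preprocess_record, segment_cycles
from vgrfgait.synthetic import (CohortConfig, GaitProfile, pd_profile,
                                simulate_cohort, simulate_subject)

from conftest import make_record


class TestCoefficientOfVariation:
    def test_zero_dispersion_standard(self):
        assert coefficient_of_variation([1.1, 1.1, 1.1], "standard") == 0.0

    def test_direct_arithmetic_oracle(self):
        # mean 1.1, sample SD 0.1 -> 100*0.1/1.1
        assert coefficient_of_variation([1.0, 1.1, 1.2], "standard") == \
            pytest.approx(100 * 0.1 / 1.1, abs=1e-9)

    def test_reciprocal_convention(self):
        assert coefficient_of_variation([1.0, 1.1, 1.2], "reciprocal") == \
            pytest.approx(100 * 1.1 / 0.1, abs=1e-9)

    def test_degenerate_cases_raise(self):
        with pytest.raises(DegenerateFeatureError):
            coefficient_of_variation([1.0, 1.0], "reciprocal")  # SD = 0
        with pytest.raises(DegenerateFeatureError):
            coefficient_of_variation([-1.0, 1.0], "standard")  # mean = 0
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestSwingStrideCV:
    def test_identical_cycles_give_zero(self):
        cycles = [GaitCycle(10 * i + 1, 10 * i + 7, 10 * (i + 1) + 1, 100.0)
                  for i in range(5)]
        assert swing_stride_cv(cycles) == (0.0, 0.0)

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            swing_stride_cv([GaitCycle(1, 5, 9, 100.0)])

    def test_recovers_programmed_stride_cv(self):
        profile = GaitProfile(stride_time_cv=4.0, sensor_noise_sd=0.0,
                              swing_blip_rate=0.0)
        rec, _ = simulate_subject(profile, seed=5, duration=140.0)
        total = floor_noise(rec.left_forces).sum(axis=1)
        cycles = segment_cycles(total, 100.0)
        assert len(cycles) >= 90
        _, cv_stride = swing_stride_cv(cycles)
        assert cv_stride == pytest.approx(4.0, abs=1.0)


class TestCoP:
    def test_symmetric_forces_balance(self, layout):
        frame = np.zeros(8)
        frame[[1, 2]] = 100.0  # sensors at x = -700 and -300
        assert cop_point(frame, layout, "x") == pytest.approx(-500.0)

    def test_weighted_mean_by_hand(self, layout):
        # forces 100 N at y=-800 (sensor 1) and 300 N at y=0 (sensor 4)
        frame = np.zeros(8)
        frame[0], frame[3] = 100.0, 300.0
        expected = (100 * -800 + 300 * 0) / 400
        assert cop_point(frame, layout, "y") == pytest.approx(expected, abs=1e-9)

    def test_single_active_sensor(self, layout):
        frame = np.zeros(8)
        frame[7] = 42.0
        assert cop_point(frame, layout, "y") == pytest.approx(800.0)

    def test_zero_frame_rejected(self, layout):
        with pytest.raises(DegenerateFeatureError):
            cop_point(np.zeros(8), layout, "x")

    def test_within_convex_hull_of_active_sensors(self, layout, noisy_subject):
        rec, _ = noisy_subject
        pre = preprocess_record(rec)
        xs = layout.coordinates("left", "x")
        for c in pre.cycles[:20]:
            for frame in pre.sensor_forces[c.stance[0]:c.stance[1]]:
                active = frame > 0
                v = cop_point(frame, layout, "x")
                assert xs[active].min() - 1e-9 <= v <= xs[active].max() + 1e-9

    def test_summary_single_sensor_degenerate(self, layout):
        left = np.zeros((40, 8))
        left[10:20, 4] = 500.0  # all force on sensor 5 at (-300, 0)
        cycles = [GaitCycle(10, 20, 30, 100.0)]
        mx, sx, my, sy = cop_summary(cycles, left, layout)
        assert (mx, sx, my, sy) == (-300.0, 0.0, 0.0, 0.0)

    def test_summary_matches_bruteforce_oracle(self, layout, noiseless_subject):
        rec, truth = noiseless_subject
        pre = preprocess_record(rec)
        _, _, _, sd_y = cop_summary(pre.cycles, pre.sensor_forces, layout)
        # oracle: SD of the generator's own per-frame CoP over the same frames
        trimmed_cop = truth.cop_y[2000:]
        pooled = np.concatenate([trimmed_cop[c.stance[0]:c.stance[1]]
                                 for c in pre.cycles])
        assert sd_y == pytest.approx(np.std(pooled, ddof=1), rel=0.10)

    def test_flat_footed_profile_has_smaller_sd_cop_y(self, layout):
        ramped = GaitProfile(cop_y_excursion=0.9)
        flat = GaitProfile(cop_y_excursion=0.2)
        sds = {}
        for name, prof in (("ramped", ramped), ("flat", flat)):
            rec, _ = simulate_subject(prof, seed=9, duration=80.0)
            pre = preprocess_record(rec)
            sds[name] = cop_summary(pre.cycles, pre.sensor_forces, layout)[3]
        assert sds["flat"] < sds["ramped"]


class TestPeakPhaseForce:
    def test_max_over_window(self, layout):
        heel_cols = layout.role_columns("left", "heel")
        series = np.zeros((30, 8))
        series[10:15, heel_cols[0]] = [650, 680, 660, 500, 300]
        cycle = GaitCycle(10, 22, 28, 100.0)
        assert peak_phase_force(cycle, series, heel_cols, "heel") == 680.0

    def test_short_stance_falls_back_to_full_stance(self, layout):
        heel_cols = layout.role_columns("left", "heel")
        series = np.zeros((30, 8))
        series[10:13, heel_cols[0]] = [100, 300, 200]
        cycle = GaitCycle(10, 13, 20, 100.0)
        assert peak_phase_force(cycle, series, heel_cols, "heel", window=5) == 300.0

    def test_recovers_programmed_heel_peak(self, layout, noisy_subject):
        rec, truth = noisy_subject
        pre = preprocess_record(rec)
        heel_cols = layout.role_columns("left", "heel")
        peaks = [peak_phase_force(c, pre.sensor_forces, heel_cols, "heel")
                 for c in pre.cycles]
        n = len(peaks)
        assert np.mean(peaks) == pytest.approx(600.0, abs=3 * 5 / np.sqrt(n) + 1.0)


class TestShapeStats:
    def test_symmetric_triangle_has_zero_skew(self):
        total = np.zeros(300)
        tri = np.concatenate([np.linspace(0, 100, 60), np.linspace(100, 0, 60)[1:]])
        total[50:50 + len(tri)] = tri + 50  # keep stance strictly positive
        cycle = GaitCycle(50, 50 + len(tri), 220, 100.0)
        _, skew = cycle_shape_stats(cycle, total)
        assert abs(skew) < 0.05

    def test_matches_direct_moment_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        total = np.concatenate([np.zeros(2), x, np.zeros(4)])
        cycle = GaitCycle(2, 7, 9, 100.0)
        kurt, skew = cycle_shape_stats(cycle, total)
        mu = x.mean()
        m2 = np.mean((x - mu) ** 2)
        m3 = np.mean((x - mu) ** 3)
        m4 = np.mean((x - mu) ** 4)
        assert skew == pytest.approx(m3 / m2 ** 1.5, abs=1e-9)
        assert kurt == pytest.approx(m4 / m2 ** 2, abs=1e-9)

    def test_constant_stance_rejected(self):
        total = np.concatenate([np.zeros(2), np.full(10, 7.0), np.zeros(4)])
        with pytest.raises(DegenerateFeatureError):
            cycle_shape_stats(GaitCycle(2, 12, 15, 100.0), total)


class TestPeakPSD:
    def test_sinusoid_peak_at_its_frequency(self):
        fs = 100.0
        n = 128
        f0 = 10.0
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        total = np.concatenate([np.zeros(2), x, np.zeros(2)])
        cycle = GaitCycle(2, 2 + n, 2 + n + 2, fs)
        from scipy.signal import periodogram
        freqs, psd = periodogram(total[2:2 + n + 2], fs=fs, window="boxcar")
        # spectral identity: the package's dB value equals the periodogram max
        db = peak_psd_power_db(cycle, total, fs)
        assert db == pytest.approx(10 * np.log10(psd.max()), abs=1e-9)
        assert abs(freqs[np.argmax(psd)] - f0) <= freqs[1] - freqs[0]

    def test_doubling_amplitude_adds_six_db(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 700, size=100)
        total = np.concatenate([np.zeros(3), x, np.zeros(3)])
        cycle = GaitCycle(3, 103, 106, 100.0)
        db1 = peak_psd_power_db(cycle, total, 100.0)
        db2 = peak_psd_power_db(cycle, 2 * total, 100.0)
        assert db2 - db1 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_deterministic(self, noisy_subject):
        rec, _ = noisy_subject
        pre = preprocess_record(rec)
        c = pre.cycles[0]
        assert peak_psd_power_db(c, pre.total, 100.0) == \
            peak_psd_power_db(c, pre.total, 100.0)


class TestExtractFeatures:
    def test_finite_vector_for_control_subject(self, noisy_subject):
        rec, _ = noisy_subject
        vec = extract_features(rec)
        assert set(vec.values) == set(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vec.values.values())

    def test_identical_records_give_identical_vectors(self, noisy_subject):
        rec, _ = noisy_subject
        a = extract_features(rec)
        b = extract_features(rec)
        assert a.values == b.values

    def test_too_few_cycles_skips_subject(self):
        rec = make_record(np.zeros((5000, 8)))
        assert extract_features(rec) is None

    def test_appending_subfloor_swing_noise_leaves_features_unchanged(self, noisy_subject):
        import dataclasses
        rec, _ = noisy_subject
        rng = np.random.default_rng(2)
        extra = 200
        pad = rng.uniform(0.0, 19.0, size=(extra, 8))
        padded = dataclasses.replace(
            rec,
            time=np.arange(rec.n_samples + extra) / rec.sampling_rate,
            left_forces=np.vstack([rec.left_forces, pad]),
            right_forces=np.vstack([rec.right_forces, pad]),
            left_total=np.concatenate([rec.left_total, pad.sum(axis=1)]),
            right_total=np.concatenate([rec.right_total, pad.sum(axis=1)]),
        )
        a = extract_features(rec)
        b = extract_features(padded)
        assert a.values == b.values

    def test_group_contrast_directionality(self):
        cfg = CohortConfig(n_control=20, n_pd=20, rng_seed=31, duration=100.0)
        table = feature_table(simulate_cohort(cfg).records)
        means = table.groupby("group")[["cv_stride", "mean_pf_heel"]].mean()
        assert means.loc["pd", "cv_stride"] > means.loc["control", "cv_stride"]
        assert means.loc["pd", "mean_pf_heel"] < means.loc["control", "mean_pf_heel"]
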