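"""Synthetic cohort generator: schedules, signatures, determinism, IO."""

import numpy as np
import pytest

from sladl.activities import (ActivityClass, SensorSite, WHEEL_MOTION_CLASSES,
                              IMU_RATE_HZ)
from sladl.cohort import (ActivitySchedule, CohortConfig, NoiseConfig,
                          ScheduleConfig, generate_cohort, generate_participant,
                          make_schedule, read_cohort, static_posture_reference,
                          synth_activity, synth_posture_hold, write_cohort)
from sladl.preprocessing import EnvelopeConfig, emg_envelope, normalize_emg


class TestSchedule:
    def test_fixed_bounds_force_total_duration(self, rng):
        sched = make_schedule(ScheduleConfig(10.0, 10.0), rng)
        assert sched.total_duration == pytest.approx(80.0)
        assert len(sched.blocks) == 8

    def test_all_eight_classes_present(self, rng):
        sched = make_schedule(ScheduleConfig(), rng)
        assert {a for a, _ in sched.blocks} == set(ActivityClass)

    def test_same_seed_gives_identical_schedule(self):
        s1 = make_schedule(ScheduleConfig(), np.random.default_rng(7))
        s2 = make_schedule(ScheduleConfig(), np.random.default_rng(7))
        assert s1 == s2

    def test_invalid_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            make_schedule(ScheduleConfig(min_duration=5.0, max_duration=3.0), rng)
        with pytest.raises(ValueError):
            make_schedule(ScheduleConfig(min_duration=-1.0), rng)

    def test_schedule_requires_every_class(self):
        with pytest.raises(ValueError, match="misses"):
            ActivitySchedule(blocks=((ActivityClass.STAT, 10.0),))


class TestSynthActivity:
    def test_stationary_wheel_gyro_stays_at_noise_floor(self, default_profile, rng):
        noise = NoiseConfig()
        block = synth_activity(ActivityClass.STAT, default_profile, 30.0, rng,
                               noise)
        wheel_z = block["sites"][SensorSite.WCW].gyro[:, 2]
        assert np.abs(wheel_z).max() < 5 * noise.gyro

    def test_armcrank_dominant_frequency_is_one_hertz(self, default_profile, rng):
        block = synth_activity(ActivityClass.ARMCRANK, default_profile, 60.0,
                               rng)
        gyro = block["sites"][SensorSite.FA].gyro
        # project on the dominant axis and find the spectral peak
        x = gyro - gyro.mean(axis=0)
        x = x[:, np.argmax(x.std(axis=0))]
        freqs = np.fft.rfftfreq(x.size, d=1 / IMU_RATE_HZ)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert peak == pytest.approx(1.0, abs=0.05)

    def test_dribbling_wheel_moves_then_returns_to_standstill(
            self, default_profile, rng):
        noise = NoiseConfig()
        block = synth_activity(ActivityClass.DRIBBLING, default_profile, 20.0,
                               rng, noise)
        wheel_z = block["sites"][SensorSite.WCW].gyro[:, 2]
        assert np.abs(wheel_z).max() > 10 * noise.gyro  # crosses noise floor
        tail = wheel_z[-30:]  # final 0.3 s: wheel at standstill
        assert np.abs(tail).max() < 5 * noise.gyro

    def test_nonpositive_duration_rejected(self, default_profile, rng):
        with pytest.raises(ValueError):
            synth_activity(ActivityClass.STAT, default_profile, 0.0, rng)

    def test_unknown_class_rejected(self, default_profile, rng):
        with pytest.raises(ValueError):
            synth_activity(99, default_profile, 5.0, rng)

    def test_emg_rate_is_ten_times_imu_rate(self, default_profile, rng):
        block = synth_activity(ActivityClass.MMH, default_profile, 12.0, rng)
        n_imu = block["sites"][SensorSite.UA].accel.shape[0]
        assert block["emg"].shape == (10 * n_imu, 2)


class TestGenerateParticipant:
    def test_eight_equal_blocks_make_eight_intervals(self, default_profile, rng):
        sched = make_schedule(ScheduleConfig(10.0, 10.0), rng)
        rec, track = generate_participant(default_profile, sched, rng)
        assert len(track.intervals) == 8
        assert track.duration == pytest.approx(80.0)
        assert rec.duration == pytest.approx(80.0)

    def test_annotation_exactly_covers_recording(self, default_profile, rng):
        sched = make_schedule(ScheduleConfig(), rng)
        rec, track = generate_participant(default_profile, sched, rng)
        total = sum(e - s for s, e, _ in track.intervals)
        assert total == pytest.approx(rec.duration, abs=1e-9)
        # contiguity is enforced by the type itself
        for (s0, e0, _), (s1, _, _) in zip(track.intervals, track.intervals[1:]):
            assert e0 == pytest.approx(s1, abs=1e-12)

    def test_seeded_rerun_is_bit_identical(self, default_profile):
        sched = make_schedule(ScheduleConfig(), np.random.default_rng(3))
        rec1, _ = generate_participant(default_profile, sched,
                                       np.random.default_rng(9))
        rec2, _ = generate_participant(default_profile, sched,
                                       np.random.default_rng(9))
        for site in rec1.sites:
            np.testing.assert_array_equal(rec1.sites[site].accel,
                                          rec2.sites[site].accel)
            np.testing.assert_array_equal(rec1.sites[site].gyro,
                                          rec2.sites[site].gyro)
        np.testing.assert_array_equal(rec1.emg, rec2.emg)


class TestGenerateCohort:
    def test_default_cohort_has_ten_unique_participants(self):
        ds = generate_cohort(10, seed=1)
        assert len(ds) == 10
        assert len(set(ds.participant_ids)) == 10

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)

    def test_different_seeds_differ(self):
        cfg = CohortConfig(n_participants=3,
                           schedule=ScheduleConfig(5.0, 5.0))
        d1 = generate_cohort(3, cfg, seed=1)
        d2 = generate_cohort(3, cfg, seed=2)
        a1 = d1.participants[0][1].sites[SensorSite.UA].accel
        a2 = d2.participants[0][1].sites[SensorSite.UA].accel
        assert not np.array_equal(a1, a2)

    def test_seed_determinism_across_regeneration(self, small_cohort):
        again = generate_cohort(3, small_cohort.config, seed=77)
        for (p1, r1, t1), (p2, r2, t2) in zip(small_cohort.participants,
                                              again.participants):
            assert p1 == p2
            assert t1 == t2
            np.testing.assert_array_equal(r1.emg, r2.emg)

    def test_wheel_motion_classes_dominate_wheel_gyro(self, small_cohort):
        """Mean |wheel gyro| in wheel classes >= 5x that of the rest."""
        for _, rec, track in small_cohort.participants:
            wheel = np.abs(rec.sites[SensorSite.WCW].gyro[:, 2])
            moving, still = [], []
            for s, e, a in track.intervals:
                seg = wheel[int(s * IMU_RATE_HZ):int(e * IMU_RATE_HZ)]
                (moving if a in WHEEL_MOTION_CLASSES else still).append(seg)
            assert (np.concatenate(moving).mean()
                    >= 5 * np.concatenate(still).mean())

    def test_equal_durations_balance_classes(self, default_profile, rng):
        sched = make_schedule(ScheduleConfig(10.0, 10.0), rng)
        _, track = generate_participant(default_profile, sched, rng)
        lengths = {a.code: round((e - s) * 10) for s, e, a in track.intervals}
        assert set(lengths.values()) == {100}


class TestPostureReference:
    def test_reference_is_profile_passthrough(self, default_profile):
        assert static_posture_reference(default_profile) == (1.0, 1.0)
        prof = default_profile.__class__(
            **{**default_profile.__dict__, "emg_posture_refs": (2.0, 0.5)})
        assert static_posture_reference(prof) == (2.0, 0.5)

    def test_normalized_envelope_of_posture_hold_is_near_one(
            self, default_profile, rng):
        """Envelope of the reference posture divided by the reference ~ 1."""
        prof = default_profile.__class__(
            **{**default_profile.__dict__, "emg_posture_refs": (1.7, 0.6)})
        raw = synth_posture_hold(prof, 30.0, rng)
        for m, ref in enumerate(static_posture_reference(prof)):
            env = emg_envelope(raw[:, m], EnvelopeConfig())
            normed = normalize_emg(env, ref)
            # ignore filter edges
            assert np.median(normed[10:-10]) == pytest.approx(1.0, rel=0.1)


def test_cohort_roundtrip_through_disk(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path / "cohort")
    back = read_cohort(tmp_path / "cohort")
    assert back.participant_ids == small_cohort.participant_ids
    p0, r0, t0 = small_cohort.participants[0]
    p1, r1, t1 = back.participants[0]
    assert p0.participant_id == p1.participant_id
    assert [a for _, _, a in t0.intervals] == [a for _, _, a in t1.intervals]
    # CSV roundtrip is lossy only at the printed precision
    np.testing.assert_allclose(r1.sites[SensorSite.FA].gyro,
                               r0.sites[SensorSite.FA].gyro,
                               rtol=1e-4, atol=1e-4)
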