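"""Simulator checks: trajectories, activations, sEMG, rendering, datasets."""

import numpy as np
import pytest
from scipy.signal import periodogram

from limbfuse.gaitsim import (GaitProfile, OccluderSpec, SimConfig,
                              make_activation, make_angle_trajectory,
                              make_dataset, render_depth, synthesize_emg)
from limbfuse.types import JOINT_NAMES, MUSCLES, JointAngleSample


def test_zero_harmonic_profile_gives_constant_angles():
    prof = GaitProfile(joint_fourier={"hip": (0.0, []), "knee": (20.0, []),
                                      "ankle": (0.0, [])})
    traj = make_angle_trajectory(prof, SimConfig(duration_s=3.0))
    knee = np.array([s.knee_deg for s in traj.samples])
    np.testing.assert_allclose(knee, 20.0)


def test_trajectory_autocorrelation_peaks_at_stride_period():
    cfg = SimConfig(duration_s=10.0)
    traj = make_angle_trajectory(GaitProfile(cadence_hz=0.9), cfg)
    knee = np.array([s.knee_deg for s in traj.samples])
    knee = knee - knee.mean()
    ac = np.correlate(knee, knee, mode="full")[len(knee) - 1:]
    expected_lag = round(cfg.frame_fps / 0.9)
    # first local peak after lag 0
    lo, hi = expected_lag // 2, expected_lag * 3 // 2
    peak = lo + int(np.argmax(ac[lo:hi]))
    assert abs(peak - expected_lag) <= 1


def test_default_knee_spans_normal_gait_range():
    prof = GaitProfile()
    phase = np.linspace(0, 1, 4096, endpoint=False)
    knee = prof.angle("knee", phase)
    assert abs(knee.min() - 0.0) <= 1.0
    assert abs(knee.max() - 65.0) <= 1.0


def test_trajectory_requires_one_full_stride():
    with pytest.raises(ValueError):
        make_angle_trajectory(GaitProfile(cadence_hz=0.5),
                              SimConfig(duration_s=1.0))


class TestActivation:
    def test_no_bumps_is_zero(self):
        prof = GaitProfile(muscle_bumps={m: [] for m in MUSCLES})
        t = np.linspace(0, 5, 100)
        np.testing.assert_allclose(make_activation(prof, t, "TA"), 0.0)

    def test_bump_peak_reaches_amplitude(self):
        prof = GaitProfile(cadence_hz=1.0,
                           muscle_bumps={"TA": [(0.5, 0.05, 1.0)]})
        assert make_activation(prof, 0.5, "TA") == pytest.approx(1.0)

    def test_wraps_around_cycle_boundary(self):
        prof = GaitProfile(cadence_hz=1.0,
                           muscle_bumps={"TA": [(0.98, 0.05, 0.8)]})
        got = make_activation(prof, 0.01, "TA")
        expected = 0.8 * np.exp(-0.5 * (0.03 / 0.05) ** 2)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_unknown_muscle_rejected(self):
        with pytest.raises(ValueError):
            make_activation(GaitProfile(), 0.0, "QUAD")


class TestEmg:
    def test_zero_activation_leaves_noise_floor_rms(self):
        prof = GaitProfile(muscle_bumps={m: [] for m in MUSCLES})
        rec = synthesize_emg(prof, SimConfig(duration_s=5.0, seed=4))
        rms = rec.samples.std(axis=0)
        np.testing.assert_allclose(rms, prof.emg_noise_floor_mv, rtol=0.1)

    def test_envelope_tracks_activation(self):
        prof, cfg = GaitProfile(), SimConfig(duration_s=10.0, seed=5)
        rec = synthesize_emg(prof, cfg)
        ta = rec.samples[:, MUSCLES.index("TA")]
        n = int(0.050 * cfg.emg_fs_hz)  # 50 ms moving RMS
        kernel = np.ones(n) / n
        env = np.sqrt(np.convolve(ta ** 2, kernel, mode="same"))
        act = make_activation(prof, rec.sample_times(), "TA")
        r = np.corrcoef(env, act)[0, 1]
        assert r > 0.8

    def test_same_seed_is_bit_identical(self):
        prof, cfg = GaitProfile(), SimConfig(duration_s=2.0, seed=6)
        a = synthesize_emg(prof, cfg)
        b = synthesize_emg(prof, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_power_is_concentrated_in_the_band(self):
        prof, cfg = GaitProfile(), SimConfig(duration_s=10.0, seed=7)
        rec = synthesize_emg(prof, cfg)
        f, p = periodogram(rec.samples[:, 0], fs=cfg.emg_fs_hz)
        lo, hi = prof.emg_band_hz
        in_band = p[(f >= lo) & (f <= hi)].sum()
        assert in_band / p.sum() >= 0.90

    def test_nyquist_violation_rejected(self):
        prof = GaitProfile(emg_band_hz=(20.0, 600.0))
        with pytest.raises(ValueError):
            synthesize_emg(prof, SimConfig(duration_s=2.0))


class TestRenderDepth:
    def setup_method(self):
        self.cfg = SimConfig(duration_s=2.0)
        self.sample = JointAngleSample(10.0, 20.0, 0.0, 0.0)

    def test_no_occluder_all_joints_visible(self):
        _, js = render_depth(self.sample, self.cfg, OccluderSpec(0.0))
        assert js.visible.all()

    def test_ankle_high_occluder_hides_feet_keeps_knees(self):
        # ankle joint sits ~0.07 m up; knees ~0.47 m
        _, js = render_depth(self.sample, self.cfg, OccluderSpec(0.30))
        idx = {n: i for i, n in enumerate(JOINT_NAMES)}
        for j in ("r_ankle", "r_foot", "l_ankle", "l_foot"):
            assert not js.visible[idx[j]]
        for j in ("r_knee", "l_knee", "pelvis", "head"):
            assert js.visible[idx[j]]

    def test_invisible_set_monotone_in_occluder_height(self):
        prev = set()
        for h in (0.0, 0.1, 0.3, 0.6, 1.2):
            _, js = render_depth(self.sample, self.cfg, OccluderSpec(h))
            cur = {i for i in range(19) if not js.visible[i]}
            assert prev <= cur
            prev = cur

    def test_depth_at_knee_pixel_matches_camera_z(self):
        frame, js = render_depth(self.sample, self.cfg, OccluderSpec(0.0))
        fx, fy, cx, cy = self.cfg.intrinsics
        knee = js["r_knee"]
        u = int(round(fx * knee[0] / knee[2] + cx))
        v = int(round(fy * knee[1] / knee[2] + cy))
        rendered = frame.depth[v, u] / 1000.0
        assert abs(rendered - knee[2]) <= self.cfg.limb_radius_m / 2 + 1e-6


class TestMakeDataset:
    def test_record_count_matches_enumeration_oracle(self, bench_dataset):
        cfg = bench_dataset.config
        frame_ts = np.arange(int(cfg.duration_s * cfg.frame_fps)) / cfg.frame_fps
        # oracle: frames whose trailing history holds >= 300 samples
        expected = sum(int(np.floor(t * cfg.emg_fs_hz)) + 1 >= 300
                       for t in frame_ts)
        assert expected == 291
        assert len(bench_dataset) == expected

    def test_windows_co_terminate(self, bench_dataset):
        i = 17
        full = bench_dataset.windows_full[i]
        np.testing.assert_array_equal(bench_dataset.windows_mid[i], full[100:])
        np.testing.assert_array_equal(bench_dataset.windows_short[i], full[200:])

    def test_phase_alternates_twice_per_stride(self, bench_dataset):
        stance = bench_dataset.stance
        transitions = int(np.abs(np.diff(stance.astype(int))).sum())
        ts = bench_dataset.trigger_ts
        strides = (ts[-1] - ts[0]) * bench_dataset.profile.cadence_hz
        assert abs(transitions - 2 * strides) <= 2

    def test_same_seed_gives_bit_identical_datasets(self):
        cfg = SimConfig(duration_s=2.5, seed=11, depth_resolution=(32, 32))
        a = make_dataset(GaitProfile(), cfg)
        b = make_dataset(GaitProfile(), cfg)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.windows_full, b.windows_full)
        np.testing.assert_array_equal(a.angles, b.angles)

    def test_npz_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "ds.npz"
        small_dataset.save_npz(p)
        back = type(small_dataset).load_npz(p)
        np.testing.assert_array_equal(back.angles, small_dataset.angles)
        np.testing.assert_allclose(back.windows_full,
                                   small_dataset.windows_full)
        assert back.config.seed == small_dataset.config.seed
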