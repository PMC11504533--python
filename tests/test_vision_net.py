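"""Vision branch: heatmaps, localization, back-projection, angle geometry."""

import numpy as np
import pytest

from limbfuse.gaitsim import (GaitProfile, OccluderSpec, SimConfig,
                              make_angle_trajectory, render_depth)
from limbfuse.nn import Tensor
from limbfuse.types import JOINT_NAMES, DepthFrame, JointSet
from limbfuse.vision_net import (PoseNet, VisionFeatures, VisionSpec, _ResBlock,
                                 angles_from_joints, extract_features,
                                 joints_from_heatmaps)

INTR = (70.0, 70.0, 31.5, 31.5)


def random_frame(rng, size=64):
    return DepthFrame(rng.uniform(500, 3000, (size, size)), 0.0, INTR)


def test_heatmap_channels_are_normalized(rng):
    model = PoseNet(seed=5)
    vf = extract_features(random_frame(rng), model)
    sums = vf.heatmaps.sum(axis=(1, 2))
    np.testing.assert_allclose(sums, 1.0, atol=1e-5)
    assert (vf.heatmaps >= 0).all()


def test_extract_features_is_deterministic_in_eval_mode(rng):
    model = PoseNet(seed=6)
    frame = random_frame(rng)
    a = extract_features(frame, model)
    b = extract_features(frame, model)
    np.testing.assert_array_equal(a.heatmaps, b.heatmaps)
    np.testing.assert_array_equal(a.feature_vec, b.feature_vec)


def test_residual_block_with_zero_branch_is_identity(rng):
    blk = _ResBlock(np.random.default_rng(0), 4)
    blk.conv1.weight.data[...] = 0.0
    blk.conv2.weight.data[...] = 0.0
    x = Tensor(rng.normal(size=(2, 4, 6, 6)).astype(np.float32))
    y = blk(x)
    np.testing.assert_allclose(y.data, x.data, atol=1e-6)


def test_resolution_mismatch_rejected(rng):
    model = PoseNet(VisionSpec(resolution=(64, 64)), seed=0)
    with pytest.raises(ValueError, match="resolution"):
        model.forward_frames(rng.uniform(0, 1, (1, 32, 32)))


class TestJointsFromHeatmaps:
    def delta_features(self, u, v, size=64):
        hm = np.zeros((19, size, size))
        hm[:, v, u] = 1.0
        return VisionFeatures(hm, np.zeros(32))

    def test_delta_heatmap_back_projects_by_pinhole_formula(self):
        fx, fy, cx, cy = INTR
        u, v, d_mm = 40, 22, 2200.0
        depth = np.full((64, 64), d_mm)
        js = joints_from_heatmaps(self.delta_features(u, v),
                                  DepthFrame(depth, 0.0, INTR))
        d = d_mm / 1000.0
        expect = [(u - cx) * d / fx, (v - cy) * d / fy, d]
        np.testing.assert_allclose(js.positions[0], expect, atol=1e-9)
        assert js.visible.all()

    def test_uniform_heatmap_localizes_at_image_center(self):
        hm = np.full((19, 64, 64), 1.0 / (64 * 64))
        depth = np.full((64, 64), 1000.0)
        js = joints_from_heatmaps(VisionFeatures(hm, np.zeros(32)),
                                  DepthFrame(depth, 0.0, INTR),
                                  threshold=0.0)
        fx, fy, cx, cy = INTR
        # soft-argmax lands on (31.5, 31.5) == the principal point
        np.testing.assert_allclose(js.positions[:, :2], 0.0, atol=1e-9)

    def test_zero_depth_patch_marks_joint_invisible(self):
        depth = np.zeros((64, 64))
        js = joints_from_heatmaps(self.delta_features(10, 10),
                                  DepthFrame(depth, 0.0, INTR))
        assert not js.visible.any()

    def test_low_peak_marks_joint_invisible(self):
        hm = np.full((19, 8, 8), 1.0 / 64)  # exactly uniform
        depth = np.full((64, 64), 1000.0)
        js = joints_from_heatmaps(VisionFeatures(hm, np.zeros(32)),
                                  DepthFrame(depth, 0.0, INTR))
        assert not js.visible.any()  # below 2x uniform threshold


class TestAnglesFromJoints:
    def place(self, **positions):
        P = np.zeros((19, 3))
        for name, p in positions.items():
            P[JOINT_NAMES.index(name)] = p
        return JointSet(P)

    def test_collinear_leg_gives_zero_knee_flexion(self):
        js = self.place(r_hip=(0, 2, 0), r_knee=(0, 1, 0), r_ankle=(0, 0, 0))
        assert angles_from_joints(js).knee_deg == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_gives_90_degree_flexion(self):
        js = self.place(r_hip=(0, 1, 0), r_knee=(0, 0, 0), r_ankle=(1, 0, 0))
        assert angles_from_joints(js).knee_deg == pytest.approx(90.0, abs=1e-9)

    def test_missing_joint_yields_nan_not_exception(self):
        js = self.place(r_hip=(0, 1, 0), r_knee=(0, 0, 0), r_ankle=(1, 0, 0))
        js.visible[JOINT_NAMES.index("r_ankle")] = False
        out = angles_from_joints(js)
        assert np.isnan(out.knee_deg)
        assert np.isnan(out.ankle_deg)

    def test_simulator_joints_reproduce_ground_truth_angles(self):
        prof, cfg = GaitProfile(), SimConfig(duration_s=3.0, seed=9)
        traj = make_angle_trajectory(prof, cfg)
        for i in (3, 31, 59):
            s = traj.samples[i]
            left = traj.samples[(i + 45) % len(traj.samples)]
            _, js = render_depth(s, cfg, OccluderSpec(0.0), left)
            rec = angles_from_joints(js, s.ts)
            assert rec.hip_deg == pytest.approx(s.hip_deg, abs=1e-6)
            assert rec.knee_deg == pytest.approx(s.knee_deg, abs=1e-6)
            assert rec.ankle_deg == pytest.approx(s.ankle_deg, abs=1e-6)

    def test_knee_and_ankle_invariant_under_rigid_transforms(self, rng):
        from scipy.spatial.transform import Rotation
        prof, cfg = GaitProfile(), SimConfig(duration_s=3.0, seed=10)
        traj = make_angle_trajectory(prof, cfg)
        s = traj.samples[20]
        _, js = render_depth(s, cfg, OccluderSpec(0.0), traj.samples[4])
        base = angles_from_joints(js)
        for _ in range(20):
            R = Rotation.random(random_state=rng.integers(2 ** 31)).as_matrix()
            t = rng.normal(scale=2.0, size=3)
            moved = JointSet(js.positions @ R.T + t, js.visible.copy())
            out = angles_from_joints(moved)
            assert out.knee_deg == pytest.approx(base.knee_deg, abs=1e-6)
            assert out.ankle_deg == pytest.approx(base.ankle_deg, abs=1e-6)


def test_supervised_training_localizes_knee_within_three_pixels(bench_dataset):
    """Seeded coordinate-regression training on simulator frames: held-out
    mean knee localization error below 3 pixels at 64x64."""
    from limbfuse.nn import no_grad
    from limbfuse.vision_net import fit_pose_net, project_joints, soft_argmax
    ds = bench_dataset
    n_tr = 231
    model = PoseNet(seed=0)
    fit_pose_net(model, ds.frames[:n_tr], ds.joints[:n_tr], ds.visible[:n_tr],
                 ds.config.intrinsics, epochs=20, seed=0)
    with no_grad():
        logits, _ = model.forward_frames(ds.frames[n_tr:])
        b, j, h, w = logits.shape
        probs = logits.reshape(b, j, h * w).softmax(axis=-1) \
                      .reshape(b, j, h, w)
        coords = soft_argmax(probs).data
    H, W = model.spec.resolution
    su, sv = W / w, H / h
    img = np.stack([(coords[..., 0] + 0.5) * su - 0.5,
                    (coords[..., 1] + 0.5) * sv - 0.5], axis=-1)
    tgt = project_joints(ds.joints[n_tr:], ds.config.intrinsics)
    k = JOINT_NAMES.index("r_knee")
    err = np.linalg.norm(img[:, k] - tgt[:, k], axis=-1)
    assert err.mean() < 3.0


def test_round_trip_on_rendered_frames_recovers_knee_position():
    """Delta-heatmaps at the true projected pixels + rendered depth must
    back-project to within half a bar width of the true knee position."""
    from limbfuse.vision_net import project_joints
    prof, cfg = GaitProfile(), SimConfig(duration_s=3.0, seed=12)
    traj = make_angle_trajectory(prof, cfg)
    s = traj.samples[25]
    frame, js = render_depth(s, cfg, OccluderSpec(0.0), traj.samples[9])
    px = project_joints(js.positions, cfg.intrinsics)
    hm = np.zeros((19, 64, 64))
    for k in range(19):
        u, v = np.clip(np.round(px[k]).astype(int), 0, 63)
        hm[k, v, u] = 1.0
    rec = joints_from_heatmaps(VisionFeatures(hm, np.zeros(32)),
                               DepthFrame(frame.depth, 0.0, cfg.intrinsics))
    k = JOINT_NAMES.index("r_knee")
    assert rec.visible[k]
    err = np.linalg.norm(rec.positions[k] - js.positions[k])
    assert err <= cfg.limb_radius_m
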