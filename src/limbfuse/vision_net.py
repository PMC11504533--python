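"""Depth-image feature extraction and joint geometry.

A lightweight residual CNN maps a depth frame to (a) one softmax-normalized
heatmap per skeleton joint and (b) a pooled feature vector for fusion.
Joints are localized by soft-argmax (the expectation of pixel coordinates
under the heatmap), read out against the depth map, and back-projected
through the pinhole intrinsics to camera-frame meters.  Sagittal joint
angles are then pure geometry on the 3D joints; the simulator places joints
with the same conventions, so simulator ground truth and recovered angles
agree by construction.

Angle conventions (degrees): knee flexion = 180 - angle(knee->hip,
knee->ankle) with 0 = straight; hip flexion = angle between the trunk-down
axis (spine->pelvis) and hip->knee, signed positive when the thigh points
forward; ankle dorsiflexion = angle(ankle->knee, ankle->foot) - 90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor,
                 avg_pool2d, no_grad)
from .types import JOINT_NAMES, MISSING_ANGLE, DepthFrame, JointAngleSample, JointSet

__all__ = ["VisionSpec", "VisionFeatures", "PoseNet", "extract_features",
           "joints_from_heatmaps", "angles_from_joints", "project_joints",
           "soft_argmax", "fit_pose_net"]

N_JOINTS = 19


@dataclass
class VisionSpec:
    resolution: tuple = (64, 64)
    initial_pool: int = 4
    mid_channels: int = 16
    deep_channels: int = 32
    feature_dim: int = 32
    depth_scale_m: float = 2.0       # subtracted after mm -> m conversion
    visibility_threshold: float | None = None  # default 2 / (heatmap pixels)

    @property
    def heatmap_size(self) -> tuple:
        h, w = self.resolution
        return (h // self.initial_pool // 2, w // self.initial_pool // 2)


@dataclass
class VisionFeatures:
    """Per-joint normalized heatmaps plus a pooled feature vector."""

    heatmaps: np.ndarray     # [19, h, w], each channel sums to 1
    feature_vec: np.ndarray  # [feature_dim]

    def __post_init__(self):
        if self.heatmaps.shape[0] != N_JOINTS:
            raise ValueError("need one heatmap per joint")
        if not np.isfinite(self.feature_vec).all():
            raise ValueError("feature vector must be finite")


class _ResBlock(Module):
    """Identity residual block: x + BN(conv(relu(BN(conv(x))))).

    With zero convolution weights the branch contributes exactly zero, so
    the block passes its input through unchanged.
    """

    def __init__(self, rng, ch: int):
        super().__init__()
        self.conv1 = Conv2d(rng, ch, ch, 3, pad=1)
        self.bn1 = BatchNorm2d(ch)
        self.conv2 = Conv2d(rng, ch, ch, 3, pad=1)
        self.bn2 = BatchNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return x + y


class PoseNet(Module):
    """avgpool -> small-kernel conv block -> residual block -> avgpool ->
    residual block -> avgpool -> (heatmap head, feature head)."""

    def __init__(self, spec: VisionSpec = VisionSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x715]))
        mc, dc = spec.mid_channels, spec.deep_channels
        self.conv1 = Conv2d(rng, 1, mc // 2, 3, pad=1)
        self.bn1 = BatchNorm2d(mc // 2)
        self.conv2 = Conv2d(rng, mc // 2, mc, 3, pad=1)
        self.bn2 = BatchNorm2d(mc)
        self.res1 = _ResBlock(rng, mc)
        self.trans = Conv2d(rng, mc, dc, 1)
        self.res2 = _ResBlock(rng, dc)
        self.head_hm = Conv2d(rng, dc, N_JOINTS, 1)
        self.head_feat = Linear(rng, dc, spec.feature_dim)

    def forward(self, x: Tensor) -> tuple:
        """x: [B, 1, H, W] normalized depth -> (heatmap logits [B,19,h,w],
        feature vector [B, feature_dim])."""
        s = self.spec
        x = avg_pool2d(x, s.initial_pool)
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        x = self.res1(x)
        x = avg_pool2d(x, 2)
        x = self.trans(x)
        x = self.res2(x)
        logits = self.head_hm(x)
        pooled = avg_pool2d(x, 2)
        feat = self.head_feat(pooled.mean(axis=(2, 3)))
        return logits, feat

    def normalize_depth(self, depth_mm: np.ndarray) -> np.ndarray:
        return depth_mm.astype(np.float32) / 1000.0 - self.spec.depth_scale_m

    def forward_frames(self, frames_mm: np.ndarray) -> tuple:
        """Convenience: [B, H, W] depth in millimeters -> forward()."""
        x = Tensor(self.normalize_depth(frames_mm)[:, None, :, :])
        if x.shape[2:] != tuple(self.spec.resolution):
            raise ValueError(f"frame resolution {x.shape[2:]} does not match "
                             f"configured {tuple(self.spec.resolution)}")
        return self(x)


def soft_argmax(probs: Tensor) -> Tensor:
    """Expected (u, v) pixel coordinates of normalized heatmaps
    [B, J, h, w] -> [B, J, 2] (heatmap pixel units)."""
    b, j, h, w = probs.shape
    uu, vv = np.meshgrid(np.arange(w, dtype=np.float32),
                         np.arange(h, dtype=np.float32))
    grid = Tensor(np.stack([uu.ravel(), vv.ravel()], axis=1))  # [hw, 2]
    return probs.reshape(b, j, h * w) @ grid


def extract_features(frame: DepthFrame, model: PoseNet) -> VisionFeatures:
    """Run the network on one frame (eval mode, deterministic)."""
    model.eval()
    with no_grad():
        logits, feat = model.forward_frames(frame.depth[None, :, :])
        b, j, h, w = logits.shape
        probs = logits.reshape(b, j, h * w).softmax(axis=-1).reshape(b, j, h, w)
    return VisionFeatures(probs.data[0].astype(np.float64),
                          feat.data[0].astype(np.float64))


def joints_from_heatmaps(vf: VisionFeatures, frame: DepthFrame,
                         threshold: float | None = None) -> JointSet:
    """Soft-argmax localization + depth readout + pinhole back-projection.

    A joint is invisible when its heatmap peak falls below ``threshold``
    (default 2 / heatmap-pixel-count, i.e. twice the uniform level) or when
    no valid depth exists in the 3x3 patch at its location.
    """
    fx, fy, cx, cy = frame.intrinsics
    hm = np.asarray(vf.heatmaps, dtype=np.float64)
    j, hh, ww = hm.shape
    H, W = frame.depth.shape
    if threshold is None:
        threshold = 2.0 / (hh * ww)
    su, sv = W / ww, H / hh

    flat = hm.reshape(j, -1)
    uu, vv = np.meshgrid(np.arange(ww), np.arange(hh))
    eu = flat @ uu.ravel()
    ev = flat @ vv.ravel()
    # heatmap coords -> image pixel coords (cell centers align)
    u_img = (eu + 0.5) * su - 0.5
    v_img = (ev + 0.5) * sv - 0.5

    pos = np.zeros((j, 3))
    vis = np.ones(j, dtype=bool)
    for k in range(j):
        if flat[k].max() < threshold:
            vis[k] = False
            continue
        ui, vi = int(round(u_img[k])), int(round(v_img[k]))
        patch = frame.depth[max(0, vi - 1):vi + 2, max(0, ui - 1):ui + 2]
        valid = patch[patch > 0]
        if valid.size == 0:
            vis[k] = False
            continue
        d = float(np.median(valid)) / 1000.0  # mm -> m
        pos[k] = [(u_img[k] - cx) * d / fx, (v_img[k] - cy) * d / fy, d]
    return JointSet(pos, vis)


def project_joints(positions_cam: np.ndarray, intrinsics) -> np.ndarray:
    """Camera-frame meters [.., 3] -> image pixels [.., 2]."""
    fx, fy, cx, cy = intrinsics
    p = np.asarray(positions_cam, dtype=np.float64)
    z = p[..., 2]
    return np.stack([fx * p[..., 0] / z + cx, fy * p[..., 1] / z + cy], axis=-1)


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return MISSING_ANGLE
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angles_from_joints(js: JointSet, ts: float = 0.0,
                       side: str = "r") -> JointAngleSample:
    """Sagittal hip/knee/ankle angles from 3D joints (degrees).

    Occluded prerequisites yield NaN for the affected angle rather than an
    exception.  Knee and ankle use only relative vectors and are invariant
    under rigid transforms; the hip sign additionally uses the body's own
    lateral (left-to-right-hip) axis, keeping it rigid-invariant too.
    """
    def p(name):
        return js[name], js.visible[js.index(name)]

    hip, v_hip = p(f"{side}_hip")
    knee, v_knee = p(f"{side}_knee")
    ankle, v_ankle = p(f"{side}_ankle")
    foot, v_foot = p(f"{side}_foot")
    pelvis, v_pelvis = p("pelvis")
    spine, v_spine = p("spine")
    other_hip, v_ohip = p("l_hip" if side == "r" else "r_hip")

    knee_deg = MISSING_ANGLE
    if v_hip and v_knee and v_ankle:
        knee_deg = 180.0 - _angle_between(hip - knee, ankle - knee)

    hip_deg = MISSING_ANGLE
    if v_hip and v_knee and v_pelvis and v_spine and v_ohip:
        trunk_down = pelvis - spine
        thigh = knee - hip
        lateral = hip - other_hip if side == "r" else other_hip - hip
        mag = _angle_between(trunk_down, thigh)
        sgn = np.sign(np.dot(np.cross(trunk_down, thigh), lateral))
        hip_deg = mag * (sgn if sgn != 0 else 1.0)

    ankle_deg = MISSING_ANGLE
    if v_knee and v_ankle and v_foot:
        ankle_deg = _angle_between(knee - ankle, foot - ankle) - 90.0

    return JointAngleSample(hip_deg, knee_deg, ankle_deg, ts)


def fit_pose_net(model: PoseNet, frames_mm: np.ndarray, joints_cam: np.ndarray,
                 visible: np.ndarray, intrinsics, epochs: int = 20,
                 batch_size: int = 16, lr: float = 1e-3, seed: int = 0) -> dict:
    """Supervised localization training: soft-argmax coordinate regression.

    Targets are the ground-truth joint projections in image pixels; the loss
    is the mean squared coordinate error in heatmap-pixel units over visible
    joints.
    """
    n = frames_mm.shape[0]
    hh, ww = model.spec.heatmap_size
    H, W = model.spec.resolution
    su, sv = W / ww, H / hh
    tgt_px = project_joints(joints_cam, intrinsics)
    # image pixels -> heatmap coords
    tgt = np.stack([(tgt_px[..., 0] + 0.5) / su - 0.5,
                    (tgt_px[..., 1] + 0.5) / sv - 0.5], axis=-1).astype(np.float32)
    mask = np.asarray(visible, dtype=np.float32)[..., None]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    opt = Adam(model.parameters(), lr=lr)
    hist = {"train_loss": []}
    model.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, batch_size):
            idx = order[i0:i0 + batch_size]
            logits, _ = model.forward_frames(frames_mm[idx])
            b, j, h, w = logits.shape
            probs = logits.reshape(b, j, h * w).softmax(axis=-1) \
                          .reshape(b, j, h, w)
            coords = soft_argmax(probs)
            m = Tensor(mask[idx])
            err = (coords - Tensor(tgt[idx])) * m
            loss = (err ** 2).sum() * (1.0 / max(float(mask[idx].sum() * 2), 1.0))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist["train_loss"].append(float(np.mean(losses)))
    model.eval()
    return hist
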