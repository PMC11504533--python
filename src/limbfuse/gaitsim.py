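"""Synthetic treadmill-gait capture: joint trajectories, sEMG, depth frames.

Emulates a synchronized lower-limb capture session — periodic sagittal
hip/knee/ankle trajectories, nine muscle activation envelopes phase-locked to
the gait cycle, activation-modulated band-limited sEMG, and rendered
stick-figure depth frames with optional ground occluders — so the whole
estimation pipeline is testable without recorded data.

The generative model: each joint angle is a small Fourier series in gait
phase; each muscle's activation is a sum of wrapped-Gaussian bumps in phase
(activation timing leads the corresponding joint motion by 0.05 of a cycle,
mimicking electromechanical delay); sEMG per channel is the activation
envelope multiplying a band-limited unit-variance Gaussian carrier plus a
noise-floor carrier, clipped to the +-11 mV acquisition range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .types import (MUSCLES, JOINT_NAMES, EmgRecording, JointAngleSample,
                    DepthFrame, JointSet)

__all__ = [
    "GaitProfile", "OccluderSpec", "SimConfig", "AngleTrajectory",
    "SyncedDataset", "make_angle_trajectory", "make_activation",
    "synthesize_emg", "render_depth", "make_dataset", "pose_world",
    "SkeletonDims",
]

# Default Fourier gait profile (phase 0 at the cycle origin). Coefficients
# were fit once to canonical sagittal walking curves and scaled so the knee
# spans exactly 0-65 deg over the cycle.
_DEFAULT_FOURIER = {
    "hip": (12.598, [(1, 20.202, 0.203), (2, 2.756, 3.0867)]),
    "knee": (23.306, [(1, 17.933, 1.7208), (2, 20.777, -2.7518),
                      (3, 3.233, -0.5764)]),
    "ankle": (-2.034, [(1, 4.792, -1.9213), (2, 9.595, 1.3763),
                       (3, 4.263, -1.1285)]),
}

# (center_phase, width_phase, amplitude) wrapped-Gaussian activation bumps.
# Centers already include the 0.05-cycle electromechanical lead.
_DEFAULT_BUMPS = {
    "RF": [(0.97, 0.05, 0.6), (0.55, 0.06, 0.8)],
    "VM": [(0.98, 0.06, 0.9)],
    "VL": [(0.98, 0.06, 0.85)],
    "TA": [(0.90, 0.08, 0.9), (0.57, 0.06, 0.5)],
    "SOL": [(0.35, 0.08, 0.9)],
    "SEM": [(0.83, 0.06, 0.8)],
    "BF": [(0.85, 0.06, 0.75)],
    "MG": [(0.37, 0.07, 0.85)],
    "LG": [(0.38, 0.07, 0.8)],
}


@dataclass
class GaitProfile:
    """Parameters of the periodic gait generator."""

    cadence_hz: float = 0.9
    joint_fourier: dict = field(default_factory=lambda: dict(_DEFAULT_FOURIER))
    muscle_bumps: dict = field(default_factory=lambda: dict(_DEFAULT_BUMPS))
    emg_noise_floor_mv: float = 0.003
    emg_band_hz: tuple = (20.0, 450.0)
    emg_gain_mv: float = 1.5

    def __post_init__(self):
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        lo, hi = self.emg_band_hz
        if not 0 < lo < hi:
            raise ValueError("emg_band_hz must satisfy 0 < low < high")
        for joint, (offset, harmonics) in self.joint_fourier.items():
            for k, amp, _ in harmonics:
                if amp < 0:
                    raise ValueError(f"negative amplitude for {joint} harmonic {k}")
        for muscle, bumps in self.muscle_bumps.items():
            for center, width, amp in bumps:
                if not 0 <= center < 1:
                    raise ValueError(f"{muscle}: bump center must be in [0,1)")
                if width <= 0 or amp < 0:
                    raise ValueError(f"{muscle}: invalid bump shape")

    def angle(self, joint: str, phase) -> np.ndarray:
        """Evaluate a joint's Fourier series at gait phase(s) in [0, 1)."""
        offset, harmonics = self.joint_fourier[joint]
        phase = np.asarray(phase, dtype=np.float64)
        y = np.full_like(phase, float(offset))
        for k, amp, ph in harmonics:
            y = y + amp * np.cos(2 * np.pi * k * phase + ph)
        return y


@dataclass
class OccluderSpec:
    """Opaque ground obstacle between camera and subject."""

    height_m: float = 0.0
    enabled: bool = True
    distance_m: float = 2.0  # depth of the occluding screen from the camera

    def __post_init__(self):
        if self.height_m < 0:
            raise ValueError("height_m must be nonnegative")


@dataclass
class SimConfig:
    """Capture-session configuration (sampling rates, camera, seed)."""

    duration_s: float = 10.0
    emg_fs_hz: float = 1111.0
    frame_fps: float = 30.0
    depth_resolution: tuple = (64, 64)
    seed: int = 0
    stature_m: float = 1.74
    camera_distance_m: float = 2.5
    camera_height_m: float = 1.0
    focal_px: float | None = None  # default scales with resolution
    contact_threshold_m: float = 0.02
    limb_radius_m: float = 0.05

    n_muscles: int = 9   # fixed by the muscle montage
    n_joints: int = 19   # fixed by the skeleton model

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_fps >= self.emg_fs_hz:
            raise ValueError("frame_fps must be below emg_fs_hz")
        if self.n_muscles != 9 or self.n_joints != 19:
            raise ValueError("the montage is fixed at 9 muscles and 19 joints")

    @property
    def intrinsics(self) -> tuple:
        h, w = self.depth_resolution
        f = self.focal_px if self.focal_px is not None else 70.0 * h / 64.0
        return (f, f, (w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class SkeletonDims:
    """Segment lengths (meters), scaled from stature with standard
    anthropometric fractions."""

    thigh: float
    shank: float
    foot_len: float
    ankle_h: float
    hip_half: float
    pelvis_spine: float
    spine_chest: float
    chest_neck: float
    neck_head: float
    shoulder_half: float
    upper_arm: float
    forearm: float

    @classmethod
    def from_stature(cls, h: float) -> "SkeletonDims":
        return cls(thigh=0.245 * h, shank=0.246 * h, foot_len=0.152 * h,
                   ankle_h=0.039 * h, hip_half=0.0955 * h / 2,
                   pelvis_spine=0.12 * h, spine_chest=0.12 * h,
                   chest_neck=0.06 * h, neck_head=0.09 * h,
                   shoulder_half=0.129 * h, upper_arm=0.186 * h,
                   forearm=0.146 * h)


class AngleTrajectory:
    """Continuous ground-truth trajectory plus its frame-rate samples."""

    def __init__(self, profile: GaitProfile, config: SimConfig):
        if config.duration_s < 1.0 / profile.cadence_hz:
            raise ValueError("duration must cover at least one stride")
        self.profile = profile
        self.config = config
        self.frame_ts = np.arange(
            int(np.floor(config.duration_s * config.frame_fps))) / config.frame_fps
        h, k, a = self.at(self.frame_ts)
        self.samples = [JointAngleSample(h[i], k[i], a[i], float(t))
                        for i, t in enumerate(self.frame_ts)]

    def at(self, t):
        """Evaluate (hip, knee, ankle) in degrees at arbitrary times."""
        phase = np.mod(np.asarray(t, dtype=np.float64) * self.profile.cadence_hz, 1.0)
        return (self.profile.angle("hip", phase),
                self.profile.angle("knee", phase),
                self.profile.angle("ankle", phase))


def make_angle_trajectory(profile: GaitProfile, config: SimConfig) -> AngleTrajectory:
    """Periodic hip/knee/ankle ground truth sampled at the frame rate."""
    return AngleTrajectory(profile, config)


def make_activation(profile: GaitProfile, t, muscle: str) -> np.ndarray:
    """Activation envelope in [0, 1]: wrapped-Gaussian bumps in gait phase."""
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}; expected one of {MUSCLES}")
    phase = np.mod(np.asarray(t, dtype=np.float64) * profile.cadence_hz, 1.0)
    act = np.zeros_like(phase)
    for center, width, amp in profile.muscle_bumps.get(muscle, []):
        d = np.mod(phase - center + 0.5, 1.0) - 0.5  # circular distance
        act = act + amp * np.exp(-0.5 * (d / width) ** 2)
    return np.clip(act, 0.0, 1.0)


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs: float,
                         band: tuple) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to `band`."""
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def synthesize_emg(profile: GaitProfile, config: SimConfig) -> EmgRecording:
    """Nine-channel sEMG: activation-modulated band-limited noise, +-11 mV."""
    lo, hi = profile.emg_band_hz
    if config.emg_fs_hz <= 2 * hi:
        raise ValueError("emg_fs_hz must exceed twice the EMG band's upper edge")
    n = int(round(config.duration_s * config.emg_fs_hz))
    t = np.arange(n) / config.emg_fs_hz
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE36]))
    out = np.empty((n, len(MUSCLES)))
    for ci, muscle in enumerate(MUSCLES):
        act = make_activation(profile, t, muscle)
        signal_carrier = _bandlimited_carrier(rng, n, config.emg_fs_hz,
                                              profile.emg_band_hz)
        floor_carrier = _bandlimited_carrier(rng, n, config.emg_fs_hz,
                                             profile.emg_band_hz)
        x = act * profile.emg_gain_mv * signal_carrier \
            + profile.emg_noise_floor_mv * floor_carrier
        out[:, ci] = np.clip(x, -11.0, 11.0)
    return EmgRecording(out, config.emg_fs_hz, MUSCLES)


# -- kinematics and rendering -------------------------------------------------

def _rot2d(vx, vy, alpha):
    c, s = np.cos(alpha), np.sin(alpha)
    return vx * c - vy * s, vx * s + vy * c


def pose_world(right: JointAngleSample, left: JointAngleSample,
               dims: SkeletonDims, pelvis_y: float) -> np.ndarray:
    """Place the 19-joint stick figure in world frame (x forward, y up,
    z lateral toward the camera-side/right)."""
    P = np.zeros((19, 3))
    idx = {n: i for i, n in enumerate(JOINT_NAMES)}
    pelvis = np.array([0.0, pelvis_y, 0.0])
    P[idx["pelvis"]] = pelvis
    P[idx["spine"]] = pelvis + [0, dims.pelvis_spine, 0]
    P[idx["chest"]] = P[idx["spine"]] + [0, dims.spine_chest, 0]
    P[idx["neck"]] = P[idx["chest"]] + [0, dims.chest_neck, 0]
    P[idx["head"]] = P[idx["neck"]] + [0, dims.neck_head, 0]

    for side, ang, zsign in (("r", right, +1.0), ("l", left, -1.0)):
        th = np.deg2rad(ang.hip_deg)
        tk = np.deg2rad(ang.knee_deg)
        ta = np.deg2rad(ang.ankle_deg)
        hip = pelvis + [0, 0, zsign * dims.hip_half]
        knee = hip + dims.thigh * np.array([np.sin(th), -np.cos(th), 0.0])
        phi = th - tk  # shank angle from vertical (flexion bends backward)
        ankle = knee + dims.shank * np.array([np.sin(phi), -np.cos(phi), 0.0])
        ux, uy = -np.sin(phi), np.cos(phi)  # ankle -> knee unit
        fx, fy = _rot2d(ux, uy, -(np.pi / 2 + ta))
        foot = ankle + dims.foot_len * np.array([fx, fy, 0.0])
        P[idx[f"{side}_hip"]] = hip
        P[idx[f"{side}_knee"]] = knee
        P[idx[f"{side}_ankle"]] = ankle
        P[idx[f"{side}_foot"]] = foot

        sh = P[idx["chest"]] + [0, 0, zsign * dims.shoulder_half]
        P[idx[f"{side}_shoulder"]] = sh
        P[idx[f"{side}_elbow"]] = sh + [0, -dims.upper_arm, 0]
        P[idx[f"{side}_wrist"]] = sh + [0, -dims.upper_arm - dims.forearm, 0]
    return P


_SEGMENTS = [
    ("pelvis", "spine"), ("spine", "chest"), ("chest", "neck"),
    ("neck", "head"),
    ("pelvis", "r_hip"), ("r_hip", "r_knee"), ("r_knee", "r_ankle"),
    ("r_ankle", "r_foot"),
    ("pelvis", "l_hip"), ("l_hip", "l_knee"), ("l_knee", "l_ankle"),
    ("l_ankle", "l_foot"),
    ("chest", "r_shoulder"), ("r_shoulder", "r_elbow"), ("r_elbow", "r_wrist"),
    ("chest", "l_shoulder"), ("l_shoulder", "l_elbow"), ("l_elbow", "l_wrist"),
]
_SEG_IDX = [(JOINT_NAMES.index(a), JOINT_NAMES.index(b)) for a, b in _SEGMENTS]


def _world_to_cam(pts: np.ndarray, config: SimConfig) -> np.ndarray:
    """World (x fwd, y up, z lateral) -> camera (X right, Y down, Z depth)."""
    cam = np.empty_like(pts)
    cam[..., 0] = pts[..., 0]
    cam[..., 1] = config.camera_height_m - pts[..., 1]
    cam[..., 2] = config.camera_distance_m - pts[..., 2]
    return cam


def _standing_pelvis_y(dims: SkeletonDims) -> float:
    return dims.thigh + dims.shank + dims.ankle_h


def render_depth(angles: JointAngleSample, config: SimConfig,
                 occluder: OccluderSpec | None = None,
                 angles_left: JointAngleSample | None = None,
                 pelvis_y: float | None = None) -> tuple[DepthFrame, JointSet]:
    """Render the stick figure to an HxW depth map (millimeters).

    Limb segments are drawn as constant-width bars (nearer surface wins);
    pixels whose line of sight passes below the occluder's top edge show the
    occluder instead, and joints whose world height is below the occluder are
    flagged invisible.  Background pixels carry depth 0 (no return).
    """
    dims = SkeletonDims.from_stature(config.stature_m)
    if pelvis_y is None:
        pelvis_y = _standing_pelvis_y(dims)
    if angles_left is None:
        angles_left = angles
    world = pose_world(angles, angles_left, dims, pelvis_y)
    cam = _world_to_cam(world, config)
    fx, fy, cx, cy = config.intrinsics
    h, w = config.depth_resolution

    zbuf = np.full((h, w), np.inf)
    for ia, ib in _SEG_IDX:
        a, b = cam[ia], cam[ib]
        ua, va = fx * a[0] / a[2] + cx, fy * a[1] / a[2] + cy
        ub, vb = fx * b[0] / b[2] + cx, fy * b[1] / b[2] + cy
        n = int(np.hypot(ub - ua, vb - va) * 2) + 2
        s = np.linspace(0.0, 1.0, n)[:, None]
        p = a[None, :] * (1 - s) + b[None, :] * s
        z = p[:, 2]
        uu = fx * p[:, 0] / z + cx
        vv = fy * p[:, 1] / z + cy
        r_px = fx * config.limb_radius_m / z
        rmax = int(np.ceil(r_px.max()))
        for dy in range(-rmax, rmax + 1):
            for dx in range(-rmax, rmax + 1):
                mask = dx * dx + dy * dy <= r_px * r_px
                if not mask.any():
                    continue
                ui = np.round(uu[mask]).astype(int) + dx
                vi = np.round(vv[mask]).astype(int) + dy
                ok = (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
                if ok.any():
                    np.minimum.at(zbuf, (vi[ok], ui[ok]), z[mask][ok])

    depth = np.where(np.isfinite(zbuf), zbuf * 1000.0, 0.0)

    visible = np.ones(19, dtype=bool)
    uj = fx * cam[:, 0] / cam[:, 2] + cx
    vj = fy * cam[:, 1] / cam[:, 2] + cy
    visible &= (uj >= 0) & (uj < w) & (vj >= 0) & (vj < h)

    if occluder is not None and occluder.enabled and occluder.height_m > 0:
        zo = occluder.distance_m
        # rows whose ray height at the occluder plane falls below its top
        v_grid = np.arange(h)[:, None]
        ray_y = config.camera_height_m - (v_grid - cy) / fy * zo
        rows = (ray_y < occluder.height_m).repeat(w, axis=1)
        depth = np.where(rows, zo * 1000.0, depth)
        visible &= world[:, 1] >= occluder.height_m

    frame = DepthFrame(depth, angles.ts, config.intrinsics)
    return frame, JointSet(cam, visible)


def ground_offset(profile: GaitProfile, config: SimConfig) -> float:
    """Pelvis height that puts the lowest foot-joint excursion on the floor."""
    dims = SkeletonDims.from_stature(config.stature_m)
    t = np.linspace(0.0, 1.0, 2048, endpoint=False) / profile.cadence_hz
    footy = _right_foot_height(profile, t, 0.0, dims)
    return -float(footy.min())  # pelvis_y such that min foot height == 0


def _right_foot_height(profile: GaitProfile, t, pelvis_y: float,
                       dims: SkeletonDims) -> np.ndarray:
    phase = np.mod(np.asarray(t) * profile.cadence_hz, 1.0)
    th = np.deg2rad(profile.angle("hip", phase))
    tk = np.deg2rad(profile.angle("knee", phase))
    ta = np.deg2rad(profile.angle("ankle", phase))
    phi = th - tk
    ankley = pelvis_y - dims.thigh * np.cos(th) - dims.shank * np.cos(phi)
    ux, uy = -np.sin(phi), np.cos(phi)
    _, fyr = _rot2d(ux, uy, -(np.pi / 2 + ta))
    return ankley + dims.foot_len * fyr


@dataclass
class SyncedDataset:
    """Per-frame records of (multi-scale sEMG windows, depth frame,
    ground-truth angles) plus stance/swing labels and stride onsets."""

    emg: EmgRecording                       # raw (unfiltered) recording
    windows_full: np.ndarray                # [N, L, 9]
    windows_mid: np.ndarray                 # [N, 2L/3, 9]
    windows_short: np.ndarray               # [N, L/3, 9]
    frames: np.ndarray                      # [N, H, W] depth, millimeters
    joints: np.ndarray                      # [N, 19, 3] camera-frame meters
    visible: np.ndarray                     # [N, 19] bool
    angles: np.ndarray                      # [N, 3] hip/knee/ankle degrees
    trigger_ts: np.ndarray                  # [N] seconds
    stance: np.ndarray                      # [N] bool, True during stance
    cycle_onsets: np.ndarray                # record indices of stance onsets
    config: SimConfig = None
    profile: GaitProfile = None

    def __len__(self):
        return self.windows_full.shape[0]

    @property
    def intrinsics(self):
        return self.config.intrinsics

    def save_npz(self, path):
        meta = {"config": asdict(self.config) if self.config else None}
        np.savez(path,
                 emg=self.emg.samples.astype(np.float32),
                 emg_fs=np.float64(self.emg.fs_hz),
                 windows_full=self.windows_full.astype(np.float32),
                 windows_mid=self.windows_mid.astype(np.float32),
                 windows_short=self.windows_short.astype(np.float32),
                 frames=self.frames.astype(np.float32),
                 joints=self.joints, visible=self.visible,
                 angles=self.angles, trigger_ts=self.trigger_ts,
                 stance=self.stance, cycle_onsets=self.cycle_onsets,
                 meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                    dtype=np.uint8))

    @classmethod
    def load_npz(cls, path) -> "SyncedDataset":
        z = np.load(path)
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["config"].items()}) \
            if meta.get("config") else None
        return cls(emg=EmgRecording(z["emg"].astype(np.float64), float(z["emg_fs"])),
                   windows_full=z["windows_full"], windows_mid=z["windows_mid"],
                   windows_short=z["windows_short"], frames=z["frames"],
                   joints=z["joints"], visible=z["visible"], angles=z["angles"],
                   trigger_ts=z["trigger_ts"], stance=z["stance"],
                   cycle_onsets=z["cycle_onsets"], config=cfg)


def make_dataset(profile: GaitProfile, config: SimConfig,
                 occluder: OccluderSpec | None = None,
                 filter_spec="default", base_len: int = 300) -> SyncedDataset:
    """Generate a fully synchronized dataset: one record per depth frame
    whose timestamp admits a full base sEMG window."""
    from .preprocess import FilterSpec, bandpass
    from .windowing import window_at_triggers

    traj = make_angle_trajectory(profile, config)
    emg = synthesize_emg(profile, config)
    if filter_spec == "default":
        filter_spec = FilterSpec(20.0, 450.0, 4)
    filtered = bandpass(emg, filter_spec) if filter_spec is not None else emg

    sets, _skipped = window_at_triggers(filtered, traj.frame_ts, base_len)
    n = len(sets)
    dims = SkeletonDims.from_stature(config.stature_m)
    pelvis_y = ground_offset(profile, config)
    half = 0.5 / profile.cadence_hz

    h, w = config.depth_resolution
    frames = np.empty((n, h, w), dtype=np.float32)
    joints = np.empty((n, 19, 3))
    vis = np.empty((n, 19), dtype=bool)
    angles = np.empty((n, 3))
    trig = np.empty(n)
    for i, ws in enumerate(sets):
        t = ws.trigger_ts
        hh, kk, aa = traj.at(t)
        right = JointAngleSample(float(hh), float(kk), float(aa), t)
        hl, kl, al = traj.at(t - half)
        left = JointAngleSample(float(hl), float(kl), float(al), t - half)
        frame, js = render_depth(right, config, occluder, left, pelvis_y)
        frames[i] = frame.depth
        joints[i] = js.positions
        vis[i] = js.visible
        angles[i] = [right.hip_deg, right.knee_deg, right.ankle_deg]
        trig[i] = t

    foot_y = _right_foot_height(profile, trig, pelvis_y, dims)
    stance = foot_y < config.contact_threshold_m
    onsets = np.where(stance[1:] & ~stance[:-1])[0] + 1

    return SyncedDataset(
        emg=emg,
        windows_full=np.stack([s.windows[0] for s in sets]).astype(np.float32),
        windows_mid=np.stack([s.windows[1] for s in sets]).astype(np.float32),
        windows_short=np.stack([s.windows[2] for s in sets]).astype(np.float32),
        frames=frames, joints=joints, visible=vis, angles=angles,
        trigger_ts=trig, stance=stance, cycle_onsets=onsets,
        config=config, profile=profile)
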