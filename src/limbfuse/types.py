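"""Shared domain containers for sEMG recordings, depth frames and joint data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Monitored lower-limb muscles, in channel order: rectus femoris, vastus
#: medialis, vastus lateralis, tibialis anterior, soleus, semitendinosus,
#: biceps femoris, medial and lateral gastrocnemius.
MUSCLES = ("RF", "VM", "VL", "TA", "SOL", "SEM", "BF", "MG", "LG")

#: Fixed 19-joint skeleton ordering used throughout the package.
JOINT_NAMES = (
    "pelvis", "spine", "chest", "neck", "head",
    "r_hip", "r_knee", "r_ankle", "r_foot",
    "l_hip", "l_knee", "l_ankle", "l_foot",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
)

#: Marker for an angle that could not be computed (occluded joints).
MISSING_ANGLE = np.nan


@dataclass
class EmgRecording:
    """Multi-channel sEMG samples in millivolts.

    samples: [n_samples, n_channels]; channels: ordered muscle labels.
    """

    samples: np.ndarray
    fs_hz: float
    channels: tuple = MUSCLES

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2D [n_samples, n_channels]")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[1]} columns but {len(self.channels)} labels")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def sample_times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class JointAngleSample:
    """Sagittal hip/knee/ankle angles in degrees at one timestamp.

    Conventions: knee flexion 0 deg = straight leg; hip flexion positive when
    the thigh points forward of the trunk-down axis; ankle dorsiflexion
    positive. Missing (occluded) angles are NaN.
    """

    hip_deg: float
    knee_deg: float
    ankle_deg: float
    ts: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hip_deg, self.knee_deg, self.ankle_deg])


@dataclass
class DepthFrame:
    """A depth map in millimeters with pinhole intrinsics (fx, fy, cx, cy)."""

    depth: np.ndarray
    ts: float
    intrinsics: tuple

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 2:
            raise ValueError("depth must be 2D")
        if not np.isfinite(self.depth).all() or (self.depth < 0).any():
            raise ValueError("depth must be finite and nonnegative")


@dataclass
class JointSet:
    """19 joint positions in camera-frame meters plus visibility flags."""

    positions: np.ndarray
    visible: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (19, 3):
            raise ValueError("positions must be 19x3")
        if self.visible is None:
            self.visible = np.ones(19, dtype=bool)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.visible.shape != (19,):
            raise ValueError("visible must have 19 flags")

    def index(self, name: str) -> int:
        return JOINT_NAMES.index(name)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]
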