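"""Evaluation designs: RMSE tables, per-phase errors, per-cycle maxima,
modality ablation and the ground-occlusion sweep.

Errors are absolute differences in degrees between predicted and
ground-truth sagittal angles.  Per-phase statistics are the mean and
standard deviation of |error| within stance and swing; the per-cycle
statistic is the maximum |error| inside each stride, summarized as
mean +- std across strides.  Missing predictions (NaN) are excluded
pairwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .gaitsim import GaitProfile, OccluderSpec, SimConfig, SyncedDataset, make_dataset
from .regressor import JointAngleModel, TrainConfig, predict_dataset, train_full

__all__ = ["EvalReport", "rmse_per_joint", "phase_errors", "cycle_max_error",
           "evaluate", "ablation", "occlusion_sweep"]

JOINTS = ("hip", "knee", "ankle")
PHASES = ("stance", "swing")


@dataclass
class EvalReport:
    """Per-joint error summary of one model on one dataset."""

    rmse_deg: dict = field(default_factory=dict)
    phase_deg: dict = field(default_factory=dict)   # joint -> phase -> (mean, std)
    cycle_max_deg: dict = field(default_factory=dict)  # joint -> (mean, std)
    occlusion_curve: list = field(default_factory=list)  # (height, mean, std)

    def to_json(self) -> str:
        return json.dumps({
            "rmse_deg": self.rmse_deg,
            "phase_deg": self.phase_deg,
            "cycle_max_deg": self.cycle_max_deg,
            "occlusion_curve": self.occlusion_curve,
        }, indent=2, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, s: str) -> "EvalReport":
        d = json.loads(s)
        rep = cls(rmse_deg=d["rmse_deg"], phase_deg=d["phase_deg"],
                  cycle_max_deg={k: tuple(v)
                                 for k, v in d["cycle_max_deg"].items()},
                  occlusion_curve=[tuple(x) for x in d["occlusion_curve"]])
        rep.phase_deg = {j: {p: tuple(v) for p, v in ph.items()}
                         for j, ph in rep.phase_deg.items()}
        return rep


def _paired(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    return pred, truth, np.isfinite(pred) & np.isfinite(truth)


def rmse_per_joint(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Root mean squared error per joint, degrees; arrays [N, 3]."""
    pred, truth, ok = _paired(pred, truth)
    out = {}
    for j, name in enumerate(JOINTS):
        m = ok[:, j]
        if not m.any():
            raise ValueError(f"no overlapping samples for {name}")
        out[name] = float(np.sqrt(np.mean((pred[m, j] - truth[m, j]) ** 2)))
    return out


def phase_errors(pred: np.ndarray, truth: np.ndarray,
                 stance: np.ndarray) -> dict:
    """Mean +- std of |error| within stance and swing, per joint.

    A phase with no samples yields (nan, nan) for that phase.
    """
    pred, truth, ok = _paired(pred, truth)
    stance = np.asarray(stance, dtype=bool)
    out = {}
    for j, name in enumerate(JOINTS):
        out[name] = {}
        for phase, sel in (("stance", stance), ("swing", ~stance)):
            m = sel & ok[:, j]
            if not m.any():
                out[name][phase] = (float("nan"), float("nan"))
                continue
            err = np.abs(pred[m, j] - truth[m, j])
            out[name][phase] = (float(err.mean()), float(err.std()))
    return out


def cycle_max_error(pred: np.ndarray, truth: np.ndarray,
                    cycle_onsets: np.ndarray) -> dict:
    """Per-stride maximum |error|, summarized mean +- std across strides.

    ``cycle_onsets`` are record indices of stride starts; strides are the
    intervals between consecutive onsets (>= 1 complete stride required).
    """
    pred, truth, ok = _paired(pred, truth)
    onsets = np.asarray(cycle_onsets, dtype=int)
    if len(onsets) < 2:
        raise ValueError("need at least one complete stride cycle")
    out = {}
    for j, name in enumerate(JOINTS):
        maxima = []
        for a, b in zip(onsets[:-1], onsets[1:]):
            m = ok[a:b, j]
            if m.any():
                maxima.append(np.abs(pred[a:b, j][m] - truth[a:b, j][m]).max())
        maxima = np.asarray(maxima)
        out[name] = (float(maxima.mean()), float(maxima.std()))
    return out


def evaluate(model: JointAngleModel, dataset: SyncedDataset) -> EvalReport:
    """All metrics of one model on one dataset."""
    pred = predict_dataset(model, dataset)
    return EvalReport(
        rmse_deg=rmse_per_joint(pred, dataset.angles),
        phase_deg=phase_errors(pred, dataset.angles, dataset.stance),
        cycle_max_deg=cycle_max_error(pred, dataset.angles,
                                      dataset.cycle_onsets))


def ablation(dataset: SyncedDataset, cfg: TrainConfig) -> dict:
    """Train sEMG-only, vision-only and fused models under identical
    settings; returns {modality: (model, EvalReport)}."""
    out = {}
    for modality in ("semg", "vision", "fused"):
        model, _ = train_full(dataset, replace(cfg, modality=modality))
        out[modality] = (model, evaluate(model, dataset))
    return out


def occlusion_sweep(model: JointAngleModel, profile: GaitProfile,
                    config: SimConfig, heights: tuple = (0.05, 0.15, 0.25, 0.35),
                    include_zero: bool = True, joint: str = "knee") -> list:
    """Evaluate mean +- std |error| of one joint while regenerating the test
    capture with ground occluders of increasing height (same seed)."""
    hs = list(heights)
    if sorted(hs) != hs:
        raise ValueError("heights must be ascending")
    if include_zero and (not hs or hs[0] > 0):
        hs = [0.0] + hs
    j = JOINTS.index(joint)
    curve = []
    for h in hs:
        ds = make_dataset(profile, config, OccluderSpec(height_m=h))
        pred = predict_dataset(model, ds)
        err = np.abs(pred[:, j] - ds.angles[:, j])
        curve.append((float(h), float(err.mean()), float(err.std())))
    return curve
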