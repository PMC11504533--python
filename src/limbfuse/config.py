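"""YAML run configuration: strict validation and dataclass construction.

A run config has three optional sections — ``sim``, ``train``, ``eval`` —
plus a global ``seed``.  Unknown keys are rejected with a nearest-valid-key
suggestion so typos (``emg_fz_hz``) fail loudly instead of silently using a
default.
"""

from __future__ import annotations

import dataclasses
import difflib

import yaml

from .gaitsim import GaitProfile, OccluderSpec, SimConfig
from .regressor import TrainConfig

__all__ = ["ConfigError", "load_run_config", "RunConfig"]


class ConfigError(ValueError):
    pass


def _fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}

_SIM_EXTRA = {"cadence_hz", "occluder_height_m"}
_EVAL_KEYS = {"heights", "joint"}
_TOP_KEYS = {"sim", "train", "eval", "seed"}


def _check_keys(given: dict, allowed: set, where: str):
    for k in given:
        if k not in allowed:
            hint = difflib.get_close_matches(k, sorted(allowed), n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {k!r} in {where}{extra}")


@dataclasses.dataclass
class RunConfig:
    sim: SimConfig
    profile: GaitProfile
    occluder: OccluderSpec
    train: TrainConfig
    eval_heights: tuple = (0.05, 0.15, 0.25, 0.35)
    eval_joint: str = "knee"
    seed: int = 0

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "profile": {"cadence_hz": self.profile.cadence_hz,
                        "emg_noise_floor_mv": self.profile.emg_noise_floor_mv,
                        "emg_band_hz": list(self.profile.emg_band_hz),
                        "emg_gain_mv": self.profile.emg_gain_mv},
            "occluder": dataclasses.asdict(self.occluder),
            "train": dataclasses.asdict(self.train),
            "eval": {"heights": list(self.eval_heights),
                     "joint": self.eval_joint},
        }


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    """Parse and validate a YAML config file (all sections optional)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    sim_raw = dict(raw.get("sim") or {})
    _check_keys(sim_raw, _fields(SimConfig) | _SIM_EXTRA, "sim")
    cadence = sim_raw.pop("cadence_hz", None)
    occ_h = sim_raw.pop("occluder_height_m", 0.0)
    if "depth_resolution" in sim_raw:
        sim_raw["depth_resolution"] = tuple(sim_raw["depth_resolution"])

    train_raw = dict(raw.get("train") or {})
    _check_keys(train_raw, _fields(TrainConfig), "train")

    eval_raw = dict(raw.get("eval") or {})
    _check_keys(eval_raw, _EVAL_KEYS, "eval")

    global_seed = seed if seed is not None else int(raw.get("seed", 0))
    sim_raw["seed"] = global_seed
    train_raw["seed"] = global_seed

    try:
        sim = SimConfig(**sim_raw)
        profile = GaitProfile(**({"cadence_hz": cadence} if cadence else {}))
        occluder = OccluderSpec(height_m=float(occ_h))
        train = TrainConfig(**train_raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e

    return RunConfig(sim=sim, profile=profile, occluder=occluder, train=train,
                     eval_heights=tuple(eval_raw.get("heights",
                                                     (0.05, 0.15, 0.25, 0.35))),
                     eval_joint=eval_raw.get("joint", "knee"),
                     seed=global_seed)
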