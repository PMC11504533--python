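"""Frame-triggered multi-scale windowing of sEMG.

Each depth-frame timestamp triggers one window set: the trailing L, 2L/3 and
L/3 samples ending at the last sEMG sample acquired at or before the trigger.
The three scales co-terminate (the shorter windows are exact suffixes of the
base window), so no sliding or overlap bookkeeping is needed and the windows
stay aligned with the frame stream by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EmgRecording

__all__ = ["MultiScaleWindowSet", "window_at_triggers"]


@dataclass
class MultiScaleWindowSet:
    """Three co-terminating per-channel windows bound to one frame trigger.

    windows: tuple of arrays with shapes [L, C], [2L/3, C], [L/3, C], all
    ending (inclusive) at sample ``end_index`` of the source recording.
    """

    trigger_ts: float
    end_index: int
    windows: tuple

    def __post_init__(self):
        l0, l1, l2 = (w.shape[0] for w in self.windows)
        if not (l0 == 3 * l2 and l1 == 2 * l2):
            raise ValueError(f"window lengths {l0},{l1},{l2} are not L, 2L/3, L/3")

    @property
    def base_len(self) -> int:
        return self.windows[0].shape[0]


def window_at_triggers(rec: EmgRecording, frame_ts, base_len: int = 300
                       ) -> tuple[list[MultiScaleWindowSet], list[int]]:
    """Cut one multi-scale window set per frame trigger.

    Returns (sets, skipped) where ``skipped`` lists the indices of triggers
    with fewer than ``base_len`` samples of history (early frames are skipped
    rather than zero-padded, so every emitted window is genuine signal).
    """
    frame_ts = np.asarray(frame_ts, dtype=np.float64)
    if base_len % 3:
        raise ValueError("base_len must be divisible by 3")
    if frame_ts.ndim != 1 or (np.diff(frame_ts) < 0).any():
        raise ValueError("frame timestamps must be sorted ascending")

    sets: list[MultiScaleWindowSet] = []
    skipped: list[int] = []
    x = rec.samples
    for i, t in enumerate(frame_ts):
        end = int(np.floor(t * rec.fs_hz + 1e-9))  # last sample with time <= t
        end = min(end, rec.n_samples - 1)
        if end + 1 < base_len:
            skipped.append(i)
            continue
        full = x[end + 1 - base_len:end + 1]
        sets.append(MultiScaleWindowSet(
            trigger_ts=float(t), end_index=end,
            windows=(full, full[base_len // 3:], full[2 * base_len // 3:])))
    return sets, skipped
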