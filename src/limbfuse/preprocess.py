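"""sEMG preprocessing: per-channel band-pass filtering, plus CSV/NPZ I/O.

Band-pass filtering is the sole preprocessing step; no rectification,
normalization or notch filtering is applied, so the windowed signal handed to
the autoencoder is the raw (filtered) millivolt trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt, sosfiltfilt

from .types import MUSCLES, EmgRecording

__all__ = ["FilterSpec", "bandpass", "read_emg_csv", "write_emg_csv"]


@dataclass
class FilterSpec:
    """Butterworth band-pass specification.

    Defaults (20-450 Hz, order 4) cover the dominant surface-EMG energy band
    while rejecting motion artifact below 20 Hz.
    """

    low_hz: float = 20.0
    high_hz: float = 450.0
    order: int = 4

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, fs_hz: float):
        if self.high_hz >= fs_hz / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz is at or above Nyquist "
                f"({fs_hz / 2} Hz)")


def bandpass(rec: EmgRecording, spec: FilterSpec,
             zero_phase: bool = True) -> EmgRecording:
    """Band-pass each channel; zero-phase (forward-backward) by default.

    Output length equals input length and no other normalization is applied.
    A causal (single-pass) option exists for online-style processing.
    """
    spec.validate_for(rec.fs_hz)
    if rec.n_samples < 3 * (spec.order + 1):
        raise ValueError("recording too short for the requested filter order")
    sos = butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                 fs=rec.fs_hz, output="sos")
    filt = sosfiltfilt if zero_phase else sosfilt
    out = filt(sos, rec.samples, axis=0)
    return EmgRecording(np.ascontiguousarray(out), rec.fs_hz, rec.channels)


def read_emg_csv(path, fs_hz: float) -> EmgRecording:
    """CSV with one header row of channel labels, one row per sample (mV)."""
    df = pd.read_csv(path)
    return EmgRecording(df.to_numpy(dtype=np.float64), fs_hz,
                        tuple(df.columns))


def write_emg_csv(rec: EmgRecording, path):
    pd.DataFrame(rec.samples, columns=list(rec.channels)).to_csv(path,
                                                                 index=False)
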