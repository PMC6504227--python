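"""Wake/sleep segmentation from EMG quieting (plus optional immobility).

Sleep is scored where windowed EMG RMS drops below a fraction of a robust
wake-reference level, sustained for a minimum bout duration, and (when an
immobility series is supplied) the animal is immobile.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from rescuephys.core import (
    ContractError,
    DegenerateInputError,
    Recording,
    StateIntervals,
)


def emg_rms(emg: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered sliding-window RMS of the EMG trace."""
    if window_s <= 0:
        raise ContractError("emg_window_s must be positive")
    size = max(1, int(round(window_s * fs)))
    ms = uniform_filter1d(np.asarray(emg, dtype=float) ** 2, size=size, mode="nearest")
    return np.sqrt(ms)


def segment_states(
    rec: Recording,
    emg_window_s: float = 1.0,
    quiet_ratio: float = 0.5,
    min_bout_s: float = 10.0,
    movement: Optional[np.ndarray] = None,
) -> StateIntervals:
    """Label every sample wake or sleep.

    Parameters
    ----------
    rec
        Recording with an ``emg`` channel.
    emg_window_s
        RMS window length.
    quiet_ratio
        Sleep threshold as a fraction of the wake-reference RMS (the median
        windowed RMS over the whole recording).
    min_bout_s
        Quiet runs shorter than this stay wake.
    movement
        Optional per-sample immobility confirmation: samples with
        ``movement > 0`` are treated as moving and cannot be sleep.
    """
    emg = rec.channel("emg")
    if not 0.0 < quiet_ratio < 1.0:
        raise ContractError("quiet_ratio must lie in (0, 1)")
    if np.ptp(emg) == 0:
        raise DegenerateInputError("EMG is constant; cannot infer state")
    if movement is not None and len(movement) != rec.n_samples:
        raise ContractError("movement series must match recording length")

    rms = emg_rms(emg, rec.fs, emg_window_s)
    wake_ref = float(np.median(rms))
    if wake_ref == 0:
        raise DegenerateInputError("EMG reference RMS is zero")

    quiet = rms < quiet_ratio * wake_ref
    if movement is not None:
        quiet &= np.asarray(movement) <= 0

    # duration gate: quiet runs shorter than min_bout_s revert to wake
    min_len = int(round(min_bout_s * rec.fs))
    is_sleep = np.zeros_like(quiet)
    n = len(quiet)
    edges = np.flatnonzero(np.diff(quiet.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [n]])
    for i0, i1 in zip(starts, ends):
        if quiet[i0] and (i1 - i0) >= min_len:
            is_sleep[i0:i1] = True

    return StateIntervals.from_bool(is_sleep, rec.fs)
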