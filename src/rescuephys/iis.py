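"""High-amplitude interictal-spike detection and state-resolved rates.

Detection runs on the hippocampal depth channel only; the cortical EEG
channels are consulted solely for artifact rejection (events that are both
abnormally large and time-locked across channels are non-physiological).
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from rescuephys.core import (
    SLEEP,
    WAKE,
    ContractError,
    RateByState,
    Recording,
    SpikeEvent,
    SpikeEvents,
    StateIntervals,
    check_tiling,
)

DETECT_CHANNEL = "hlfp"


class UnitScaleWarning(UserWarning):
    """Trace looks like it is not in mV (never exceeds 0.01 in magnitude)."""


def detect_spikes(
    rec: Recording,
    threshold_mV: float = 1.0,
    refractory_s: float = 0.2,
) -> SpikeEvents:
    """Log one event per supra-threshold excursion of the depth channel.

    Each contiguous run of samples above ``threshold_mV`` yields one event at
    the run's maximum; runs whose peaks fall closer than ``refractory_s``
    are merged into a single event at the larger peak.
    """
    if threshold_mV <= 0:
        raise ContractError("threshold_mV must be positive")
    if refractory_s < 0:
        raise ContractError("refractory_s must be >= 0")
    x = rec.channel(DETECT_CHANNEL)
    if len(x) and np.max(np.abs(x)) < 0.01:
        warnings.warn(
            "hlfp magnitude never exceeds 0.01; trace may not be mV-scaled",
            UnitScaleWarning,
            stacklevel=2,
        )

    above = x > threshold_mV
    if not above.any():
        return SpikeEvents(events=[], threshold_mV=threshold_mV)
    d = np.diff(above.astype(int))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        run_starts = np.concatenate([[0], run_starts])
    if above[-1]:
        run_ends = np.concatenate([run_ends, [len(x)]])

    peaks: list[tuple[float, float]] = []
    for i0, i1 in zip(run_starts, run_ends):
        k = i0 + int(np.argmax(x[i0:i1]))
        peaks.append((k / rec.fs, float(x[k])))

    merged: list[tuple[float, float]] = []
    for t, a in peaks:
        if merged and t - merged[-1][0] < refractory_s:
            if a > merged[-1][1]:
                merged[-1] = (t, a)
        else:
            merged.append((t, a))

    events = [SpikeEvent(peak_time_s=t, peak_amp_mV=a) for t, a in merged]
    return SpikeEvents(events=events, threshold_mV=threshold_mV)


def reject_artifacts(
    events: SpikeEvents,
    rec: Recording,
    sync_window_s: float = 0.01,
    sync_min_channels: int = 2,
    amp_cap_mV: float = 10.0,
) -> SpikeEvents:
    """Flag non-physiological events; nothing is deleted.

    An event is rejected when (a) its depth-channel peak exceeds
    ``amp_cap_mV`` AND (b) within +/- ``sync_window_s`` of the peak at least
    ``sync_min_channels`` *other* channels exceed the detection threshold on
    their own scale. Genuine generalized spikes are synchronous but stay
    under the amplitude cap, so they survive.
    """
    other = [name for name in rec.channels if name not in (DETECT_CHANNEL, "emg")]
    if len(rec.channels) < 2:
        raise ContractError("artifact rejection needs >= 2 channels")
    if sync_min_channels > len(other):
        raise ContractError(
            f"sync_min_channels={sync_min_channels} exceeds the "
            f"{len(other)} non-detection channels available"
        )
    half = max(1, int(round(sync_window_s * rec.fs)))
    out = []
    for ev in events:
        k = int(round(ev.peak_time_s * rec.fs))
        lo, hi = max(0, k - half), min(rec.n_samples, k + half + 1)
        n_sync = sum(
            1
            for name in other
            if np.max(rec.channels[name][lo:hi], initial=-np.inf)
            > events.threshold_mV
        )
        if ev.peak_amp_mV > amp_cap_mV and n_sync >= sync_min_channels:
            out.append(
                replace(
                    ev,
                    accepted=False,
                    reject_reason=(
                        f"amp {ev.peak_amp_mV:.2f} mV > cap {amp_cap_mV} with "
                        f"{n_sync} synchronous channels"
                    ),
                )
            )
        else:
            out.append(replace(ev, accepted=True, reject_reason=None))
    return SpikeEvents(events=out, threshold_mV=events.threshold_mV)


def spike_rate_by_state(events: SpikeEvents, states: StateIntervals) -> RateByState:
    """Accepted-event rates per vigilance state, in events/min.

    A state with zero total time gets rate ``None`` (undefined, not 0).
    """
    counts = {WAKE: 0, SLEEP: 0}
    for ev in events.accepted:
        state = states.state_at(ev.peak_time_s)
        if state is None:
            raise ContractError(
                f"event at {ev.peak_time_s:.3f}s outside labeled intervals"
            )
        counts[state] += 1
    wake_time = states.total_time(WAKE)
    sleep_time = states.total_time(SLEEP)
    return RateByState(
        wake_rate=counts[WAKE] / (wake_time / 60.0) if wake_time > 0 else None,
        sleep_rate=counts[SLEEP] / (sleep_time / 60.0) if sleep_time > 0 else None,
        wake_time_s=wake_time,
        sleep_time_s=sleep_time,
        n_wake=counts[WAKE],
        n_sleep=counts[SLEEP],
    )


def fold_change(
    group_a_rates: Sequence[float],
    group_b_rates: Sequence[float],
    pseudo_rate: float = 0.0,
) -> tuple[float, bool]:
    """Ratio of group mean rates (a / b).

    Returns ``(ratio, used_pseudo)``; when the denominator mean is zero the
    configured ``pseudo_rate`` replaces it and ``used_pseudo`` is True.
    """
    a = np.asarray(group_a_rates, dtype=float)
    b = np.asarray(group_b_rates, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("fold_change requires non-empty groups")
    denom = b.mean()
    used_pseudo = False
    if denom == 0:
        if pseudo_rate <= 0:
            raise ContractError(
                "denominator group mean is 0 and no pseudo_rate configured"
            )
        denom = pseudo_rate
        used_pseudo = True
    return float(a.mean() / denom), used_pseudo
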