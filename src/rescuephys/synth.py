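"""Synthetic recordings and behavioral cohorts with retained ground truth.

Everything downstream (segmentation, spike detection, spectral analysis,
cohort statistics) is exercised against the generators here, so each
generator keeps its ground truth alongside the artifact it produces and is
bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from rescuephys.core import (
    SLEEP,
    WAKE,
    GenerationError,
    ParameterError,
    Recording,
    StateIntervals,
)

SEIZURE_ENDPOINTS = ("1st clonus", "T/C", "THE")

#: canonical long-format cohort-table columns
COHORT_COLUMNS = ("animal_id", "genotype", "cre", "tmx", "endpoint", "value")


@dataclass
class SimRecordingParams:
    """Parameters of the synthetic 4-channel recording generator.

    Spike rates are in events/min and apply within the matching vigilance
    state; the hippocampal LFP carries theta and delta sinusoids on a 1/f
    background, and EMG RMS switches abruptly at state boundaries.
    """

    duration_s: float
    fs: float = 2000.0
    spike_rate_wake: float = 0.0
    spike_rate_sleep: float = 0.0
    spike_amp_mV: float = 2.0
    spike_width_ms: float = 25.0
    theta_amp: float = 0.2
    delta_amp: float = 0.2
    theta_freq_hz: float = 8.0
    delta_freq_hz: float = 2.5
    noise_exponent: float = 1.0
    noise_rms: float = 0.05
    sleep_fraction: float = 0.0
    sleep_bout_s: float = 60.0
    emg_wake_rms: float = 1.0
    emg_sleep_rms: float = 0.1
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.fs <= 200.0:
            # Nyquist must cover the 1-100 Hz analysis range
            raise ParameterError(f"fs must exceed 200 Hz, got {self.fs}")
        if self.spike_rate_wake < 0 or self.spike_rate_sleep < 0:
            raise ParameterError("spike rates must be >= 0")
        if not 0.0 <= self.sleep_fraction <= 1.0:
            raise ParameterError("sleep_fraction must lie in [0, 1]")
        if self.spike_amp_mV < 0 or self.spike_width_ms <= 0:
            raise ParameterError("spike amplitude/width invalid")
        if self.sleep_bout_s <= 0:
            raise ParameterError("sleep_bout_s must be positive")
        if self.emg_wake_rms <= 0 or self.emg_sleep_rms < 0:
            raise ParameterError("EMG RMS levels invalid")


@dataclass
class SimRecording:
    """A generated recording plus the ground truth used to make it."""

    recording: Recording
    true_spike_times: np.ndarray
    true_states: StateIntervals
    true_theta_amp: float


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _spike_template(fs: float, width_ms: float) -> np.ndarray:
    """Biphasic transient: sharp positive peak, slow shallow after-wave.

    Peak value is exactly 1 so a caller can scale to a target mV amplitude.
    """
    sigma = width_ms / 1000.0 / 2.355  # width interpreted as FWHM
    t = np.arange(-4 * sigma, 13 * sigma, 1.0 / fs)
    w = np.exp(-(t**2) / (2 * sigma**2))
    w -= 0.30 * np.exp(-((t - 4 * sigma) ** 2) / (2 * (3 * sigma) ** 2))
    return w / w.max()


def _draw_states(params: SimRecordingParams, rng: np.random.Generator) -> StateIntervals:
    """Alternating exponential wake/sleep bouts hitting sleep_fraction on average."""
    dur = params.duration_s
    f = params.sleep_fraction
    if f == 0.0:
        return StateIntervals([(0.0, dur, WAKE)])
    if f == 1.0:
        return StateIntervals([(0.0, dur, SLEEP)])
    mean_sleep = params.sleep_bout_s
    mean_wake = mean_sleep * (1.0 - f) / f
    bounds = [0.0]
    states: list[str] = []
    state = WAKE
    t = 0.0
    min_bout = min(1.0, dur / 4)
    while t < dur:
        mean = mean_wake if state == WAKE else mean_sleep
        bout = max(min_bout, rng.exponential(mean))
        t = min(dur, t + bout)
        bounds.append(t)
        states.append(state)
        state = SLEEP if state == WAKE else WAKE
    # snap boundaries to the sample grid so intervals tile the sample array
    snapped = [round(b * params.fs) / params.fs for b in bounds]
    intervals = []
    for b0, b1, s in zip(snapped[:-1], snapped[1:], states):
        if b1 > b0:
            intervals.append((b0, b1, s))
    return StateIntervals(intervals)


def simulate_recording(params: SimRecordingParams) -> SimRecording:
    """Generate a 4-channel recording (eeg_l, eeg_r, hlfp, emg).

    Spike times are Poisson within each vigilance state at that state's
    rate and inserted as biphasic transients on all EEG/LFP channels (full
    amplitude on hlfp). Deterministic for a given seed.
    """
    params.validate()
    seq = np.random.SeedSequence(params.seed)
    state_rng, spike_rng, *noise_rngs = [
        np.random.default_rng(s) for s in seq.spawn(7)
    ]

    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    states = _draw_states(params, state_rng)

    # --- ground-truth spikes -------------------------------------------------
    template = _spike_template(params.fs, params.spike_width_ms)
    guard = len(template) / params.fs  # keep whole transient inside recording
    spike_times: list[float] = []
    for start, end, state in states.intervals:
        rate_per_s = (
            params.spike_rate_wake if state == WAKE else params.spike_rate_sleep
        ) / 60.0
        if rate_per_s <= 0:
            continue
        count = spike_rng.poisson(rate_per_s * (end - start))
        times = spike_rng.uniform(start, end, size=count)
        spike_times.extend(times[(times > guard) & (times < params.duration_s - guard)])
    spike_times_arr = np.sort(np.asarray(spike_times))

    # --- channels ------------------------------------------------------------
    hlfp = (
        params.theta_amp * np.sin(2 * np.pi * params.theta_freq_hz * t)
        + params.delta_amp * np.sin(2 * np.pi * params.delta_freq_hz * t)
        + params.noise_rms * _colored_noise(n, params.noise_exponent, noise_rngs[0])
    )
    eeg_l = params.noise_rms * _colored_noise(n, params.noise_exponent, noise_rngs[1])
    eeg_r = params.noise_rms * _colored_noise(n, params.noise_exponent, noise_rngs[2])

    peak_offset = int(np.argmax(template))
    for st in spike_times_arr:
        i0 = int(round(st * params.fs)) - peak_offset
        i1 = i0 + len(template)
        if i0 < 0 or i1 > n:
            continue
        hlfp[i0:i1] += params.spike_amp_mV * template
        eeg_l[i0:i1] += 0.6 * params.spike_amp_mV * template
        eeg_r[i0:i1] += 0.6 * params.spike_amp_mV * template

    emg = noise_rngs[3].standard_normal(n)
    sleep_mask = states.sample_labels(n, params.fs) == SLEEP
    emg[~sleep_mask] *= params.emg_wake_rms
    emg[sleep_mask] *= params.emg_sleep_rms

    rec = Recording(
        channels={"eeg_l": eeg_l, "eeg_r": eeg_r, "hlfp": hlfp, "emg": emg},
        fs=params.fs,
        meta=dict(params.meta),
    )
    return SimRecording(
        recording=rec,
        true_spike_times=spike_times_arr,
        true_states=states,
        true_theta_amp=params.theta_amp,
    )


# ---------------------------------------------------------------------------
# behavioral cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimCohortParams:
    """Per-cell Gaussian design for behavioral cohorts.

    ``group_means``/``group_sds`` map a (genotype, cre, tmx) cell to either a
    scalar (single endpoint) or a mapping endpoint -> value.
    """

    n_per_group: int
    group_means: Mapping[tuple[str, str, str], object]
    group_sds: Mapping[tuple[str, str, str], object]
    seed: int = 0
    max_retries: int = 1000

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if set(self.group_means) != set(self.group_sds):
            raise ParameterError("group_means and group_sds must share cells")
        for cell, sd in self.group_sds.items():
            vals = sd.values() if isinstance(sd, Mapping) else [sd]
            if any(v <= 0 for v in vals):
                raise ParameterError(f"sds must be > 0 (cell {cell})")


def _cell_values(spec: object, endpoints: Sequence[str]) -> dict[str, float]:
    if isinstance(spec, Mapping):
        return {e: float(spec[e]) for e in endpoints}
    return {e: float(spec) for e in endpoints}


def simulate_seizure_cohort(params: SimCohortParams) -> pd.DataFrame:
    """Draw staged seizure latencies: truncated-Gaussian per cell, with stage
    monotonicity (1st clonus <= T/C <= THE) enforced per animal by resampling.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    animal = 0
    for cell in sorted(params.group_means):
        genotype, cre, tmx = cell
        means = _cell_values(params.group_means[cell], SEIZURE_ENDPOINTS)
        sds = _cell_values(params.group_sds[cell], SEIZURE_ENDPOINTS)
        for _ in range(params.n_per_group):
            animal += 1
            for attempt in range(params.max_retries):
                draws = {
                    e: rng.normal(means[e], sds[e]) for e in SEIZURE_ENDPOINTS
                }
                vals = [draws[e] for e in SEIZURE_ENDPOINTS]
                if min(vals) > 0 and vals == sorted(vals):
                    break
            else:
                raise GenerationError(
                    f"could not draw monotone positive latencies for cell {cell} "
                    f"after {params.max_retries} tries"
                )
            for e in SEIZURE_ENDPOINTS:
                rows.append((f"a{animal:03d}", genotype, cre, tmx, e, draws[e]))
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def simulate_fear_cohort(params: SimCohortParams) -> pd.DataFrame:
    """Draw fear-conditioning cohorts through the suppression-ratio identity.

    Each animal gets a target ratio r drawn from its cell's Gaussian
    (resampled into (0, 1)), a training activity, and a testing activity
    ``train * r / (1 - r)`` so that test/(train+test) equals r exactly.
    """
    params.validate()
    for cell, m in params.group_means.items():
        vals = m.values() if isinstance(m, Mapping) else [m]
        if any(not 0.0 < v < 1.0 for v in vals):
            raise ParameterError(f"fear-cohort cell means must lie in (0,1): {cell}")
    rng = np.random.default_rng(params.seed)
    rows = []
    animal = 0
    for cell in sorted(params.group_means):
        genotype, cre, tmx = cell
        mean = float(_cell_values(params.group_means[cell], ("r",))["r"])
        sd = float(_cell_values(params.group_sds[cell], ("r",))["r"])
        for _ in range(params.n_per_group):
            animal += 1
            for attempt in range(params.max_retries):
                r = rng.normal(mean, sd)
                if 0.0 < r < 1.0:
                    break
            else:
                raise GenerationError(f"could not draw ratio in (0,1) for cell {cell}")
            train = max(1.0, rng.normal(90.0, 15.0))
            test = train * r / (1.0 - r)
            aid = f"a{animal:03d}"
            rows.append((aid, genotype, cre, tmx, "train_activity_cm", train))
            rows.append((aid, genotype, cre, tmx, "test_activity_cm", test))
            rows.append((aid, genotype, cre, tmx, "suppression_ratio", r))
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
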