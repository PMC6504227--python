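"""Complex Morlet amplitude spectra of the CA1 LFP and phase-change inference.

The transform evaluates 50 logarithmically spaced frequencies on [1, 100] Hz
with a six-period wavelet width. Wavelets are normalized to unit area under
their magnitude envelope, which makes the amplitude of a unit sinusoid
approximately frequency-independent. Within-subject amplitude changes
between recording phases are normalized by the Phase I amplitude; inference
uses an animal-level bootstrap and a sign-flip permutation test on the
band-averaged change.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve

from rescuephys.core import (
    AmplitudeSpectrum,
    BandDefs,
    ContractError,
    Recording,
)

N_FREQS = 50
FREQ_RANGE_HZ = (1.0, 100.0)


def default_freqs() -> np.ndarray:
    """The 50 log-spaced analysis frequencies on [1, 100] Hz."""
    return np.logspace(
        np.log10(FREQ_RANGE_HZ[0]), np.log10(FREQ_RANGE_HZ[1]), N_FREQS
    )


def analysis_window(rec: Recording, minutes: float = 10.0) -> Recording:
    """Leading segment of a session (analysis focuses on the first minutes)."""
    if minutes <= 0:
        raise ContractError("minutes must be positive")
    if rec.n_samples == 0:
        raise ContractError("empty recording")
    want_s = minutes * 60.0
    if rec.duration_s < want_s:
        warnings.warn(
            f"recording lasts {rec.duration_s / 60:.2f} min < {minutes} min; "
            "using the whole recording",
            stacklevel=2,
        )
        return rec
    return rec.slice(0.0, want_s)


def _morlet_wavelet(
    f: float, fs: float, n_cycles: float, norm: str
) -> np.ndarray:
    """Complex Morlet wavelet at frequency f, sampled at fs.

    sigma_t = n_cycles / (2 pi f); support spans +/- 4 sigma_t.
    norm='area' scales the magnitude envelope to unit sum (discrete area);
    norm='energy' scales to unit L2 norm.
    """
    sigma_t = n_cycles / (2 * np.pi * f)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    if norm == "area":
        w /= np.sum(np.abs(w))
    elif norm == "energy":
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
    else:
        raise ContractError(f"unknown wavelet norm {norm!r}")
    return w


def morlet_amplitude(
    trace: np.ndarray,
    fs: float,
    freqs: Optional[np.ndarray] = None,
    n_cycles: float = 6.0,
    norm: str = "area",
) -> AmplitudeSpectrum:
    """Time-resolved wavelet amplitude (modulus of the complex convolution).

    Edge samples within one wavelet half-support of either boundary are
    flagged unreliable; the convolution itself uses reflect padding.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ContractError("trace contains non-finite samples")
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if fs < 2 * freqs.max():
        raise ContractError(
            f"fs={fs} Hz cannot resolve {freqs.max():.1f} Hz (need >= 2x)"
        )
    n = len(trace)
    amp = np.empty((len(freqs), n))
    reliable = np.ones((len(freqs), n), dtype=bool)
    for i, f in enumerate(freqs):
        w = _morlet_wavelet(f, fs, n_cycles, norm)
        half = (len(w) - 1) // 2
        pad = min(half, n - 1)
        padded = np.concatenate([trace[pad:0:-1], trace, trace[-2 : -pad - 2 : -1]])
        conv = fftconvolve(padded, w, mode="same")
        amp[i] = np.abs(conv[pad : pad + n])
        edge = min(half, n)
        reliable[i, :edge] = False
        if edge > 0:
            reliable[i, -edge:] = False
    return AmplitudeSpectrum(freqs_hz=freqs, amp=amp, fs=fs, reliable=reliable)


@dataclass
class RatioSeries:
    """Theta/delta power-ratio time series (non-finite = flagged samples)."""

    values: np.ndarray
    fs: float


def theta_delta_ratio(
    spec: AmplitudeSpectrum,
    bands: BandDefs = BandDefs(),
    smooth_s: float = 1.0,
) -> RatioSeries:
    """Smoothed ratio of theta to delta band power.

    Band power per sample is the mean squared amplitude over the band's
    frequency rows; the ratio is smoothed by a centered moving average of
    ``smooth_s``. Samples where delta power is zero come out infinite and
    are excluded from representative-window selection downstream.
    """
    theta_rows = spec.band_rows(*bands.theta)
    delta_rows = spec.band_rows(*bands.delta)
    theta_p = np.mean(spec.amp[theta_rows] ** 2, axis=0)
    delta_p = np.mean(spec.amp[delta_rows] ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta_p > 0, theta_p / np.where(delta_p > 0, delta_p, 1.0), np.inf)
    if smooth_s > 0:
        size = max(1, int(round(smooth_s * spec.fs)))
        finite = np.isfinite(ratio)
        smoothed = np.full_like(ratio, np.inf)
        if finite.all():
            smoothed = uniform_filter1d(ratio, size=size, mode="nearest")
        else:
            # smooth finite stretches only; windows touching a flagged
            # sample stay flagged
            vals = np.where(finite, ratio, 0.0)
            num = uniform_filter1d(vals, size=size, mode="nearest")
            ok = (
                uniform_filter1d(finite.astype(float), size=size, mode="nearest")
                > 1 - 1e-9
            )
            smoothed[ok] = num[ok]
        ratio = smoothed
    return RatioSeries(values=ratio, fs=spec.fs)


def select_representative_window(
    ratio: RatioSeries, window_s: float = 1.0
) -> tuple[float, float]:
    """Window with the highest mean ratio; ties break to the earliest start."""
    wlen = int(round(window_s * ratio.fs))
    n = len(ratio.values)
    if wlen <= 0 or n < wlen:
        raise ContractError("series shorter than the selection window")
    finite = np.isfinite(ratio.values)
    if not finite.any():
        raise ContractError("all ratio samples are flagged")
    vals = np.where(finite, ratio.values, 0.0)
    means = uniform_filter1d(vals, size=wlen, mode="constant", origin=0)
    # valid centered windows: require every sample finite
    ok = uniform_filter1d(finite.astype(float), size=wlen, mode="constant") > 1 - 1e-9
    means = np.where(ok, means, -np.inf)
    # restrict to fully interior windows
    half_lo = (wlen - 1) // 2
    half_hi = wlen // 2
    means[:half_lo] = -np.inf
    if half_hi > 0:
        means[-half_hi:] = -np.inf
    if not np.isfinite(means).any():
        raise ContractError("no unflagged window available")
    center = int(np.argmax(means))
    start = (center - half_lo) / ratio.fs
    return start, start + wlen / ratio.fs


@dataclass
class AmplitudeChange:
    """Per-animal normalized amplitude change (PhaseII - PhaseI)/PhaseI."""

    animals: list[str]
    freqs_hz: np.ndarray
    per_animal: np.ndarray  # (n_animals, n_freqs)
    grand_mean: np.ndarray  # (n_freqs,)
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    ci_degenerate: bool = False


def _mean_session_amplitude(specs: Sequence[AmplitudeSpectrum]) -> np.ndarray:
    """Time-averaged amplitude over reliable samples, averaged over sessions."""
    per_session = []
    for spec in specs:
        amp = np.where(spec.reliable, spec.amp, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(amp, axis=1)
        # fall back to the full average for rows with no reliable samples
        bad = ~np.isfinite(m)
        if bad.any():
            m[bad] = spec.amp[bad].mean(axis=1)
        per_session.append(m)
    return np.mean(per_session, axis=0)


def normalized_amplitude_change(
    phase1: Mapping[str, Sequence[AmplitudeSpectrum]],
    phase2: Mapping[str, Sequence[AmplitudeSpectrum]],
) -> AmplitudeChange:
    """Within-animal amplitude change between phases, normalized by Phase I.

    Sessions within a phase are averaged first; animals missing either
    phase are excluded with a warning.
    """
    animals = sorted(set(phase1) & set(phase2))
    skipped = sorted((set(phase1) | set(phase2)) - set(animals))
    if skipped:
        warnings.warn(
            f"animals missing a phase were excluded: {skipped}", stacklevel=2
        )
    if not animals:
        raise ContractError("no animal present in both phases")
    freqs = None
    rows = []
    for animal in animals:
        a1 = _mean_session_amplitude(phase1[animal])
        a2 = _mean_session_amplitude(phase2[animal])
        spec0 = phase1[animal][0]
        if freqs is None:
            freqs = spec0.freqs_hz
        if np.any(a1 <= 0):
            raise ContractError(
                f"animal {animal} has non-positive Phase I amplitude"
            )
        rows.append((a2 - a1) / a1)
    per_animal = np.vstack(rows)
    return AmplitudeChange(
        animals=animals,
        freqs_hz=freqs,
        per_animal=per_animal,
        grand_mean=per_animal.mean(axis=0),
    )


def bootstrap_ci(
    change: AmplitudeChange,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> AmplitudeChange:
    """Percentile bootstrap CI over animals, per frequency."""
    n = len(change.animals)
    if n < 1:
        raise ContractError("bootstrap needs at least one animal")
    if n == 1:
        return AmplitudeChange(
            animals=change.animals,
            freqs_hz=change.freqs_hz,
            per_animal=change.per_animal,
            grand_mean=change.grand_mean,
            ci_low=change.grand_mean.copy(),
            ci_high=change.grand_mean.copy(),
            ci_degenerate=True,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = change.per_animal[idx].mean(axis=1)  # (n_boot, n_freqs)
    alpha = (1 - level) / 2
    lo = np.quantile(boot_means, alpha, axis=0)
    hi = np.quantile(boot_means, 1 - alpha, axis=0)
    return AmplitudeChange(
        animals=change.animals,
        freqs_hz=change.freqs_hz,
        per_animal=change.per_animal,
        grand_mean=change.grand_mean,
        ci_low=lo,
        ci_high=hi,
    )


@dataclass
class PermutationResult:
    p: float
    observed: float
    n_shuffles: int
    exhaustive: bool


def band_permutation_test(
    change: AmplitudeChange,
    band: tuple[float, float] = (6.0, 12.0),
    n_shuffles: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided sign-flip permutation test on the band-averaged change.

    The statistic is the mean over animals of each animal's band-averaged
    normalized change; the null exchanges the phase labels within each
    animal, which flips the sign of its change. When the full set of sign
    patterns (2^n) fits within ``n_shuffles`` the test enumerates it
    exactly; otherwise it samples with the add-one correction
    p = (1 + #{|null| >= |obs|}) / (n_shuffles + 1).
    """
    rows = np.flatnonzero(
        (change.freqs_hz >= band[0]) & (change.freqs_hz <= band[1])
    )
    if len(rows) == 0:
        raise ContractError(f"band {band} outside the analyzed spectrum")
    per_animal = change.per_animal[:, rows].mean(axis=1)
    n = len(per_animal)
    if n < 2:
        raise ContractError("permutation test needs >= 2 animals")
    observed = per_animal.mean()
    if 2**n <= n_shuffles:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = (signs * per_animal).mean(axis=1)
        p = float(np.mean(np.abs(null) >= np.abs(observed) - 1e-12))
        return PermutationResult(
            p=p, observed=float(observed), n_shuffles=2**n, exhaustive=True
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_shuffles, n))
    null = (signs * per_animal).mean(axis=1)
    hits = int(np.sum(np.abs(null) >= np.abs(observed) - 1e-12))
    p = (1 + hits) / (n_shuffles + 1)
    return PermutationResult(
        p=float(p), observed=float(observed), n_shuffles=n_shuffles, exhaustive=False
    )
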