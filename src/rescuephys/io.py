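"""Plain-text serialization: recordings (CSV + JSON sidecar), state
intervals (BED-like), cohort tables (CSV) and spectra (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rescuephys.core import (
    AmplitudeSpectrum,
    ContractError,
    Recording,
    SpikeEvents,
    StateIntervals,
)

RECORDING_COLUMNS = ("t", "eeg_l", "eeg_r", "hlfp_mV", "emg")


def write_recording(rec: Recording, csv_path: str | Path) -> Path:
    """Columnar CSV (t, eeg_l, eeg_r, hlfp_mV, emg) + JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "t": rec.times,
            "eeg_l": rec.channel("eeg_l"),
            "eeg_r": rec.channel("eeg_r"),
            "hlfp_mV": rec.channel("hlfp"),
            "emg": rec.channel("emg"),
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs": rec.fs, **rec.meta}, indent=2))
    return csv_path


def read_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise ContractError(f"recording file lacks columns: {sorted(missing)}")
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.pop("fs"))
    else:
        dt = np.diff(df["t"].to_numpy()[:2])
        if len(dt) == 0 or dt[0] <= 0:
            raise ContractError("cannot infer fs without sidecar")
        fs, meta = 1.0 / dt[0], {}
    return Recording(
        channels={
            "eeg_l": df["eeg_l"].to_numpy(),
            "eeg_r": df["eeg_r"].to_numpy(),
            "hlfp": df["hlfp_mV"].to_numpy(),
            "emg": df["emg"].to_numpy(),
        },
        fs=fs,
        meta=meta,
    )


def write_states(states: StateIntervals, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{s:.6f}\t{e:.6f}\t{state}" for s, e, state in states.intervals]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_states(path: str | Path) -> StateIntervals:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        s, e, state = line.split("\t")
        intervals.append((float(s), float(e), state))
    return StateIntervals(intervals=intervals)


def write_events(
    events: SpikeEvents, path: str | Path, states: StateIntervals | None = None
) -> Path:
    rows = []
    for ev in events:
        state = states.state_at(ev.peak_time_s) if states is not None else ""
        rows.append(
            {
                "peak_time_s": ev.peak_time_s,
                "peak_amp_mV": ev.peak_amp_mV,
                "state": state,
                "accepted": ev.accepted,
                "reject_reason": ev.reject_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    table.to_csv(path, index=False)
    return Path(path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype": str, "cre": str, "tmx": str})
    required = {"animal_id", "genotype", "cre", "tmx", "endpoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"cohort table lacks columns: {sorted(missing)}")
    return df


def write_spectrum(spec: AmplitudeSpectrum, path: str | Path) -> Path:
    """CSV matrix: first column frequency (Hz), then one column per sample."""
    df = pd.DataFrame(spec.amp, index=spec.freqs_hz)
    df.index.name = "freq_hz"
    df.to_csv(path, float_format="%.6g")
    return Path(path)
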