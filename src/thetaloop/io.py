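"""File round-tripping: flat-binary signals with JSON sidecars, trial and
pulse CSV logs, and CSV writers for spectra, evoked averages and histograms.

Signals are stored as little-endian float32 with a JSON sidecar carrying
the sampling rate, start time, units and sample count; the reader verifies
the binary length against the sidecar so truncated files are detected.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PulseTrain, SignalTrace

__all__ = [
    "SchemaError", "write_signal", "read_signal", "write_trials", "read_trials",
    "write_pulses", "read_pulses", "write_psd", "write_evoked", "write_histogram",
    "write_json",
]

TRIAL_SCHEMA_VERSION = 1
TRIAL_REQUIRED_COLUMNS = ["mouse_id", "condition", "stim", "correct"]
TRIAL_OPTIONAL_COLUMNS = [
    "start_arm", "correct_arm", "choice", "prev_correct", "cue_relation",
    "trial_type", "n_pulses", "occ_retrieval", "occ_encoding_inbound",
    "occ_encoding_outbound", "occ_reward_approach",
]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def _stem(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in {".bin", ".json"} else p


def write_signal(trace: SignalTrace, path, channel_name: str = "lfp") -> dict:
    """Write <path>.bin (float32 LE) and <path>.json; returns the sidecar."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = trace.samples.astype("<f4")
    stem.with_suffix(".bin").write_bytes(data.tobytes())
    sidecar = {
        "fs": trace.fs, "t0": trace.t0, "units": "uV",
        "channel_name": channel_name, "n_samples": int(trace.samples.size),
        "dtype": "float32-le",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def read_signal(path) -> SignalTrace:
    """Read a flat-binary signal; errors if the binary is truncated."""
    stem = _stem(path)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    raw = stem.with_suffix(".bin").read_bytes()
    expected = sidecar["n_samples"] * 4
    if len(raw) != expected:
        raise ValueError(
            f"{stem.with_suffix('.bin')}: expected {expected} bytes "
            f"({sidecar['n_samples']} float32 samples), found {len(raw)}")
    samples = np.frombuffer(raw, dtype="<f4").astype(np.float64)
    return SignalTrace(samples=samples, fs=sidecar["fs"], t0=sidecar["t0"])


def write_trials(trials, path) -> None:
    from .behavior_sim import trials_to_frame
    frame = trials_to_frame(trials)
    missing = [c for c in TRIAL_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    frame["correct"] = frame["correct"].astype(bool)
    if "prev_correct" in frame.columns:
        frame["prev_correct"] = frame["prev_correct"].map(
            {True: True, False: False, "True": True, "False": False})
    return frame


def write_pulses(train: PulseTrain, path, zone_id: str = "") -> None:
    trig = (train.trigger_times if train.trigger_times is not None
            else np.full(len(train), np.nan))
    frame = pd.DataFrame({
        "trigger_time_s": trig, "onset_s": train.onsets,
        "mode": train.mode, "zone_id": zone_id,
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_pulses(path) -> PulseTrain:
    frame = pd.read_csv(path)
    for col in ("onset_s", "mode"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column(s): {col}")
    if frame.empty:
        return PulseTrain.empty()
    mode = str(frame["mode"].iloc[0])
    trig = (frame["trigger_time_s"].to_numpy()
            if "trigger_time_s" in frame.columns else None)
    return PulseTrain(onsets=frame["onset_s"].to_numpy(), mode=mode,
                      trigger_times=trig)


def write_psd(estimate, path) -> None:
    pd.DataFrame({"freq_hz": estimate.freqs, "psd_uv2_hz": estimate.psd}
                 ).to_csv(path, index=False)


def write_evoked(evoked, path) -> None:
    pd.DataFrame({"lag_ms": evoked.lags_ms, "mean_uv": evoked.mean,
                  "sem_uv": evoked.sem}).to_csv(path, index=False)


def write_histogram(bin_left, counts, path, column: str = "bin_left_deg") -> None:
    pd.DataFrame({column: bin_left, "count": counts}).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
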