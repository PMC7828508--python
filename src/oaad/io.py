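"""Reading and writing of envelopes, EEG matrices, decoders and sessions.

All on-disk formats are plain text: WAV audio is read with scipy, EEG
matrices are CSV (samples x channels, labelled columns) with a JSON
sidecar holding rate, channel labels, EOG flags and trial id, envelopes
are small headered CSVs, decoders are a JSON header plus a weight CSV, and
sessions are a directory of per-trial files tied together by a JSON
manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .decoder import Decoder, LagGrid
from .errors import InvalidInputError
from .online_model import AttentionSchedule, TrialData
from .preprocessing import AudioSegment, EegSegment, EnvelopeSignal

__all__ = [
    "read_wav",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_eeg",
    "read_eeg",
    "save_decoder",
    "load_decoder",
    "save_session",
    "load_session",
]


def read_wav(path: str | Path) -> AudioSegment:
    """Read a mono (or first-channel) PCM or float WAV file."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioSegment(samples=data.astype(float), rate_hz=float(rate))


def write_envelope_csv(env: EnvelopeSignal, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# trial_id={env.trial_id or ''}\n")
        fh.write(f"# side={env.side or ''}\n")
        fh.write(f"# rate_hz={env.env_rate_hz}\n")
        fh.write("value\n")
        for v in env.values:
            fh.write(f"{v:.10g}\n")


def read_envelope_csv(path: str | Path) -> EnvelopeSignal:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    values = pd.read_csv(path, skiprows=body_start)["value"].to_numpy(float)
    return EnvelopeSignal(
        values=values,
        env_rate_hz=float(meta.get("rate_hz", 64.0)),
        side=meta.get("side") or None,
        trial_id=meta.get("trial_id") or None,
    )


def write_eeg(eeg: EegSegment, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (samples x channels) and ``<prefix>.json``."""
    prefix = Path(prefix)
    pd.DataFrame(eeg.data.T, columns=eeg.channel_labels).to_csv(
        prefix.with_suffix(".csv"), index=False, float_format="%.10g"
    )
    sidecar = {
        "rate_hz": eeg.rate_hz,
        "channel_labels": list(eeg.channel_labels),
        "eog_mask": [bool(m) for m in eeg.eog_mask],
        "trial_id": eeg.trial_id,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(prefix: str | Path) -> EegSegment:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = pd.read_csv(prefix.with_suffix(".csv")).to_numpy(float).T
    return EegSegment(
        data=data,
        rate_hz=float(meta["rate_hz"]),
        channel_labels=list(meta["channel_labels"]),
        eog_mask=np.asarray(meta["eog_mask"], dtype=bool),
        trial_id=meta.get("trial_id"),
    )


def save_decoder(decoder: Decoder, prefix: str | Path) -> None:
    """Write ``<prefix>.json`` (lag grid, lambda, provenance) and ``<prefix>.csv``."""
    prefix = Path(prefix)
    header = {
        "tau_min_ms": decoder.lag_grid.tau_min_ms,
        "tau_max_ms": decoder.lag_grid.tau_max_ms,
        "rate_hz": decoder.lag_grid.rate_hz,
        "lambda_reg": decoder.lambda_reg,
        "n_channels": decoder.n_channels,
        "meta": decoder.meta,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(prefix.with_suffix(".csv"), decoder.weights, delimiter=",", fmt="%.12g")


def load_decoder(prefix: str | Path) -> Decoder:
    prefix = Path(prefix)
    h = json.loads(prefix.with_suffix(".json").read_text())
    weights = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    return Decoder(
        weights=weights,
        lag_grid=LagGrid(h["tau_min_ms"], h["tau_max_ms"], h["rate_hz"]),
        lambda_reg=h["lambda_reg"],
        n_channels=h["n_channels"],
        meta=h.get("meta", {}),
    )


def save_session(trials: list[TrialData], roles: list[str], out_dir: str | Path) -> None:
    """Write a session directory: per-trial EEG + envelopes and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"trials": []}
    for trial, role in zip(trials, roles):
        tid = trial.trial_id or f"trial{len(manifest['trials']):02d}"
        write_eeg(trial.eeg, out / f"{tid}_eeg")
        write_envelope_csv(trial.env_left, out / f"{tid}_env_left.csv")
        write_envelope_csv(trial.env_right, out / f"{tid}_env_right.csv")
        manifest["trials"].append(
            {
                "trial_id": tid,
                "role": role,
                "schedule": [list(seg) for seg in trial.schedule.segments],
                "eeg": f"{tid}_eeg",
                "env_left": f"{tid}_env_left.csv",
                "env_right": f"{tid}_env_right.csv",
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_session(session_dir: str | Path) -> tuple[list[TrialData], list[str]]:
    """Read a session directory written by :func:`save_session`."""
    session_dir = Path(session_dir)
    manifest_path = session_dir / "manifest.json"
    if not manifest_path.exists():
        raise InvalidInputError(f"no manifest.json in {session_dir}")
    manifest = json.loads(manifest_path.read_text())
    trials: list[TrialData] = []
    roles: list[str] = []
    for entry in manifest["trials"]:
        schedule = AttentionSchedule(
            [(float(a), float(b), str(s)) for a, b, s in entry["schedule"]]
        )
        trials.append(
            TrialData(
                eeg=read_eeg(session_dir / entry["eeg"]),
                env_left=read_envelope_csv(session_dir / entry["env_left"]),
                env_right=read_envelope_csv(session_dir / entry["env_right"]),
                schedule=schedule,
                trial_id=entry["trial_id"],
            )
        )
        roles.append(entry["role"])
    return trials, roles
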