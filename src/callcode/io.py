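"""Plain-text readers/writers for the pipeline's tables and WAV clips."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthgen import AudioClip, BehaviorSession, RecordingSession, UnitRecord

__all__ = [
    "checksum",
    "read_tsv",
    "read_wav",
    "write_behavior_session",
    "write_recording_session",
    "write_tsv",
    "write_wav",
]


def write_tsv(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_wav(clip: AudioClip, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate_hz, (x * 32767).astype(np.int16))
    return path


def read_wav(path: Path | str, stimulus_id: str = "") -> AudioClip:
    sr, x = wavfile.read(path)
    if x.ndim != 1:
        raise ValueError("mono WAV required")
    if x.dtype.kind == "i":
        x = x.astype(float) / np.iinfo(x.dtype).max
    return AudioClip(samples=x, sample_rate_hz=int(sr), stimulus_id=stimulus_id or Path(path).stem)


def write_behavior_session(session: BehaviorSession, out_dir: Path | str) -> list[Path]:
    out = Path(out_dir)
    paths = [
        write_tsv(session.trials, out / f"{session.bird_id}_trials.tsv"),
        write_tsv(session.responses, out / f"{session.bird_id}_responses.tsv"),
    ]
    gt = out / f"{session.bird_id}_ground_truth.json"
    gt.parent.mkdir(parents=True, exist_ok=True)
    gt.write_text(json.dumps(session.ground_truth, indent=2))
    paths.append(gt)
    return paths


def _units_frame(units: list[UnitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "session_id": u.session_id,
                "class_truth": u.class_truth,
                "trough_to_peak_ms_truth": u.trough_to_peak_ms_truth,
                "n_spikes": int(u.spike_times_s.size),
                **{k: v for k, v in u.qc.items()},
            }
            for u in units
        ]
    )


def write_recording_session(session: RecordingSession, out_dir: Path | str) -> list[Path]:
    out = Path(out_dir)
    sid = session.session_id
    spikes = pd.DataFrame(
        [
            {"unit_id": u.unit_id, "spike_time_s": t}
            for u in session.units
            for t in u.spike_times_s
        ]
    )
    waveforms = pd.DataFrame(
        {u.unit_id: u.mean_waveform for u in session.units}
    )
    paths = [
        write_tsv(session.trials, out / f"{sid}_trials.tsv"),
        write_tsv(spikes, out / f"{sid}_spikes.tsv"),
        write_tsv(_units_frame(session.units), out / f"{sid}_units.tsv"),
        write_tsv(waveforms, out / f"{sid}_waveforms.tsv"),
    ]
    gt = out / f"{sid}_ground_truth.json"
    gt.write_text(json.dumps(session.ground_truth, indent=2))
    paths.append(gt)
    return paths


def checksum(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
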