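"""On-disk formats: the HDF5 session container and PCM WAV stimuli.

HDF5 layout per session file::

    /meta        (group attrs: frame_rate_hz, day_index, plane_id)
    /traces      float  (n_neurons, n_frames)   raw fluorescence, a.u.
    /events      int    (n_events, 2)           onset_frame, stimulus_id
    /locomotion  bool   (n_frames,)
    /roi_stats   float  (n_neurons, 2)          compactness, skewness

Schema validation happens on read, before any computation touches the
data.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .preprocess import SessionRecording
from .synth import StimulusSet

__all__ = ["write_session", "read_session", "write_stimuli_wav", "read_wav"]

_REQUIRED = ("traces", "events", "locomotion", "roi_stats")


def write_session(path: str | Path, session: SessionRecording) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["frame_rate_hz"] = float(session.frame_rate_hz)
        meta.attrs["day_index"] = int(session.day_index)
        meta.attrs["plane_id"] = str(session.plane_id)
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("events", data=session.events.astype(np.int64))
        f.create_dataset("locomotion", data=session.locomotion_mask.astype(bool))
        roi = session.roi_stats if session.roi_stats is not None else np.full(
            (session.n_neurons, 2), np.nan
        )
        f.create_dataset("roi_stats", data=np.asarray(roi, dtype=float))


def read_session(path: str | Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise ValueError(f"{path}: missing /meta group")
        for name in _REQUIRED:
            if name not in f:
                raise ValueError(f"{path}: missing dataset /{name}")
        meta = f["meta"].attrs
        for key in ("frame_rate_hz", "day_index"):
            if key not in meta:
                raise ValueError(f"{path}: /meta missing attribute {key}")
        rate = meta["frame_rate_hz"]
        if not np.issubdtype(np.asarray(rate).dtype, np.floating) and not np.issubdtype(
            np.asarray(rate).dtype, np.integer
        ):
            raise ValueError(f"{path}: frame_rate_hz must be numeric, got {rate!r}")
        traces = f["traces"][()]
        events = f["events"][()]
        if events.size and events[:, 0].max() >= traces.shape[1]:
            raise ValueError(f"{path}: event onset beyond trace length")
        return SessionRecording(
            traces=traces,
            frame_rate_hz=float(rate),
            events=events,
            locomotion_mask=f["locomotion"][()],
            day_index=int(meta["day_index"]),
            plane_id=str(meta.get("plane_id", "plane0")),
            roi_stats=f["roi_stats"][()],
        )


def write_stimuli_wav(out_dir: str | Path, stimuli: StimulusSet) -> list[Path]:
    """Write each waveform as 16-bit PCM WAV named after its label."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for w, label in zip(stimuli.waveforms, stimuli.labels):
        peak = np.abs(w).max()
        scaled = (w / peak * 32767 if peak > 0 else w).astype(np.int16)
        p = out / f"{label}.wav"
        wavfile.write(p, int(stimuli.sample_rate_hz), scaled)
        paths.append(p)
    return paths


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a PCM (16/24/32-bit) or float WAV as float amplitude in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, float(rate)
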