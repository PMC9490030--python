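"""File formats: flat-binary recordings with YAML sidecars, and CSV tables
for events, targets and judgments.

Recordings are 16-bit signed little-endian, interleaved by channel
(sample-major frames), with a sidecar ``<name>.yaml`` holding channel count,
sampling rate, tetrode map, scale factor and sample count. Tables are UTF-8
CSV with a header row; times in ms with 6 decimals, sample indices as
integers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ChannelMismatchError, MetadataError, TruncatedFileError
from .infer import CollisionTarget
from .signal import RecordingSegment
from .simulate import SimGroundTruth, StimulusEvent

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_schedule",
    "read_schedule",
    "write_targets",
    "write_judgments",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def write_recording(path, segment: RecordingSegment, scale: float | None = None) -> None:
    """Write a recording as int16-LE flat binary plus a YAML sidecar.

    ``scale`` is the physical value of one integer step; integer-valued data
    with ``scale=1`` round-trips bit-identically.
    """
    path = Path(path)
    if scale is None:
        peak = float(np.abs(segment.samples).max()) if segment.samples.size else 1.0
        scale = 1.0 if peak <= 32000 and np.allclose(segment.samples, np.round(segment.samples)) else max(peak / 32000.0, 1e-12)
    ints = np.round(np.asarray(segment.samples, dtype=float) / scale)
    ints = np.clip(ints, -32768, 32767).astype("<i2")
    ints.tofile(path)
    meta = {
        "n_channels": int(segment.n_channels),
        "n_samples": int(segment.n_samples),
        "fs": float(segment.fs),
        "dtype": "int16-le",
        "scale": float(scale),
        "t0": int(segment.t0),
        "tetrodes": [list(t) for t in segment.tetrodes],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_recording(path) -> RecordingSegment:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"missing sidecar metadata {side}")
    try:
        meta = yaml.safe_load(side.read_text())
    except yaml.YAMLError as exc:
        raise MetadataError(f"unparseable sidecar metadata: {exc}") from exc
    if not isinstance(meta, dict):
        raise MetadataError("sidecar metadata is not a mapping")
    for key in ("n_channels", "n_samples", "fs", "scale", "tetrodes"):
        if key not in meta:
            raise MetadataError(f"sidecar metadata lacks key {key!r}")
    n_ch = int(meta["n_channels"])
    n_samp = int(meta["n_samples"])
    size = os.path.getsize(path)
    if n_ch <= 0 or size % (2 * n_ch) != 0:
        raise ChannelMismatchError(
            f"payload of {size} bytes is not a whole number of {n_ch}-channel frames"
        )
    if size != 2 * n_ch * n_samp:
        raise TruncatedFileError(
            f"expected {2 * n_ch * n_samp} bytes for {n_samp} samples x {n_ch} channels, found {size}"
        )
    ints = np.fromfile(path, dtype="<i2").reshape(n_samp, n_ch)
    return RecordingSegment(
        samples=ints.astype(float) * float(meta["scale"]),
        fs=float(meta["fs"]),
        tetrodes=[tuple(t) for t in meta["tetrodes"]],
        t0=int(meta.get("t0", 0)),
    )


def write_events(path, truth: SimGroundTruth) -> None:
    df = truth.events.copy()
    df["t_ms"] = df["t_ms"].round(6)
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegating message
        raise MetadataError(f"cannot read event table {path}: {exc}") from exc


def write_schedule(path, schedule: list[StimulusEvent], fs: float) -> None:
    pd.DataFrame(
        {
            "site": [s.site for s in schedule],
            "t_stim": [s.t_stim for s in schedule],
            "duration_ms": [round(s.duration_ms, 6) for s in schedule],
            "triggered_by": [s.triggered_by for s in schedule],
        }
    ).to_csv(path, index=False)


def read_schedule(path) -> list[StimulusEvent]:
    df = pd.read_csv(path)
    return [
        StimulusEvent(
            site=int(r.site),
            t_stim=int(r.t_stim),
            duration_ms=float(r.duration_ms),
            triggered_by=None if pd.isna(r.triggered_by) else float(r.triggered_by),
        )
        for r in df.itertuples()
    ]


def write_targets(path, targets: list[CollisionTarget], waveform_store: str | None = None) -> None:
    """One CSV row per target; median waveforms optionally to an ``.npz``."""
    rows = []
    for j, t in enumerate(targets):
        row = {
            "target": j,
            "tetrode": t.tetrode_id,
            "site": t.site,
            "protocol": t.protocol,
            "t_min_ms": round(t.t_min, 6),
            "t_max_ms": round(t.t_max, 6),
            "L_min_ms": round(t.L_min, 6),
            "L_max_ms": round(t.L_max, 6),
        }
        for c in range(4):
            row[f"u{c+1}"] = t.u[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if waveform_store is not None:
        np.savez(
            waveform_store,
            **{f"target_{j}": t.median_waveform for j, t in enumerate(targets)},
        )


def write_judgments(path, judgments: pd.DataFrame) -> None:
    df = judgments.copy()
    for col in ("jitter_ms", "latency_ms"):
        if col in df:
            df[col] = df[col].round(6)
    df.to_csv(path, index=False)
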