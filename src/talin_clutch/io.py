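"""Track tables and versioned result files.

Tracks travel as CSV with columns ``track_id, frame, t_s, x_nm, y_nm``
(interoperable with common tracker exports); results are written as
JSON carrying a schema id, the package version, a hash of the resolved
configuration and the seed, so any run can be reproduced from its
outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .sims import SpeckleTrack, TrackFormatError

__all__ = ["read_tracks", "write_tracks", "write_results", "config_hash"]

REQUIRED_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm"]
SCHEMA_ID = "talin-clutch/results-v1"


def read_tracks(
    path: str | Path,
    frame_interval: float | None = None,
    flow_axis: tuple = (1.0, 0.0),
    localization_sd: float = 18.6,
) -> list[SpeckleTrack]:
    """Read speckle tracks from CSV.

    Frames are re-sorted by time (with a warning) if stored shuffled;
    malformed rows are reported with their file line numbers; a missing
    column raises :class:`TrackFormatError` naming it.  If
    ``frame_interval`` is None it is inferred per track from the time
    stamps (and must be uniform).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing column(s) {missing}")
    bad = df.index[df[REQUIRED_COLUMNS].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:20]]  # header + 1-based
        raise TrackFormatError(
            f"{path}: {len(bad)} malformed row(s) at line(s) {lines}"
        )
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        if not grp["t_s"].is_monotonic_increasing:
            warnings.warn(
                f"track {tid}: frames out of order; re-sorting by time",
                stacklevel=2,
            )
            grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise TrackFormatError(f"track {tid}: needs >= 2 frames")
        fi = frame_interval if frame_interval is not None else float(t[1] - t[0])
        tracks.append(
            SpeckleTrack(
                id=str(tid),
                frame_interval=fi,
                t=t,
                x=grp["x_nm"].to_numpy(dtype=float),
                y=grp["y_nm"].to_numpy(dtype=float),
                flow_axis=tuple(flow_axis),
                localization_sd=localization_sd,
            )
        )
    return tracks


def write_tracks(tracks, path: str | Path) -> None:
    """Write tracks to the CSV interchange format (deterministic order)."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            rows.append(
                {
                    "track_id": tr.id,
                    "frame": i,
                    "t_s": tr.t[i],
                    "x_nm": tr.x[i],
                    "y_nm": tr.y[i],
                }
            )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def config_hash(config_dict: dict) -> str:
    """Stable hash of a resolved configuration dictionary."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sanitize(obj, flags: list):
    if isinstance(obj, dict):
        return {k: _sanitize(v, flags) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v, flags) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v, flags) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f) or math.isinf(f):
            flags.append("non_finite_values_as_null")
            return None
        return f
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _sanitize(obj.to_dict(orient="records"), flags)
    return obj


def write_results(
    results: dict,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a versioned, deterministically serialised results JSON.

    NaN/inf observables are serialised as null and flagged; the same
    results dictionary always produces byte-identical output.
    """
    flags: list = []
    payload = _sanitize(results, flags)
    doc = {
        "schema": SCHEMA_ID,
        "package_version": _package_version(),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "config": _sanitize(config, flags) if config is not None else None,
        "flags": sorted(set(flags)),
        "results": payload,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("talin-clutch")
    except Exception:  # pragma: no cover - not installed
        return "unknown"
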