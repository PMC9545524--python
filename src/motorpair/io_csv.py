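"""Plain-text (CSV) interchange for traces, manifests and analysis tables.

Schemas
-------
Trace file (one per particle): columns ``time_s``, ``position_nm``.
Manifest: ``trace_id``, ``file``, ``condition``, ``frame_dt``, ``pixel_nm``.
Segment table: one row per segment with trace id, frame span, velocity,
duration, displacement and state.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from motorpair.trace_analysis import (
    FRAME_DT,
    PIXEL_NM,
    SampledTrace,
    SegmentSet,
)

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
    "read_manifest",
    "segments_table",
]


def write_trace_csv(trace: SampledTrace, path: str | Path) -> None:
    """Write one trace as a two-column CSV (time_s, position_nm)."""
    pd.DataFrame(
        {"time_s": trace.times, "position_nm": trace.positions}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path, origin: str = "imported") -> SampledTrace:
    """Read a trace CSV; the frame interval is inferred from the time column."""
    df = pd.read_csv(path)
    for col in ("time_s", "position_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: a trace needs at least two frames")
    dts = np.diff(t)
    frame_dt = float(np.median(dts))
    if frame_dt <= 0 or np.any(np.abs(dts - frame_dt) > 1e-6 * max(1.0, frame_dt)):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return SampledTrace(
        df["position_nm"].to_numpy(dtype=float), frame_dt=frame_dt, origin=origin
    )


def write_manifest(
    entries: Sequence[dict],
    path: str | Path,
) -> None:
    """Write the trace manifest; entries need trace_id/file/condition keys."""
    df = pd.DataFrame(entries)
    required = {"trace_id", "file", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest entries missing keys: {sorted(missing)}")
    if "frame_dt" not in df.columns:
        df["frame_dt"] = FRAME_DT
    if "pixel_nm" not in df.columns:
        df["pixel_nm"] = PIXEL_NM
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trace_id", "file", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def segments_table(
    segsets: Iterable[tuple[object, SegmentSet]],
) -> pd.DataFrame:
    """Tidy per-segment table over (trace_id, SegmentSet) pairs."""
    rows = []
    for trace_id, segs in segsets:
        for k, s in enumerate(segs):
            rows.append(
                {
                    "trace_id": trace_id,
                    "segment": k,
                    "start_frame": s.start_frame,
                    "end_frame": s.end_frame,
                    "velocity_nm_per_s": s.velocity,
                    "duration_s": s.duration,
                    "displacement_nm": s.displacement,
                    "state": s.state,
                }
            )
    return pd.DataFrame(rows)
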