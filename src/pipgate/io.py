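"""File formats: trace CSV + JSON sidecar, event TSV, dataset CSV, image TIFF.

Traces are stored as two-column CSV (``time_ms,current_pA``) with an optional
JSON metadata sidecar (same path with ``.json`` appended) that embeds the
generator seed.  Event lists are TSV (``level, start_ms, duration_ms``).
Images are 16-bit grayscale TIFF, one file per channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .idealize import EventList
from .synth import ImagePair, Trace

__all__ = [
    "read_trace", "write_trace",
    "read_events", "write_events",
    "read_image_pair", "write_image_pair",
]


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_ms": trace.times, "current_pA": trace.samples}).to_csv(
        path, index=False, float_format="%.17g")
    if trace.metadata:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(trace.metadata, indent=2, default=str))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_ms", "current_pA"]
    if list(df.columns[:2]) != expected:
        missing = [c for c in expected if c not in df.columns]
        raise ValueError(f"trace CSV must have columns {expected}; missing {missing}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace must have at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_ms column must be strictly increasing")
    sidecar = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {"source": "unknown"}
    return Trace(sampling_interval=float(np.median(dt)),
                 samples=df["current_pA"].to_numpy(dtype=float), metadata=metadata)


def write_events(events: EventList, path) -> None:
    pd.DataFrame({
        "level": events.levels,
        "start_ms": events.starts,
        "duration_ms": events.durations,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    needed = {"level", "start_ms", "duration_ms"}
    if not needed.issubset(df.columns):
        raise ValueError(f"event TSV must have columns {sorted(needed)}")
    durations = df["duration_ms"].to_numpy(dtype=float)
    return EventList(levels=df["level"].to_numpy(dtype=int),
                     starts=df["start_ms"].to_numpy(dtype=float),
                     durations=durations, total_time=float(durations.sum()))


def write_image_pair(pair: ImagePair, path_ch1, path_ch2) -> None:
    tifffile.imwrite(path_ch1, pair.channel1.astype(np.uint16))
    tifffile.imwrite(path_ch2, pair.channel2.astype(np.uint16))


def read_image_pair(path_ch1, path_ch2) -> ImagePair:
    ch1 = tifffile.imread(path_ch1)
    ch2 = tifffile.imread(path_ch2)
    return ImagePair(channel1=ch1, channel2=ch2, ground_truth={"source": "file"})
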