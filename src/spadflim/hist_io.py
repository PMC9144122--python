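"""Plain-text histogram I/O.

Histograms are written as delimited text with a header line and
``bin_start_ns,count`` rows; simulation metadata (tres, tw, nw, n_pixel,
seed, ...) goes into a JSON sidecar next to the table so a histogram file
is always re-fittable on its own.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detector import Histogram

__all__ = ["write_histogram", "read_histogram", "sidecar_path"]

HEADER = "bin_start_ns,count"


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_histogram(
    path: str | Path, hist: Histogram, metadata: dict | None = None
) -> None:
    """Write ``bin_start_ns,count`` rows plus a JSON metadata sidecar."""
    path = Path(path)
    lines = [HEADER]
    starts = hist.bin_edges[:-1]
    lines += [f"{s:.10g},{c}" for s, c in zip(starts, hist.counts)]
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "tres_ns": hist.tres_ns,
        "tw_ns": hist.tw_ns,
        "n_dropped": hist.n_dropped,
    }
    if metadata:
        meta.update(metadata)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_histogram(path: str | Path) -> Histogram:
    """Read a histogram table, using the JSON sidecar when present."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0].strip() != HEADER:
        raise ValueError(f"{path}: expected header line {HEADER!r}")
    starts, counts = [], []
    for ln in lines[1:]:
        s, c = ln.split(",")
        starts.append(float(s))
        counts.append(int(c))
    starts_arr = np.asarray(starts)
    counts_arr = np.asarray(counts, dtype=np.int64)
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        tres = float(meta["tres_ns"])
        tw = float(meta["tw_ns"])
        n_dropped = int(meta.get("n_dropped", 0))
    else:
        if starts_arr.size < 2:
            raise ValueError(f"{path}: need >= 2 bins to infer tres without sidecar")
        tres = float(starts_arr[1] - starts_arr[0])
        tw = float(starts_arr[-1] + tres)
        n_dropped = 0
    return Histogram(counts=counts_arr, tres_ns=tres, tw_ns=tw, n_dropped=n_dropped)
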