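"""Tabular text I/O for spike events, rasters and weight snapshots.

Event files are plain text (inspectable and diffable): one event per line,
comma- or whitespace-separated integer columns ``tick, channel[, delay]``,
``#`` comments allowed.  Events are sorted by tick on write; unsorted
input is accepted and sorted on read.  Rasters are written as
``tick,core,neuron`` CSV.
"""

from __future__ import annotations

import io
import re

import numpy as np

__all__ = ["read_events", "write_events", "write_raster", "read_raster",
           "write_weights", "EventFormatError"]

_SPLIT = re.compile(r"[,\s]+")


class EventFormatError(ValueError):
    """Malformed event file; the message carries the line number."""


def read_events(path_or_buf) -> np.ndarray:
    """Read events as an (n, 2) or (n, 3) int array sorted by tick."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
        name = "<buffer>"
    else:
        with open(path_or_buf) as f:
            lines = f.read().splitlines()
        name = str(path_or_buf)
    rows, width = [], None
    for lineno, line in enumerate(lines, 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = _SPLIT.split(line)
        if len(fields) not in (2, 3):
            raise EventFormatError(f"{name}:{lineno}: expected 2-3 columns, "
                                   f"got {len(fields)}")
        try:
            vals = [int(v) for v in fields]
        except ValueError:
            raise EventFormatError(f"{name}:{lineno}: non-integer field in "
                                   f"{line!r}") from None
        if vals[0] < 0:
            raise EventFormatError(f"{name}:{lineno}: negative tick {vals[0]}")
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise EventFormatError(f"{name}:{lineno}: inconsistent column count")
        rows.append(vals)
    if not rows:
        return np.zeros((0, 2), dtype=np.int64)
    ev = np.array(rows, dtype=np.int64)
    return ev[np.argsort(ev[:, 0], kind="stable")]


def write_events(path_or_buf, events: np.ndarray) -> None:
    """Write events sorted by tick; round-trips through :func:`read_events`."""
    events = np.asarray(events, dtype=np.int64)
    if events.ndim != 2 or events.shape[1] not in (2, 3):
        raise EventFormatError("events must be (n, 2) or (n, 3)")
    events = events[np.argsort(events[:, 0], kind="stable")]
    _write_table(path_or_buf, events, "tick,channel" +
                 (",delay" if events.shape[1] == 3 else ""))


def write_raster(path_or_buf, raster: np.ndarray) -> None:
    _write_table(path_or_buf, np.asarray(raster, dtype=np.int64),
                 "tick,core,neuron")


def read_raster(path_or_buf) -> np.ndarray:
    ev = read_events(path_or_buf)
    return ev.reshape(-1, 3) if ev.size else np.zeros((0, 3), dtype=np.int64)


def write_weights(path_or_buf, weights: np.ndarray) -> None:
    """One weight slot per line: slot,weight."""
    w = np.asarray(weights, dtype=np.int64)
    table = np.column_stack([np.arange(len(w)), w])
    _write_table(path_or_buf, table, "slot,weight")


def _write_table(path_or_buf, table: np.ndarray, header: str) -> None:
    buf = io.StringIO()
    buf.write(f"# {header}\n")
    for row in table:
        buf.write(",".join(str(int(v)) for v in row) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as f:
            f.write(text)
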