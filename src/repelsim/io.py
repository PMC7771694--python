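"""Readers and writers for event logs, trajectories, summaries and histograms.

Event times are written in seconds with three decimal places, which renders
multiples of the 0.03 s step exactly, so a write-then-read round trip is
lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .engine import EventRecord, ReplicateResult
from .outcomes import ExperimentSummary, HistogramSpec

__all__ = [
    "write_events",
    "read_events",
    "write_trajectories",
    "write_summary",
    "write_histogram",
]

_EVENT_HEADER = ["replicate", "mosquito_id", "fate", "time_s"]


def write_events(results: Iterable[ReplicateResult], path) -> Path:
    """Write all events of an experiment as CSV (header row, UTF-8, '.' decimal)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_EVENT_HEADER)
        for rep in results:
            for ev in rep.events:
                w.writerow([ev.replicate, ev.mosquito_id, ev.fate, f"{ev.time:.3f}"])
    return path


def read_events(path) -> List[EventRecord]:
    """Read an events CSV back into records; malformed rows name the line."""
    path = Path(path)
    events: List[EventRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _EVENT_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                events.append(
                    EventRecord(
                        replicate=int(row[0]),
                        mosquito_id=int(row[1]),
                        fate=row[2],
                        time=float(row[3]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed event on line {lineno}: {row!r}") from exc
    return events


def write_trajectories(results: Sequence[ReplicateResult], path, dt: float) -> Path:
    """Write per-step positions (only for results run with trajectory recording)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["replicate", "mosquito_id", "step", "x_cm", "y_cm", "z_cm"])
        for i, rep in enumerate(results):
            if rep.trajectories is None:
                raise ValueError(f"replicate {i} has no recorded trajectory")
            n_steps, n, _ = rep.trajectories.shape
            for m in range(n):
                for k in range(n_steps):
                    x, y, z = rep.trajectories[k, m]
                    w.writerow([rep.events[m].replicate, m, k, f"{x:.2f}", f"{y:.2f}", f"{z:.2f}"])
    return path


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_summary(summary: ExperimentSummary, path, extra: Optional[dict] = None) -> Path:
    """Write an ExperimentSummary (plus scenario echo / seed) as JSON."""
    path = Path(path)
    doc = {k: _jsonable(v) for k, v in summary.to_dict().items()}
    if extra:
        doc.update({k: _jsonable(v) for k, v in extra.items()})
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path


def write_histogram(counts: np.ndarray, spec: HistogramSpec, path) -> Path:
    """Write binned event counts as CSV (bin_start_s, bin_end_s, count)."""
    path = Path(path)
    edges = spec.edges
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_start_s", "bin_end_s", "count"])
        for i, c in enumerate(counts):
            w.writerow([f"{edges[i]:.3f}", f"{edges[i + 1]:.3f}", int(c)])
    return path
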