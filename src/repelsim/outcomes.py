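"""Outcome measurements: time-to-event summaries, histograms, hut-trial indicators.

Summaries pool mosquitoes across replicates by default (the per-replicate-mean
alternative is available via ``by_replicate=True``, in which case the mean and
SD are taken over replicate means).  Toxicity is deliberately not computed:
the repellent is assumed to repel but not kill.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .engine import EventRecord, ReplicateResult

__all__ = [
    "ExperimentSummary",
    "HistogramSpec",
    "flatten_events",
    "summarize",
    "histogram",
    "deterrence",
    "excito_repellency",
]


@dataclass(frozen=True)
class ExperimentSummary:
    """Aggregated fates and time statistics of one experiment.

    Counts pool all mosquitoes of all replicates; time statistics are over the
    mosquitoes of the corresponding fate only and are ``None`` when that fate
    did not occur (SD additionally requires at least two events).
    """

    n_total: int
    n_landed: int
    n_repelled: int
    n_censored: int
    landing_rate: float
    repelling_rate: float
    mean_landing_time: Optional[float]
    sd_landing_time: Optional[float]
    min_landing_time: Optional[float]
    max_landing_time: Optional[float]
    mean_repelling_time: Optional[float]
    sd_repelling_time: Optional[float]
    min_repelling_time: Optional[float]
    max_repelling_time: Optional[float]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class HistogramSpec:
    """Half-open time bins ``[k*w, (k+1)*w)`` covering ``[0, t_max]``."""

    bin_width: float = 2.0
    t_max: float = 1800.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.t_max / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width


def flatten_events(results: Iterable[ReplicateResult]) -> List[EventRecord]:
    """All events of an experiment in replicate order."""
    return [ev for rep in results for ev in rep.events]


def _time_stats(times: np.ndarray) -> tuple:
    if times.size == 0:
        return None, None, None, None
    mean = float(np.mean(times))
    sd = float(np.std(times, ddof=1)) if times.size > 1 else None
    return mean, sd, float(np.min(times)), float(np.max(times))


def summarize(events: Sequence[EventRecord], by_replicate: bool = False) -> ExperimentSummary:
    """Counts, rates and landing/repelling time statistics over an event list.

    With ``by_replicate=True`` the time mean/SD are computed over the
    per-replicate means (replicates without the fate are skipped); min/max
    remain pooled.
    """
    events = list(events)
    if not events:
        raise ValueError("summarize requires a non-empty event list")
    n_total = len(events)
    landed = [ev for ev in events if ev.fate == "landed"]
    repelled = [ev for ev in events if ev.fate == "repelled"]
    n_landed, n_repelled = len(landed), len(repelled)
    n_censored = n_total - n_landed - n_repelled

    stats = {}
    for label, evs in (("landing", landed), ("repelling", repelled)):
        times = np.array([ev.time for ev in evs], dtype=float)
        mean, sd, tmin, tmax = _time_stats(times)
        if by_replicate and times.size:
            reps = np.array([ev.replicate for ev in evs])
            rep_means = np.array([times[reps == r].mean() for r in np.unique(reps)])
            mean = float(rep_means.mean())
            sd = float(rep_means.std(ddof=1)) if rep_means.size > 1 else None
        stats[label] = (mean, sd, tmin, tmax)

    return ExperimentSummary(
        n_total=n_total,
        n_landed=n_landed,
        n_repelled=n_repelled,
        n_censored=n_censored,
        landing_rate=n_landed / n_total,
        repelling_rate=n_repelled / n_total,
        mean_landing_time=stats["landing"][0],
        sd_landing_time=stats["landing"][1],
        min_landing_time=stats["landing"][2],
        max_landing_time=stats["landing"][3],
        mean_repelling_time=stats["repelling"][0],
        sd_repelling_time=stats["repelling"][1],
        min_repelling_time=stats["repelling"][2],
        max_repelling_time=stats["repelling"][3],
    )


def histogram(events: Sequence[EventRecord], fate: str, spec: HistogramSpec = HistogramSpec()) -> np.ndarray:
    """Counts of events of one fate per half-open bin; totals conserve the fate count."""
    if fate not in ("landed", "repelled", "censored"):
        raise ValueError(f"unknown fate: {fate!r}")
    times = np.array([ev.time for ev in events if ev.fate == fate], dtype=float)
    counts = np.zeros(spec.n_bins, dtype=int)
    if times.size:
        idx = np.floor(times / spec.bin_width).astype(int)
        idx = np.clip(idx, 0, spec.n_bins - 1)  # an event at exactly t_max falls in the last bin
        np.add.at(counts, idx, 1)
    return counts


def deterrence(treatment: ExperimentSummary, control: ExperimentSummary) -> float:
    """Hut-trial deterrence: relative reduction of mosquitoes remaining in the cage.

    "Remaining" counts mosquitoes neither landed nor expelled at the end
    (censored).  Negative values are reported as computed.
    """
    control_remaining = control.n_censored
    treatment_remaining = treatment.n_censored
    if control_remaining == 0:
        raise ZeroDivisionError("deterrence undefined: no mosquitoes remaining in control")
    return (control_remaining - treatment_remaining) / control_remaining


def excito_repellency(treatment: ExperimentSummary, control: ExperimentSummary) -> Tuple[float, float, float]:
    """Proportions of mosquitoes driven to the far end of the cage.

    Returns ``(treatment_rate, control_rate, difference)``.
    """
    if treatment.n_total == 0 or control.n_total == 0:
        raise ValueError("excito_repellency requires non-empty experiments")
    tr = treatment.repelling_rate
    cr = control.repelling_rate
    return tr, cr, tr - cr
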