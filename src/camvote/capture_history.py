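"""Search effort and species detection histories for ecological re-use.

Consensus records plus camera operation dates convert into the inputs that
occupancy and relative-abundance analyses expect: a site × time-bin matrix
of active trap-days, and per-species site × time-bin detection histories
(presence/absence or event counts). Time bins are half-open ``[start, end)``
spans of whole calendar days in the cameras' local zone (UTC+3, no DST),
so a midnight event falls in exactly one bin. Days not covered by any
operation interval count as zero effort; detections landing on zero-effort
site/bins are flagged, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .tables_io import ConsensusRecord, OperationInterval
from .vocabulary import canonical_species

__all__ = [
    "TimeBins",
    "EffortMatrix",
    "DetectionHistory",
    "build_effort",
    "build_history",
    "relative_abundance",
]


@dataclasses.dataclass(frozen=True)
class TimeBins:
    """Contiguous half-open calendar-day bins covering a study window."""

    start: _dt.date
    end: _dt.date  # exclusive
    days_per_bin: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("time window is empty")
        if self.days_per_bin < 1:
            raise ValueError("days_per_bin must be >= 1")

    @property
    def n_bins(self) -> int:
        total = (self.end - self.start).days
        return -(-total // self.days_per_bin)

    def labels(self) -> list[str]:
        return [
            (self.start + _dt.timedelta(days=i * self.days_per_bin)).isoformat()
            for i in range(self.n_bins)
        ]

    def index_of(self, day: _dt.date) -> int | None:
        """Bin index containing ``day``, or None outside the window."""
        offset = (day - self.start).days
        if offset < 0 or day >= self.end:
            return None
        return offset // self.days_per_bin

    def bin_length_days(self, idx: int) -> int:
        start = self.start + _dt.timedelta(days=idx * self.days_per_bin)
        end = min(start + _dt.timedelta(days=self.days_per_bin), self.end)
        return (end - start).days


@dataclasses.dataclass(frozen=True)
class EffortMatrix:
    """Active trap-days per site and time bin."""

    frame: pd.DataFrame  # index: site_id, columns: bin start dates
    bins: TimeBins

    @property
    def total_trap_days(self) -> float:
        return float(self.frame.to_numpy().sum())


@dataclasses.dataclass(frozen=True)
class DetectionHistory:
    """Detections of one species per site and time bin.

    ``frame`` holds 0/1 presences or event counts on the same grid as the
    effort matrix; ``orphans`` lists (site, bin label) cells that received
    detections despite zero recorded effort.
    """

    species: str
    mode: str
    frame: pd.DataFrame
    orphans: tuple[tuple[str, str], ...] = ()


def build_effort(
    intervals: Iterable[OperationInterval], bins: TimeBins
) -> EffortMatrix:
    """Count active trap-days per site and bin.

    A day counts once per site if covered by at least one interval
    (overlapping SD-card intervals never double-count), so effort is
    invariant under splitting an interval into contiguous pieces.
    """
    intervals = list(intervals)
    sites = sorted({iv.site_id for iv in intervals})
    grid = np.zeros((len(sites), bins.n_bins), dtype=int)
    site_pos = {s: i for i, s in enumerate(sites)}
    active: dict[str, set[_dt.date]] = {s: set() for s in sites}
    for iv in intervals:
        day = iv.start_date
        while day <= iv.end_date:
            active[iv.site_id].add(day)
            day += _dt.timedelta(days=1)
    for site, days in active.items():
        for day in days:
            idx = bins.index_of(day)
            if idx is not None:
                grid[site_pos[site], idx] += 1
    frame = pd.DataFrame(grid, index=pd.Index(sites, name="site"), columns=bins.labels())
    return EffortMatrix(frame=frame, bins=bins)


def build_history(
    records: Iterable[ConsensusRecord],
    effort: EffortMatrix,
    species: str,
    mode: Literal["presence", "counts"] = "presence",
) -> DetectionHistory:
    """Detection history for one species on the effort grid.

    ``presence`` mode marks 1 where at least one consensus record of the
    species falls in a site/bin; ``counts`` mode counts capture events.
    Records at site/bins with zero effort are kept and flagged in
    ``orphans``. Records outside the time window or at sites absent from
    the effort matrix are ignored.
    """
    species = canonical_species(species)
    if mode not in ("presence", "counts"):
        raise ValueError(f"mode must be 'presence' or 'counts', got {mode!r}")
    bins = effort.bins
    frame = pd.DataFrame(
        np.zeros(effort.frame.shape, dtype=int),
        index=effort.frame.index,
        columns=effort.frame.columns,
    )
    labels = list(effort.frame.columns)
    orphans: list[tuple[str, str]] = []
    for rec in records:
        if rec.species != species:
            continue
        site = rec.metadata.site_id
        if site not in frame.index:
            continue
        idx = bins.index_of(rec.metadata.datetime.date())
        if idx is None:
            continue
        frame.loc[site, labels[idx]] += 1
        if effort.frame.loc[site, labels[idx]] == 0:
            orphans.append((site, labels[idx]))
    if mode == "presence":
        frame = (frame > 0).astype(int)
    return DetectionHistory(
        species=species,
        mode=mode,
        frame=frame,
        orphans=tuple(sorted(set(orphans))),
    )


def relative_abundance(history: DetectionHistory, effort: EffortMatrix) -> pd.Series:
    """Per-site capture-event rate, events per 100 trap-days.

    Requires a counts-mode history; sites with zero total effort are
    dropped. Raises if no site has any effort.
    """
    if history.mode != "counts":
        raise ValueError("relative abundance needs a counts-mode history")
    trap_days = effort.frame.sum(axis=1)
    events = history.frame.sum(axis=1)
    keep = trap_days > 0
    if not keep.any():
        raise ValueError("no site has positive search effort")
    rai = 100.0 * events[keep] / trap_days[keep]
    rai.name = f"rai_{history.species}"
    return rai
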