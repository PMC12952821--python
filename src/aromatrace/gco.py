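"""Panel-consensus reduction of GC-olfactometry sniffing logs.

Each trained sniffer, in duplicate runs, records the onset and
disappearance retention times of every perceived odor, a free-text
descriptor, and the maximum perceived intensity (Imax) on a 0–5 scale.
Events from all sniffers are grouped in retention time by
single-linkage clustering; a cluster becomes a valid aroma-active
region only when at least ``min_detectors`` distinct sniffers (default
3, a panel majority of 5) contributed to it.  A sniffer votes once: the
replicates of one sniffer are first averaged, then the region intensity
is the arithmetic mean of the per-sniffer Imax values.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Sequence

from .errors import ValidationError

__all__ = ["SnifferEvent", "AromaRegion", "cluster_events", "consensus_regions", "read_events"]


@dataclass(frozen=True)
class SnifferEvent:
    """One perceived odor in one sniffer's run."""

    sniffer_id: str
    replicate: int
    rt_onset: float
    rt_end: float
    descriptor: str
    imax: float

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(f"field 'replicate' must be >= 1, got {self.replicate}")
        if not self.rt_onset < self.rt_end:
            raise ValidationError(
                f"field 'rt_onset' must precede rt_end ({self.rt_onset} vs {self.rt_end})"
            )
        if not (0.0 <= self.imax <= 5.0):
            raise ValidationError(f"field 'imax' must lie in [0, 5], got {self.imax}")

    @property
    def rt_center(self) -> float:
        return 0.5 * (self.rt_onset + self.rt_end)


@dataclass(frozen=True)
class AromaRegion:
    """A panel-consensus odor-active retention-time region."""

    rt_center: float
    rt_lo: float
    rt_hi: float
    consensus_descriptor: str
    mean_imax: float
    n_detectors: int

    def __post_init__(self):
        if not (self.rt_lo <= self.rt_center <= self.rt_hi):
            raise ValidationError("field 'rt_center' must lie within [rt_lo, rt_hi]")
        if not (0.0 <= self.mean_imax <= 5.0):
            raise ValidationError(f"field 'mean_imax' must lie in [0, 5], got {self.mean_imax}")


def cluster_events(
    events: Sequence[SnifferEvent], rt_window: float = 0.2
) -> list[list[SnifferEvent]]:
    """Single-linkage grouping of events on their rt centers.

    In one dimension single linkage with link distance ``rt_window``
    reduces to: sort by center and cut wherever the gap between
    neighbouring centers exceeds the window.  Every event lands in
    exactly one cluster.
    """
    if not events:
        raise ValidationError("field 'events' must be non-empty")
    if rt_window <= 0:
        raise ValidationError(f"field 'rt_window' must be > 0, got {rt_window}")
    ordered = sorted(events, key=lambda e: (e.rt_center, e.sniffer_id, e.replicate))
    clusters: list[list[SnifferEvent]] = [[ordered[0]]]
    for prev, ev in zip(ordered, ordered[1:]):
        if ev.rt_center - prev.rt_center <= rt_window:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    return clusters


def _normalize_descriptor(text: str) -> str:
    return " ".join(text.split()).lower()


def consensus_regions(
    events: Sequence[SnifferEvent],
    min_detectors: int = 3,
    rt_window: float = 0.2,
) -> list[AromaRegion]:
    """Reduce raw events to valid aroma-active regions.

    Clusters with fewer than ``min_detectors`` distinct sniffers are
    dropped.  The consensus descriptor is the modal normalized
    descriptor, ties broken lexicographically; descriptor disagreement
    never rejects a region, it only affects the label.
    """
    if min_detectors < 1:
        raise ValidationError(f"field 'min_detectors' must be >= 1, got {min_detectors}")
    regions = []
    for cluster in cluster_events(events, rt_window=rt_window):
        by_sniffer: dict[str, list[SnifferEvent]] = defaultdict(list)
        for ev in cluster:
            by_sniffer[ev.sniffer_id].append(ev)
        if len(by_sniffer) < min_detectors:
            continue
        per_sniffer_imax = [mean(e.imax for e in evs) for evs in by_sniffer.values()]
        votes = Counter(_normalize_descriptor(e.descriptor) for e in cluster)
        best_count = max(votes.values())
        # ties broken lexicographically (smallest string wins)
        descriptor = min(d for d, c in votes.items() if c == best_count)
        regions.append(
            AromaRegion(
                rt_center=mean(e.rt_center for e in cluster),
                rt_lo=min(e.rt_onset for e in cluster),
                rt_hi=max(e.rt_end for e in cluster),
                consensus_descriptor=descriptor,
                mean_imax=mean(per_sniffer_imax),
                n_detectors=len(by_sniffer),
            )
        )
    return regions


def read_events(path: str | Path) -> list[SnifferEvent]:
    """Read a sniffer event log CSV.

    Columns: ``sniffer_id,replicate,rt_onset_min,rt_end_min,descriptor,imax``.
    """
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SnifferEvent(
                    sniffer_id=row["sniffer_id"],
                    replicate=int(row["replicate"]),
                    rt_onset=float(row["rt_onset_min"]),
                    rt_end=float(row["rt_end_min"]),
                    descriptor=row["descriptor"],
                    imax=float(row["imax"]),
                )
            )
    return out
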