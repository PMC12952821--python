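"""Retention-index calibration and odor-activity-value arithmetic.

The linear (temperature-programmed) retention index normalizes a
compound's retention time against an n-alkane ladder (C7–C30):

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))

for the two alkanes bracketing ``rt``.  The odor activity value is the
concentration divided by the compound's odor threshold; a compound with
no published threshold (ND) is assigned OAV 0 by the convention of the
source tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InvalidThresholdError, LadderRangeError, ValidationError
from .types import ND, NDType

__all__ = ["AlkaneLadder", "kovats_ri", "compute_oav", "read_alkane_ladder"]


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of the n-alkane calibration series.

    ``entries`` maps carbon number (7–30) to retention time in minutes;
    retention times must increase strictly with carbon number.
    """

    entries: Mapping[int, float]

    def __post_init__(self):
        items = sorted((int(n), float(rt)) for n, rt in self.entries.items())
        if len(items) < 2:
            raise ValidationError("field 'entries': ladder needs at least two alkanes")
        for n, _ in items:
            if not (7 <= n <= 30):
                raise ValidationError(f"field 'entries': carbon number {n} outside 7..30")
        for (n0, t0), (n1, t1) in zip(items, items[1:]):
            if t1 <= t0:
                raise ValidationError(
                    f"field 'entries': rt must increase strictly with carbon number "
                    f"(C{n0}={t0}, C{n1}={t1})"
                )
        object.__setattr__(self, "entries", dict(items))

    @property
    def carbons(self) -> list[int]:
        return list(self.entries)

    @property
    def rt_span(self) -> tuple[float, float]:
        rts = list(self.entries.values())
        return rts[0], rts[-1]


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Linear retention index of ``rt`` against the ladder.

    Piecewise linear and monotone; each ladder alkane maps exactly to
    100·n.  Retention times outside the ladder span raise
    :class:`LadderRangeError` — no extrapolation.
    """
    lo, hi = ladder.rt_span
    if not (lo <= rt <= hi):
        raise LadderRangeError(
            f"rt {rt} min outside ladder span [{lo}, {hi}] min; no extrapolation"
        )
    items = list(ladder.entries.items())
    for (n0, t0), (n1, t1) in zip(items, items[1:]):
        if t0 <= rt <= t1:
            return 100.0 * (n0 + (n1 - n0) * (rt - t0) / (t1 - t0))
    raise AssertionError("unreachable: rt inside span must be bracketed")


def compute_oav(concentration: float, threshold: float | NDType) -> float:
    """Odor activity value, with the ND-threshold convention.

    A numeric threshold of exactly zero is a data error, distinct from
    the ND sentinel (which yields OAV 0).
    """
    if concentration < 0:
        raise ValidationError(f"field 'concentration' must be >= 0, got {concentration!r}")
    if isinstance(threshold, NDType):
        return 0.0
    if threshold == 0:
        raise InvalidThresholdError("numeric odor threshold of 0 is invalid (use ND)")
    if threshold < 0:
        raise ValidationError(f"field 'odor_threshold' must be > 0 or ND, got {threshold!r}")
    return concentration / threshold


def read_alkane_ladder(path: str | Path) -> AlkaneLadder:
    """Read a ``carbon_number,rt_min`` CSV into an AlkaneLadder."""
    df = pd.read_csv(path)
    return AlkaneLadder(dict(zip(df["carbon_number"].astype(int), df["rt_min"].astype(float))))
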