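"""Cross-stage compound identity matching and Venn partitioning.

Compound identity across the three stage tables is decided by canonical
name (after synonym resolution); when both members of a name match
carry a retention index, an RI difference beyond ``ri_tolerance`` is
flagged as a warning but does not break the match — many table rows
have no RI at all, and the nominal match is authoritative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from .errors import ValidationError
from .types import Stage, StageTable, SynonymTable

__all__ = ["SUBSET_LABELS", "StageOverlap", "RIConflict", "match_across_stages", "write_overlap"]

#: The seven non-empty cells of the three-set Venn partition.
SUBSET_LABELS = (
    "LEAF_only",
    "PY_only",
    "SMOKE_only",
    "LEAF_PY",
    "LEAF_SMOKE",
    "PY_SMOKE",
    "ALL",
)


@dataclass(frozen=True)
class RIConflict:
    """A name-matched pair whose retention indices disagree."""

    canonical_name: str
    stage_a: Stage
    stage_b: Stage
    ri_a: float
    ri_b: float


@dataclass(frozen=True)
class StageOverlap:
    """Venn partition of compound names over the three stages."""

    partition: dict[str, tuple[str, ...]]
    ri_conflicts: tuple[RIConflict, ...] = field(default=())

    def __post_init__(self):
        missing = [lab for lab in SUBSET_LABELS if lab not in self.partition]
        if missing:
            raise ValidationError(f"field 'partition' missing subset label(s) {missing}")
        seen: set[str] = set()
        for label in SUBSET_LABELS:
            names = set(self.partition[label])
            if names & seen:
                raise ValidationError(
                    f"field 'partition': cells are not disjoint at {label!r}"
                )
            seen |= names

    def subset(self, label: str) -> tuple[str, ...]:
        return self.partition[label]

    @property
    def all_names(self) -> set[str]:
        return {n for names in self.partition.values() for n in names}


def match_across_stages(
    leaf: StageTable,
    py: StageTable,
    smoke: StageTable,
    synonyms: SynonymTable | None = None,
    ri_tolerance: float = 30.0,
) -> StageOverlap:
    """Partition the union of compounds into the seven Venn cells."""
    if ri_tolerance < 0:
        raise ValidationError(f"field 'ri_tolerance' must be >= 0, got {ri_tolerance}")

    def names_of(t: StageTable) -> dict[str, object]:
        out = {}
        for rec in t:
            name = rec.canonical_name
            if synonyms is not None:
                name = synonyms.resolve(name)
            out[name] = rec
        return out

    by_stage = {Stage.LEAF: names_of(leaf), Stage.PYROLYSIS: names_of(py), Stage.SMOKE: names_of(smoke)}
    L, P, S = (set(by_stage[s]) for s in (Stage.LEAF, Stage.PYROLYSIS, Stage.SMOKE))
    partition = {
        "ALL": L & P & S,
        "LEAF_PY": (L & P) - S,
        "LEAF_SMOKE": (L & S) - P,
        "PY_SMOKE": (P & S) - L,
        "LEAF_only": L - P - S,
        "PY_only": P - L - S,
        "SMOKE_only": S - L - P,
    }
    conflicts = []
    stages = [Stage.LEAF, Stage.PYROLYSIS, Stage.SMOKE]
    for i, sa in enumerate(stages):
        for sb in stages[i + 1:]:
            for name in set(by_stage[sa]) & set(by_stage[sb]):
                ra, rb = by_stage[sa][name].ri, by_stage[sb][name].ri
                if ra is not None and rb is not None and abs(ra - rb) > ri_tolerance:
                    conflicts.append(RIConflict(name, sa, sb, ra, rb))
    return StageOverlap(
        partition={k: tuple(sorted(v)) for k, v in partition.items()},
        ri_conflicts=tuple(sorted(conflicts, key=lambda c: (c.canonical_name, c.stage_a.value))),
    )


def write_overlap(overlap: StageOverlap, path: str | Path) -> Path:
    """Write the partition as a ``subset_label,compound`` CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subset_label", "compound"])
        for label in SUBSET_LABELS:
            for name in overlap.subset(label):
                writer.writerow([label, name])
    return path
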