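"""Core domain types: stages, the ND sentinel, compound records and tables.

The pipeline tracks aroma-active compounds through three matrices of the
same tobacco material: the unburned leaf sampled by stir-bar sorptive
extraction (LEAF), the 350 °C pyrolysate (PYROLYSIS), and mainstream
smoke particulate (SMOKE).  Each compound-level observation is a
:class:`CompoundRecord`; one per-matrix table of such records is a
:class:`StageTable`; per-sample quantitative data live in an
:class:`AbundanceMatrix`.

Input tables distinguish three states for a numeric cell:

* a number — measured value;
* ``ND`` — "not detected" (or no published odor threshold), a sentinel
  distinct from numeric zero;
* blank — the field was not reported at all (absent).

``ND`` behaves as zero wherever it enters a ratio denominator or an
average, but an ``ND`` odor threshold forces the odor activity value to
zero rather than to infinity.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import AlignmentError, DuplicateCompoundError, ValidationError

__all__ = [
    "ND",
    "NDType",
    "Stage",
    "SynonymTable",
    "CompoundRecord",
    "StageTable",
    "AbundanceMatrix",
    "canonicalize_name",
]


class NDType:
    """Singleton sentinel for "not detected / no published threshold"."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "ND"

    def __bool__(self) -> bool:
        return False


#: The ND sentinel instance used throughout the package.
ND = NDType()

#: A threshold/abundance cell: a float, the ND sentinel, or absent (None).
MaybeValue = Union[float, NDType, None]


class Stage(enum.Enum):
    """The three matrices of the leaf → pyrolysis → smoke pathway."""

    LEAF = "LEAF"
    PYROLYSIS = "PYROLYSIS"
    SMOKE = "SMOKE"


_PRIME_CHARS = {"′": "'", "’": "'", "ʹ": "'", "−": "-"}


def canonicalize_name(raw: str, synonyms: "SynonymTable | None" = None) -> str:
    """Canonicalize a compound name for cross-table identity matching.

    Lowercases, collapses runs of whitespace, and normalizes prime and
    apostrophe variants (``2,3′-`` vs ``2,3'-``) before applying the
    optional synonym table.  Canonical names are fixed points of this
    function.
    """
    name = raw.strip()
    for bad, good in _PRIME_CHARS.items():
        name = name.replace(bad, good)
    name = re.sub(r"\s+", " ", name).lower()
    if synonyms is not None:
        name = synonyms.resolve(name)
    return name


@dataclass(frozen=True)
class SynonymTable:
    """Functional mapping from raw compound names to canonical names.

    Needed because the source tables themselves use different names for
    one molecule (e.g. "Phytol" in the pyrolysate table versus
    "3,7,11,15-Tetramethyl-2-hexadecen-1-ol" in the leaf table).
    """

    mapping: Mapping[str, str]

    def __post_init__(self):
        norm = {}
        for raw, canon in self.mapping.items():
            key = canonicalize_name(raw)
            val = canonicalize_name(canon)
            if key in norm and norm[key] != val:
                raise ValidationError(
                    f"synonym mapping is not functional: {raw!r} maps to both "
                    f"{norm[key]!r} and {val!r}"
                )
            norm[key] = val
        for canon in list(norm.values()):
            # canonical names must be fixed points
            if norm.get(canon, canon) != canon:
                raise ValidationError(
                    f"canonical name {canon!r} is itself remapped; "
                    "canonical names must be fixed points"
                )
        object.__setattr__(self, "mapping", norm)

    def resolve(self, normalized_name: str) -> str:
        return self.mapping.get(normalized_name, normalized_name)

    @classmethod
    def empty(cls) -> "SynonymTable":
        return cls({})


def _check_nonneg(value, name: str):
    if value is not None and not isinstance(value, NDType):
        if not math.isfinite(value) or value < 0:
            raise ValidationError(f"field {name!r} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """One aroma compound observed in one stage.

    ``oav`` is the odor activity value (concentration / odor threshold);
    ``vip`` the variable-importance-in-projection score from a PLS-DA
    model; ``relative_content`` the percent share of total volatiles.
    """

    canonical_name: str
    raw_name: str
    stage: Stage
    rt_min: float
    relative_content: float
    oav: float
    ri: float | None = None
    odor_threshold: MaybeValue = None
    concentration: float | None = None
    vip: float | None = None
    odor_descriptors: tuple[str, ...] = ()
    origin_class: str = ""

    def __post_init__(self):
        if self.rt_min is None or self.rt_min < 0:
            raise ValidationError(f"field 'rt_min' must be >= 0, got {self.rt_min!r}")
        if not (0.0 <= self.relative_content <= 100.0):
            raise ValidationError(
                f"field 'relative_content' must lie in [0, 100], got {self.relative_content!r}"
            )
        if self.oav < 0:
            raise ValidationError(f"field 'oav' must be >= 0, got {self.oav!r}")
        if self.vip is not None and self.vip < 0:
            raise ValidationError(f"field 'vip' must be >= 0 when present, got {self.vip!r}")
        if self.ri is not None and self.ri < 0:
            raise ValidationError(f"field 'ri' must be >= 0 when present, got {self.ri!r}")
        _check_nonneg(self.concentration, "concentration")
        if (
            self.odor_threshold is not None
            and not isinstance(self.odor_threshold, NDType)
            and self.odor_threshold <= 0
        ):
            raise ValidationError(
                f"field 'odor_threshold' must be > 0 or ND, got {self.odor_threshold!r}"
            )
        # consistency: when a concentration is carried alongside a numeric
        # threshold the stored OAV must be their ratio (0.5% tolerance).
        if (
            self.concentration is not None
            and self.odor_threshold is not None
            and not isinstance(self.odor_threshold, NDType)
        ):
            expected = self.concentration / self.odor_threshold
            if expected > 0 and abs(self.oav - expected) / expected > 0.005:
                raise ValidationError(
                    f"field 'oav' ({self.oav}) inconsistent with "
                    f"concentration/odor_threshold ({expected:.6g})"
                )


@dataclass(frozen=True)
class StageTable:
    """All compound records for one stage (one per-matrix table)."""

    stage: Stage
    records: tuple[CompoundRecord, ...]
    sample_id: str = "pooled"

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.stage is not self.stage:
                raise ValidationError(
                    f"field 'stage': record {rec.raw_name!r} carries {rec.stage}, "
                    f"table is {self.stage}"
                )
            if rec.canonical_name in seen:
                raise DuplicateCompoundError(
                    f"duplicate canonical name {rec.canonical_name!r} from rows "
                    f"{seen[rec.canonical_name]!r} and {rec.raw_name!r}"
                )
            seen[rec.canonical_name] = rec.raw_name

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.canonical_name for r in self.records)

    def get(self, canonical_name: str) -> CompoundRecord:
        for rec in self.records:
            if rec.canonical_name == canonical_name:
                return rec
        raise KeyError(canonical_name)


@dataclass
class AbundanceMatrix:
    """Per-sample abundances for one stage.

    Stored as a samples × compounds DataFrame; ``NaN`` encodes the ND
    sentinel.  Values must be non-negative.
    """

    stage: Stage
    data: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("field 'values': abundance matrix has negative entries")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("field 'sample_ids'/'compound_names': labels must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    def filled(self) -> pd.DataFrame:
        """Return the matrix with ND entries replaced by zero."""
        return self.data.fillna(0.0)

    def stage_means(self) -> pd.Series:
        """Per-compound averages with ND counted as zero."""
        return self.filled().mean(axis=0)


def check_aligned(matrices: Sequence[AbundanceMatrix]) -> None:
    """Raise :class:`AlignmentError` unless all matrices share sample ids."""
    if not matrices:
        return
    ref = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ref:
            raise AlignmentError(
                f"sample ids of stage {m.stage.value} do not match stage "
                f"{matrices[0].stage.value}"
            )
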