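"""Descriptor tokenization and stage-level sensory profiles.

Free-text odor descriptions ("Sweet, caramel, buttery, toasted/Nutty
(almond-like)") are tokenized — parentheticals stripped, split on
commas and slashes, lowercased, filler words trimmed — and each token
is routed through an :class:`AromaLexicon` to one of a fixed set of
aroma categories.  A stage profile distributes each record's weight
over the categories in proportion to its token counts, so total profile
mass equals total record weight (conservation).

Three weightings are offered because the aggregation behind the
published stage profiles is not stated: ``COUNT`` (one vote per
record), ``RELATIVE_CONTENT`` (percent abundance) and ``OAV``
(odor activity, capped so a single extreme low-threshold compound
cannot saturate the profile).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .types import Stage, StageTable

__all__ = [
    "CATEGORIES",
    "AromaLexicon",
    "SensoryProfile",
    "tokenize_descriptors",
    "stage_profile",
    "read_lexicon",
]

CATEGORIES = (
    "sweet",
    "caramel",
    "fruity",
    "citrus",
    "green_grassy",
    "floral",
    "woody",
    "roasted_nutty",
    "smoky",
    "sour",
    "fatty_waxy",
    "amine",
    "earthy_tobacco",
    "herbal",
    "other",
)

_LEAD_FILLERS = {"and", "with", "a", "slight", "slightly", "typical", "no"}
_TRAIL_FILLERS = {"odor", "odour", "flavor", "flavour", "note", "notes", "aroma", "aromas"}


def tokenize_descriptors(odor_description: str) -> list[str]:
    """Split a packed descriptor cell into normalized tokens.

    Parentheticals are stripped, the remainder is split on commas and
    slashes, lowercased, and leading/trailing filler words ("and",
    "with a slight", trailing "odor"/"notes") are trimmed.
    """
    if not odor_description:
        return []
    text = re.sub(r"\([^)]*\)", " ", odor_description)
    tokens = []
    for raw in re.split(r"[,/]", text):
        words = raw.lower().split()
        while words and words[0] in _LEAD_FILLERS:
            words.pop(0)
        while words and words[-1] in _TRAIL_FILLERS:
            words.pop()
        token = " ".join(words).strip(" .;:-")
        if token:
            tokens.append(token)
    return tokens


@dataclass(frozen=True)
class AromaLexicon:
    """Token → category mapping; unknown tokens route to ``other``."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        norm = {}
        for token, cat in self.mapping.items():
            if cat not in CATEGORIES:
                raise ValidationError(f"field 'category': unknown category {cat!r} for {token!r}")
            norm[token.strip().lower()] = cat
        object.__setattr__(self, "mapping", norm)

    def category(self, token: str) -> str:
        return self.mapping.get(token.strip().lower(), "other")


def read_lexicon(path: str | Path) -> AromaLexicon:
    """Read a ``token,category`` CSV."""
    df = pd.read_csv(path, dtype=str)
    return AromaLexicon(dict(zip(df["token"], df["category"])))


def default_lexicon() -> AromaLexicon:
    """The packaged lexicon covering the fixture tables' vocabulary."""
    from .fixtures import fixture_path
    from importlib import resources

    with resources.as_file(fixture_path("aroma_lexicon.csv")) as p:
        return read_lexicon(p)


@dataclass(frozen=True)
class SensoryProfile:
    """Aggregated aroma-category intensities for one stage."""

    stage: Stage
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cat, v in self.scores.items():
            if cat not in CATEGORIES:
                raise ValidationError(f"field 'scores': unknown category {cat!r}")
            if v < 0:
                raise ValidationError(f"field 'scores': negative score for {cat!r}")

    @property
    def total(self) -> float:
        return sum(self.scores.values())


def stage_profile(
    table: StageTable,
    lexicon: AromaLexicon | None = None,
    weighting: str = "RELATIVE_CONTENT",
    oav_cap: float = 100.0,
) -> SensoryProfile:
    """Aggregate a stage table into a category profile.

    Each record contributes ``weight × (fraction of its tokens in the
    category)``, so the profile total equals the summed weights.
    """
    if weighting not in ("COUNT", "RELATIVE_CONTENT", "OAV"):
        raise ValidationError(
            f"field 'weighting' must be COUNT, RELATIVE_CONTENT or OAV, got {weighting!r}"
        )
    if lexicon is None:
        lexicon = default_lexicon()
    scores = {cat: 0.0 for cat in CATEGORIES}
    for rec in table:
        tokens = tokenize_descriptors(", ".join(rec.odor_descriptors))
        if not tokens:
            continue
        if weighting == "COUNT":
            weight = 1.0
        elif weighting == "RELATIVE_CONTENT":
            weight = rec.relative_content
        else:
            weight = min(rec.oav, oav_cap)
        frac = weight / len(tokens)
        for token in tokens:
            scores[lexicon.category(token)] += frac
    return SensoryProfile(stage=table.stage, scores=scores)


def write_profiles(profiles: Iterable[SensoryProfile], path: str | Path) -> Path:
    """Write profiles as a long-format ``stage,category,score`` CSV."""
    rows = [
        {"stage": p.stage.value, "category": cat, "score": p.scores.get(cat, 0.0)}
        for p in profiles
        for cat in CATEGORIES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
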