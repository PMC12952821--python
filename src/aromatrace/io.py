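"""CSV readers and writers for the canonical table schemas.

All files are UTF-8, comma-separated, quoted where needed, with a
mandatory header row.  The stage-table schema is::

    compound,odor_description,rt_min,ri,odor_threshold_ug_L,
    relative_content_pct,concentration_ug_L,oav,vip,origin

``ND`` cells parse to the :data:`~aromatrace.types.ND` sentinel; blank
cells for RI / VIP / concentration parse to absent (``None``).
Round-trips are stable field-for-field, including sentinels.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .types import (
    ND,
    AbundanceMatrix,
    CompoundRecord,
    NDType,
    Stage,
    StageTable,
    SynonymTable,
    canonicalize_name,
)

STAGE_TABLE_COLUMNS = [
    "compound",
    "odor_description",
    "rt_min",
    "ri",
    "odor_threshold_ug_L",
    "relative_content_pct",
    "concentration_ug_L",
    "oav",
    "vip",
    "origin",
]

_ND_TOKENS = {"nd", "n.d.", "n.d"}


def _parse_cell(text: str, *, nd_allowed: bool) -> float | NDType | None:
    text = text.strip()
    if text == "":
        return None
    if text.lower() in _ND_TOKENS:
        if not nd_allowed:
            raise ValidationError(f"ND sentinel not allowed here: {text!r}")
        return ND
    return float(text.replace(",", ""))


def split_descriptor_cell(cell: str) -> tuple[str, ...]:
    """Split a packed odor-description cell on top-level commas.

    Commas inside parentheses (e.g. "floral (rose, violet)") do not
    split.  The finer slash/parenthesis tokenization used for sensory
    aggregation lives in :mod:`aromatrace.sensory`.
    """
    parts, depth, buf = [], 0, []
    for ch in cell:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == "," and depth == 0:
            parts.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        parts.append(tail)
    return tuple(p for p in parts if p)


def read_stage_table(
    path: str | Path,
    stage: Stage,
    synonyms: SynonymTable | None = None,
) -> StageTable:
    """Read one per-matrix compound table into a validated StageTable."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in STAGE_TABLE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: header is missing required column(s) {missing}"
            )
        records = []
        for i, row in enumerate(reader):
            try:
                rel = _parse_cell(row["relative_content_pct"], nd_allowed=True)
                rel = 0.0 if rel is None or isinstance(rel, NDType) else rel
                oav = _parse_cell(row["oav"], nd_allowed=True)
                oav = 0.0 if oav is None or isinstance(oav, NDType) else oav
                ri = _parse_cell(row["ri"], nd_allowed=False)
                vip = _parse_cell(row["vip"], nd_allowed=False)
                conc = _parse_cell(row["concentration_ug_L"], nd_allowed=False)
                thr = _parse_cell(row["odor_threshold_ug_L"], nd_allowed=True)
                rec = CompoundRecord(
                    canonical_name=canonicalize_name(row["compound"], synonyms),
                    raw_name=row["compound"].strip(),
                    stage=stage,
                    rt_min=float(row["rt_min"]),
                    ri=ri,
                    odor_threshold=thr,
                    relative_content=rel,
                    concentration=conc,
                    oav=oav,
                    vip=vip,
                    odor_descriptors=split_descriptor_cell(row["odor_description"]),
                    origin_class=row["origin"].strip(),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} row {i}: {exc}") from exc
            except ValueError as exc:
                raise ValidationError(f"{path.name} row {i}: {exc}") from exc
            records.append(rec)
    return StageTable(stage=stage, records=tuple(records))


def _format_maybe(value) -> str:
    if value is None:
        return ""
    if isinstance(value, NDType):
        return "ND"
    return repr(float(value))


def write_stage_table(table: StageTable, path: str | Path) -> Path:
    """Write a StageTable; ``read(write(t))`` reproduces ``t``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(STAGE_TABLE_COLUMNS)
        for rec in table:
            writer.writerow(
                [
                    rec.raw_name,
                    ", ".join(rec.odor_descriptors),
                    repr(rec.rt_min),
                    _format_maybe(rec.ri),
                    _format_maybe(rec.odor_threshold),
                    repr(rec.relative_content),
                    _format_maybe(rec.concentration),
                    repr(rec.oav),
                    _format_maybe(rec.vip),
                    rec.origin_class,
                ]
            )
    return path


def read_synonyms(path: str | Path) -> SynonymTable:
    """Read a ``raw_name,canonical_name`` CSV into a SynonymTable."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("raw_name", "canonical_name") if c not in df.columns]
    if missing:
        raise SchemaError(f"synonyms file missing column(s) {missing}")
    return SynonymTable(dict(zip(df["raw_name"], df["canonical_name"])))


def read_abundance_matrix(path: str | Path, stage: Stage) -> AbundanceMatrix:
    """Read a sample × compound abundance CSV (first column ``sample_id``).

    ``ND`` cells become NaN (the ND sentinel for matrices).
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "sample_id":
        raise SchemaError("abundance matrix must have 'sample_id' as its first column")
    df = df.set_index("sample_id")
    parsed = df.map(lambda v: float("nan") if str(v).strip().lower() in _ND_TOKENS else float(v))
    parsed.columns = [canonicalize_name(c) for c in parsed.columns]
    return AbundanceMatrix(stage=stage, data=parsed)


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.data.copy()
    out = out.where(out.notna(), "ND")
    out.index.name = "sample_id"
    out.to_csv(path)
    return path
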