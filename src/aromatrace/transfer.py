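"""Transfer indices along the leaf → pyrolysis → smoke pathway.

For each compound with per-stage average abundances
``avg_leaf`` (SBSE), ``avg_py`` (pyrolysate) and ``avg_smoke``
(mainstream smoke), the module computes:

* DTE, direct transfer efficiency  = avg_smoke / avg_leaf
* RIR(Smk/SBSE)                    = avg_smoke / avg_leaf  (≡ DTE)
* RIR(Smk/PY)                      = avg_smoke / avg_py
* TGF, thermal generation factor   = avg_py    / avg_leaf
* PCI, precursor contribution idx  = avg_py    / avg_smoke

A ratio whose denominator is zero is UNDEFINED (``None``, printed
``—``); a zero numerator over a positive denominator is a defined 0.
DTE and RIR(Smk/SBSE) are the same quantity; both are kept because the
published table schema prints both columns.

Fate classification quantifies the qualitative reading of these
ratios: "≈1" is the ``near_one`` band (default [0.5, 2]), "≫1" the
``high_ratio`` cutoff (default 5), "≪1" the ``low_ratio`` cutoff
(default 0.5).  The decision tree runs in a fixed order, leaf-absent
cases first, so every record receives exactly one label.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .types import AbundanceMatrix, check_aligned

__all__ = [
    "FateLabel",
    "FateThresholds",
    "TransferRecord",
    "transfer_indices",
    "classify_fate",
    "build_transfer_table",
    "averages_from_matrices",
    "write_transfer_table",
    "read_transfer_table",
]

UNDEFINED = None  # ratio with zero denominator; serialized as "—"


class FateLabel(str, enum.Enum):
    """Per-compound fate along the pathway."""

    NOT_DETECTED = "NOT_DETECTED"
    THERMALLY_GENERATED = "THERMALLY_GENERATED"
    THERMALLY_GENERATED_PARTIAL_TRANSFER = "THERMALLY_GENERATED_PARTIAL_TRANSFER"
    SMOKE_ONLY = "SMOKE_ONLY"
    THERMOGENESIS_PLUS_RELEASE = "THERMOGENESIS_PLUS_RELEASE"
    THERMOGENESIS_DOMINANT = "THERMOGENESIS_DOMINANT"
    EFFICIENT_RELEASE = "EFFICIENT_RELEASE"
    EQUAL_TRANSFER = "EQUAL_TRANSFER"
    PARTIAL_LOSS = "PARTIAL_LOSS"
    MODERATE_TRANSFER = "MODERATE_TRANSFER"


@dataclass(frozen=True)
class FateThresholds:
    """Quantification of the qualitative ≈1 / ≫1 / ≪1 decision rules."""

    near_one_band: tuple[float, float] = (0.5, 2.0)
    high_ratio: float = 5.0
    low_ratio: float = 0.5

    def __post_init__(self):
        lo, hi = self.near_one_band
        if not (0 < lo <= 1 <= hi):
            raise ValidationError("field 'near_one_band' must bracket 1")
        if self.high_ratio <= 1 or self.low_ratio >= 1:
            raise ValidationError("field 'high_ratio' must exceed 1 and 'low_ratio' be below 1")


@dataclass(frozen=True)
class TransferRecord:
    """Per-stage averages and derived indices for one matched compound."""

    canonical_name: str
    avg_leaf: float
    avg_py: float
    avg_smoke: float
    dte: float | None
    rir_smoke_leaf: float | None
    rir_smoke_py: float | None
    tgf: float | None
    pci: float | None
    fate_label: FateLabel | None = None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else UNDEFINED


def transfer_indices(
    name: str, avg_leaf: float, avg_py: float, avg_smoke: float
) -> TransferRecord:
    """Compute all five indices; ND averages are passed in as 0."""
    for label, v in (("avg_leaf", avg_leaf), ("avg_py", avg_py), ("avg_smoke", avg_smoke)):
        if v < 0:
            raise ValidationError(f"field {label!r} must be >= 0, got {v}")
    dte = _ratio(avg_smoke, avg_leaf)
    return TransferRecord(
        canonical_name=name,
        avg_leaf=avg_leaf,
        avg_py=avg_py,
        avg_smoke=avg_smoke,
        dte=dte,
        rir_smoke_leaf=dte,
        rir_smoke_py=_ratio(avg_smoke, avg_py),
        tgf=_ratio(avg_py, avg_leaf),
        pci=_ratio(avg_py, avg_smoke),
    )


def classify_fate(
    record: TransferRecord, thresholds: FateThresholds = FateThresholds()
) -> FateLabel:
    """Deterministic fate decision tree, evaluated in a fixed order."""
    t = thresholds
    lo_band, hi_band = t.near_one_band
    if record.avg_leaf == 0 and record.avg_py == 0 and record.avg_smoke == 0:
        return FateLabel.NOT_DETECTED
    if record.avg_leaf == 0 and record.avg_py > 0:
        if record.avg_smoke > 0:
            return FateLabel.THERMALLY_GENERATED_PARTIAL_TRANSFER
        return FateLabel.THERMALLY_GENERATED
    if record.avg_leaf == 0 and record.avg_py == 0 and record.avg_smoke > 0:
        return FateLabel.SMOKE_ONLY
    # from here avg_leaf > 0, so dte and tgf are defined
    if record.tgf is not None and record.tgf >= t.high_ratio:
        if record.dte is not None and record.dte >= t.high_ratio:
            return FateLabel.THERMOGENESIS_PLUS_RELEASE
        return FateLabel.THERMOGENESIS_DOMINANT
    if record.dte >= t.high_ratio:
        return FateLabel.EFFICIENT_RELEASE
    if lo_band <= record.dte <= hi_band:
        return FateLabel.EQUAL_TRANSFER
    if record.dte < t.low_ratio:
        return FateLabel.PARTIAL_LOSS
    return FateLabel.MODERATE_TRANSFER


def build_transfer_table(
    averages: pd.DataFrame,
    thresholds: FateThresholds = FateThresholds(),
) -> list[TransferRecord]:
    """Index every row of a (compound, avg_sbse, avg_py, avg_smokiness) frame."""
    required = ["compound", "avg_sbse", "avg_py", "avg_smokiness"]
    missing = [c for c in required if c not in averages.columns]
    if missing:
        raise ValidationError(f"field 'averages' missing column(s) {missing}")
    out = []
    for row in averages.itertuples(index=False):
        rec = transfer_indices(
            row.compound, float(row.avg_sbse), float(row.avg_py), float(row.avg_smokiness)
        )
        out.append(replace(rec, fate_label=classify_fate(rec, thresholds)))
    return out


def averages_from_matrices(
    leaf: AbundanceMatrix, py: AbundanceMatrix, smoke: AbundanceMatrix
) -> pd.DataFrame:
    """Ratio-of-means inputs: per-stage sample averages with ND as 0.

    The estimator mirrors the published table, which divides per-stage
    averages rather than averaging per-sample ratios.  Compounds absent
    from a stage get average 0 there.
    """
    check_aligned([leaf, py, smoke])
    names = sorted(set(leaf.compound_names) | set(py.compound_names) | set(smoke.compound_names))
    means = {m.stage: m.stage_means() for m in (leaf, py, smoke)}

    def get(stage_means: pd.Series, name: str) -> float:
        return float(stage_means.get(name, 0.0))

    from .types import Stage

    return pd.DataFrame(
        {
            "compound": names,
            "avg_sbse": [get(means[Stage.LEAF], n) for n in names],
            "avg_py": [get(means[Stage.PYROLYSIS], n) for n in names],
            "avg_smokiness": [get(means[Stage.SMOKE], n) for n in names],
        }
    )


_CSV_COLUMNS = [
    "compound",
    "avg_sbse",
    "avg_py",
    "avg_smokiness",
    "dte",
    "rir_smk_sbse",
    "rir_smk_py",
    "tgf",
    "pci",
    "fate_label",
]


def _fmt(v) -> str:
    return "—" if v is None else repr(float(v))


def write_transfer_table(records: Sequence[TransferRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.canonical_name,
                    repr(r.avg_leaf),
                    repr(r.avg_py),
                    repr(r.avg_smoke),
                    _fmt(r.dte),
                    _fmt(r.rir_smoke_leaf),
                    _fmt(r.rir_smoke_py),
                    _fmt(r.tgf),
                    _fmt(r.pci),
                    r.fate_label.value if r.fate_label else "",
                ]
            )
    return path


def read_transfer_table(path: str | Path) -> list[TransferRecord]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            def num(key):
                v = row[key].strip()
                return None if v in ("—", "") else float(v)

            out.append(
                TransferRecord(
                    canonical_name=row["compound"],
                    avg_leaf=float(row["avg_sbse"]),
                    avg_py=float(row["avg_py"]),
                    avg_smoke=float(row["avg_smokiness"]),
                    dte=num("dte"),
                    rir_smoke_leaf=num("rir_smk_sbse"),
                    rir_smoke_py=num("rir_smk_py"),
                    tgf=num("tgf"),
                    pci=num("pci"),
                    fate_label=FateLabel(row["fate_label"]) if row["fate_label"] else None,
                )
            )
    return out
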