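"""Loaders for the packaged reference tables.

The package ships, as plain CSV, the published key-compound tables for
the three stages (13 leaf, 27 pyrolysate, 20 smoke records), the
15-row three-stage average-abundance table used for transfer-index
computation, the compound synonym seeds, the default aroma lexicon and
the mapping from the transfer table's free-text "Notes" strings to fate
labels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_stage_table, read_synonyms
from .types import Stage, StageTable, SynonymTable, canonicalize_name

__all__ = [
    "load_stage_table",
    "load_synonyms",
    "load_transfer_averages",
    "load_notes_labels",
    "fixture_path",
]

_FILES = {
    Stage.LEAF: "table_leaf.csv",
    Stage.PYROLYSIS: "table_pyrolysis.csv",
    Stage.SMOKE: "table_smoke.csv",
}


def fixture_path(name: str):
    """Return a filesystem path to a packaged data file."""
    return resources.files("aromatrace.data").joinpath(name)


def load_synonyms() -> SynonymTable:
    """The shipped synonym seeds (Phytol, nicotine)."""
    with resources.as_file(fixture_path("synonyms.csv")) as p:
        return read_synonyms(p)


def load_stage_table(stage: Stage, synonyms: SynonymTable | None = None) -> StageTable:
    """Load the packaged key-compound table for one stage."""
    if synonyms is None:
        synonyms = load_synonyms()
    with resources.as_file(fixture_path(_FILES[stage])) as p:
        return read_stage_table(p, stage, synonyms)


def load_transfer_averages() -> pd.DataFrame:
    """The 15-row three-stage average table, printed values included.

    Columns: ``compound`` (canonicalized), ``avg_sbse``, ``avg_py``,
    ``avg_smokiness`` plus the printed indices ``dte``,
    ``rir_smk_sbse``, ``rir_smk_py``, ``pci`` (``—`` parsed to NaN) and
    the free-text ``notes``.
    """
    with resources.as_file(fixture_path("table_transfer.csv")) as p:
        df = pd.read_csv(p, dtype=str)
    df["compound"] = [canonicalize_name(c) for c in df["compound"]]
    for col in ("avg_sbse", "avg_py", "avg_smokiness", "dte", "rir_smk_sbse", "rir_smk_py", "pci"):
        df[col] = pd.to_numeric(df[col].replace({"—": None}), errors="coerce")
    return df


def load_notes_labels() -> dict[str, str]:
    """Mapping from the transfer table's Notes strings to fate labels."""
    with resources.as_file(fixture_path("table_notes_labels.csv")) as p:
        df = pd.read_csv(p, dtype=str)
    return dict(zip(df["notes"], df["fate_label"]))
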