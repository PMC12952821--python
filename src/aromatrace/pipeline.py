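"""End-to-end orchestration: screen → match → transfer → network → sensory.

``run_pipeline`` consumes a :class:`PipelineConfig` (constructible from
a YAML file), runs every stage for which inputs are available, writes
the per-stage output files into the output directory and returns the
JSON-serializable summary it also writes to ``summary.json``.  Runs are
idempotent for fixed inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fixtures, io, matching, sensory, transfer
from .errors import ValidationError
from .network import build_network, write_edges
from .screening import ScreeningCriteria, screen_key_compounds
from .sensory import stage_profile, write_profiles
from .transfer import FateThresholds, build_transfer_table, averages_from_matrices, write_transfer_table
from .types import Stage

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Any table path left as ``None`` falls back to the packaged
    reference table for that stage; ``averages_table`` falls back to
    the packaged three-stage average table.  Abundance-matrix paths are
    optional and enable the correlation-network step.
    """

    out_dir: str = "aromatrace_out"
    leaf_table: str | None = None
    py_table: str | None = None
    smoke_table: str | None = None
    averages_table: str | None = None
    synonyms: str | None = None
    lexicon: str | None = None
    leaf_matrix: str | None = None
    py_matrix: str | None = None
    smoke_matrix: str | None = None
    screening: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    fate_thresholds: FateThresholds = field(default_factory=FateThresholds)
    r_min: float = 0.8
    p_max: float = 0.01
    pairing: str = "INTER_STAGE"
    weighting: str = "RELATIVE_CONTENT"
    ri_tolerance: float = 30.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "screening" in raw:
            raw["screening"] = ScreeningCriteria(**raw["screening"])
        if "fate_thresholds" in raw:
            ft = raw["fate_thresholds"]
            if "near_one_band" in ft:
                ft["near_one_band"] = tuple(ft["near_one_band"])
            raw["fate_thresholds"] = FateThresholds(**ft)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"config has unknown key(s) {sorted(unknown)}")
        return cls(**raw)


def _load_tables(config: PipelineConfig, synonyms):
    paths = {
        Stage.LEAF: ("leaf table", config.leaf_table),
        Stage.PYROLYSIS: ("pyrolysis table", config.py_table),
        Stage.SMOKE: ("smoke table", config.smoke_table),
    }
    tables = {}
    for stage, (label, path) in paths.items():
        if path is None:
            tables[stage] = fixtures.load_stage_table(stage, synonyms)
        else:
            p = Path(path)
            if not p.exists():
                raise ValidationError(f"missing input: {label} at {p}")
            tables[stage] = io.read_stage_table(p, stage, synonyms)
    return tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every available stage and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    synonyms = (
        fixtures.load_synonyms() if config.synonyms is None else io.read_synonyms(config.synonyms)
    )
    lexicon = (
        sensory.default_lexicon() if config.lexicon is None else sensory.read_lexicon(config.lexicon)
    )
    tables = _load_tables(config, synonyms)
    summary: dict = {"seed": config.seed, "n_key_compounds": {}, "screened": {}}

    # 1. screening
    for stage, table in tables.items():
        summary["n_key_compounds"][stage.value] = len(table)
        outcome = screen_key_compounds(table, config.screening)
        io.write_stage_table(outcome.table, out / f"screened_{stage.value.lower()}.csv")
        summary["screened"][stage.value] = len(outcome.table)

    # 2. cross-stage matching
    overlap = matching.match_across_stages(
        tables[Stage.LEAF],
        tables[Stage.PYROLYSIS],
        tables[Stage.SMOKE],
        synonyms=synonyms,
        ri_tolerance=config.ri_tolerance,
    )
    matching.write_overlap(overlap, out / "overlap.csv")
    summary["overlap"] = {label: len(overlap.subset(label)) for label in matching.SUBSET_LABELS}
    summary["triple_intersection"] = sorted(overlap.subset("ALL"))

    # 3. transfer indices
    matrices = None
    if config.leaf_matrix and config.py_matrix and config.smoke_matrix:
        matrices = [
            io.read_abundance_matrix(config.leaf_matrix, Stage.LEAF),
            io.read_abundance_matrix(config.py_matrix, Stage.PYROLYSIS),
            io.read_abundance_matrix(config.smoke_matrix, Stage.SMOKE),
        ]
    if config.averages_table is not None:
        import pandas as pd

        averages = pd.read_csv(config.averages_table)
    elif matrices is not None:
        averages = averages_from_matrices(*matrices)
    else:
        averages = fixtures.load_transfer_averages()
    records = build_transfer_table(averages, config.fate_thresholds)
    write_transfer_table(records, out / "transfer_table.csv")
    summary["transfer"] = {
        r.canonical_name: {
            "dte": r.dte,
            "tgf": r.tgf,
            "pci": r.pci,
            "fate": r.fate_label.value if r.fate_label else None,
        }
        for r in records
    }

    # 4. correlation network (needs per-sample matrices)
    if matrices is not None:
        edges = build_network(
            matrices, r_min=config.r_min, p_max=config.p_max, pairing=config.pairing
        )
        write_edges(edges, out / "network_edges.csv")
        summary["n_network_edges"] = len(edges)

    # 5. sensory profiles
    profiles = [
        stage_profile(tables[s], lexicon, weighting=config.weighting)
        for s in (Stage.LEAF, Stage.PYROLYSIS, Stage.SMOKE)
    ]
    write_profiles(profiles, out / "sensory_profiles.csv")
    summary["sensory_top_category"] = {
        p.stage.value: max(p.scores, key=lambda c: (p.scores[c], c)) for p in profiles
    }

    with (out / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; %d output files in %s", len(list(out.iterdir())), out)
    return summary
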