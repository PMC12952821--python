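"""Synthetic three-stage abundance data with known transfer structure.

Because the study's per-sample matrices are not published, end-to-end
behaviour is exercised on generated data whose ground truth is known.
Each compound belongs to one of four fate classes:

* ``TRANSFERRED`` — present in leaf, roughly conserved into smoke
  (true DTE drawn within the equal-transfer band);
* ``LOST`` — present in leaf, largely retained/degraded (true DTE ≪ 1);
* ``THERMOGENIC`` — absent from leaf, created during pyrolysis and
  partially carried into smoke (true TGF undefined by construction);
* ``SMOKE_ONLY`` — appears only in the smoke matrix.

The generative model is multiplicative:  for compound *i*, sample *s*,

    leaf_is  = base_i            · ε_is
    py_is    = base_i · tgf_i    · ε'_is
    smoke_is = base_i · dte_i    · ε''_is

with ε i.i.d. lognormal, mean 1, coefficient of variation ``noise_cv``.
Cells below the detection floor or hit by random ND masking become ND.
Abundances are positive and span orders of magnitude, mirroring the
published tables; the default sample count (14) matches the study's
leaf panel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .transfer import FateLabel
from .types import AbundanceMatrix, Stage

__all__ = [
    "TruthClass",
    "SyntheticTruth",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "inject_correlation_structure",
    "expected_fate",
]


class TruthClass(str, enum.Enum):
    TRANSFERRED = "TRANSFERRED"
    THERMOGENIC = "THERMOGENIC"
    LOST = "LOST"
    SMOKE_ONLY = "SMOKE_ONLY"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters for one generated compound."""

    name: str
    truth_class: TruthClass
    base_leaf_abundance: float
    true_dte: float | None
    true_tgf: float | None

    def __post_init__(self):
        if self.truth_class in (TruthClass.THERMOGENIC, TruthClass.SMOKE_ONLY):
            if self.base_leaf_abundance != 0:
                raise ValidationError(
                    "field 'base_leaf_abundance' must be 0 for leaf-absent classes"
                )
        if self.truth_class is TruthClass.LOST and not (self.true_dte or 0) < 1:
            raise ValidationError("field 'true_dte' must be < 1 for LOST compounds")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study-like conditions."""

    n_samples: int = 14
    n_transferred: int = 12
    n_thermogenic: int = 6
    n_lost: int = 6
    n_smoke_only: int = 3
    noise_cv: float = 0.1
    nd_fraction: float = 0.0
    detection_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValidationError(f"field 'n_samples' must be >= 3, got {self.n_samples}")
        if self.noise_cv < 0:
            raise ValidationError("field 'noise_cv' must be >= 0")
        if not (0.0 <= self.nd_fraction <= 1.0):
            raise ValidationError("field 'nd_fraction' must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    leaf: AbundanceMatrix
    py: AbundanceMatrix
    smoke: AbundanceMatrix
    truth: tuple[SyntheticTruth, ...]

    @property
    def matrices(self) -> list[AbundanceMatrix]:
        return [self.leaf, self.py, self.smoke]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """i.i.d. lognormal factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate aligned leaf/pyrolysis/smoke matrices plus ground truth.

    Reproducible: the same config (including seed) yields bit-identical
    matrices.  True DTE/TGF are drawn inside their class's fate band,
    away from the decision boundaries, so estimated indices should
    recover both the ratios and the fate labels.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i+1:02d}" for i in range(config.n_samples)]

    truths: list[SyntheticTruth] = []
    rows_leaf, rows_py, rows_smoke, names = [], [], [], []

    def add(name: str, cls: TruthClass, base: float, dte, tgf, mu_leaf, mu_py, mu_smoke):
        names.append(name)
        truths.append(SyntheticTruth(name, cls, base if cls in (TruthClass.TRANSFERRED, TruthClass.LOST) else 0.0, dte, tgf))
        rows_leaf.append(mu_leaf)
        rows_py.append(mu_py)
        rows_smoke.append(mu_smoke)

    for i in range(config.n_transferred):
        base = 10.0 ** rng.uniform(-1.0, 1.5)
        dte = rng.uniform(0.8, 1.6)
        tgf = rng.uniform(0.02, 0.3)
        add(f"syn_transferred_{i+1:02d}", TruthClass.TRANSFERRED, base, dte, tgf,
            base, base * tgf, base * dte)
    for i in range(config.n_lost):
        base = 10.0 ** rng.uniform(-1.0, 1.5)
        dte = rng.uniform(0.05, 0.3)
        tgf = rng.uniform(0.02, 0.3)
        add(f"syn_lost_{i+1:02d}", TruthClass.LOST, base, dte, tgf,
            base, base * tgf, base * dte)
    for i in range(config.n_thermogenic):
        base = 10.0 ** rng.uniform(-1.0, 1.5)   # pyrolysate-side own base
        carry = rng.uniform(0.3, 3.0)
        add(f"syn_thermogenic_{i+1:02d}", TruthClass.THERMOGENIC, base, None, None,
            0.0, base, base * carry)
    for i in range(config.n_smoke_only):
        base = 10.0 ** rng.uniform(-1.0, 1.5)
        add(f"syn_smoke_only_{i+1:02d}", TruthClass.SMOKE_ONLY, base, None, None,
            0.0, 0.0, base)

    n, m = config.n_samples, len(names)
    data = {}
    for stage, mus in (
        (Stage.LEAF, rows_leaf),
        (Stage.PYROLYSIS, rows_py),
        (Stage.SMOKE, rows_smoke),
    ):
        grid = np.asarray(mus)[None, :] * _lognormal_noise(rng, config.noise_cv, (n, m))
        nd_mask = grid < config.detection_floor
        if config.nd_fraction > 0:
            nd_mask |= rng.random((n, m)) < config.nd_fraction
        grid = np.where(nd_mask, np.nan, grid)
        data[stage] = AbundanceMatrix(
            stage=stage, data=pd.DataFrame(grid, index=samples, columns=names)
        )
    return SyntheticDataset(
        leaf=data[Stage.LEAF],
        py=data[Stage.PYROLYSIS],
        smoke=data[Stage.SMOKE],
        truth=tuple(truths),
    )


def expected_fate(truth: SyntheticTruth) -> FateLabel:
    """The fate label the generator's parameters imply (default bands)."""
    if truth.truth_class is TruthClass.THERMOGENIC:
        return FateLabel.THERMALLY_GENERATED_PARTIAL_TRANSFER
    if truth.truth_class is TruthClass.SMOKE_ONLY:
        return FateLabel.SMOKE_ONLY
    if truth.truth_class is TruthClass.LOST:
        return FateLabel.PARTIAL_LOSS
    return FateLabel.EQUAL_TRANSFER


def inject_correlation_structure(
    dataset: SyntheticDataset,
    pairs: Sequence[tuple[tuple[Stage, str], tuple[Stage, str], float]],
    seed: int = 0,
) -> SyntheticDataset:
    """Plant known correlations between node pairs (Gaussian copula).

    For each ``((stage_a, compound_a), (stage_b, compound_b), target_r)``
    the two columns are regenerated from correlated log-scale normals
    with the columns' own means and dispersions, so the planted pair
    reaches approximately ``target_r`` while other columns are left
    untouched.  An empty pair list passes the data through unchanged.
    """
    rng = np.random.default_rng(seed)
    by_stage = {m.stage: m.data.copy() for m in dataset.matrices}
    for (sa, ca), (sb, cb), target_r in pairs:
        if not (-1.0 < target_r < 1.0):
            raise ValidationError(f"field 'target_r' must lie in (-1, 1), got {target_r}")
        for stage, comp in ((sa, ca), (sb, cb)):
            if comp not in by_stage[stage].columns:
                raise KeyError(f"node {comp!r} not found in stage {stage.value}")
        n = len(by_stage[sa].index)
        cov = np.array([[1.0, target_r], [target_r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        for k, (stage, comp) in enumerate(((sa, ca), (sb, cb))):
            col = by_stage[stage][comp].to_numpy(dtype=float)
            level = np.nanmean(col)
            sd = np.nanstd(col)
            cv = sd / level if level > 0 else 0.2
            cv = cv if cv > 0 else 0.2
            sigma2 = math.log1p(cv * cv)
            sigma = math.sqrt(sigma2)
            by_stage[stage][comp] = level * np.exp(sigma * z[:, k] - sigma2 / 2.0)
    return SyntheticDataset(
        leaf=AbundanceMatrix(Stage.LEAF, by_stage[Stage.LEAF]),
        py=AbundanceMatrix(Stage.PYROLYSIS, by_stage[Stage.PYROLYSIS]),
        smoke=AbundanceMatrix(Stage.SMOKE, by_stage[Stage.SMOKE]),
        truth=dataset.truth,
    )
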