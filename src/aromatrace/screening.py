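"""Key-compound screening: PLS-DA variable importance and the
multi-indicator filter.

A compound is flagged as a key aroma compound when it satisfies one or
more (mode ``ANY``, the default) of three inclusive criteria:
relative content ≥ 10 %, odor activity value ≥ 1, and PLS-DA VIP ≥ 1.
Mode ``ALL`` requires every criterion.  A record lacking an optional
field (e.g. no VIP) simply fails that one criterion.

The VIP (variable importance in projection) score for variable *j* over
*A* latent components is

    VIP_j = sqrt( p * sum_a( w_ja^2 * SSY_a ) / sum_a( SSY_a ) )

with ``p`` variables, unit-norm component weight vectors ``w_a`` and
per-component explained response variance ``SSY_a = |t_a|^2 |q_a|^2``.
The identity Σ_j VIP_j² = p holds exactly.  The PLS fit itself is
scikit-learn's NIPALS implementation (deterministic) on autoscaled X
with a one-hot class response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import DegenerateDesignError, RankError, ValidationError
from .types import AbundanceMatrix, StageTable

__all__ = ["ScreeningCriteria", "ScreeningOutcome", "pls_da_vip", "screen_key_compounds"]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds of the multi-indicator key-compound screen."""

    rel_content_min: float = 10.0
    oav_min: float = 1.0
    vip_min: float = 1.0
    mode: str = "ANY"

    def __post_init__(self):
        for name in ("rel_content_min", "oav_min", "vip_min"):
            if getattr(self, name) < 0:
                raise ValidationError(f"field {name!r} must be >= 0")
        if self.mode not in ("ANY", "ALL"):
            raise ValidationError(f"field 'mode' must be ANY or ALL, got {self.mode!r}")


@dataclass(frozen=True)
class ScreeningOutcome:
    """Retained records plus, per record, the criteria each passed."""

    table: StageTable
    passed: dict[str, tuple[str, ...]]


def pls_da_vip(
    X: AbundanceMatrix | pd.DataFrame | np.ndarray,
    y: Sequence,
    n_components: int = 2,
) -> pd.Series:
    """VIP score per compound from a PLS-DA fit.

    ND entries count as zero abundance.  Raises on a single-class
    design, on zero-variance columns (remove them first), and when more
    components are requested than the centered X matrix supports.
    """
    if isinstance(X, AbundanceMatrix):
        frame = X.filled()
    elif isinstance(X, pd.DataFrame):
        frame = X.fillna(0.0)
    else:
        frame = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDesignError("PLS-DA needs at least two classes")
    n, p = frame.shape
    if n != y.size:
        raise ValidationError(f"field 'y': {y.size} labels for {n} samples")
    if n < n_components + 2:
        raise ValidationError(
            f"field 'n_components': need n_samples >= n_components + 2 ({n} < {n_components + 2})"
        )
    Xm = frame.to_numpy(dtype=float)
    stds = Xm.std(axis=0, ddof=1)
    dead = [str(frame.columns[j]) for j in np.flatnonzero(stds == 0)]
    if dead:
        raise ValidationError(f"field 'X': zero-variance column(s) {dead}; remove them first")
    rank = np.linalg.matrix_rank(Xm - Xm.mean(axis=0))
    if n_components > rank:
        raise RankError(f"n_components={n_components} exceeds X rank {rank}")
    Y = (y[:, None] == classes[None, :]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns near-null residual deflation
        pls = PLSRegression(n_components=n_components, scale=True).fit(Xm, Y)
    W = pls.x_weights_          # (p, A), unit-norm columns
    T = pls.x_scores_           # (n, A)
    Q = pls.y_loadings_         # (k, A)
    ssy = np.einsum("na,na->a", T, T) * np.einsum("ka,ka->a", Q, Q)
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=frame.columns, name="vip")


def _passes(record, criteria: ScreeningCriteria) -> tuple[str, ...]:
    hits = []
    if record.relative_content >= criteria.rel_content_min:
        hits.append("relative_content")
    if record.oav >= criteria.oav_min:
        hits.append("oav")
    if record.vip is not None and record.vip >= criteria.vip_min:
        hits.append("vip")
    return tuple(hits)


def screen_key_compounds(table: StageTable, criteria: ScreeningCriteria) -> ScreeningOutcome:
    """Apply the multi-indicator screen, preserving record order."""
    kept, passed = [], {}
    for rec in table:
        hits = _passes(rec, criteria)
        keep = len(hits) >= 1 if criteria.mode == "ANY" else len(hits) == 3
        if keep:
            kept.append(rec)
            passed[rec.canonical_name] = hits
    return ScreeningOutcome(
        table=StageTable(stage=table.stage, records=tuple(kept), sample_id=table.sample_id),
        passed=passed,
    )
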