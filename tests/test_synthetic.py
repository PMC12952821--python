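"""Generator determinism, parameter recovery, ND masking, planted edges."""

import numpy as np
import pandas as pd
import pytest

from aromatrace.network import build_network
from aromatrace.synthetic import (
    SyntheticConfig,
    TruthClass,
    expected_fate,
    generate_dataset,
    inject_correlation_structure,
)
from aromatrace.transfer import averages_from_matrices, build_transfer_table
from aromatrace.types import Stage


def _estimated_records(ds):
    averages = averages_from_matrices(ds.leaf, ds.py, ds.smoke)
    return {r.canonical_name: r for r in build_transfer_table(averages)}


def test_same_seed_is_bit_identical():
    cfg = SyntheticConfig(seed=42)
    a, b = generate_dataset(cfg), generate_dataset(cfg)
    for ma, mb in zip(a.matrices, b.matrices):
        pd.testing.assert_frame_equal(ma.data, mb.data)
    assert a.truth == b.truth


def test_noiseless_data_reproduces_truth_exactly():
    ds = generate_dataset(SyntheticConfig(noise_cv=0.0, nd_fraction=0.0, seed=7))
    recs = _estimated_records(ds)
    for t in ds.truth:
        rec = recs[t.name]
        if t.true_dte is None:
            assert rec.dte is None
        else:
            assert rec.dte == pytest.approx(t.true_dte, rel=1e-12)
            assert rec.tgf == pytest.approx(t.true_tgf, rel=1e-12)


def test_dte_bias_vanishes_as_noise_shrinks():
    errs = {}
    for cv in (0.0, 0.05, 0.2):
        ds = generate_dataset(SyntheticConfig(n_samples=50, noise_cv=cv, seed=11))
        recs = _estimated_records(ds)
        rel = [
            abs(recs[t.name].dte - t.true_dte) / t.true_dte
            for t in ds.truth
            if t.truth_class in (TruthClass.TRANSFERRED, TruthClass.LOST)
        ]
        errs[cv] = float(np.mean(rel))
    assert errs[0.0] < 1e-12
    assert errs[0.05] < 0.05
    assert errs[0.2] < 0.15
    assert errs[0.0] <= errs[0.05] <= errs[0.2]


def test_dte_recovery_at_study_noise():
    """cv = 0.2, n = 50: ≥90% of transferred compounds within 10%."""
    ds = generate_dataset(SyntheticConfig(n_samples=50, n_transferred=40, noise_cv=0.2, seed=5))
    recs = _estimated_records(ds)
    transferred = [t for t in ds.truth if t.truth_class is TruthClass.TRANSFERRED]
    within = [
        abs(recs[t.name].dte - t.true_dte) / t.true_dte <= 0.10 for t in transferred
    ]
    assert sum(within) / len(within) >= 0.90


def test_fate_label_recovery_at_panel_size():
    """cv = 0.1, n = 14: ≥95% of compounds get their generating class's label."""
    ds = generate_dataset(SyntheticConfig(n_samples=14, noise_cv=0.1, seed=3))
    recs = _estimated_records(ds)
    hits = [recs[t.name].fate_label is expected_fate(t) for t in ds.truth]
    assert sum(hits) / len(hits) >= 0.95


def test_nd_masking_bounds():
    full = generate_dataset(SyntheticConfig(nd_fraction=1.0, seed=1))
    for m in full.matrices:
        assert m.data.isna().all().all()
    some = generate_dataset(SyntheticConfig(nd_fraction=0.3, seed=1))
    for m in some.matrices:
        vals = m.data.to_numpy()
        assert np.nanmin(vals, initial=0.0) >= 0.0


def test_planted_edge_recovered_and_null_pair_absent():
    node_hi = ((Stage.LEAF, "syn_transferred_01"), (Stage.SMOKE, "syn_transferred_02"), 0.95)
    node_null = ((Stage.LEAF, "syn_transferred_03"), (Stage.SMOKE, "syn_transferred_04"), 0.0)
    ds = inject_correlation_structure(
        generate_dataset(SyntheticConfig(n_samples=50, noise_cv=0.2, seed=2)),
        [node_hi, node_null],
        seed=9,
    )
    edges = build_network(ds.matrices, r_min=0.8, p_max=0.01)
    pairs = {(e.node_a, e.node_b) for e in edges}
    assert (("LEAF", "syn_transferred_01"), ("SMOKE", "syn_transferred_02")) in pairs
    assert (("LEAF", "syn_transferred_03"), ("SMOKE", "syn_transferred_04")) not in pairs
    planted = next(
        e for e in edges
        if (e.node_a, e.node_b) == (("LEAF", "syn_transferred_01"), ("SMOKE", "syn_transferred_02"))
    )
    assert planted.r == pytest.approx(0.95, abs=0.1)


def test_empty_pair_list_passes_through_unchanged():
    ds = generate_dataset(SyntheticConfig(seed=4))
    out = inject_correlation_structure(ds, [], seed=0)
    for ma, mb in zip(ds.matrices, out.matrices):
        pd.testing.assert_frame_equal(ma.data, mb.data)


def test_unknown_node_raises():
    ds = generate_dataset(SyntheticConfig(seed=4))
    with pytest.raises(KeyError):
        inject_correlation_structure(
            ds, [((Stage.LEAF, "nope"), (Stage.SMOKE, "syn_transferred_01"), 0.5)], seed=0
        )
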