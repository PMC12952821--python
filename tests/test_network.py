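"""Pearson edges against brute-force oracles, and filter monotonicity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aromatrace.errors import AlignmentError, ConstantVectorError
from aromatrace.network import build_network, pearson_r_p, write_edges
from aromatrace.types import AbundanceMatrix, Stage


def brute_force_r_p(x, y):
    """Independent oracle: covariance formula + t-distribution tail."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xd, yd = x - x.mean(), y - y.mean()
    r = (xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, p


def test_perfect_linear_dependence():
    x = np.arange(10.0)
    r, p = pearson_r_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p < 1e-12
    r_neg, _ = pearson_r_p(x, -x)
    assert r_neg == pytest.approx(-1.0)


def test_five_point_vectors_match_brute_force():
    x = [1.0, 2, 3, 4, 5]
    y = [2.0, 1, 4, 3, 6]
    r, p = pearson_r_p(x, y)
    r_ref, p_ref = brute_force_r_p(x, y)
    assert r == pytest.approx(r_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_symmetry_in_arguments():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=12), rng.normal(size=12)
    assert pearson_r_p(x, y) == pearson_r_p(y, x)


def test_constant_vector_raises():
    with pytest.raises(ConstantVectorError):
        pearson_r_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def _matrices(seed=0, n=14, m=10):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    mats = []
    for stage in (Stage.LEAF, Stage.SMOKE):
        data = pd.DataFrame(
            rng.lognormal(size=(n, m)),
            index=samples,
            columns=[f"{stage.value.lower()}_c{j}" for j in range(m)],
        )
        mats.append(AbundanceMatrix(stage, data))
    return mats


def test_shared_vector_across_stages_yields_single_unit_edge():
    rng = np.random.default_rng(3)
    vec = rng.lognormal(size=8)
    samples = [f"S{i}" for i in range(8)]
    leaf = AbundanceMatrix(Stage.LEAF, pd.DataFrame({"a": vec}, index=samples))
    smoke = AbundanceMatrix(Stage.SMOKE, pd.DataFrame({"b": vec}, index=samples))
    edges = build_network([leaf, smoke])
    assert len(edges) == 1
    assert edges[0].r == pytest.approx(1.0)


def test_edge_set_matches_brute_force_all_pairs():
    mats = _matrices(seed=11)
    edges = build_network(mats, r_min=0.5, p_max=0.05, pairing="ALL_PAIRS")
    cols = {}
    for m in mats:
        for name in m.compound_names:
            cols[(m.stage.value, name)] = m.filled()[name].to_numpy()
    expected = set()
    for a, b in itertools.combinations(sorted(cols), 2):
        r, p = brute_force_r_p(cols[a], cols[b])
        if abs(r) > 0.5 and p < 0.05:
            expected.add((a, b))
    assert {(e.node_a, e.node_b) for e in edges} == expected


def test_inter_stage_pairing_excludes_within_stage_pairs():
    mats = _matrices(seed=11)
    edges = build_network(mats, r_min=0.0, p_max=1.0 - 1e-12, pairing="INTER_STAGE")
    assert edges and all(e.node_a[0] != e.node_b[0] for e in edges)


def test_unattainable_threshold_gives_empty_set():
    assert build_network(_matrices(seed=1), r_min=1.01) == []


def test_filter_monotonicity():
    mats = _matrices(seed=4)
    loose = {(e.node_a, e.node_b) for e in build_network(mats, r_min=0.3, p_max=0.2, pairing="ALL_PAIRS")}
    tighter_r = {(e.node_a, e.node_b) for e in build_network(mats, r_min=0.6, p_max=0.2, pairing="ALL_PAIRS")}
    tighter_p = {(e.node_a, e.node_b) for e in build_network(mats, r_min=0.3, p_max=0.01, pairing="ALL_PAIRS")}
    assert tighter_r <= loose and tighter_p <= loose


def test_column_permutation_invariance():
    mats = _matrices(seed=9)
    baseline = {(e.node_a, e.node_b, round(e.r, 12)) for e in build_network(mats, r_min=0.4, p_max=0.1)}
    permuted = [
        AbundanceMatrix(m.stage, m.data[list(reversed(m.compound_names))]) for m in mats
    ]
    shuffled = {(e.node_a, e.node_b, round(e.r, 12)) for e in build_network(permuted, r_min=0.4, p_max=0.1)}
    assert shuffled == baseline


def test_bh_correction_never_adds_edges():
    mats = _matrices(seed=2)
    raw = {(e.node_a, e.node_b) for e in build_network(mats, r_min=0.3, p_max=0.05, pairing="ALL_PAIRS")}
    bh = {(e.node_a, e.node_b) for e in build_network(mats, r_min=0.3, p_max=0.05, pairing="ALL_PAIRS", bh_correct=True)}
    assert bh <= raw


def test_sample_mismatch_raises():
    leaf, smoke = _matrices(seed=0)
    bad = AbundanceMatrix(Stage.SMOKE, smoke.data.iloc[::-1])
    with pytest.raises(AlignmentError):
        build_network([leaf, bad])


def test_edge_csv_has_expected_schema(tmp_path):
    edges = build_network(_matrices(seed=11), r_min=0.5, p_max=0.05, pairing="ALL_PAIRS")
    path = write_edges(edges, tmp_path / "edges.csv")
    header = path.read_text().splitlines()[0]
    assert header == "stage_a,compound_a,stage_b,compound_b,r,p,n"
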