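"""Descriptor tokenization and stage-profile aggregation."""

import random

import pytest

from aromatrace.sensory import (
    CATEGORIES,
    AromaLexicon,
    default_lexicon,
    stage_profile,
    tokenize_descriptors,
)
from aromatrace.types import CompoundRecord, Stage, StageTable


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Sweet, caramel, buttery", ["sweet", "caramel", "buttery"]),
        ("", []),
        ("Fruity, green/grassy, woody", ["fruity", "green", "grassy", "woody"]),
        (
            "Sweet, caramel, buttery, toasted/Nutty (almond-like), and toasty/Bready, "
            "with a slight sourness/Tang",
            ["sweet", "caramel", "buttery", "toasted", "nutty", "toasty", "bready",
             "sourness", "tang"],
        ),
        ("Amine odor, sour odor, unpleasant odor", ["amine", "sour", "unpleasant"]),
    ],
)
def test_tokenize_descriptors(text, expected):
    assert tokenize_descriptors(text) == expected


def _rec(name, descriptors, rel=1.0, oav=0.0):
    return CompoundRecord(
        canonical_name=name, raw_name=name, stage=Stage.LEAF,
        rt_min=1.0, relative_content=rel, oav=oav,
        odor_descriptors=tuple(descriptors),
    )


def test_single_category_table_concentrates_all_mass():
    table = StageTable(Stage.LEAF, (_rec("a", ["sweet"], rel=3.0), _rec("b", ["sweet"], rel=2.0)))
    profile = stage_profile(table, weighting="RELATIVE_CONTENT")
    assert profile.scores["sweet"] == pytest.approx(5.0)
    assert profile.total == pytest.approx(5.0)


def test_profile_mass_conservation(py_table):
    """Total profile mass equals summed weights (token fractions sum to 1)."""
    profile = stage_profile(py_table, weighting="RELATIVE_CONTENT")
    expected = sum(r.relative_content for r in py_table if r.odor_descriptors)
    assert profile.total == pytest.approx(expected)
    counts = stage_profile(py_table, weighting="COUNT")
    assert counts.total == pytest.approx(sum(1 for r in py_table if r.odor_descriptors))


def test_empty_table_gives_zero_profile():
    profile = stage_profile(StageTable(Stage.LEAF, ()))
    assert profile.total == 0.0
    assert set(profile.scores) == set(CATEGORIES)


def test_profile_invariant_to_record_and_token_order():
    recs = [
        _rec("a", ["sweet", "woody"], rel=2.0),
        _rec("b", ["floral"], rel=1.0),
        _rec("c", ["smoky", "sweet", "sour"], rel=4.0),
    ]
    baseline = stage_profile(StageTable(Stage.LEAF, tuple(recs))).scores
    rng = random.Random(3)
    for _ in range(4):
        rng.shuffle(recs)
        flipped = [
            _rec(r.canonical_name, tuple(reversed(r.odor_descriptors)), rel=r.relative_content)
            for r in recs
        ]
        assert stage_profile(StageTable(Stage.LEAF, tuple(flipped))).scores == pytest.approx(baseline)


def test_pyrolysate_profile_sweet_caramel_dominate_fruity_under_oav():
    """Aroma-activity weighting puts the pyrolysate's mass on the
    Maillard sweet/caramel side, far above fruity+citrus — the
    caramelized-sweet character of heated tobacco."""
    lexicon = default_lexicon()
    from aromatrace.fixtures import load_stage_table

    py = load_stage_table(Stage.PYROLYSIS)
    profile = stage_profile(py, lexicon, weighting="OAV")
    sweet_side = profile.scores["sweet"] + profile.scores["caramel"]
    fruity_side = profile.scores["fruity"] + profile.scores["citrus"]
    assert sweet_side == pytest.approx(11.519, rel=1e-3)  # frozen from this fixture
    assert fruity_side == pytest.approx(2.568, rel=1e-3)
    assert sweet_side > 4 * fruity_side


def test_oav_cap_limits_single_compound_dominance():
    table = StageTable(Stage.LEAF, (_rec("bomb", ["sweet"], oav=13336.36),))
    capped = stage_profile(table, weighting="OAV", oav_cap=100.0)
    assert capped.scores["sweet"] == pytest.approx(100.0)


def test_unknown_tokens_route_to_other():
    lex = AromaLexicon({"sweet": "sweet"})
    table = StageTable(Stage.LEAF, (_rec("a", ["sweet", "blorpy"], rel=2.0),))
    profile = stage_profile(table, lex, weighting="RELATIVE_CONTENT")
    assert profile.scores["sweet"] == pytest.approx(1.0)
    assert profile.scores["other"] == pytest.approx(1.0)
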