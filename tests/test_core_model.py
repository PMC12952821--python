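"""Domain types, CSV schemas, round-trips and the packaged tables."""

import pytest

from aromatrace import io
from aromatrace.errors import DuplicateCompoundError, SchemaError, ValidationError
from aromatrace.types import (
    ND,
    CompoundRecord,
    Stage,
    StageTable,
    SynonymTable,
    canonicalize_name,
)

HEADER = ",".join(io.STAGE_TABLE_COLUMNS)


@pytest.mark.parametrize(
    "table_fixture,count",
    [("leaf_table", 13), ("py_table", 27), ("smoke_table", 20)],
)
def test_packaged_table_record_counts(table_fixture, count, request):
    """Each stage's key-compound table carries its published row count."""
    assert len(request.getfixturevalue(table_fixture)) == count


@pytest.mark.parametrize("table_fixture", ["leaf_table", "py_table", "smoke_table"])
def test_roundtrip_is_identity(table_fixture, request, tmp_path, synonyms):
    """read(write(t)) reproduces every record field-for-field (under the
    same synonym table, since canonicalization applies on read)."""
    table = request.getfixturevalue(table_fixture)
    path = io.write_stage_table(table, tmp_path / "t.csv")
    back = io.read_stage_table(path, table.stage, synonyms)
    assert len(back) == len(table)
    for a, b in zip(table, back):
        assert a == b


def test_nd_sentinel_written_literally(tmp_path):
    rec = CompoundRecord(
        canonical_name="foo",
        raw_name="Foo",
        stage=Stage.LEAF,
        rt_min=1.0,
        relative_content=1.0,
        oav=0.0,
        odor_threshold=ND,
    )
    path = io.write_stage_table(StageTable(Stage.LEAF, (rec,)), tmp_path / "nd.csv")
    assert ",ND," in path.read_text()
    assert io.read_stage_table(path, Stage.LEAF).records[0].odor_threshold is ND


def test_descriptor_commas_survive_roundtrip(tmp_path):
    """Commas inside parenthesized descriptor qualifiers are preserved."""
    rec = CompoundRecord(
        canonical_name="bar",
        raw_name="Bar",
        stage=Stage.SMOKE,
        rt_min=2.0,
        relative_content=0.5,
        oav=1.0,
        odor_descriptors=("floral (rose, violet)", "sweet"),
    )
    path = io.write_stage_table(StageTable(Stage.SMOKE, (rec,)), tmp_path / "q.csv")
    back = io.read_stage_table(path, Stage.SMOKE)
    assert back.records[0].odor_descriptors == ("floral (rose, violet)", "sweet")


def test_empty_file_with_valid_header(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text(HEADER + "\n")
    assert len(io.read_stage_table(p, Stage.LEAF)) == 0


def test_missing_column_named_in_schema_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(HEADER.replace("oav,", "") + "\n")
    with pytest.raises(SchemaError, match="oav"):
        io.read_stage_table(p, Stage.LEAF)


def test_negative_abundance_reports_row_index(tmp_path):
    p = tmp_path / "neg.csv"
    p.write_text(HEADER + "\nGood,sweet,1.0,,ND,1.0,,0,,x\nBad,sweet,1.0,,ND,-5,,0,,x\n")
    with pytest.raises(ValidationError, match="row 1"):
        io.read_stage_table(p, Stage.LEAF)


def test_duplicate_canonical_name_lists_both_raw_names(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(HEADER + "\nPhenol,sweet,1.0,,ND,1.0,,0,,x\nPHENOL ,sweet,2.0,,ND,2.0,,0,,x\n")
    with pytest.raises(DuplicateCompoundError) as err:
        io.read_stage_table(p, Stage.LEAF)
    assert "Phenol" in str(err.value) and "PHENOL" in str(err.value)


def test_canonicalization_normalizes_case_space_and_primes():
    assert canonicalize_name("  2,3′-Dipyridyl ") == "2,3'-dipyridyl"
    assert canonicalize_name("2,3'-dipyridyl") == "2,3'-dipyridyl"
    assert canonicalize_name("D-Limonene") == canonicalize_name("d-limonene")


def test_synonyms_unify_phytol_and_nicotine(synonyms):
    long_name = canonicalize_name("3,7,11,15-Tetramethyl-2-hexadecen-1-ol")
    assert canonicalize_name("Phytol", synonyms) == long_name
    assert canonicalize_name("Nicotine", synonyms) == canonicalize_name(
        "Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-"
    )


def test_synonym_table_rejects_non_functional_mapping():
    with pytest.raises(ValidationError):
        SynonymTable({"a": "b", "A": "c"})


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(relative_content=150.0), "relative_content"),
        (dict(oav=-1.0), "oav"),
        (dict(vip=-0.1), "vip"),
        (dict(odor_threshold=-2.0), "odor_threshold"),
        (dict(concentration=2.0, odor_threshold=1.0, oav=5.0), "oav"),
    ],
)
def test_record_validation_names_offending_field(kwargs, field):
    base = dict(
        canonical_name="x",
        raw_name="x",
        stage=Stage.LEAF,
        rt_min=1.0,
        relative_content=1.0,
        oav=0.0,
    )
    base.update(kwargs)
    with pytest.raises(ValidationError, match=field):
        CompoundRecord(**base)
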