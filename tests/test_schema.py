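import pytest
import yaml

import emrsql as E
from emrsql.errors import ExecutionError, LoadError, SchemaError
from emrsql.schema import ColumnDef, schema_to_dict, schema_from_dict


def test_bundled_schema_shape(schema):
    assert [t.name for t in schema.tables] == [
        "demographic", "diagnoses", "procedures", "prescriptions", "lab"
    ]
    assert [len(t.columns) for t in schema.tables] == [23, 5, 5, 7, 9]
    assert len(schema.columns) == 49


def test_single_table_schema_trivially_connected(tmp_path):
    p = tmp_path / "one.yaml"
    p.write_text(yaml.safe_dump(
        {"tables": [{"name": "t", "columns": [{"name": "a"}]}]}))
    s = E.load_schema(p)
    assert len(s.tables) == 1


@pytest.mark.parametrize(
    "raw, fragment",
    [
        ({"tables": [{"name": "t", "columns": [{"name": "a"}]},
                     {"name": "u", "columns": [{"name": "a"}]}]},
         "disconnected"),
        ({"tables": [{"name": "t", "columns": [{"name": "a"}]},
                     {"name": "u", "columns": [{"name": "a"}]}],
          "joins": [["t", "u", "missing"]]},
         "missing"),
        ({"tables": [{"name": "t", "columns": []}]}, "no columns"),
        ({"tables": [{"name": "t",
                      "columns": [{"name": "a", "kind": "blob"}]}]},
         "value kind"),
    ],
)
def test_invalid_schema_rejected(tmp_path, raw, fragment):
    p = tmp_path / "bad.yaml"
    p.write_text(yaml.safe_dump(raw))
    with pytest.raises(SchemaError, match=fragment):
        E.load_schema(p)


def test_schema_dict_round_trip(schema):
    assert schema_from_dict(schema_to_dict(schema)) == schema


def test_fixture_counts_and_rebuild_determinism(schema, tmp_path):
    records = E.sample_records(schema, 10, seed=2)
    probe = 'select count(distinct demographic.subject_id) from demographic'
    db1 = E.build_fixture_db(schema, records, tmp_path / "a.db")
    assert E.execute_query(db1, probe).rows == [(10,)]
    db2 = E.build_fixture_db(schema, records, tmp_path / "b.db")
    q = 'select name, admityear from demographic'
    assert E.execute_query(db1, q).rows == E.execute_query(db2, q).rows
    # same handle, same query, twice
    assert E.execute_query(db1, q).rows == E.execute_query(db1, q).rows


def test_empty_records_make_empty_tables(schema, tmp_path):
    db = E.build_fixture_db(schema, {}, tmp_path / "empty.db")
    for t in schema.tables:
        assert E.execute_query(db, f"select count(*) from {t.name}").rows == [(0,)]


def test_value_kind_mismatch_rejected(schema, tmp_path):
    rows = {"demographic": [{"subject_id": "not-a-number"}]}
    with pytest.raises(LoadError, match="numeric"):
        E.build_fixture_db(schema, rows, tmp_path / "bad.db")


def test_malformed_sql_is_execution_failure_not_crash(schema, tmp_path):
    db = E.build_fixture_db(schema, {}, tmp_path / "x.db")
    with pytest.raises(ExecutionError):
        E.execute_query(db, "selecty nonsense from nowhere")


def test_lookup_values_order_and_dedup(schema, tmp_path):
    rows = {"demographic": [
        {"subject_id": 1, "name": "John Gartman"},
        {"subject_id": 2, "name": "Walter Locher"},
        {"subject_id": 3, "name": "John Gartman"},
    ]}
    db = E.build_fixture_db(schema, rows, tmp_path / "n.db")
    col = schema.table("demographic").column("name")
    # stored lower-cased, first-seen order, duplicates collapsed
    assert E.lookup_values(db, col) == ["john gartman", "walter locher"]
    empty = schema.table("lab").column("label")
    assert E.lookup_values(db, empty) == []
    with pytest.raises(SchemaError):
        E.lookup_values(db, ColumnDef(name="nope", table="demographic"))
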