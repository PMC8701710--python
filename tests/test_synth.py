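import numpy as np
import pytest

import emrsql as E
from emrsql.errors import GenerationError
from emrsql.grammar import tree_to_actions
from emrsql.sqlgen import sql_to_tree


def test_schema_shape(schema):
    s = E.make_schema()
    assert len(s.tables) == 5
    assert [len(t.columns) for t in s.tables] == [23, 5, 5, 7, 9]
    # star join on the admission key keeps the graph connected
    assert all(key == "hadm_id" for _, _, key in s.join_edges)


def test_records_deterministic_and_referentially_intact(schema):
    r1 = E.sample_records(schema, 50, seed=7)
    r2 = E.sample_records(schema, 50, seed=7)
    assert r1 == r2
    admissions = {row["hadm_id"] for row in r1["demographic"]}
    for table in ("diagnoses", "procedures", "prescriptions", "lab"):
        assert all(row["hadm_id"] in admissions for row in r1[table])
    names = {row["name"] for row in r1["demographic"]}
    assert len(names) <= 50
    with pytest.raises(GenerationError):
        E.sample_records(schema, 0, seed=1)


def test_pairs_parse_convert_execute(schema, corpus300):
    examples, db = corpus300
    assert len(examples) == 300
    for ex in examples:
        tree = sql_to_tree(ex.sql, schema)  # 100% parse
        actions = tree_to_actions(tree, ex.marked_question)  # convertible
        assert actions == ex.actions
        assert db.executes_ok(ex.sql)  # 100% executable


def test_generation_deterministic(schema):
    records = E.sample_records(schema, 40, seed=3)
    cfg = E.GenConfig(n_pairs=60, n_patients=40, seed=3)
    ex1, db1 = E.generate_pairs(schema, records, cfg)
    ex2, db2 = E.generate_pairs(schema, records, cfg)
    assert [(e.question, e.sql, e.split) for e in ex1] == [
        (e.question, e.sql, e.split) for e in ex2]


def test_split_ratios(schema, corpus300):
    examples, _ = corpus300
    counts = {s: sum(1 for e in examples if e.split == s)
              for s in ("train", "val", "test")}
    assert counts == {"train": 240, "val": 30, "test": 30}


def test_zero_paraphrase_keeps_template_text(schema):
    records = E.sample_records(schema, 40, seed=3)
    ex0, _ = E.generate_pairs(
        schema, records, E.GenConfig(n_pairs=40, n_patients=40, seed=3,
                                     paraphrase_rate=0.0))
    # with the noise channel off, rephrasing words that only the synonym
    # table can introduce never appear in the questions
    markers = {"subjects", "display"}
    for e in ex0:
        assert not (set(e.question.split()) & markers)


def test_paraphrase_preserves_value_spans(schema):
    records = E.sample_records(schema, 40, seed=3)
    ex, _ = E.generate_pairs(
        schema, records, E.GenConfig(n_pairs=80, n_patients=40, seed=3,
                                     paraphrase_rate=1.0))
    for e in ex:
        tree = sql_to_tree(e.sql, schema)
        tree_to_actions(tree, e.marked_question)  # values still present


def test_grammar_closure_at_500(schema):
    records = E.sample_records(schema, 60, seed=5)
    ex, _ = E.generate_pairs(
        schema, records, E.GenConfig(n_pairs=500, n_patients=60, seed=5))
    used = set()
    for e in ex:
        for node in sql_to_tree(e.sql, schema).walk():
            if node.production is not None:
                used.add(node.production.id)
    assert used == set(range(24))


def test_corpus_statistics_near_targets(schema, corpus300):
    """Mean select-column and condition counts match the design targets
    (1.1 and 1.76) within +-0.3."""
    examples, _ = corpus300
    n_sel = n_cond = 0
    for e in examples:
        t = sql_to_tree(e.sql, schema)
        n_sel += len(t.children[0].children[0].children)
        n_cond += sum(1 for n in t.walk()
                      if n.symbol == "Filter"
                      and n.production.tag not in ("and", "or"))
    assert abs(n_sel / len(examples) - 1.1) <= 0.3
    assert abs(n_cond / len(examples) - 1.76) <= 0.3
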