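import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emrsql as E
from emrsql.linking import tokenize_with_offsets


def test_tokenize_splits_punctuation_and_lowercases():
    assert E.tokenize("Tell me the insurance of James Sloan.") == [
        "tell", "me", "the", "insurance", "of", "james", "sloan", "."
    ]
    assert E.tokenize("") == []


def test_token_offsets_recover_source_spans():
    rng = np.random.default_rng(0)
    words = ["alpha", "beta2", "x-ray", "42", "Gamma,", "delta."]
    for _ in range(100):
        text = " ".join(rng.choice(words, size=rng.integers(1, 8)))
        tokens, offsets = tokenize_with_offsets(text)
        for tok, (a, b) in zip(tokens, offsets):
            assert text.lower()[a:b] == tok


def test_insurance_linked_as_demographic_column(schema):
    toks = E.tokenize("tell me the insurance and primary disease of james sloan")
    mq = E.link(toks, schema)
    marked = {s.tokens: (s.mark, s.entity) for s in mq.spans if s.mark != "NONE"}
    assert marked[("insurance",)] == ("COLUMN", "demographic.insurance")


def test_column_mark_beats_table_mark(schema):
    # "lab" is a table name, and also a word-subset of no column; make an
    # ambiguous token by checking "diagnoses" (table) vs "diagnosis" (column)
    toks = ["lab", "flag"]
    mq = E.link(toks, schema)
    by_tok = {s.tokens: s for s in mq.spans}
    assert by_tok[("lab",)].mark == "TABLE"
    assert by_tok[("flag",)].mark == "COLUMN"
    # a word matching both a column and a table must take the column mark
    toks = E.tokenize("diagnosis")
    mq = E.link(toks, schema)
    assert mq.spans[0].mark == "COLUMN"
    assert mq.spans[0].entity == "demographic.diagnosis"


def test_column_priority_on_true_collision():
    """A token matching a column name AND a table name takes COLUMN."""
    from emrsql.schema import ColumnDef, DatabaseSchema, TableDef

    collide = DatabaseSchema(tables=(
        TableDef(name="record", columns=(
            ColumnDef(name="rid", table="record"),
            ColumnDef(name="visits", table="record"),
        )),
        TableDef(name="visits", columns=(
            ColumnDef(name="rid", table="visits"),
        )),
    ), join_edges=(("record", "visits", "rid"),))
    mq = E.link(["count", "visits", "please"], collide)
    span = next(s for s in mq.spans if s.tokens == ("visits",))
    assert span.mark == "COLUMN"
    assert span.entity == "record.visits"


def test_word_subset_matches_underscored_column(schema):
    mq = E.link(["days", "stay"], schema)
    assert mq.spans[0].tokens == ("days", "stay")
    assert mq.spans[0].mark == "COLUMN"
    assert mq.spans[0].entity == "demographic.days_stay"


def test_unrelated_question_all_none(schema):
    toks = E.tokenize("hello cruel world")
    mq = E.link(toks, schema)
    assert all(s.mark == "NONE" and len(s.tokens) == 1 for s in mq.spans)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sampled_from(
    ["days", "stay", "admission", "type", "insurance", "lab", "of", "the",
     "james", "2150", "marital", "status", "drug", "route"]),
    min_size=0, max_size=12))
def test_partition_and_idempotence(tokens):
    schema = E.bundled_schema()
    mq = E.link(tokens, schema)
    flat = [t for s in mq.spans for t in s.tokens]
    assert flat == tokens  # spans partition the question exactly
    again = E.link(list(mq.source_tokens), schema)
    assert again.spans == mq.spans  # idempotent


def test_longest_match_dominates(schema):
    # "admission type" links as one 2-gram; neither word gets its own mark
    mq = E.link(["admission", "type"], schema)
    assert len(mq.spans) == 1
    assert mq.spans[0].entity == "demographic.admission_type"
    # entity spans never overlap
    ranges = mq.span_token_ranges
    for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
        assert b1 < a2
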