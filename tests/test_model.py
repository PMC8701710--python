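import numpy as np
import pytest

import emrsql as E
from emrsql.grammar import DecodingState
from emrsql.model import (
    CLS,
    collate,
    preprocess_example,
    serialize_input,
    teacher_forced_loss,
)
from emrsql.sqlgen import sql_to_tree


def mq(schema, text="tell me the insurance of james sloan"):
    return E.link(E.tokenize(text), schema)


def test_serialize_layout_and_token_count(schema):
    q = mq(schema)
    stream = serialize_input(q, schema)
    assert stream.tokens[0] == CLS
    # brute-force count: CLS + question words + one mark per linked span +
    # 3 block separators + all column words + all table words
    n_marks = sum(1 for s in q.spans if s.mark != "NONE")
    n_col_words = sum(len(c.name_words) for c in schema.columns)
    n_tab_words = sum(len(t.name_words) for t in schema.tables)
    expected = 1 + len(q.source_tokens) + n_marks + 3 + n_col_words + n_tab_words
    assert len(stream.tokens) == expected
    assert len(stream.span_positions) == len(q.spans)
    assert len(stream.col_positions) == len(schema.columns)


def test_serialize_empty_question(schema):
    empty = E.link([], schema)
    stream = serialize_input(empty, schema)
    assert stream.tokens[0] == CLS
    assert stream.span_positions == []


def test_encode_deterministic_and_shapes(schema, tiny_params):
    stream = serialize_input(mq(schema), schema)
    enc1 = E.encode(stream, tiny_params)
    enc2 = E.encode(stream, tiny_params)
    np.testing.assert_array_equal(enc1.H_X.data, enc2.H_X.data)
    assert enc1.H_C.shape == (1, 49, tiny_params.config.enc_width)
    assert enc1.H_T.shape == (1, 5, tiny_params.config.enc_width)
    assert np.all(np.isfinite(enc1.H_X.data))


def test_column_swap_permutes_column_encodings(schema, tiny_params):
    stream = serialize_input(mq(schema), schema)
    enc = E.encode(stream, tiny_params)
    # swapping two single-word columns of equal width permutes their pooled
    # rows and leaves everything else identical
    i = schema.column_index("demographic", "insurance")
    j = schema.column_index("demographic", "ethnicity")
    swapped = serialize_input(mq(schema), schema)
    swapped.col_positions[i], swapped.col_positions[j] = (
        swapped.col_positions[j], swapped.col_positions[i])
    enc_sw = E.encode(swapped, tiny_params)
    np.testing.assert_allclose(enc_sw.H_C.data[0, i], enc.H_C.data[0, j],
                               atol=1e-6)
    np.testing.assert_allclose(enc_sw.H_C.data[0, j], enc.H_C.data[0, i],
                               atol=1e-6)
    np.testing.assert_allclose(enc_sw.H_T.data, enc.H_T.data, atol=1e-6)


def test_init_decoder_contract(schema, tiny_params):
    import emrsql.autodiff as ad

    zeros = ad.Tensor(np.zeros((1, tiny_params.config.enc_width), np.float32))
    w = tiny_params.tensors["init_w"].data.copy()
    b = tiny_params.tensors["init_b"].data.copy()
    tiny_params.tensors["init_b"].data[:] = 0.0
    state = E.init_decoder(zeros, tiny_params)
    np.testing.assert_array_equal(state.h.data, 0.0)  # tanh(0) = 0
    tiny_params.tensors["init_b"].data[:] = b
    stream = serialize_input(mq(schema), schema)
    enc = E.encode(stream, tiny_params)
    state = E.init_decoder(enc.h_cls, tiny_params)
    assert np.all(np.abs(state.h.data) < 1.0)  # tanh range
    assert float(np.abs(state.c.data).sum()) == 0.0
    assert state.memory == ()


def test_decode_step_distributions(schema, tiny_params):
    q = mq(schema)
    stream = serialize_input(q, schema)
    enc = E.encode(stream, tiny_params)
    gstate = DecodingState(schema, len(q.source_tokens))
    state = E.init_decoder(enc.h_cls, tiny_params)
    dist, state = E.decode_step(state, enc, gstate, tiny_params)
    assert dist.kind == "rule"
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-5)
    # only Z -> R admissible at the empty state
    assert dist.probs[0] == pytest.approx(1.0, abs=1e-5)
    assert all(dist.prob(E.ApplyRule(r)) == 0.0 for r in range(1, 24))


def test_memory_pointer_two_step_trace(schema, tiny_params):
    """After choosing a column via the schema branch, its schema-branch mass
    is zero at the next column frontier while it stays reachable via MEM."""
    q = mq(schema)
    stream = serialize_input(q, schema)
    enc = E.encode(stream, tiny_params)
    gstate = DecodingState(schema, len(q.source_tokens))
    state = E.init_decoder(enc.h_cls, tiny_params)
    # Z->R, R->Select, Select->A A, A->none C T
    for rid in (0, 1, 4, 6):
        dist, state = E.decode_step(state, enc, gstate, tiny_params)
        a = E.ApplyRule(rid)
        gstate.apply(a)
        E.model._note_action(state, a, q)
    dist, state = E.decode_step(state, enc, gstate, tiny_params)
    assert dist.kind == "column"
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-4)
    chosen = E.SelectColumn(int(np.argmax(dist.probs)))
    gstate.apply(chosen)
    E.model._note_action(state, chosen, q)
    # table, then next A and its column frontier
    dist, state = E.decode_step(state, enc, gstate, tiny_params)
    assert dist.kind == "table"
    tab = dist.best_action()
    gstate.apply(tab)
    E.model._note_action(state, tab, q)
    dist, state = E.decode_step(state, enc, gstate, tiny_params)
    a = E.ApplyRule(6)
    gstate.apply(a)
    E.model._note_action(state, a, q)
    dist, state = E.decode_step(state, enc, gstate, tiny_params)
    assert dist.kind == "column"
    # mixture still sums to one and the chosen column is still reachable
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-4)
    assert dist.probs[chosen.column_id] > 0.0
    # schema-branch-only probability of the chosen column is exactly zero
    sch_mask = np.zeros((1, 49), bool)
    sch_mask[0, gstate.schema_branch_column_ids()] = True
    assert not sch_mask[0, chosen.column_id]


def test_random_weight_inference_always_parses_and_executes(
        schema, corpus300, tiny_params):
    examples, db = corpus300
    rng = np.random.default_rng(9)
    idx = rng.choice(len(examples), size=25, replace=False)
    for i in idx:
        sql = E.infer(examples[i].question, schema, db, tiny_params)
        sql_to_tree(sql, schema)  # parses
        assert db.executes_ok(sql)  # executes


def test_inference_deterministic(schema, corpus300, tiny_params):
    examples, db = corpus300
    q = examples[0].question
    assert E.infer(q, schema, db, tiny_params) == E.infer(q, schema, db, tiny_params)


def test_teacher_forced_loss_matches_sequence_loss(schema, corpus300,
                                                   tiny_params):
    """Batched training loss equals the per-step API loss on one example."""
    examples, _ = corpus300
    ex = examples[0]
    pre = preprocess_example(ex.marked_question, ex.actions, schema,
                             tiny_params.vocab, tiny_params.config)
    batch = collate([pre], 49, 5)
    _, per = teacher_forced_loss(tiny_params, batch)

    # replay with decode_step collecting per-step distributions
    stream = serialize_input(ex.marked_question, schema)
    enc = E.encode(stream, tiny_params)
    gstate = DecodingState(schema, len(ex.marked_question.source_tokens))
    state = E.init_decoder(enc.h_cls, tiny_params)
    dists = []
    for a in ex.actions:
        dist, state = E.decode_step(state, enc, gstate, tiny_params)
        dists.append(dist)
        gstate.apply(a)
        E.model._note_action(state, a, ex.marked_question)
    expected = E.sequence_loss(ex.actions, dists)
    assert per[0] == pytest.approx(expected, rel=2e-3, abs=1e-3)
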