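import numpy as np
import pytest

import emrsql as E
from emrsql.errors import EmrSqlError, InputError
from emrsql.grammar import DecodingState
from emrsql.model import serialize_input
from emrsql.sqlgen import canonicalize
from emrsql.training import load_checkpoint, save_checkpoint


def replay_dists(ex, params, schema):
    stream = serialize_input(ex.marked_question, schema)
    enc = E.encode(stream, params)
    gstate = DecodingState(schema, len(ex.marked_question.source_tokens))
    state = E.init_decoder(enc.h_cls, params)
    dists = []
    for a in ex.actions:
        dist, state = E.decode_step(state, enc, gstate, params)
        dists.append(dist)
        gstate.apply(a)
        E.model._note_action(state, a, ex.marked_question)
    return dists


def test_sequence_loss_uniform_closed_form(schema, corpus300, tiny_params):
    """With distributions replaced by uniform ones over the admissible set,
    the loss is the closed form sum of log k (pointer steps per pointer)."""
    examples, _ = corpus300
    ex = examples[1]
    dists = replay_dists(ex, tiny_params, schema)
    uniform = []
    expected = 0.0
    n_spans = len(ex.marked_question.spans)
    for d in dists:
        if d.kind == "value":
            # uniform start over S spans; end uniform over spans >= start
            gold_start = None
            for a in ex.actions:
                pass
            uniform.append(d)
            continue
        k = int((d.probs > 0).sum())
        d.probs = np.where(d.probs > 0, 1.0 / k, 0.0)
        expected += np.log(k)
        uniform.append(d)
    # value steps keep model probabilities; add their true contribution
    for a, d in zip(ex.actions, dists):
        if d.kind == "value":
            starts = {r[0]: i for i, r in enumerate(d.span_ranges)}
            ends = {r[1]: i for i, r in enumerate(d.span_ranges)}
            s, e = starts[a.start], ends[a.end]
            expected -= np.log(d.p_start[s]) + np.log(d.p_end(s)[e])
    got = E.sequence_loss(ex.actions, uniform)
    assert got == pytest.approx(expected, rel=1e-5)


def test_sequence_loss_perfect_probabilities_zero(schema, corpus300,
                                                  tiny_params):
    examples, _ = corpus300
    ex = next(e for e in examples
              if not any(isinstance(a, E.SelectValue) for a in e.actions))
    dists = replay_dists(ex, tiny_params, schema)
    for a, d in zip(ex.actions, dists):
        d.probs = np.zeros_like(d.probs)
        if isinstance(a, E.ApplyRule):
            d.probs[a.rule_id] = 1.0
        elif isinstance(a, E.SelectColumn):
            d.probs[a.column_id] = 1.0
        else:
            d.probs[a.table_id] = 1.0
    assert E.sequence_loss(ex.actions, dists) == pytest.approx(0.0, abs=1e-9)


def test_sequence_loss_rejects_inadmissible_gold(schema, corpus300,
                                                 tiny_params):
    examples, _ = corpus300
    ex = examples[2]
    dists = replay_dists(ex, tiny_params, schema)
    bad = [E.ApplyRule(23)] + list(ex.actions[1:])  # Filter rule at Z frontier
    with pytest.raises(EmrSqlError):
        E.sequence_loss(bad, dists)


TINY = dict(enc_width=32, enc_ffn=64, dec_width=64, act_width=32,
            rule_score_width=32)


def test_training_deterministic_under_seed(schema, tmp_path):
    records = E.sample_records(schema, 30, seed=9)
    cfg = E.GenConfig(n_pairs=8, n_patients=30, seed=9,
                      db_path=str(tmp_path / "m.db"))
    examples, db = E.generate_pairs(schema, records, cfg)
    vocab = E.Vocab.build(
        [list(e.marked_question.source_tokens) for e in examples], schema)
    tcfg = E.TrainConfig(learning_rate=5e-3, epochs=15, batch_size=8, seed=9,
                         lr_decay="none")
    losses = []
    for _ in range(2):
        params = E.ModelParams.init(E.ModelConfig(**TINY), vocab, schema,
                                    seed=9)
        res = E.train(examples, tcfg, params)
        losses.append(res.log[-1]["train_loss"])
    assert losses[0] == pytest.approx(losses[1], rel=1e-6)  # fixed seed
    assert res.log[0]["train_loss"] > res.log[-1]["train_loss"]


def test_single_pair_memorization(schema, tmp_path):
    """Trained to convergence on one pair, the model reproduces its SQL."""
    records = E.sample_records(schema, 30, seed=9)
    cfg = E.GenConfig(n_pairs=1, n_patients=30, seed=9,
                      db_path=str(tmp_path / "one.db"))
    examples, db = E.generate_pairs(schema, records, cfg)
    vocab = E.Vocab.build(
        [list(e.marked_question.source_tokens) for e in examples], schema)
    params = E.ModelParams.init(E.ModelConfig(**TINY), vocab, schema, seed=9)
    tcfg = E.TrainConfig(learning_rate=1e-2, epochs=250, batch_size=1,
                         seed=9, lr_decay="cosine")
    E.train(examples, tcfg, params)
    ex = examples[0]
    assert canonicalize(E.infer(ex.question, schema, db, params)) == \
        canonicalize(ex.sql)


def test_empty_corpus_rejected(schema, tiny_params):
    with pytest.raises(InputError):
        E.train([], E.TrainConfig(), tiny_params)


def test_checkpoint_round_trip(schema, corpus300, tiny_params, tmp_path):
    examples, db = corpus300
    save_checkpoint(tmp_path / "ckpt", tiny_params, train_cfg=E.TrainConfig())
    loaded = load_checkpoint(tmp_path / "ckpt")
    q = examples[0].question
    assert E.infer(q, schema, db, loaded) == E.infer(q, schema, db, tiny_params)
    # tampered grammar fingerprint refuses to load
    import json
    meta = json.loads((tmp_path / "ckpt" / "config.json").read_text())
    meta["grammar_fingerprint"] = "deadbeef"
    (tmp_path / "ckpt" / "config.json").write_text(json.dumps(meta))
    with pytest.raises(InputError):
        load_checkpoint(tmp_path / "ckpt")
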