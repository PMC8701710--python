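import numpy as np
import pytest

import emrsql as E
from emrsql.casestudy import CASE_STUDY_PAIRS
from emrsql.errors import InputError
from emrsql.evaluation import acc_ex, acc_lf, component_accuracy, evaluate


GOLD = [g for _, g, _ in CASE_STUDY_PAIRS]
PRED = [p for _, _, p in CASE_STUDY_PAIRS]


def test_gold_vs_gold_is_perfect(case_db, schema):
    rep = evaluate(GOLD, GOLD, case_db, schema)
    assert rep.acc_lf == 1.0 and rep.acc_ex == 1.0
    assert all(v == 1.0 for v in rep.components.values())


def test_length_mismatch_rejected(case_db):
    with pytest.raises(InputError):
        acc_lf(GOLD[:2], GOLD)
    with pytest.raises(InputError):
        acc_ex(GOLD[:2], GOLD, case_db)


def test_join_order_breaks_lf_but_not_ex(case_db):
    ratio, _ = acc_lf([PRED[0]], [GOLD[0]])
    assert ratio == 0.0
    ratio, _ = acc_ex([PRED[0]], [GOLD[0]], case_db)
    assert ratio == 1.0


def test_select_column_order_breaks_both(case_db):
    assert acc_lf([PRED[1]], [GOLD[1]])[0] == 0.0
    assert acc_ex([PRED[1]], [GOLD[1]], case_db)[0] == 0.0


def test_unexecutable_prediction_counts_as_miss(case_db):
    ratio, n = acc_ex(["select nonsense"], [GOLD[0]], case_db)
    assert (ratio, n) == (0.0, 0)


def test_gold_must_execute(case_db):
    with pytest.raises(InputError):
        acc_ex([GOLD[0]], ["select broken from nowhere"], case_db)


def test_component_scores_operator_flip(schema):
    """A flipped comparison operator: condition column+op wrong, value right,
    aggregation and table right."""
    comps_pair5 = component_accuracy([PRED[4]], [GOLD[4]], schema)
    assert comps_pair5["con_c_plus_o"] == 0.0
    assert comps_pair5["con_val"] == 1.0
    assert comps_pair5["agg_op"] == 1.0
    assert comps_pair5["agg_col"] == 1.0
    assert comps_pair5["table"] == 1.0


def test_component_scores_wrong_condition_column(schema):
    comps_pair4 = component_accuracy([PRED[3]], [GOLD[3]], schema)
    assert comps_pair4["con_c_plus_o"] == 0.0
    # join-order swap scores every component correct (unordered collections)
    comps_pair1 = component_accuracy([PRED[0]], [GOLD[0]], schema)
    assert all(v == 1.0 for v in comps_pair1.values())


def test_unparseable_prediction_zeroes_all_components(schema):
    comps = component_accuracy(["complete garbage ("], [GOLD[0]], schema)
    assert all(v == 0.0 for v in comps.values())


def test_report_permutation_invariant(case_db, schema):
    rep1 = evaluate(PRED, GOLD, case_db, schema)
    order = [4, 2, 0, 3, 1]
    rep2 = evaluate([PRED[i] for i in order], [GOLD[i] for i in order],
                    case_db, schema)
    assert rep1.acc_lf == rep2.acc_lf and rep1.acc_ex == rep2.acc_ex
    assert rep1.components == rep2.components


def test_acc_ex_at_least_acc_lf_on_noisy_predictions(schema, corpus300):
    """Canonical equality implies execution equality, so Acc_EX >= Acc_LF
    under any prediction corruption."""
    examples, db = corpus300
    rng = np.random.default_rng(4)
    gold = [e.sql for e in examples[:120]]
    pred = []
    for g in gold:
        r = rng.random()
        if r < 0.5:
            pred.append(g)
        elif r < 0.8:
            pred.append(gold[int(rng.integers(len(gold)))])
        else:
            pred.append(g.replace('"', "'"))
    rep = evaluate(pred, gold, db, schema)
    assert rep.acc_ex >= rep.acc_lf
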