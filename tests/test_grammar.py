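import numpy as np
import pytest

import emrsql as E
from emrsql.errors import (
    JoinPathError,
    MalformedSequenceError,
    UnsupportedSyntaxError,
    ValueNotFoundError,
)
from emrsql.grammar import DecodingState, random_tree
from emrsql.sqlgen import sql_to_tree, tree_to_sql

QTOKS = ("tell me the insurance of james sloan born before 2150 "
         "with 17 extra filler tokens for value spans").split()


def mq_for(schema, tokens=QTOKS):
    return E.link(list(tokens), schema)


def test_production_inventory(schema):
    g = E.productions()
    assert len(g) == 24
    assert len(g.by_lhs("A")) == 7
    # 8 binary comparison rules plus BETWEEN
    comparisons = [p for p in g.by_lhs("Filter") if p.tag not in ("and", "or")]
    assert len(comparisons) == 9
    known = {"Z", "R", "Select", "A", "Filter", "C", "T", "V"}
    tags = {f"agg:{a}" for a in E.grammar.AGGREGATORS} | {
        f"op:{o}" for o in E.grammar.COMPARISONS} | {"and", "or", "between"}
    for p in g.productions:
        assert p.rhs
        for sym in p.rhs:
            assert sym in known or sym in tags


def test_fig_style_running_example(schema):
    # two plain select columns and one equality condition on the name
    sql = ('select demographic."insurance", demographic."diagnosis" '
           'from demographic where demographic."name" = "james sloan"')
    tree = sql_to_tree(sql, schema)
    r = tree.children[0]
    assert r.production.rhs == ("Select", "Filter")
    select, filt = r.children
    assert len(select.children) == 2  # Select -> A A
    assert filt.production.tag == "="
    actions = E.tree_to_actions(tree, mq_for(schema))
    # prefix: Z->R, R->Select Filter, Select->A A, A->none C T, then leaves
    assert actions[0] == E.ApplyRule(0)
    assert actions[1] == E.ApplyRule(2)
    assert actions[2] == E.ApplyRule(4)
    prod3 = E.productions().by_id(actions[3].rule_id)
    assert prod3.lhs == "A" and prod3.tag == "none"
    assert actions[4] == E.SelectColumn(schema.column_index("demographic", "insurance"))
    assert actions[5] == E.SelectTable(0)


def test_min_aggregate_with_year_condition(schema):
    sql = ('select min(demographic."days_stay") from demographic '
           'where demographic."dob_year" > "2200"')
    tree = sql_to_tree(sql, schema)
    select = tree.children[0].children[0]
    assert select.children[0].production.tag == "min"
    assert tree.children[0].children[1].production.tag == ">"


def test_unsupported_constructs_rejected(schema):
    with pytest.raises(UnsupportedSyntaxError, match="GROUP BY"):
        sql_to_tree("select demographic.\"age\" from demographic "
                    "group by demographic.\"age\"", schema)
    with pytest.raises(UnsupportedSyntaxError):
        sql_to_tree("select * from demographic", schema)


def test_single_column_no_where_is_six_actions(schema):
    sql = 'select demographic."age" from demographic'
    actions = E.tree_to_actions(sql_to_tree(sql, schema), mq_for(schema))
    assert len(actions) == 6


def test_value_missing_from_question_raises(schema):
    sql = ('select demographic."age" from demographic '
           'where demographic."name" = "not in question"')
    with pytest.raises(ValueNotFoundError):
        E.tree_to_actions(sql_to_tree(sql, schema), mq_for(schema))


def test_malformed_sequences(schema):
    with pytest.raises(MalformedSequenceError) as exc:
        E.actions_to_tree([E.SelectColumn(0)])
    assert exc.value.position == 0
    good = E.tree_to_actions(
        sql_to_tree('select demographic."age" from demographic', schema),
        mq_for(schema))
    with pytest.raises(MalformedSequenceError):
        E.actions_to_tree(good[:-1])  # truncated prefix
    with pytest.raises(MalformedSequenceError):
        E.actions_to_tree(good + [E.ApplyRule(0)])  # trailing action


def test_valid_actions_masking(schema):
    st = DecodingState(schema, 10)
    assert st.valid_actions() == [E.ApplyRule(0)]  # only Z -> R
    st.apply(E.ApplyRule(0))
    st.apply(E.ApplyRule(1))  # R -> Select
    st.apply(E.ApplyRule(3))  # Select -> A
    assert st.valid_rule_ids() == [p.id for p in E.productions().by_lhs("A")]
    assert len(st.valid_rule_ids()) == 7
    st.apply(E.ApplyRule(6))  # A -> none C T
    insurance = schema.column_index("demographic", "insurance")
    st.apply(E.SelectColumn(insurance))
    # table pruning: only the table containing the chosen column remains
    assert st.valid_table_ids() == [0]
    assert st.memory == [insurance]


def test_filter_a_node_restricted_to_plain_column(schema):
    st = DecodingState(schema, 10)
    for rid in (0, 2, 3, 6):  # Z->R, R->Select Filter, Select->A, A->none C T
        st.apply(E.ApplyRule(rid))
    st.apply(E.SelectColumn(2))
    st.apply(E.SelectTable(0))
    # frontier is now the Filter node
    filter_rules = st.valid_rule_ids()
    assert all(E.productions().by_id(r).lhs == "Filter" for r in filter_rules)
    eq_rule = next(r for r in filter_rules
                   if E.productions().by_id(r).tag == "=")
    st.apply(E.ApplyRule(eq_rule))
    # A under Filter: only the aggregate-free production is admissible
    a_rules = st.valid_rule_ids()
    assert [E.productions().by_id(r).tag for r in a_rules] == ["none"]


def test_tree_action_round_trip_random(schema):
    rng = np.random.default_rng(42)
    mq = mq_for(schema)
    for _ in range(300):
        t = random_tree(schema, rng, list(mq.source_tokens))
        actions = E.tree_to_actions(t, mq)
        assert E.actions_to_tree(actions, question_tokens=mq.source_tokens) == t


def test_tree_sql_round_trip_random(schema):
    rng = np.random.default_rng(7)
    toks = list(QTOKS)
    for _ in range(300):
        t = random_tree(schema, rng, toks)
        rendered = tree_to_sql(t, schema, question_tokens=toks)
        assert sql_to_tree(rendered.text, schema) == t


def test_constrained_prefixes_always_parse(schema):
    # any sequence accepted step-by-step by valid_actions parses afterwards
    rng = np.random.default_rng(3)
    for _ in range(50):
        st = DecodingState(schema, len(QTOKS))
        actions = []
        while not st.finished:
            cands = st.valid_actions()
            a = cands[int(rng.integers(len(cands)))]
            st.apply(a)
            actions.append(a)
        E.actions_to_tree(actions, question_tokens=QTOKS)


def test_join_path_rendering(schema):
    sql = ('select diagnoses."icd9_code" from diagnoses inner join '
           "demographic on diagnoses.hadm_id = demographic.hadm_id "
           'where demographic."name" = "james sloan"')
    tree = sql_to_tree(sql, schema)
    rendered = tree_to_sql(tree, schema).text
    assert ("from diagnoses inner join demographic on "
            "diagnoses.hadm_id = demographic.hadm_id") in rendered
    # single-table tree renders without joins
    one = sql_to_tree('select demographic."age" from demographic', schema)
    assert "join" not in tree_to_sql(one, schema).text


def test_canonicalize_behaviour():
    a = 'select demographic."age"   FROM demographic'
    b = "select demographic.'age' from demographic"
    assert E.canonicalize(a) == E.canonicalize(b)
    # order still distinguishes queries
    g = 'select t."a", t."b" from t'
    p = 'select t."b", t."a" from t'
    assert E.canonicalize(g) != E.canonicalize(p)
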