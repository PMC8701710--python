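"""Evaluation metrics: logic-form accuracy, execution accuracy, components.

Logic-form accuracy (Acc_LF) counts predictions whose canonical token
sequence equals the gold query's exactly — order-sensitive everywhere, so
swapped select columns or swapped join tables break the match. Execution
accuracy (Acc_EX) counts predictions that execute and return the gold
result, with column order respected and rows compared as unordered
multisets; a canonical match implies an execution match, so
Acc_EX >= Acc_LF on every evaluation set.

The component breakdown scores five aspects of each pair independently as
unordered collections: aggregation operations (multiset), aggregation
columns, tables, (condition column, operator) pairs, and case-folded
condition values. An unparseable prediction counts all five as wrong.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import EmrSqlError, ExecutionError, InputError
from .grammar import TreeNode
from .schema import Database, DatabaseSchema, execute_query
from .sqlgen import canonicalize, sql_to_tree

__all__ = ["EvalReport", "acc_lf", "acc_ex", "component_accuracy", "evaluate"]

COMPONENTS = ("agg_op", "agg_col", "table", "con_c_plus_o", "con_val")


@dataclass
class EvalReport:
    n: int
    n_lf: int
    n_ex: int
    components: dict[str, float] = field(default_factory=dict)

    @property
    def acc_lf(self) -> float:
        return self.n_lf / self.n if self.n else 0.0

    @property
    def acc_ex(self) -> float:
        return self.n_ex / self.n if self.n else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "acc_lf": self.acc_lf,
                "acc_ex": self.acc_ex,
                "components": self.components,
            },
            indent=2,
        )


def _check_lengths(pred, gold):
    if len(pred) != len(gold):
        raise InputError(
            f"prediction/gold length mismatch: {len(pred)} vs {len(gold)}"
        )


def acc_lf(pred: list[str], gold: list[str]) -> tuple[float, int]:
    """Exact canonical-token-sequence match rate and count."""
    _check_lengths(pred, gold)
    n_match = sum(
        1 for p, g in zip(pred, gold) if canonicalize(p) == canonicalize(g)
    )
    return (n_match / len(gold) if gold else 0.0), n_match


def acc_ex(pred: list[str], gold: list[str], db: Database) -> tuple[float, int]:
    """Execution-result match rate and count.

    A prediction that fails to execute is a miss; a gold query that fails
    to execute is a dataset error.
    """
    _check_lengths(pred, gold)
    n_match = 0
    for p, g in zip(pred, gold):
        try:
            gold_result = execute_query(db, g)
        except ExecutionError as exc:
            raise InputError(f"gold query failed to execute: {g!r}") from exc
        try:
            pred_result = execute_query(db, p)
        except ExecutionError:
            continue
        if pred_result.same_result(gold_result):
            n_match += 1
    return (n_match / len(gold) if gold else 0.0), n_match


def _components_of(tree: TreeNode, schema: DatabaseSchema):
    agg_ops = []
    agg_cols = set()
    tables = set()
    con_co = set()
    con_val = set()
    r_node = tree.children[0]
    select_node = r_node.children[0]
    for a in select_node.children:
        agg_ops.append(a.production.tag)
        col = schema.columns[a.children[0].column]
        agg_cols.add(col.qualified)
    for t in tree.leaves("T"):
        tables.add(schema.tables[t.table].name)
    if len(r_node.children) > 1:

        def walk(f_node):
            tag = f_node.production.tag
            if tag in ("and", "or"):
                walk(f_node.children[0])
                walk(f_node.children[1])
                return
            a = f_node.children[0]
            col = schema.columns[a.children[0].column]
            con_co.add((col.qualified, tag))
            for v in f_node.children[1:]:
                con_val.add((v.text or "").lower())

        walk(r_node.children[1])
    return {
        "agg_op": tuple(sorted(agg_ops)),  # multiset as sorted tuple
        "agg_col": frozenset(agg_cols),
        "table": frozenset(tables),
        "con_c_plus_o": frozenset(con_co),
        "con_val": frozenset(con_val),
    }


def component_accuracy(
    pred: list[str], gold: list[str], schema: DatabaseSchema
) -> dict[str, float]:
    """Per-component exact-collection match rates over a prediction set."""
    _check_lengths(pred, gold)
    counts = {k: 0 for k in COMPONENTS}
    for p, g in zip(pred, gold):
        gold_comp = _components_of(sql_to_tree(g, schema), schema)
        try:
            pred_comp = _components_of(sql_to_tree(p, schema), schema)
        except EmrSqlError:
            continue  # unparseable prediction: all five wrong
        for k in COMPONENTS:
            if pred_comp[k] == gold_comp[k]:
                counts[k] += 1
    n = len(gold)
    return {k: (v / n if n else 0.0) for k, v in counts.items()}


def evaluate(
    pred: list[str],
    gold: list[str],
    db: Database,
    schema: DatabaseSchema | None = None,
) -> EvalReport:
    """Full report: Acc_LF, Acc_EX and the five-component breakdown."""
    schema = schema or db.schema
    _, n_lf = acc_lf(pred, gold)
    _, n_ex = acc_ex(pred, gold, db)
    comps = component_accuracy(pred, gold, schema)
    return EvalReport(n=len(gold), n_lf=n_lf, n_ex=n_ex, components=comps)


def write_per_pair_tsv(path, pred: list[str], gold: list[str], db: Database):
    """Per-pair match flags (logic form / execution), one row per pair."""
    _check_lengths(pred, gold)
    with open(path, "w") as fh:
        fh.write("index\tlf_match\tex_match\n")
        for i, (p, g) in enumerate(zip(pred, gold)):
            lf = int(canonicalize(p) == canonicalize(g))
            try:
                ex = int(
                    execute_query(db, p).same_result(execute_query(db, g)))
            except ExecutionError:
                ex = 0
            fh.write(f"{i}\t{lf}\t{ex}\n")
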