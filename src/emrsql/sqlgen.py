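"""SQL rendering, parsing and canonicalization for the supported subset.

The subset is exactly what the IR grammar generates: a select clause of up
to three (optionally aggregated) columns, a from clause of inner joins along
the schema's join-key graph, and a where clause of and/or-combined
comparisons. Rendering is deterministic: lower-case keywords, columns as
``table."column"``, condition values double-quoted and lower-cased, the
from clause built from the shortest join paths connecting the referenced
tables. ``sql_to_tree`` inverts ``tree_to_sql`` exactly (tree-level
round trip), and ``canonicalize`` gives the order-sensitive token sequence
used for logic-form accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .errors import SchemaError, UnsupportedSyntaxError
from .grammar import TreeNode, productions
from .schema import DatabaseSchema

__all__ = ["SQLQuery", "tree_to_sql", "sql_to_tree", "canonicalize"]

Condition = Union[tuple, None]  # ("and"|"or", l, r) | ("cmp", col, tab, op, [values])


@dataclass
class SQLQuery:
    """Structured select/join/where form plus its canonical text."""

    select_items: list[tuple[str, str, str]]  # (aggregator, column, table)
    joins: list[tuple[str, str, str]]  # (existing table, new table, key)
    conditions: Optional[tuple] = None
    text: str = ""

    def __post_init__(self):
        if not self.select_items:
            raise UnsupportedSyntaxError("query needs at least one select item")


# ---------------------------------------------------------------------------
# rendering


def _render_col(table: str, column: str) -> str:
    return f'{table}."{column}"'


def _render_item(agg: str, table: str, column: str) -> str:
    col = _render_col(table, column)
    if agg == "none":
        return col
    if agg == "count_distinct":
        return f"count(distinct {col})"
    return f"{agg}({col})"


def _render_value(text: str) -> str:
    return '"' + text.lower().replace('"', "") + '"'


_OP_TEXT = {
    "=": "=", "!=": "!=", ">": ">", ">=": ">=", "<": "<", "<=": "<=",
    "like": "like", "not_like": "not like",
}


def _render_condition(node: tuple) -> str:
    kind = node[0]
    if kind in ("and", "or"):
        _, left, right = node
        lt = _render_condition(left)
        rt = _render_condition(right)
        # parenthesize exactly where a flat reparse would reassociate:
        # any connective left child; a right child connective of other type
        if left[0] in ("and", "or"):
            lt = f"({lt})"
        if right[0] in ("and", "or") and right[0] != kind:
            rt = f"({rt})"
        return f"{lt} {kind} {rt}"
    if kind == "between":
        _, table, column, values = node
        return (
            f"{_render_col(table, column)} between "
            f"{_render_value(values[0])} and {_render_value(values[1])}"
        )
    _, table, column, op, value = node
    return f"{_render_col(table, column)} {_OP_TEXT[op]} {_render_value(value)}"


def _condition_tables(node: Optional[tuple]) -> list[str]:
    if node is None:
        return []
    if node[0] in ("and", "or"):
        return _condition_tables(node[1]) + _condition_tables(node[2])
    return [node[1]]


def tree_to_sql(
    tree: TreeNode,
    schema: DatabaseSchema,
    question_tokens: Optional[Sequence[str]] = None,
) -> SQLQuery:
    """Traverse a complete IR tree and render the SQL query.

    V leaves use their ``text`` when present, otherwise the detokenized
    question span (``question_tokens`` required in that case).
    """

    def a_parts(a_node: TreeNode) -> tuple[str, str, str]:
        agg = a_node.production.tag
        c_node, t_node = a_node.children
        table = schema.tables[t_node.table].name
        column = schema.columns[c_node.column].name
        return agg, column, table

    def v_text(v_node: TreeNode) -> str:
        if v_node.text is not None:
            return v_node.text
        if v_node.span is None or question_tokens is None:
            raise UnsupportedSyntaxError(
                "V leaf has no text and no question tokens were given"
            )
        s, e = v_node.span
        return " ".join(question_tokens[s : e + 1])

    def build_condition(f_node: TreeNode) -> tuple:
        tag = f_node.production.tag
        if tag in ("and", "or"):
            return (tag, build_condition(f_node.children[0]),
                    build_condition(f_node.children[1]))
        a_node = f_node.children[0]
        _, column, table = a_parts(a_node)
        if tag == "between":
            vals = [v_text(v) for v in f_node.children[1:]]
            return ("between", table, column, vals)
        return ("cmp", table, column, tag, v_text(f_node.children[1]))

    r_node = tree.children[0]
    select_node = r_node.children[0]
    select_items = [a_parts(a) for a in select_node.children]
    conditions = None
    if len(r_node.children) > 1:
        conditions = build_condition(r_node.children[1])

    # from clause: origin is the first select-item table; remaining tables
    # in first-appearance order get connected via shortest join paths
    origin = select_items[0][2]
    referenced: list[str] = []
    for _, _, tab in select_items:
        if tab not in referenced:
            referenced.append(tab)
    for tab in _condition_tables(conditions):
        if tab not in referenced:
            referenced.append(tab)
    joined = [origin]
    joins: list[tuple[str, str, str]] = []
    for tab in referenced:
        if tab in joined:
            continue
        best = None
        for anchor in joined:  # shortest path from any already-joined table
            path = schema.join_path(anchor, tab)
            if best is None or len(path) < len(best):
                best = path
        for src, dst, key in best:
            if dst not in joined:
                joins.append((src, dst, key))
                joined.append(dst)

    parts = ["select ", ", ".join(_render_item(a, t, c) for a, c, t in select_items)]
    parts.append(f" from {origin}")
    for src, dst, key in joins:
        parts.append(f" inner join {dst} on {src}.{key} = {dst}.{key}")
    if conditions is not None:
        parts.append(" where " + _render_condition(conditions))
    text = "".join(parts)
    return SQLQuery(
        select_items=select_items, joins=joins, conditions=conditions, text=text
    )


# ---------------------------------------------------------------------------
# parsing

_SQL_TOKEN_RE = re.compile(
    r"\"[^\"]*\"|'[^']*'|>=|<=|!=|<>|[A-Za-z_][A-Za-z_0-9]*"
    r"|\d+(?:\.\d+)?|[(),.*=<>]"
)

_UNSUPPORTED_KEYWORDS = {
    "group": "GROUP BY", "order": "ORDER BY", "limit": "LIMIT",
    "union": "UNION", "intersect": "INTERSECT", "except": "EXCEPT",
    "having": "HAVING", "outer": "OUTER JOIN", "left": "LEFT JOIN",
}


def _sql_tokens(sql: str) -> list[str]:
    return _SQL_TOKEN_RE.findall(sql)


def _unquote(tok: str) -> str:
    if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "\"'":
        return tok[1:-1]
    return tok


class _Parser:
    def __init__(self, tokens: list[str], schema: DatabaseSchema):
        self.toks = tokens
        self.pos = 0
        self.schema = schema

    def peek(self) -> Optional[str]:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise UnsupportedSyntaxError("unexpected end of SQL text")
        self.pos += 1
        return tok

    def expect(self, word: str):
        tok = self.next()
        if tok.lower() != word:
            raise UnsupportedSyntaxError(f"expected {word!r}, found {tok!r}")

    def at_keyword(self, word: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.lower() == word

    def check_supported(self, tok: str):
        kw = _UNSUPPORTED_KEYWORDS.get(tok.lower())
        if kw:
            raise UnsupportedSyntaxError(f"unsupported construct: {kw}")

    def colref(self) -> tuple[str, str]:
        tab = self.next().lower()
        self.check_supported(tab)
        if self.peek() != ".":
            raise UnsupportedSyntaxError(
                f"columns must be table-qualified, found {tab!r}"
            )
        self.next()
        col = _unquote(self.next()).lower()
        self.schema.table(tab)  # SchemaError if unknown
        self.schema.table(tab).column(col)
        return tab, col

    def select_item(self) -> tuple[str, str, str]:
        tok = self.peek()
        self.check_supported(tok)
        if tok.lower() in ("max", "min", "count", "sum", "avg") and (
            self.pos + 1 < len(self.toks) and self.toks[self.pos + 1] == "("
        ):
            agg = self.next().lower()
            self.expect("(")
            if self.at_keyword("distinct"):
                self.next()
                if agg != "count":
                    raise UnsupportedSyntaxError(
                        f"distinct is only supported inside count(), not {agg}()"
                    )
                agg = "count_distinct"
            tab, col = self.colref()
            self.expect(")")
            return agg, col, tab
        tab, col = self.colref()
        return "none", col, tab

    def value(self) -> str:
        tok = self.next()
        return _unquote(tok).lower()

    def comparison(self) -> tuple:
        tab, col = self.colref()
        tok = self.next().lower()
        if tok == "not":
            self.expect("like")
            return ("cmp", tab, col, "not_like", self.value())
        if tok == "like":
            return ("cmp", tab, col, "like", self.value())
        if tok == "between":
            v1 = self.value()
            self.expect("and")
            v2 = self.value()
            return ("between", tab, col, [v1, v2])
        if tok == "<>":
            tok = "!="
        if tok not in ("=", "!=", ">", ">=", "<", "<="):
            raise UnsupportedSyntaxError(f"unsupported operator {tok!r}")
        return ("cmp", tab, col, tok, self.value())

    def term(self) -> tuple:
        if self.peek() == "(":
            self.next()
            node = self.expression()
            self.expect(")")
            return node
        return self.comparison()

    def expression(self) -> tuple:
        # right-recursive: "a and b and c" nests right-leaning
        left = self.term()
        tok = self.peek()
        if tok is not None and tok.lower() in ("and", "or"):
            conn = self.next().lower()
            right = self.expression()
            return (conn, left, right)
        return left


def sql_to_tree(sql: str, schema: DatabaseSchema) -> TreeNode:
    """Parse supported-subset SQL text into its IR tree."""
    grammar = productions()
    rules_by_key = {}
    for p in grammar.productions:
        rules_by_key[(p.lhs, p.tag, len(p.symbols))] = p

    toks = _sql_tokens(sql)
    for t in toks:
        if t.lower() in _UNSUPPORTED_KEYWORDS:
            raise UnsupportedSyntaxError(
                f"unsupported construct: {_UNSUPPORTED_KEYWORDS[t.lower()]}"
            )
        if t == "*":
            raise UnsupportedSyntaxError("unsupported construct: select *")
    parser = _Parser(toks, schema)
    parser.expect("select")
    items = [parser.select_item()]
    while parser.peek() == ",":
        parser.next()
        items.append(parser.select_item())
    if len(items) > 3:
        raise UnsupportedSyntaxError("more than 3 select columns")
    parser.expect("from")
    from_table = parser.next().lower()
    schema.table(from_table)
    while parser.at_keyword("inner"):
        parser.next()
        parser.expect("join")
        tab = parser.next().lower()
        schema.table(tab)
        parser.expect("on")
        parser.colref()
        parser.expect("=")
        parser.colref()
    conditions = None
    if parser.at_keyword("where"):
        parser.next()
        conditions = parser.expression()
    if parser.peek() is not None:
        raise UnsupportedSyntaxError(
            f"unsupported trailing SQL: {parser.peek()!r}"
        )

    def a_node(agg: str, col: str, tab: str) -> TreeNode:
        prod = rules_by_key[("A", agg, 2)]
        return TreeNode(
            "A",
            production=prod,
            children=[
                TreeNode("C", column=schema.column_index(tab, col)),
                TreeNode("T", table=schema.table_index(tab)),
            ],
        )

    def filter_node(cond: tuple) -> TreeNode:
        kind = cond[0]
        if kind in ("and", "or"):
            prod = rules_by_key[("Filter", kind, 2)]
            return TreeNode("Filter", production=prod,
                            children=[filter_node(cond[1]), filter_node(cond[2])])
        if kind == "between":
            _, tab, col, values = cond
            prod = rules_by_key[("Filter", "between", 3)]
            return TreeNode("Filter", production=prod, children=[
                a_node("none", col, tab),
                TreeNode("V", text=values[0]),
                TreeNode("V", text=values[1]),
            ])
        _, tab, col, op, value = cond
        prod = rules_by_key[("Filter", op, 2)]
        return TreeNode("Filter", production=prod, children=[
            a_node("none", col, tab),
            TreeNode("V", text=value),
        ])

    sel_prod = rules_by_key[("Select", None, len(items))]
    select = TreeNode("Select", production=sel_prod,
                      children=[a_node(a, c, t) for a, c, t in items])
    if conditions is None:
        r_prod = rules_by_key[("R", None, 1)]
        r = TreeNode("R", production=r_prod, children=[select])
    else:
        r_prod = rules_by_key[("R", None, 2)]
        r = TreeNode("R", production=r_prod,
                     children=[select, filter_node(conditions)])
    z_prod = rules_by_key[("Z", None, 1)]
    return TreeNode("Z", production=z_prod, children=[r])


# ---------------------------------------------------------------------------
# canonical form


def canonicalize(sql: str) -> tuple[str, ...]:
    """Order-preserving canonical token sequence for logic-form matching.

    Lower-cases, normalizes whitespace and quote style, and maps ``<>`` to
    ``!=``; select-column order and join-table order stay significant.
    """
    out = []
    for tok in _sql_tokens(sql):
        if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "\"'":
            out.append('"' + tok[1:-1].lower() + '"')
        elif tok == "<>":
            out.append("!=")
        else:
            out.append(tok.lower())
    return tuple(out)
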