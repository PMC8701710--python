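"""Tree-structured intermediate representation and its action serialization.

The IR is a syntax tree over nonterminals Z, R, Select, A, Filter with
terminal leaves C (a column), T (a table) and V (a condition-value span in
the question). A fixed inventory of 24 productions generates every query in
the supported subset:

    Z -> R
    R -> Select | Select Filter
    Select -> A | A A | A A A
    A -> agg C T            agg in {none, max, min, count, sum, avg,
                                    count_distinct}               (7 rules)
    Filter -> and Filter Filter | or Filter Filter
    Filter -> op A V        op in {=, !=, >, >=, <, <=, like, not_like}
                                                                  (8 rules)
    Filter -> between A V V

A tree serializes to a depth-first, left-to-right action sequence with four
action types: ApplyRule expands a nonterminal; SelectColumn / SelectTable /
SelectValue fill the C / T / V leaves. The two directions (``tree_to_actions``
and ``actions_to_tree``) are exact inverses, and :class:`DecodingState`
exposes, at every prefix, exactly the set of actions that keep the sequence
grammar-consistent — the mask that makes constrained decoding incapable of
emitting an unparseable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

from .errors import DecodingError, MalformedSequenceError, ValueNotFoundError
from .linking import MarkedQuestion, tokenize
from .schema import DatabaseSchema

__all__ = [
    "AGGREGATORS",
    "COMPARISONS",
    "Production",
    "Grammar",
    "productions",
    "ApplyRule",
    "SelectColumn",
    "SelectTable",
    "SelectValue",
    "Action",
    "TreeNode",
    "DecodingState",
    "tree_to_actions",
    "actions_to_tree",
    "random_tree",
    "action_to_json",
    "action_from_json",
]

AGGREGATORS = ("none", "max", "min", "count", "sum", "avg", "count_distinct")
COMPARISONS = ("=", "!=", ">", ">=", "<", "<=", "like", "not_like")

NONTERMINALS = ("Z", "R", "Select", "A", "Filter")
TERMINALS = ("C", "T", "V")


@dataclass(frozen=True)
class Production:
    id: int
    lhs: str
    rhs: tuple[str, ...]  # nonterminals, terminal slots C/T/V, tag constants

    def __post_init__(self):
        if not self.rhs:
            raise ValueError("production rhs must be nonempty")

    @property
    def tag(self) -> Optional[str]:
        """The constant tag (aggregator/operator/connective), if any."""
        for sym in self.rhs:
            if sym.startswith(("agg:", "op:")) or sym in ("and", "or", "between"):
                return sym.split(":", 1)[-1]
        return None

    @property
    def symbols(self) -> tuple[str, ...]:
        """rhs symbols that become child nodes (tags stripped)."""
        return tuple(
            s for s in self.rhs if s in NONTERMINALS or s in TERMINALS
        )


def _build_inventory() -> tuple[Production, ...]:
    rules: list[Production] = []

    def add(lhs, rhs):
        rules.append(Production(id=len(rules), lhs=lhs, rhs=tuple(rhs)))

    add("Z", ["R"])
    add("R", ["Select"])
    add("R", ["Select", "Filter"])
    add("Select", ["A"])
    add("Select", ["A", "A"])
    add("Select", ["A", "A", "A"])
    for agg in AGGREGATORS:
        add("A", [f"agg:{agg}", "C", "T"])
    add("Filter", ["and", "Filter", "Filter"])
    add("Filter", ["or", "Filter", "Filter"])
    for op in COMPARISONS:
        add("Filter", [f"op:{op}", "A", "V"])
    add("Filter", ["between", "A", "V", "V"])
    return tuple(rules)


@dataclass(frozen=True)
class Grammar:
    productions: tuple[Production, ...]

    def __post_init__(self):
        if len({p.id for p in self.productions}) != len(self.productions):
            raise ValueError("duplicate production ids")
        if sum(1 for p in self.productions if p.lhs == "Z") != 1:
            raise ValueError("grammar must have exactly one Z production")

    def __len__(self) -> int:
        return len(self.productions)

    def by_id(self, rule_id: int) -> Production:
        return self.productions[rule_id]

    def by_lhs(self, lhs: str) -> tuple[Production, ...]:
        return tuple(p for p in self.productions if p.lhs == lhs)

    def fingerprint(self) -> str:
        import hashlib

        text = ";".join(f"{p.id}:{p.lhs}->{','.join(p.rhs)}" for p in self.productions)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_GRAMMAR = Grammar(productions=_build_inventory())


def productions() -> Grammar:
    """The fixed 24-production inventory."""
    return _GRAMMAR


# ---------------------------------------------------------------------------
# actions


@dataclass(frozen=True)
class ApplyRule:
    rule_id: int


@dataclass(frozen=True)
class SelectColumn:
    column_id: int  # index into schema.columns


@dataclass(frozen=True)
class SelectTable:
    table_id: int  # index into schema.tables


@dataclass(frozen=True)
class SelectValue:
    start: int  # 0-based question-token indices, inclusive
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError("invalid value span")


Action = Union[ApplyRule, SelectColumn, SelectTable, SelectValue]


def action_to_json(a: Action) -> dict:
    if isinstance(a, ApplyRule):
        return {"t": "rule", "id": a.rule_id}
    if isinstance(a, SelectColumn):
        return {"t": "col", "id": a.column_id}
    if isinstance(a, SelectTable):
        return {"t": "tab", "id": a.table_id}
    return {"t": "val", "s": a.start, "e": a.end}


def action_from_json(d: dict) -> Action:
    kind = d["t"]
    if kind == "rule":
        return ApplyRule(d["id"])
    if kind == "col":
        return SelectColumn(d["id"])
    if kind == "tab":
        return SelectTable(d["id"])
    if kind == "val":
        return SelectValue(d["s"], d["e"])
    raise ValueError(f"unknown action kind {kind!r}")


# ---------------------------------------------------------------------------
# tree


@dataclass
class TreeNode:
    """IR tree node. Internal nodes carry their production; leaves carry
    the selected column/table index or value span/text."""

    symbol: str
    production: Optional[Production] = None
    children: list["TreeNode"] = field(default_factory=list)
    column: Optional[int] = None  # C leaves
    table: Optional[int] = None  # T leaves
    span: Optional[tuple[int, int]] = None  # V leaves (token indices)
    text: Optional[str] = None  # V leaves (value text)

    def __eq__(self, other):
        if not isinstance(other, TreeNode):
            return NotImplemented
        if self.symbol != other.symbol:
            return False
        if (self.production is None) != (other.production is None):
            return False
        if self.production is not None and self.production.id != other.production.id:
            return False
        if self.symbol == "C":
            return self.column == other.column
        if self.symbol == "T":
            return self.table == other.table
        if self.symbol == "V":
            if self.text is not None and other.text is not None:
                return self.text == other.text
            return self.span == other.span
        return self.children == other.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self, symbol: str) -> list["TreeNode"]:
        return [n for n in self.walk() if n.symbol == symbol]


# ---------------------------------------------------------------------------
# decoding state / frontier


class _Slot:
    """Shared cell linking an A-node's chosen column to its T frontier."""

    __slots__ = ("column",)

    def __init__(self):
        self.column: Optional[int] = None


@dataclass
class _Frame:
    symbol: str
    context: str  # "select" or "filter" (meaningful for A frontiers)
    slot: Optional[_Slot] = None  # for C and T frames of the same A node


class DecodingState:
    """Frontier of a partial depth-first derivation.

    Tracks the pending-symbol stack, the memory of already-selected columns
    (for the memory-enhanced column pointer) and the column owning the
    current T frontier (for table pruning).
    """

    def __init__(self, schema: DatabaseSchema, n_question_tokens: int,
                 max_actions: int = 128, max_connectives: int = 7):
        self.schema = schema
        self.n_question_tokens = n_question_tokens
        self.max_actions = max_actions
        # bounding and/or applications bounds the condition count, which
        # guarantees greedy decoding terminates under any weights
        self.max_connectives = max_connectives
        self.n_connectives = 0
        self.stack: list[_Frame] = [_Frame("Z", "select")]
        self.memory: list[int] = []  # selected column ids, first-selected first
        self.n_actions = 0

    @property
    def finished(self) -> bool:
        return not self.stack

    def frontier(self) -> Optional[_Frame]:
        return self.stack[-1] if self.stack else None

    def clone(self) -> "DecodingState":
        import copy

        return copy.deepcopy(self)

    # -- admissibility ----------------------------------------------------

    def valid_rule_ids(self) -> list[int]:
        fr = self.frontier()
        if fr is None or fr.symbol not in NONTERMINALS:
            return []
        rules = _GRAMMAR.by_lhs(fr.symbol)
        if fr.symbol == "A" and fr.context == "filter":
            # conditions never aggregate: WHERE cannot hold an aggregate in
            # the engine, so the admissible set keeps only the plain column
            rules = tuple(p for p in rules if p.tag == "none")
        if (fr.symbol == "Filter"
                and self.n_connectives >= self.max_connectives):
            rules = tuple(p for p in rules if p.tag not in ("and", "or"))
        return [p.id for p in rules]

    def valid_column_ids(self) -> list[int]:
        # schema-minus-memory plus the memory entries = the full universe;
        # the split matters to the model's SCH/MEM branches, not to masking
        return list(range(len(self.schema.columns)))

    def schema_branch_column_ids(self) -> list[int]:
        mem = set(self.memory)
        return [i for i in range(len(self.schema.columns)) if i not in mem]

    def valid_table_ids(self) -> list[int]:
        fr = self.frontier()
        if fr is None or fr.symbol != "T":
            return []
        if fr.slot is None or fr.slot.column is None:
            return list(range(len(self.schema.tables)))
        # the column universe is schema-qualified, so the only table
        # containing the chosen column is the one that owns it
        col = self.schema.columns[fr.slot.column]
        return [self.schema.table_index(col.table)]

    def valid_value_spans(self, max_span_len: int = 8) -> list[tuple[int, int]]:
        n = self.n_question_tokens
        return [
            (s, e)
            for s in range(n)
            for e in range(s, min(n, s + max_span_len))
        ]

    def valid_actions(self) -> list[Action]:
        """Every action whose application keeps the sequence consistent."""
        fr = self.frontier()
        if fr is None:
            return []
        if fr.symbol in NONTERMINALS:
            return [ApplyRule(i) for i in self.valid_rule_ids()]
        if fr.symbol == "C":
            return [SelectColumn(i) for i in self.valid_column_ids()]
        if fr.symbol == "T":
            return [SelectTable(i) for i in self.valid_table_ids()]
        if fr.symbol == "V":
            return [SelectValue(s, e) for s, e in self.valid_value_spans()]
        raise DecodingError(f"unknown frontier symbol {fr.symbol!r}")

    # -- transition --------------------------------------------------------

    def apply(self, action: Action) -> None:
        fr = self.frontier()
        pos = self.n_actions
        if fr is None:
            raise MalformedSequenceError("action after completed tree", pos)
        if self.n_actions >= self.max_actions:
            raise MalformedSequenceError("action-length cap exceeded", pos)
        if isinstance(action, ApplyRule):
            if action.rule_id not in self.valid_rule_ids():
                raise MalformedSequenceError(
                    f"rule {action.rule_id} inadmissible at frontier "
                    f"{fr.symbol}", pos)
            prod = _GRAMMAR.by_id(action.rule_id)
            if prod.tag in ("and", "or"):
                self.n_connectives += 1
            self.stack.pop()
            frames = []
            slot = None
            child_ctx = fr.context
            if prod.lhs == "Filter":
                child_ctx = "filter"
            for sym in prod.symbols:
                if sym == "A" and prod.lhs == "Select":
                    frames.append(_Frame("A", "select"))
                elif sym in ("C", "T"):
                    if slot is None:
                        slot = _Slot()
                    frames.append(_Frame(sym, child_ctx, slot))
                else:
                    frames.append(_Frame(sym, child_ctx))
            for f in reversed(frames):
                self.stack.append(f)
        elif isinstance(action, SelectColumn):
            if fr.symbol != "C":
                raise MalformedSequenceError(
                    f"SelectColumn at frontier {fr.symbol}", pos)
            if not 0 <= action.column_id < len(self.schema.columns):
                raise MalformedSequenceError("column id out of range", pos)
            self.stack.pop()
            if fr.slot is not None:
                fr.slot.column = action.column_id
            if action.column_id not in self.memory:
                self.memory.append(action.column_id)
        elif isinstance(action, SelectTable):
            if fr.symbol != "T":
                raise MalformedSequenceError(
                    f"SelectTable at frontier {fr.symbol}", pos)
            if action.table_id not in self.valid_table_ids():
                raise MalformedSequenceError("table id inadmissible", pos)
            self.stack.pop()
        elif isinstance(action, SelectValue):
            if fr.symbol != "V":
                raise MalformedSequenceError(
                    f"SelectValue at frontier {fr.symbol}", pos)
            if action.end >= self.n_question_tokens:
                raise MalformedSequenceError("value span out of range", pos)
            self.stack.pop()
        else:
            raise MalformedSequenceError(f"unknown action {action!r}", pos)
        self.n_actions += 1


# ---------------------------------------------------------------------------
# tree <-> actions


def tree_to_actions(
    tree: TreeNode, marked_question: MarkedQuestion
) -> list[Action]:
    """Depth-first, left-to-right serialization of a complete tree.

    V leaves must carry value text occurring as a contiguous token span in
    the question (or an explicit span); the emitted SelectValue points at
    the first occurrence.
    """
    tokens = list(marked_question.source_tokens)
    actions: list[Action] = []

    def locate(text: str) -> tuple[int, int]:
        vtoks = tokenize(text)
        if not vtoks:
            raise ValueNotFoundError(f"empty condition value {text!r}")
        n = len(vtoks)
        for s in range(0, len(tokens) - n + 1):
            if tokens[s : s + n] == vtoks:
                return (s, s + n - 1)
        raise ValueNotFoundError(
            f"value {text!r} does not occur in the question"
        )

    def emit(node: TreeNode):
        if node.symbol == "C":
            actions.append(SelectColumn(node.column))
        elif node.symbol == "T":
            actions.append(SelectTable(node.table))
        elif node.symbol == "V":
            if node.text is not None:
                s, e = locate(node.text)
            elif node.span is not None:
                s, e = node.span
            else:
                raise ValueNotFoundError("V leaf carries neither text nor span")
            actions.append(SelectValue(s, e))
        else:
            actions.append(ApplyRule(node.production.id))
            for child in node.children:
                emit(child)

    emit(tree)
    return actions


def actions_to_tree(
    actions: Sequence[Action],
    question_tokens: Optional[Sequence[str]] = None,
    schema: Optional[DatabaseSchema] = None,
) -> TreeNode:
    """Reconstruct the unique tree a grammar-consistent sequence encodes.

    ``question_tokens`` (when given) fills V-leaf text from the spans, which
    makes the function the exact inverse of :func:`tree_to_actions`.
    """

    idx = 0
    n = len(actions)

    def need(symbol: str) -> Action:
        nonlocal idx
        if idx >= n:
            raise MalformedSequenceError(
                f"sequence ended while expecting {symbol}", n)
        a = actions[idx]
        idx += 1
        return a

    def build(symbol: str) -> TreeNode:
        if symbol == "C":
            a = need("C")
            if not isinstance(a, SelectColumn):
                raise MalformedSequenceError("expected SelectColumn", idx - 1)
            return TreeNode("C", column=a.column_id)
        if symbol == "T":
            a = need("T")
            if not isinstance(a, SelectTable):
                raise MalformedSequenceError("expected SelectTable", idx - 1)
            return TreeNode("T", table=a.table_id)
        if symbol == "V":
            a = need("V")
            if not isinstance(a, SelectValue):
                raise MalformedSequenceError("expected SelectValue", idx - 1)
            text = None
            if question_tokens is not None:
                text = " ".join(question_tokens[a.start : a.end + 1])
            return TreeNode("V", span=(a.start, a.end), text=text)
        a = need(symbol)
        if not isinstance(a, ApplyRule):
            raise MalformedSequenceError(
                f"expected ApplyRule for {symbol}", idx - 1)
        prod = _GRAMMAR.by_id(a.rule_id)
        if prod.lhs != symbol:
            raise MalformedSequenceError(
                f"rule {a.rule_id} has lhs {prod.lhs}, frontier {symbol}",
                idx - 1)
        node = TreeNode(symbol, production=prod)
        for child_sym in prod.symbols:
            node.children.append(build(child_sym))
        return node

    tree = build("Z")
    if idx != n:
        raise MalformedSequenceError("trailing actions after complete tree", idx)
    return tree


# ---------------------------------------------------------------------------
# random trees (property tests, fuzzing, corpus checks)


def random_tree(
    schema: DatabaseSchema,
    rng,
    question_tokens: Sequence[str],
    max_filters: int = 3,
) -> TreeNode:
    """Sample a grammar-valid tree by walking the admissible action sets.

    ``rng`` is a ``numpy.random.Generator``. Connective nesting is capped so
    trees stay small; every production remains reachable.
    """
    state = DecodingState(schema, len(question_tokens))
    actions: list[Action] = []
    n_connectives = 0
    while not state.finished:
        fr = state.frontier()
        if fr.symbol in NONTERMINALS:
            ids = state.valid_rule_ids()
            if fr.symbol == "Filter" and n_connectives >= max_filters:
                ids = [i for i in ids
                       if _GRAMMAR.by_id(i).tag not in ("and", "or")]
            rid = int(rng.choice(ids))
            if _GRAMMAR.by_id(rid).tag in ("and", "or"):
                n_connectives += 1
            a: Action = ApplyRule(rid)
        elif fr.symbol == "C":
            a = SelectColumn(int(rng.choice(state.valid_column_ids())))
        elif fr.symbol == "T":
            a = SelectTable(int(rng.choice(state.valid_table_ids())))
        else:
            spans = state.valid_value_spans(max_span_len=3)
            s, e = spans[int(rng.integers(len(spans)))]
            a = SelectValue(s, e)
        state.apply(a)
        actions.append(a)
    return actions_to_tree(actions, question_tokens=question_tokens)
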