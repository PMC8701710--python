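"""Schema linking: mark column/table mentions in a question.

All n-grams (n from 5 down to 1) of the tokenized question are scanned in
descending length order, left to right within a length. An n-gram that
exactly matches a column name or whose word set is contained in a column
name's word set (names are normalised by lower-casing and splitting
underscores) is marked COLUMN; likewise TABLE for table names. When an
n-gram matches both, the column mark wins. Once a span is fixed, any
overlapping candidate is discarded. Remaining tokens become single-token
NONE spans, so the spans always partition the question exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional

from .schema import DatabaseSchema

__all__ = ["MarkedSpan", "MarkedQuestion", "tokenize", "tokenize_with_offsets", "link"]

COLUMN, TABLE, NONE = "COLUMN", "TABLE", "NONE"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(question: str) -> list[str]:
    """Lower-cased word tokens with punctuation split off."""
    return _TOKEN_RE.findall(question.lower())


def tokenize_with_offsets(question: str) -> tuple[list[str], list[tuple[int, int]]]:
    """Tokens plus their (start, end) character offsets in the source text."""
    tokens, offsets = [], []
    for m in _TOKEN_RE.finditer(question.lower()):
        tokens.append(m.group(0))
        offsets.append((m.start(), m.end()))
    return tokens, offsets


@dataclass(frozen=True)
class MarkedSpan:
    tokens: tuple[str, ...]
    mark: str = NONE
    entity: Optional[str] = None  # "table.column", table name, or None

    def __post_init__(self):
        if (self.mark != NONE) != (self.entity is not None):
            raise ValueError("mark != NONE iff entity present")


@dataclass(frozen=True)
class MarkedQuestion:
    spans: tuple[MarkedSpan, ...]
    source_tokens: tuple[str, ...]

    def __post_init__(self):
        flat = tuple(tok for s in self.spans for tok in s.tokens)
        if flat != tuple(self.source_tokens):
            raise ValueError("spans do not partition the source tokens")

    @property
    def span_token_ranges(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) token indices covered by each span."""
        out, pos = [], 0
        for s in self.spans:
            out.append((pos, pos + len(s.tokens) - 1))
            pos += len(s.tokens)
        return out

    def token_to_span(self) -> list[int]:
        """Span index owning each source token."""
        owner = []
        for i, s in enumerate(self.spans):
            owner.extend([i] * len(s.tokens))
        return owner

    def to_json(self) -> str:
        return json.dumps(
            [
                {"tokens": list(s.tokens), "mark": s.mark, "entity": s.entity}
                for s in self.spans
            ]
        )


def _is_wordish(tok: str) -> bool:
    return bool(re.fullmatch(r"\w+", tok))


def _match_entities(ngram: tuple[str, ...], names: list[tuple[str, tuple[str, ...]]]):
    """Return (is_exact, identifier) for the best-matching name, if any.

    Exact full-name matches beat word-subset matches; ties break by
    declaration order (the order of ``names``).
    """
    if not all(_is_wordish(t) for t in ngram):
        return None
    gram_words = set(ngram)
    subset_hit = None
    for ident, words in names:
        if ngram == words or " ".join(ngram) == "_".join(words):
            return (True, ident)
        if subset_hit is None and gram_words <= set(words):
            subset_hit = (False, ident)
    return subset_hit


def link(tokens: list[str], schema: DatabaseSchema) -> MarkedQuestion:
    """Attach COLUMN/TABLE linking marks to a tokenized question."""
    col_names = [(c.qualified, c.name_words) for c in schema.columns]
    tab_names = [(t.name, t.name_words) for t in schema.tables]

    n_tok = len(tokens)
    fixed: list[tuple[int, int, str, str]] = []  # (start, end incl, mark, entity)
    taken = [False] * n_tok
    for n in range(5, 0, -1):
        for start in range(0, n_tok - n + 1):
            end = start + n - 1
            if any(taken[start : end + 1]):
                continue
            ngram = tuple(tokens[start : end + 1])
            col_hit = _match_entities(ngram, col_names)
            tab_hit = _match_entities(ngram, tab_names)
            if col_hit is not None and tab_hit is not None:
                hit, mark = col_hit, COLUMN  # column beats table
            elif col_hit is not None:
                hit, mark = col_hit, COLUMN
            elif tab_hit is not None:
                hit, mark = tab_hit, TABLE
            else:
                continue
            fixed.append((start, end, mark, hit[1]))
            for i in range(start, end + 1):
                taken[i] = True

    fixed.sort()
    spans: list[MarkedSpan] = []
    pos = 0
    for start, end, mark, entity in fixed:
        while pos < start:
            spans.append(MarkedSpan(tokens=(tokens[pos],)))
            pos += 1
        spans.append(
            MarkedSpan(tokens=tuple(tokens[start : end + 1]), mark=mark, entity=entity)
        )
        pos = end + 1
    while pos < n_tok:
        spans.append(MarkedSpan(tokens=(tokens[pos],)))
        pos += 1
    return MarkedQuestion(spans=tuple(spans), source_tokens=tuple(tokens))
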