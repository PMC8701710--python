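"""Condition-value recovery: snap an extracted value to stored content.

The decoder copies condition values out of the question, but the copied
phrase need not equal the string stored in the database (tokenization
artifacts, partial copies, rephrased questions). Recovery looks up the
distinct stored values of the condition column and returns the one most
similar to the extraction under ROUGE-L (the LCS-based F-measure), so the
rendered query always filters on a value that can actually match.

Recovery only applies to text columns; numeric extractions pass through
verbatim so "2123" is never snapped to an unrelated stored number.
"""

from __future__ import annotations

import warnings

from .linking import tokenize
from .schema import ColumnDef, Database, lookup_values

__all__ = ["rouge_l", "recover"]


def _lcs_len(a: list[str], b: list[str]) -> int:
    # O(len(a)*len(b)) dynamic program; value phrases are short
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            if x == y:
                cur.append(prev[j - 1] + 1)
            else:
                cur.append(max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(a: list[str], b: list[str]) -> float:
    """ROUGE-L F-measure between two token lists (equal P/R weighting).

    1.0 for identical nonempty lists, 0.0 when the LCS is empty (including
    the both-empty case).
    """
    lcs = _lcs_len(list(a), list(b))
    if lcs == 0:
        return 0.0
    precision = lcs / len(a)
    recall = lcs / len(b)
    return 2 * precision * recall / (precision + recall)


def recover(extracted: str, column: ColumnDef, db: Database) -> str:
    """Most similar stored value of ``column`` to the extracted string.

    Returns a stored value or the unmodified input, never a fabricated
    string. Exact case-insensitive matches are returned as stored; ties
    break toward the first candidate in stable lookup order.
    """
    if column.value_kind == "numeric":
        return extracted
    candidates = lookup_values(db, column)
    candidates = [c for c in candidates if isinstance(c, str)]
    if not candidates:
        warnings.warn(
            f"no stored values for {column.qualified}; "
            f"returning extraction unchanged",
            stacklevel=2,
        )
        return extracted
    low = extracted.lower()
    for cand in candidates:
        if cand.lower() == low:
            return cand
    ext_toks = tokenize(extracted)
    best, best_score = extracted, -1.0
    for cand in candidates:
        score = rouge_l(ext_toks, tokenize(cand))
        if score > best_score:
            best, best_score = cand, score
    return best
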