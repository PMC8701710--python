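"""Contextual encoder over question+schema and the grammar-constrained decoder.

The encoder serializes the marked question and the schema into one token
stream ([CLS] question-with-marks [SEP] column names [SEP]-separated, table
names [SEP]-separated), contextualizes it with a small multihead-attention
transformer trained from scratch, and pools per-span / per-column /
per-table representations (the average of a span's word and mark positions,
through a fully connected pooling layer). The [CLS] vector initializes the
LSTM decoder through tanh(W·h_cls + b).

At each step the decoder embeds the previous action, updates the LSTM,
attends over the question spans (context v) and over the concatenated
column+table encodings (context u), and scores the actions admissible at
the grammar frontier:

* ApplyRule — softmax of e(r)·W_r[h; v; u] over the rules sharing the
  frontier nonterminal;
* SelectColumn — a memory-enhanced pointer mixing a select-from-schema
  branch (already-selected columns removed) and a select-from-memory
  branch, gated by a sigmoid of [h; v];
* SelectTable — a pointer over the tables compatible with the current
  column;
* SelectValue — independent start and end pointers over question spans,
  the end pointer conditioned on the chosen start (end >= start enforced
  by masking).

The grammar masks make every emitted sequence parseable by construction,
for any parameter setting. The encoder backend is pluggable: anything that
maps the token stream to per-position hidden vectors satisfies the
contract; the bundled backend is the small jointly-trained transformer
(a full-scale pretrained bidirectional transformer at width 768 would slot
in the same way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DecodingError, EmrSqlError, IncompleteOutputError
from .grammar import (
    Action,
    ApplyRule,
    DecodingState,
    SelectColumn,
    SelectTable,
    SelectValue,
    actions_to_tree,
    productions,
)
from .linking import MarkedQuestion, link, tokenize
from .recovery import recover
from .schema import Database, DatabaseSchema
from .sqlgen import tree_to_sql

__all__ = [
    "ModelConfig",
    "Vocab",
    "TokenStream",
    "Encodings",
    "DecoderState",
    "ActionDistribution",
    "ModelParams",
    "serialize_input",
    "encode",
    "init_decoder",
    "decode_step",
    "infer",
    "init_params",
    "preprocess_example",
    "collate",
    "teacher_forced_loss",
]

PAD, CLS, SEP, UNK = "[PAD]", "[CLS]", "[SEP]", "[UNK]"
MARK_TOKENS = {"COLUMN": "[MCOL]", "TABLE": "[MTAB]", "NONE": "[MNONE]"}
SPECIALS = [PAD, CLS, SEP, UNK, "[MCOL]", "[MTAB]", "[MNONE]"]

ROLE_SPECIAL, ROLE_QWORD, ROLE_MARK, ROLE_COLWORD, ROLE_TABWORD = range(5)
N_ROLES = 5

# previous-action kinds fed to the decoder input embedding
PREV_BOS, PREV_RULE, PREV_COL, PREV_TAB, PREV_VAL = range(5)


@dataclass(frozen=True)
class ModelConfig:
    """Desk-scale defaults; a pretrained-encoder deployment would use
    encoder width 768 with decoder/attention width 300."""

    enc_width: int = 64
    enc_layers: int = 2
    enc_heads: int = 2
    enc_ffn: int = 128
    dec_width: int = 128
    act_width: int = 64
    rule_score_width: int = 64
    max_actions: int = 128
    max_positions: int = 320
    max_value_span: int = 8

    def __post_init__(self):
        if self.enc_width % self.enc_heads:
            raise EmrSqlError("enc_width must be divisible by enc_heads")


class Vocab:
    """Token vocabulary with reserved special tokens; unseen words map to UNK."""

    def __init__(self, tokens: Sequence[str] = ()):
        self._id = {}
        for t in SPECIALS:
            self._id[t] = len(self._id)
        for t in tokens:
            if t not in self._id:
                self._id[t] = len(self._id)

    def __len__(self):
        return len(self._id)

    def id(self, token: str) -> int:
        return self._id.get(token, self._id[UNK])

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.id(t) for t in tokens], dtype=np.int64)

    def to_json(self) -> str:
        items = sorted(self._id.items(), key=lambda kv: kv[1])
        return json.dumps([k for k, _ in items])

    @classmethod
    def from_json(cls, text: str) -> "Vocab":
        toks = json.loads(text)
        v = cls()
        for t in toks:
            if t not in v._id:
                v._id[t] = len(v._id)
        return v

    @classmethod
    def build(cls, questions: Sequence[Sequence[str]], schema: DatabaseSchema):
        words: list[str] = []
        for t in schema.tables:
            words.extend(t.name_words)
            for c in t.columns:
                words.extend(c.name_words)
        for q in questions:
            words.extend(q)
        return cls(words)


# ---------------------------------------------------------------------------
# input serialization


@dataclass
class TokenStream:
    """Serialized encoder input with role tags and pooling position lists."""

    tokens: list[str]
    roles: list[int]
    span_positions: list[list[int]]  # per question span: word + mark positions
    col_positions: list[list[int]]  # per schema column: its word positions
    tab_positions: list[list[int]]
    marked_question: MarkedQuestion

    @property
    def n_question_tokens(self) -> int:
        return len(self.marked_question.source_tokens)


def serialize_input(mq: MarkedQuestion, schema: DatabaseSchema) -> TokenStream:
    """[CLS] + spans (linked spans followed by their mark token) + [SEP] +
    column-name words + [SEP] + table-name words + [SEP].

    Unlinked spans carry no mark position (their mark is None); linked
    spans pool the average of their word and mark positions. Column/table
    boundaries are tracked by position lists rather than separator tokens,
    which keeps the sequence short.
    """
    tokens = [CLS]
    roles = [ROLE_SPECIAL]
    span_positions = []
    for span in mq.spans:
        positions = []
        for w in span.tokens:
            positions.append(len(tokens))
            tokens.append(w)
            roles.append(ROLE_QWORD)
        if span.mark != "NONE":
            positions.append(len(tokens))
            tokens.append(MARK_TOKENS[span.mark])
            roles.append(ROLE_MARK)
        span_positions.append(positions)
    tokens.append(SEP)
    roles.append(ROLE_SPECIAL)
    col_positions = []
    for c in schema.columns:
        positions = []
        for w in c.name_words:
            positions.append(len(tokens))
            tokens.append(w)
            roles.append(ROLE_COLWORD)
        col_positions.append(positions)
    tokens.append(SEP)
    roles.append(ROLE_SPECIAL)
    tab_positions = []
    for t in schema.tables:
        positions = []
        for w in t.name_words:
            positions.append(len(tokens))
            tokens.append(w)
            roles.append(ROLE_TABWORD)
        tab_positions.append(positions)
    tokens.append(SEP)
    roles.append(ROLE_SPECIAL)
    return TokenStream(
        tokens=tokens,
        roles=roles,
        span_positions=span_positions,
        col_positions=col_positions,
        tab_positions=tab_positions,
        marked_question=mq,
    )


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(np.float32)


def init_params(
    cfg: ModelConfig, vocab: Vocab, schema: DatabaseSchema, rng
) -> dict[str, Tensor]:
    d, h = cfg.enc_width, cfg.dec_width
    da, dr = cfg.act_width, cfg.rule_score_width
    n_rules = len(productions())
    n_cols = len(schema.columns)
    n_tabs = len(schema.tables)

    p: dict[str, np.ndarray] = {}
    p["emb_tok"] = rng.normal(0, 0.02, (len(vocab), d)).astype(np.float32)
    p["emb_pos"] = rng.normal(0, 0.02, (cfg.max_positions, d)).astype(np.float32)
    p["emb_role"] = rng.normal(0, 0.02, (N_ROLES, d)).astype(np.float32)
    for l in range(cfg.enc_layers):
        for w in ("wq", "wk", "wv", "wo"):
            p[f"l{l}.{w}"] = _glorot(rng, d, d)
        p[f"l{l}.ln1_g"] = np.ones(d, np.float32)
        p[f"l{l}.ln1_b"] = np.zeros(d, np.float32)
        p[f"l{l}.w1"] = _glorot(rng, d, cfg.enc_ffn)
        p[f"l{l}.b1"] = np.zeros(cfg.enc_ffn, np.float32)
        p[f"l{l}.w2"] = _glorot(rng, cfg.enc_ffn, d)
        p[f"l{l}.b2"] = np.zeros(d, np.float32)
        p[f"l{l}.ln2_g"] = np.ones(d, np.float32)
        p[f"l{l}.ln2_b"] = np.zeros(d, np.float32)
    for name in ("pool_x", "pool_c", "pool_t"):
        p[f"{name}_w"] = _glorot(rng, d, d)
        p[f"{name}_b"] = np.zeros(d, np.float32)
    p["init_w"] = _glorot(rng, d, h)
    p["init_b"] = np.zeros(h, np.float32)
    # decoder input embeddings for the previous action; unlike the encoder
    # embeddings these feed an LSTM without normalization, so they start at
    # unit-ish scale or the recurrence barely sees its input
    s_in = 1.0 / np.sqrt(da)
    p["e_rule"] = rng.normal(0, s_in, (n_rules, da)).astype(np.float32)
    p["e_col_in"] = rng.normal(0, s_in, (n_cols, da)).astype(np.float32)
    p["e_tab_in"] = rng.normal(0, s_in, (n_tabs, da)).astype(np.float32)
    p["e_val_in"] = rng.normal(0, s_in, (1, da)).astype(np.float32)
    p["e_bos"] = rng.normal(0, s_in, (1, da)).astype(np.float32)
    # LSTM
    p["w_ih"] = _glorot(rng, da, 4 * h)
    p["w_hh"] = _glorot(rng, h, 4 * h)
    p["b_lstm"] = np.zeros(4 * h, np.float32)
    # attention query projections (keys are the encodings themselves)
    p["att_x_w"] = _glorot(rng, h, d)
    p["att_s_w"] = _glorot(rng, h, d)
    # action heads
    p["w_rule"] = _glorot(rng, h + 2 * d, dr)
    p["b_rule"] = np.zeros(dr, np.float32)
    p["e_rule_score"] = rng.normal(0, 0.02, (n_rules, dr)).astype(np.float32)
    for name in ("w_sch", "w_mem", "w_tab", "w_start"):
        p[name] = _glorot(rng, h + d, d)
        p[name.replace("w_", "b_")] = np.zeros(d, np.float32)
    p["w_end"] = _glorot(rng, h + 2 * d, d)
    p["b_end"] = np.zeros(d, np.float32)
    p["w_gate"] = _glorot(rng, h + d, 1)
    p["b_gate"] = np.zeros(1, np.float32)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


@dataclass
class ModelParams:
    """Trainable parameters plus everything needed to reuse them."""

    config: ModelConfig
    vocab: Vocab
    schema: DatabaseSchema
    tensors: dict[str, Tensor]
    grammar_fingerprint: str = field(
        default_factory=lambda: productions().fingerprint()
    )

    @classmethod
    def init(cls, cfg: ModelConfig, vocab: Vocab, schema: DatabaseSchema, seed=0):
        rng = np.random.default_rng(seed)
        return cls(
            config=cfg, vocab=vocab, schema=schema,
            tensors=init_params(cfg, vocab, schema, rng),
        )

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def load_weights(self, weights: dict[str, np.ndarray]):
        for k, t in self.tensors.items():
            t.data = weights[k].copy()


# ---------------------------------------------------------------------------
# encoder


def _pool_matrix(position_lists: list[list[int]], length: int) -> np.ndarray:
    m = np.zeros((len(position_lists), length), np.float32)
    for i, positions in enumerate(position_lists):
        if positions:
            m[i, positions] = 1.0 / len(positions)
    return m


def _encoder_forward(tensors, cfg: ModelConfig, ids, roles, key_mask):
    """ids/roles (B, L) int arrays, key_mask (B, 1, L) bool -> H (B, L, d)."""
    B, L = ids.shape
    if L > cfg.max_positions:
        raise EmrSqlError(
            f"input length {L} exceeds max_positions {cfg.max_positions}"
        )
    d, nh = cfg.enc_width, cfg.enc_heads
    dh = d // nh
    x = ad.add(
        ad.add(ad.gather_rows(tensors["emb_tok"], ids),
               ad.gather_rows(tensors["emb_role"], roles)),
        ad.narrow(tensors["emb_pos"], 0, 0, L),
    )
    for l in range(cfg.enc_layers):
        q = ad.matmul(x, tensors[f"l{l}.wq"])
        k = ad.matmul(x, tensors[f"l{l}.wk"])
        v = ad.matmul(x, tensors[f"l{l}.wv"])
        head_outs = []
        for hd in range(nh):
            qh = ad.narrow(q, 2, hd * dh, dh)
            kh = ad.narrow(k, 2, hd * dh, dh)
            vh = ad.narrow(v, 2, hd * dh, dh)
            scores = ad.scale(
                ad.matmul(qh, ad.transpose_last(kh)), 1.0 / np.sqrt(dh)
            )
            att = ad.masked_softmax(scores, key_mask)
            head_outs.append(ad.matmul(att, vh))
        attn_out = ad.matmul(ad.concat(head_outs, axis=-1), tensors[f"l{l}.wo"])
        x = ad.layer_norm(
            ad.add(x, attn_out), tensors[f"l{l}.ln1_g"], tensors[f"l{l}.ln1_b"]
        )
        ffn = ad.matmul(
            ad.relu(ad.add(ad.matmul(x, tensors[f"l{l}.w1"]), tensors[f"l{l}.b1"])),
            tensors[f"l{l}.w2"],
        )
        ffn = ad.add(ffn, tensors[f"l{l}.b2"])
        x = ad.layer_norm(
            ad.add(x, ffn), tensors[f"l{l}.ln2_g"], tensors[f"l{l}.ln2_b"]
        )
    return x


def _pooled(tensors, name: str, pool: np.ndarray, H) -> Tensor:
    raw = ad.matmul(Tensor(pool), H)  # (B, N, L) @ (B, L, d)
    return ad.tanh(ad.add(ad.matmul(raw, tensors[f"{name}_w"]),
                          tensors[f"{name}_b"]))


@dataclass
class Encodings:
    """Per-span, per-column and per-table vectors plus the [CLS] vector.

    Batch dimension is 1 in the single-example API; the arrays are
    Tensors of shape (1, N, enc_width) / (1, enc_width).
    """

    H_X: Tensor
    H_C: Tensor
    H_T: Tensor
    h_cls: Tensor
    stream: TokenStream

    @property
    def n_spans(self) -> int:
        return self.H_X.shape[1]


def encode(stream: TokenStream, params: ModelParams) -> Encodings:
    """Single-example encoder forward pass."""
    cfg, tensors = params.config, params.tensors
    ids = params.vocab.encode(stream.tokens)[None, :]
    roles = np.asarray(stream.roles, np.int64)[None, :]
    L = ids.shape[1]
    key_mask = np.ones((1, 1, L), bool)
    H = _encoder_forward(tensors, cfg, ids, roles, key_mask)
    H_X = _pooled(tensors, "pool_x", _pool_matrix(stream.span_positions, L)[None], H)
    H_C = _pooled(tensors, "pool_c", _pool_matrix(stream.col_positions, L)[None], H)
    H_T = _pooled(tensors, "pool_t", _pool_matrix(stream.tab_positions, L)[None], H)
    h_cls = ad.reshape(ad.narrow(H, 1, 0, 1), (1, cfg.enc_width))
    return Encodings(H_X=H_X, H_C=H_C, H_T=H_T, h_cls=h_cls, stream=stream)


# ---------------------------------------------------------------------------
# decoder


@dataclass
class DecoderState:
    """Recurrent decoder state: LSTM vectors, attention contexts, step."""

    h: Tensor
    c: Tensor
    v: Tensor
    u: Tensor
    step: int = 0
    prev_kind: int = PREV_BOS
    prev_index: int = 0
    prev_span: tuple[int, int] = (0, 0)
    memory: tuple[int, ...] = ()


def init_decoder(h_cls: Tensor, params: ModelParams) -> DecoderState:
    """hidden = tanh(W·h_cls + b); cell zeroed; empty memory; step 0."""
    cfg, tensors = params.config, params.tensors
    h = ad.tanh(ad.add(ad.matmul(h_cls, tensors["init_w"]), tensors["init_b"]))
    zeros_h = Tensor(np.zeros((h.shape[0], cfg.dec_width), np.float32))
    zeros_d = Tensor(np.zeros((h.shape[0], cfg.enc_width), np.float32))
    return DecoderState(h=h, c=zeros_h, v=zeros_d, u=zeros_d)


def _lstm_step(tensors, x, h, c, width):
    gates = ad.add(
        ad.add(ad.matmul(x, tensors["w_ih"]), ad.matmul(h, tensors["w_hh"])),
        tensors["b_lstm"],
    )
    i = ad.sigmoid(ad.narrow(gates, -1, 0, width))
    f = ad.sigmoid(ad.narrow(gates, -1, width, width))
    g = ad.tanh(ad.narrow(gates, -1, 2 * width, width))
    o = ad.sigmoid(ad.narrow(gates, -1, 3 * width, width))
    c2 = ad.add(ad.mul(f, c), ad.mul(i, g))
    h2 = ad.mul(o, ad.tanh(c2))
    return h2, c2


def _attend(tensors, wname, h, keys, mask):
    """Scaled dot-product attention of h over keys -> (B, d) context."""
    d = keys.shape[-1]
    q = ad.matmul(h, tensors[wname])  # (B, d)
    B = q.shape[0]
    scores = ad.scale(
        ad.matmul(ad.reshape(q, (B, 1, d)), ad.transpose_last(keys)),
        1.0 / np.sqrt(d),
    )  # (B, 1, N)
    att = ad.masked_softmax(scores, mask[:, None, :])
    return ad.reshape(ad.matmul(att, keys), (B, d))


def _pointer_logits(tensors, wname, bname, query_parts, keys):
    d = keys.shape[-1]
    q = ad.tanh(ad.add(ad.matmul(ad.concat(query_parts, axis=-1),
                                 tensors[wname]), tensors[bname]))
    B = q.shape[0]
    scores = ad.matmul(ad.reshape(q, (B, 1, d)), ad.transpose_last(keys))
    return ad.reshape(ad.scale(scores, 1.0 / np.sqrt(d)), (B, keys.shape[1]))


def _rule_logits(tensors, h, v, u):
    q = ad.tanh(ad.add(ad.matmul(ad.concat([h, v, u], axis=-1),
                                 tensors["w_rule"]), tensors["b_rule"]))
    return ad.matmul(q, ad.transpose_last(tensors["e_rule_score"]))


def _column_probs(tensors, h, v, H_C, sch_mask, mem_mask, mem_any):
    """Memory-enhanced pointer: (1-g)·p_sch + g·p_mem (gate zeroed while
    the memory is empty). Returns probabilities (B, n_cols)."""
    p_sch = ad.masked_softmax(
        _pointer_logits(tensors, "w_sch", "b_sch", [h, v], H_C), sch_mask
    )
    p_mem = ad.masked_softmax(
        _pointer_logits(tensors, "w_mem", "b_mem", [h, v], H_C), mem_mask
    )
    gate = ad.sigmoid(ad.add(ad.matmul(ad.concat([h, v], axis=-1),
                                       tensors["w_gate"]), tensors["b_gate"]))
    g_eff = ad.mul(gate, Tensor(mem_any))  # (B,1) * (B,1)
    one = Tensor(np.ones_like(g_eff.data))
    return ad.add(ad.mul(ad.sub(one, g_eff), p_sch), ad.mul(g_eff, p_mem))


class ActionDistribution:
    """Probabilities over the admissible actions at one decoding step.

    For rule/column/table frontiers ``probs`` spans the full candidate
    universe with zeros at inadmissible entries. For value frontiers the
    start distribution is stored and the end distribution is produced per
    chosen start (end >= start masking).
    """

    def __init__(self, kind: str, probs=None, actions=None,
                 p_start=None, end_fn=None, span_ranges=None):
        self.kind = kind
        self.probs = probs
        self.actions = actions
        self.p_start = p_start
        self._end_fn = end_fn
        self.span_ranges = span_ranges

    def prob(self, action: Action) -> float:
        if self.kind == "value":
            raise EmrSqlError("use p_start / p_end for value distributions")
        if isinstance(action, ApplyRule):
            idx = action.rule_id
        elif isinstance(action, SelectColumn):
            idx = action.column_id
        elif isinstance(action, SelectTable):
            idx = action.table_id
        else:
            return 0.0
        expected = {"rule": ApplyRule, "column": SelectColumn,
                    "table": SelectTable}[self.kind]
        if not isinstance(action, expected):
            return 0.0
        return float(self.probs[idx])

    def p_end(self, start_span: int) -> np.ndarray:
        return self._end_fn(start_span)

    def best_action(self) -> Action:
        if self.kind == "rule":
            return ApplyRule(int(np.argmax(self.probs)))
        if self.kind == "column":
            return SelectColumn(int(np.argmax(self.probs)))
        if self.kind == "table":
            return SelectTable(int(np.argmax(self.probs)))
        s = int(np.argmax(self.p_start))
        e = int(np.argmax(self.p_end(s)))
        return SelectValue(self.span_ranges[s][0], self.span_ranges[e][1])


def _prev_embedding(tensors, state: DecoderState) -> Tensor:
    if state.prev_kind == PREV_BOS:
        return tensors["e_bos"]
    if state.prev_kind == PREV_RULE:
        return ad.gather_rows(tensors["e_rule"], np.array([state.prev_index]))
    if state.prev_kind == PREV_COL:
        return ad.gather_rows(tensors["e_col_in"], np.array([state.prev_index]))
    if state.prev_kind == PREV_TAB:
        return ad.gather_rows(tensors["e_tab_in"], np.array([state.prev_index]))
    return tensors["e_val_in"]


def decode_step(
    state: DecoderState,
    enc: Encodings,
    gstate: DecodingState,
    params: ModelParams,
) -> tuple[ActionDistribution, DecoderState]:
    """One decoding step: distribution over the frontier's admissible set.

    ``gstate`` supplies the grammar frontier and masks; the caller applies
    the chosen action to it.
    """
    cfg, tensors, schema = params.config, params.tensors, params.schema
    frontier = gstate.frontier()
    if frontier is None:
        raise DecodingError("decode_step called on a finished tree")
    x = _prev_embedding(tensors, state)
    h, c = _lstm_step(tensors, x, state.h, state.c, cfg.dec_width)
    n_spans = enc.n_spans
    span_mask = np.ones((1, n_spans), bool)
    v = _attend(tensors, "att_x_w", h, enc.H_X, span_mask)
    schema_keys = ad.concat([enc.H_C, enc.H_T], axis=1)
    u = _attend(
        tensors, "att_s_w", h, schema_keys,
        np.ones((1, schema_keys.shape[1]), bool),
    )
    new_state = DecoderState(h=h, c=c, v=v, u=u, step=state.step + 1,
                             memory=tuple(gstate.memory))

    if frontier.symbol in ("Z", "R", "Select", "A", "Filter"):
        mask = np.zeros((1, len(productions())), bool)
        mask[0, gstate.valid_rule_ids()] = True
        logp = ad.masked_log_softmax(_rule_logits(tensors, h, v, u), mask)
        dist = ActionDistribution("rule", probs=np.exp(logp.data[0]))
    elif frontier.symbol == "C":
        n_cols = len(schema.columns)
        sch_mask = np.zeros((1, n_cols), bool)
        sch_mask[0, gstate.schema_branch_column_ids()] = True
        mem_mask = np.zeros((1, n_cols), bool)
        mem_mask[0, list(gstate.memory)] = True
        mem_any = np.array([[1.0 if gstate.memory else 0.0]], np.float32)
        p = _column_probs(tensors, h, v, enc.H_C, sch_mask, mem_mask, mem_any)
        dist = ActionDistribution("column", probs=p.data[0])
    elif frontier.symbol == "T":
        mask = np.zeros((1, len(schema.tables)), bool)
        mask[0, gstate.valid_table_ids()] = True
        logits = _pointer_logits(tensors, "w_tab", "b_tab", [h, v], enc.H_T)
        logp = ad.masked_log_softmax(logits, mask)
        dist = ActionDistribution("table", probs=np.exp(logp.data[0]))
    elif frontier.symbol == "V":
        start_logits = _pointer_logits(
            tensors, "w_start", "b_start", [h, v], enc.H_X
        )
        p_start = np.exp(
            ad.masked_log_softmax(start_logits, span_mask).data[0]
        )
        span_ranges = enc.stream.marked_question.span_token_ranges

        def end_fn(start_span: int) -> np.ndarray:
            start_rep = ad.gather_batch(enc.H_X, np.array([start_span]))
            logits = _pointer_logits(
                tensors, "w_end", "b_end", [h, v, start_rep], enc.H_X
            )
            emask = np.zeros((1, n_spans), bool)
            emask[0, start_span:] = True
            return np.exp(ad.masked_log_softmax(logits, emask).data[0])

        dist = ActionDistribution(
            "value", p_start=p_start, end_fn=end_fn, span_ranges=span_ranges
        )
    else:  # pragma: no cover - frontier symbols are exhaustive
        raise DecodingError(f"unknown frontier {frontier.symbol!r}")
    return dist, new_state


def _note_action(state: DecoderState, action: Action, mq: MarkedQuestion):
    """Record the applied action so the next step embeds it."""
    if isinstance(action, ApplyRule):
        state.prev_kind, state.prev_index = PREV_RULE, action.rule_id
    elif isinstance(action, SelectColumn):
        state.prev_kind, state.prev_index = PREV_COL, action.column_id
    elif isinstance(action, SelectTable):
        state.prev_kind, state.prev_index = PREV_TAB, action.table_id
    else:
        state.prev_kind = PREV_VAL
        state.prev_span = (action.start, action.end)


def infer(
    question: str,
    schema: DatabaseSchema,
    db: Optional[Database],
    params: ModelParams,
    max_len: int = 128,
) -> str:
    """Greedy grammar-constrained decoding of a question into SQL text.

    Constrained decoding guarantees the emitted action sequence parses;
    condition values are snapped to stored content through value recovery
    when ``db`` is given.
    """
    tokens = tokenize(question)
    mq = link(tokens, schema)
    stream = serialize_input(mq, schema)
    actions: list[Action] = []
    with ad.no_grad():
        enc = encode(stream, params)
        gstate = DecodingState(schema, len(tokens), max_actions=max_len)
        state = init_decoder(enc.h_cls, params)
        while not gstate.finished:
            if len(actions) >= max_len:
                raise IncompleteOutputError(
                    f"tree incomplete after {max_len} actions"
                )
            dist, state = decode_step(state, enc, gstate, params)
            action = dist.best_action()
            gstate.apply(action)
            _note_action(state, action, mq)
            actions.append(action)
    tree = actions_to_tree(actions, question_tokens=tokens, schema=schema)
    if db is not None:
        _recover_values(tree, schema, db)
    return tree_to_sql(tree, schema, question_tokens=tokens).text


def _recover_values(tree, schema: DatabaseSchema, db: Database):
    """Snap every comparison V leaf to the most similar stored value."""

    def walk(node):
        if node.symbol == "Filter" and node.production.tag not in ("and", "or"):
            a_node = node.children[0]
            col = schema.columns[a_node.children[0].column]
            for v in node.children[1:]:
                if v.text is not None:
                    v.text = recover(v.text, col, db)
        for child in node.children:
            walk(child)

    walk(tree)


# ---------------------------------------------------------------------------
# batched teacher forcing (training path)


def preprocess_example(
    mq: MarkedQuestion,
    actions: Sequence[Action],
    schema: DatabaseSchema,
    vocab: Vocab,
    cfg: ModelConfig,
) -> dict:
    """Convert one training pair into the numpy arrays the batch loss uses.

    Replays the gold actions through the grammar state to record, per step,
    the admissible-rule mask, the schema/memory split of the column
    universe, the table mask and the gold indices.
    """
    stream = serialize_input(mq, schema)
    ids = vocab.encode(stream.tokens)
    roles = np.asarray(stream.roles, np.int64)
    n_spans = len(stream.span_positions)
    span_ranges = mq.span_token_ranges
    start_of = {r[0]: i for i, r in enumerate(span_ranges)}
    end_of = {r[1]: i for i, r in enumerate(span_ranges)}

    n_rules = len(productions())
    n_cols = len(schema.columns)
    n_tabs = len(schema.tables)
    gstate = DecodingState(schema, len(mq.source_tokens),
                           max_actions=cfg.max_actions)
    steps = []
    prev = (PREV_BOS, 0)
    for a in actions:
        fr = gstate.frontier()
        rec = {
            "prev_kind": prev[0], "prev_idx": prev[1],
            "is_rule": 0.0, "is_col": 0.0, "is_tab": 0.0, "is_val": 0.0,
            "gold_rule": 0, "gold_col": 0, "gold_tab": 0,
            "gold_start": 0, "gold_end": 0,
            "rule_mask": np.zeros(n_rules, bool),
            "sch_mask": np.zeros(n_cols, bool),
            "mem_mask": np.zeros(n_cols, bool),
            "mem_any": 0.0,
            "tab_mask": np.zeros(n_tabs, bool),
        }
        if isinstance(a, ApplyRule):
            rec["is_rule"] = 1.0
            rec["gold_rule"] = a.rule_id
            rec["rule_mask"][gstate.valid_rule_ids()] = True
            prev = (PREV_RULE, a.rule_id)
        elif isinstance(a, SelectColumn):
            rec["is_col"] = 1.0
            rec["gold_col"] = a.column_id
            rec["sch_mask"][gstate.schema_branch_column_ids()] = True
            rec["mem_mask"][list(gstate.memory)] = True
            rec["mem_any"] = 1.0 if gstate.memory else 0.0
            prev = (PREV_COL, a.column_id)
        elif isinstance(a, SelectTable):
            rec["is_tab"] = 1.0
            rec["gold_tab"] = a.table_id
            rec["tab_mask"][gstate.valid_table_ids()] = True
            prev = (PREV_TAB, a.table_id)
        else:
            rec["is_val"] = 1.0
            if a.start not in start_of or a.end not in end_of:
                raise EmrSqlError(
                    "gold value span does not align with question spans"
                )
            rec["gold_start"] = start_of[a.start]
            rec["gold_end"] = end_of[a.end]
            prev = (PREV_VAL, 0)
        steps.append(rec)
        gstate.apply(a)
    if not gstate.finished:
        raise EmrSqlError("gold action sequence does not complete a tree")
    L = len(ids)
    return {
        "ids": ids,
        "roles": roles,
        "pool_x": _pool_matrix(stream.span_positions, L),
        "pool_c": _pool_matrix(stream.col_positions, L),
        "pool_t": _pool_matrix(stream.tab_positions, L),
        "n_spans": n_spans,
        "steps": steps,
    }


def collate(examples: list[dict], n_cols: int, n_tabs: int) -> dict:
    """Pad a list of preprocessed examples into one batch of arrays."""
    B = len(examples)
    L = max(len(e["ids"]) for e in examples)
    S = max(e["n_spans"] for e in examples)
    T = max(len(e["steps"]) for e in examples)
    n_rules = len(productions())

    batch = {
        "ids": np.zeros((B, L), np.int64),
        "roles": np.zeros((B, L), np.int64),
        "key_mask": np.zeros((B, 1, L), bool),
        "pool_x": np.zeros((B, S, L), np.float32),
        "pool_c": np.zeros((B, n_cols, L), np.float32),
        "pool_t": np.zeros((B, n_tabs, L), np.float32),
        "span_mask": np.zeros((B, S), bool),
        "step_live": np.zeros((B, T), np.float32),
        "prev_kind": np.full((B, T), PREV_BOS, np.int64),
        "prev_idx": np.zeros((B, T), np.int64),
        "is_rule": np.zeros((B, T), np.float32),
        "is_col": np.zeros((B, T), np.float32),
        "is_tab": np.zeros((B, T), np.float32),
        "is_val": np.zeros((B, T), np.float32),
        "gold_rule": np.zeros((B, T), np.int64),
        "gold_col": np.zeros((B, T), np.int64),
        "gold_tab": np.zeros((B, T), np.int64),
        "gold_start": np.zeros((B, T), np.int64),
        "gold_end": np.zeros((B, T), np.int64),
        "rule_mask": np.zeros((B, T, n_rules), bool),
        "sch_mask": np.zeros((B, T, n_cols), bool),
        "mem_mask": np.zeros((B, T, n_cols), bool),
        "mem_any": np.zeros((B, T), np.float32),
        "tab_mask": np.zeros((B, T, n_tabs), bool),
        "end_mask": np.zeros((B, T, S), bool),
        "n_steps": np.zeros(B, np.int64),
    }
    for b, e in enumerate(examples):
        l = len(e["ids"])
        s = e["n_spans"]
        batch["ids"][b, :l] = e["ids"]
        batch["roles"][b, :l] = e["roles"]
        batch["key_mask"][b, 0, :l] = True
        batch["pool_x"][b, :s, :l] = e["pool_x"]
        batch["pool_c"][b, :, :l] = e["pool_c"]
        batch["pool_t"][b, :, :l] = e["pool_t"]
        batch["span_mask"][b, :s] = True
        batch["n_steps"][b] = len(e["steps"])
        for t, rec in enumerate(e["steps"]):
            batch["step_live"][b, t] = 1.0
            batch["prev_kind"][b, t] = rec["prev_kind"]
            batch["prev_idx"][b, t] = rec["prev_idx"]
            for key in ("is_rule", "is_col", "is_tab", "is_val",
                        "gold_rule", "gold_col", "gold_tab",
                        "gold_start", "gold_end", "mem_any"):
                batch[key][b, t] = rec[key]
            batch["rule_mask"][b, t] = rec["rule_mask"]
            batch["sch_mask"][b, t] = rec["sch_mask"]
            batch["mem_mask"][b, t] = rec["mem_mask"]
            batch["tab_mask"][b, t] = rec["tab_mask"]
            if rec["is_val"]:
                batch["end_mask"][b, t, rec["gold_start"]: s] = True
    return batch


def _batch_prev_embedding(tensors, kinds, idxs):
    """Previous-action input embeddings for all steps: (B, T, act_width).

    Mixes the per-type embedding tables by one-hot action kind.
    """
    parts = []
    for kind, table in ((PREV_RULE, "e_rule"), (PREV_COL, "e_col_in"),
                        (PREV_TAB, "e_tab_in")):
        sel = (kinds == kind)
        emb = ad.gather_rows(tensors[table], np.where(sel, idxs, 0))
        parts.append(ad.mul(emb, Tensor(sel[..., None].astype(np.float32))))
    for kind, table in ((PREV_VAL, "e_val_in"), (PREV_BOS, "e_bos")):
        sel = (kinds == kind)[..., None].astype(np.float32)
        parts.append(ad.mul(tensors[table], Tensor(sel)))
    out = parts[0]
    for p in parts[1:]:
        out = ad.add(out, p)
    return out


def _pointer_logits_seq(tensors, wname, bname, query, keys):
    """query (B, T, q) against keys (B, N, d) -> logits (B, T, N)."""
    d = keys.shape[-1]
    q = ad.tanh(ad.add(ad.matmul(query, tensors[wname]), tensors[bname]))
    return ad.scale(ad.matmul(q, ad.transpose_last(keys)), 1.0 / np.sqrt(d))


def teacher_forced_loss(
    params: ModelParams, batch: dict
) -> tuple[Tensor, np.ndarray]:
    """Mean negative log-likelihood of the gold actions over a batch.

    Only the LSTM recurrence runs step by step; the attention contexts and
    all four action heads are evaluated for every step at once in batched
    matmuls (teacher forcing makes the whole gold prefix available up
    front). Returns the scalar loss tensor and the per-example loss values
    (value steps contribute log p_start + log p_end).
    """
    cfg, tensors = params.config, params.tensors
    H = _encoder_forward(tensors, cfg, batch["ids"], batch["roles"],
                         batch["key_mask"])
    H_X = _pooled(tensors, "pool_x", batch["pool_x"], H)
    H_C = _pooled(tensors, "pool_c", batch["pool_c"], H)
    H_T = _pooled(tensors, "pool_t", batch["pool_t"], H)
    B = batch["ids"].shape[0]
    T = batch["step_live"].shape[1]
    hw = cfg.dec_width
    h_cls = ad.reshape(ad.narrow(H, 1, 0, 1), (B, cfg.enc_width))
    h = ad.tanh(ad.add(ad.matmul(h_cls, tensors["init_w"]), tensors["init_b"]))
    c = Tensor(np.zeros((B, hw), np.float32))

    # LSTM recurrence; input projections for all steps precomputed
    x_all = _batch_prev_embedding(tensors, batch["prev_kind"],
                                  batch["prev_idx"])  # (B, T, da)
    gates_x = ad.add(ad.matmul(x_all, tensors["w_ih"]), tensors["b_lstm"])
    hs = []
    for t in range(T):
        gates = ad.add(ad.reshape(ad.narrow(gates_x, 1, t, 1), (B, 4 * hw)),
                       ad.matmul(h, tensors["w_hh"]))
        i = ad.sigmoid(ad.narrow(gates, -1, 0, hw))
        f = ad.sigmoid(ad.narrow(gates, -1, hw, hw))
        g = ad.tanh(ad.narrow(gates, -1, 2 * hw, hw))
        o = ad.sigmoid(ad.narrow(gates, -1, 3 * hw, hw))
        c = ad.add(ad.mul(f, c), ad.mul(i, g))
        h = ad.mul(o, ad.tanh(c))
        hs.append(ad.reshape(h, (B, 1, hw)))
    H_dec = ad.concat(hs, axis=1)  # (B, T, hw)

    # attention contexts for all steps at once
    schema_keys = ad.concat([H_C, H_T], axis=1)
    d = cfg.enc_width

    def attend_seq(wname, keys, mask):
        q = ad.matmul(H_dec, tensors[wname])  # (B, T, d)
        scores = ad.scale(ad.matmul(q, ad.transpose_last(keys)),
                          1.0 / np.sqrt(d))
        att = ad.masked_softmax(scores, mask)
        return ad.matmul(att, keys)  # (B, T, d)

    V = attend_seq("att_x_w", H_X, batch["span_mask"][:, None, :])
    U = attend_seq("att_s_w", schema_keys, True)
    hv = ad.concat([H_dec, V], axis=-1)
    hvu = ad.concat([H_dec, V, U], axis=-1)

    # ApplyRule head
    q_rule = ad.tanh(ad.add(ad.matmul(hvu, tensors["w_rule"]),
                            tensors["b_rule"]))
    rule_logp = ad.masked_log_softmax(
        ad.matmul(q_rule, ad.transpose_last(tensors["e_rule_score"])),
        batch["rule_mask"],
    )
    nll_rule = ad.scale(ad.take_last(rule_logp, batch["gold_rule"]), -1.0)

    # SelectColumn head (memory-enhanced pointer)
    p_sch = ad.masked_softmax(
        _pointer_logits_seq(tensors, "w_sch", "b_sch", hv, H_C),
        batch["sch_mask"],
    )
    p_mem = ad.masked_softmax(
        _pointer_logits_seq(tensors, "w_mem", "b_mem", hv, H_C),
        batch["mem_mask"],
    )
    gate = ad.sigmoid(ad.add(ad.matmul(hv, tensors["w_gate"]),
                             tensors["b_gate"]))  # (B, T, 1)
    g_eff = ad.mul(gate, Tensor(batch["mem_any"][..., None]))
    one = Tensor(np.ones_like(g_eff.data))
    p_col = ad.add(ad.mul(ad.sub(one, g_eff), p_sch), ad.mul(g_eff, p_mem))
    nll_col = ad.scale(ad.log(ad.take_last(p_col, batch["gold_col"])), -1.0)

    # SelectTable head
    tab_logp = ad.masked_log_softmax(
        _pointer_logits_seq(tensors, "w_tab", "b_tab", hv, H_T),
        batch["tab_mask"],
    )
    nll_tab = ad.scale(ad.take_last(tab_logp, batch["gold_tab"]), -1.0)

    # SelectValue heads (end pointer conditioned on the gold start)
    start_logp = ad.masked_log_softmax(
        _pointer_logits_seq(tensors, "w_start", "b_start", hv, H_X),
        batch["span_mask"][:, None, :],
    )
    start_rep = ad.gather_batch(H_X, batch["gold_start"])  # (B, T, d)
    end_logp = ad.masked_log_softmax(
        _pointer_logits_seq(tensors, "w_end", "b_end",
                            ad.concat([hv, start_rep], axis=-1), H_X),
        batch["end_mask"],
    )
    nll_val = ad.add(
        ad.scale(ad.take_last(start_logp, batch["gold_start"]), -1.0),
        ad.scale(ad.take_last(end_logp, batch["gold_end"]), -1.0),
    )

    step_loss = ad.add(
        ad.add(ad.mul(Tensor(batch["is_rule"]), nll_rule),
               ad.mul(Tensor(batch["is_col"]), nll_col)),
        ad.add(ad.mul(Tensor(batch["is_tab"]), nll_tab),
               ad.mul(Tensor(batch["is_val"]), nll_val)),
    )
    total = ad.sum_(ad.mul(Tensor(batch["step_live"]), step_loss), axis=1)
    loss = ad.mean_(total)
    return loss, total.data.copy()
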