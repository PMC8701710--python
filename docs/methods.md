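# Methods

`emrsql` turns a natural-language question about an EMR-style relational
database into an executable SQL query. The pipeline has four stages —
schema linking, joint question+schema encoding, grammar-constrained action
decoding over a tree intermediate representation (IR), and deterministic
SQL rendering with value recovery — plus evaluation metrics and a synthetic
corpus generator that makes the whole system trainable with no external
data. This note records the model, the choices that were genuinely open,
the numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## Schema linking

Questions are lower-cased and tokenized with punctuation split off. All
n-grams for n = 5..1, scanned longest first and left to right within a
length, are matched against column and table names; names are normalized by
splitting underscores into words. An n-gram matches a name exactly, or as a
*word subset* (its word set contained in the name's word set) — the weakest
reading that lets "days stay" reach `days_stay` without letting "disease"
link to everything. A match fixes the span, removes overlapping candidates,
and marks it COLUMN or TABLE; on a double match the column mark wins.
Remaining tokens become single-token unmarked spans, so the spans always
partition the question. Ties among entities break exact-before-subset, then
schema declaration order. Cell values are deliberately not matched — value
identification is the decoder's job.

## Encoder

The marked question and the schema are serialized into one stream:
`[CLS]`, the question spans (each linked span followed by its mark token;
unmarked spans contribute only their words), `[SEP]`, the column-name
words, `[SEP]`, the table-name words, `[SEP]`. Span, column and table
boundaries are carried as position lists; no separator tokens are spent
inside the column block, which keeps the sequence short enough for CPU
training (the pooling matrices, not separators, define the units). A
2-layer, 2-head transformer (width 64, FFN 128, learned positional and
role embeddings) trained from scratch contextualizes the stream. Span
representations average the hidden vectors of a span's word and mark
positions; column and table representations average their name-word
positions; each pooled block passes through its own fully connected tanh
layer, giving H_X, H_C, H_T. The decoder's initial hidden state is
tanh(W·h_CLS + b) with zero cell state.

The encoder is a pluggable backend: anything mapping the token stream to
per-position vectors satisfies the contract, so a frozen or fine-tuned
pretrained bidirectional transformer (width 768) can replace the small
backend without touching the decoder. The desk-scale defaults
(encoder 64, decoder LSTM 128, attention = encoder width) were sized for
single-CPU training from scratch; a pretrained deployment would use the
conventional 768/300/300.

## Grammar and IR

The IR grammar has exactly 24 productions: `Z→R`; `R→Select` and
`R→Select Filter`; `Select→A|AA|AAA`; seven `A→agg C T` rules for
aggregators none/max/min/count/sum/avg/count-distinct; `Filter→and|or
Filter Filter`; eight comparison rules `Filter→op A V` for
=, !=, >, >=, <, <=, like, not like; and `Filter→between A V V`.
Count-distinct is its own aggregator because the query family prints
`count(distinct …)` as a unit. The select arity cap of three keeps the
inventory at 24 while covering the observed query shapes (mean ≈ 1.1
select columns).

A complete tree serializes depth-first, left-to-right into four action
types: ApplyRule, SelectColumn, SelectTable, SelectValue(start, end) with
0-based inclusive token coordinates. `DecodingState` exposes the exact
admissible set at every prefix: rules sharing the frontier nonterminal,
all columns (the schema/memory split matters to the model, not to
admissibility), the tables compatible with the pending column, and all
question spans. Two refinements make every decodable sequence render to
engine-accepted SQL:

* the `A` node under a `Filter` admits only the aggregate-free production —
  SQL forbids aggregates in WHERE, and the supported query family never
  uses them there;
* since the column universe is schema-qualified (49 columns, not
  name-deduplicated), the only table "containing" a chosen column is its
  owner, so the table frontier is a singleton. The SelectTable action and
  its pointer head are kept — with a name-level column universe the same
  machinery would face a real choice;
* connective applications (`and`/`or`) are capped at 7 per query (8
  conditions, far beyond the query family's observed maximum). Without a
  bound, a greedy decoder with adversarial weights could expand `Filter →
  and Filter Filter` forever; the cap makes termination a structural
  property rather than a property of trained weights.

Multi-condition WHERE clauses nest right-leaning. Rendering emits flat
chains for same-connective nesting (`a and b and c`) and parenthesizes
exactly the children that a flat reparse would reassociate (any left
connective child; a right child of the other connective type), so
tree → SQL → tree is the identity on every grammar-valid tree. The FROM
clause joins the referenced tables along shortest join-key paths (BFS,
declaration-order tie-break) anchored at the first select item's table.
Rendered text is deterministic: lower-case keywords, `table."column"`
quoting, double-quoted lower-cased condition values.

`canonicalize` lower-cases, normalizes whitespace and quote style and maps
`<>` to `!=`, while preserving token order — so select-column order and
join order still distinguish queries, which is what logic-form accuracy
requires.

## Decoder

A single LSTM (width 128) decodes all four action types in depth-first
order — a coarse-to-fine skeleton-then-leaf ordering realized in one pass
rather than two networks. The input at each step is an embedding of the
previous action (per-type tables; rule, column, table, value, and a
beginning-of-sequence vector). After each recurrence the state attends,
by scaled dot product with learned query projections, over the question
spans (context v) and over the concatenated column+table encodings
(context u). Heads:

* **ApplyRule** — logits e(r)·tanh(W_r [h; v; u]) over the admissible rules;
* **SelectColumn** — a memory-enhanced pointer: a schema branch over
  not-yet-selected columns and a memory branch over already-selected ones,
  both bilinear against H_C, mixed by a sigmoid gate on [h; v]; the gate is
  forced to the schema branch while the memory is empty. Selecting a column
  removes it from the schema branch and records it in the memory;
* **SelectTable** — pointer over H_T masked to the tables compatible with
  the current column;
* **SelectValue** — independent start and end pointers over question spans,
  the end pointer seeing the chosen start's representation and masked to
  end ≥ start.

All distributions are masked log-softmaxes over the admissible set:
probabilities sum to one there and are exactly zero elsewhere, so for any
parameter setting — including untrained weights — greedy or sampled
decoding yields a parseable sequence and executable SQL. Decoding is
greedy by default with a 128-action cap.

Condition values are extracted by pointing, then snapped to stored content:
ROUGE-L (the LCS F-measure with equal precision/recall weighting, on
lower-cased word tokens) selects the most similar distinct stored value of
the condition column. Exact case-insensitive matches short-circuit; ties
break toward first-seen stored order; numeric-column extractions pass
through verbatim so numbers are never snapped to unrelated stored numbers.
The output is always a stored value or the unmodified extraction.

## Training

Teacher-forced maximum likelihood: the loss is the negative sum of gold
action log-probabilities (value steps contribute log p_start + log p_end),
averaged over the batch. Because teacher forcing exposes the whole gold
prefix, only the LSTM recurrence runs sequentially; attention contexts and
all four heads are evaluated for every step at once in batched matrix
products. Adam with global-norm clipping at 5.0 optimizes everything
jointly. Batches are bucketed by action-sequence length to limit padding;
bucket order reshuffles per epoch under the run seed, making runs exactly
reproducible. Model selection keeps the weights with the best validation
logic-form accuracy; an optional early-stop threshold ends the run once
validation accuracy is high enough. Desk defaults: learning rate 3e-3 with
cosine decay to 10%, 18 epochs, batch 32. A deployment fine-tuning a large
pretrained encoder would instead use a rate near 1e-6 for ~100 epochs at
batch 8 — that regime is impractical from scratch, which is why the small
backend uses its own defaults (plain config fields, never hard-coded).

The gradients come from a small in-package reverse-mode autodiff engine
over numpy (`emrsql.autodiff`): a tape of backward closures over exactly
the ops the model needs, each verified against central finite differences
in the test suite; inference paths run under a no-grad mode that skips tape
construction.

One initialization detail matters disproportionately: the decoder's
previous-action embeddings feed the LSTM without any normalization layer,
so they start at scale 1/sqrt(width). Initialized near zero (the usual
transformer-embedding scale), the recurrence barely sees its input, every
step with the same admissible mask collapses to the marginal gold
distribution, and the loss plateaus at the corresponding entropy — the
model cannot even memorize a single pair in hundreds of epochs.

## Evaluation

* **Acc_LF** — exact canonical-token-sequence match, order-sensitive
  everywhere.
* **Acc_EX** — both queries execute and return the same result, with
  column order respected and rows compared as unordered multisets (the
  query family has no ORDER BY, so row order is engine incidental, while
  a swapped select-column order is a different answer). A prediction that
  fails to execute is a miss. Canonical equality implies execution
  equality, so Acc_EX ≥ Acc_LF on every set.
* **Components** — per pair, five collections compared independently of
  order: aggregation-operation multiset, aggregation-column set, table
  set, (condition column, operator) pairs, and case-folded condition
  values. Unordered comparison is forced by the metric's intent: a
  join-order swap should score every component correct. An unparseable
  prediction scores all five wrong.

A bundled five-pair diagnostic suite (`emrsql.casestudy`) pins the metric
semantics: five characteristic gold/prediction disagreements over a
purpose-built fixture population yield Acc_LF 0/5 and Acc_EX 1/5, with the
operator-flip pair scoring condition-column+operator wrong while its
condition value is right.

## Synthetic data

`make_schema` returns the bundled five-table schema (demographic 23
columns; diagnoses, procedures 5 each; prescriptions 7; laboratory 9) star-
joined on the admission key. `sample_records` draws a synthetic population
— names, demographics, diagnosis/procedure codes and titles, prescriptions,
lab rows — with referential integrity and full determinism under the seed.
Stored text is lower-cased at load; numeric columns get NUMERIC affinity so
quoted numeric literals compare numerically (the engine's affinity rules do
the coercion). Content pools avoid schema-name words so linking never
swallows a value span.

`generate_pairs` samples from eight template families (patient-attribute
lookup with 1–3 select columns, satellite-table lookups through joins,
counts under one or two conditions, rare-operator counts exercising
or/between/!=/like/not-like/>=/<=, numeric aggregates, no-WHERE counts, and
satellite-keyed lookups). Family weights target the corpus statistics of a
template-built clinical text-to-SQL benchmark — mean ≈ 1.1 select columns
and ≈ 1.76 conditions — matched approximately (asserted within ±0.3); with
500+ pairs every one of the 24 productions is exercised. Every condition
value appears verbatim in the question (so gold SelectValue spans always
exist), every gold query parses, converts to actions, and executes on the
paired fixture. Paraphrase noise (default rate 0.3) applies seeded synonym
substitution and filler dropout to the template text around the protected
value spans, emulating crowd-sourced rephrasing.

What passing on this corpus shows: the architecture can learn the full
question→SQL mapping end to end, the constrained decoder is safe, and the
metrics behave as specified. What it does not show: performance on real
clinical questions — real rephrasings are far more diverse than the
synonym channel, real values are not guaranteed to appear verbatim
(the hardest documented failure mode), and a from-scratch 64-wide encoder
stands in for a pretrained language model. Numbers obtained here are not
comparable to results on credentialed clinical datasets.

## Reference experiment

The end-to-end check trains the small backend on a 3000-pair corpus
(200 patients, paraphrase rate 0.3, 0.8/0.1/0.1 split) and requires
held-out Acc_LF ≥ 0.90 and Acc_EX ≥ 0.95 on the same-template test split,
passing on at least 2 of 3 seeds. Problem sizes (3000 pairs, width-64
encoder, 18 epochs) were chosen so a run finishes in a few minutes on one
CPU core; accuracy saturates slowly beyond that budget.

## Known limitations

* Single-schema setting; no cross-database generalization.
* No nested queries, GROUP BY/ORDER BY/LIMIT, outer joins, or set
  operations — absent from the target query family by design.
* Greedy decoding; beam search would be a small extension but the
  constrained greedy decoder already emits only valid SQL.
* Double-quoted condition values rely on the engine treating a
  non-identifier double-quoted string as a literal; generated content is
  constructed never to collide with identifier names.
* Condition-value recovery searches only the condition column's own
  stored values.
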