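"""Schema linking: mark column/table mentions in a clinical question.

Loads the bundled five-table EMR schema, tokenizes a question, and shows
which spans link to schema entities. Linked spans become single encoder
units and carry COLUMN/TABLE marks that bias the downstream pointers.
"""

import emrsql as E

schema = E.bundled_schema()
print("tables:", ", ".join(f"{t.name}({len(t.columns)})" for t in schema.tables))

question = "tell me the insurance and days of hospital stay of james sloan"
tokens = E.tokenize(question)
mq = E.link(tokens, schema)

print(f"\nquestion: {question}")
for span in mq.spans:
    tag = f"  -> {span.mark}({span.entity})" if span.mark != "NONE" else ""
    print(f"  {' '.join(span.tokens):30s}{tag}")

# 'insurance' links to demographic.insurance (exact name match) and
# 'days ... stay' words link to demographic.days_stay (word-subset match);
# everything else, including the patient name, stays unmarked.
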