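"""The tree-structured intermediate representation and its action form.

Parses a SQL query into the 24-rule IR grammar, serializes the tree as a
depth-first action sequence, reconstructs it, and renders it back to SQL.
Both round trips are exact, which is what lets the decoder emit actions
instead of raw tokens without ever producing invalid SQL.
"""

import emrsql as E
from emrsql.sqlgen import sql_to_tree, tree_to_sql

schema = E.bundled_schema()
question = "tell me the insurance and primary disease of james sloan"
mq = E.link(E.tokenize(question), schema)

sql = ('select demographic."insurance", demographic."diagnosis" '
       'from demographic where demographic."name" = "james sloan"')
tree = sql_to_tree(sql, schema)
actions = E.tree_to_actions(tree, mq)

print(f"grammar size: {len(E.productions())} productions")
print(f"question: {question}")
print(f"sql:      {sql}\n")
print(f"action sequence ({len(actions)} actions):")
for a in actions:
    if isinstance(a, E.ApplyRule):
        p = E.productions().by_id(a.rule_id)
        print(f"  ApplyRule   {p.lhs} -> {' '.join(p.rhs)}")
    elif isinstance(a, E.SelectColumn):
        print(f"  SelectColumn {schema.columns[a.column_id].qualified}")
    elif isinstance(a, E.SelectTable):
        print(f"  SelectTable  {schema.tables[a.table_id].name}")
    else:
        toks = mq.source_tokens[a.start : a.end + 1]
        print(f"  SelectValue  tokens[{a.start}:{a.end}] = {' '.join(toks)!r}")

rebuilt = E.actions_to_tree(actions, question_tokens=mq.source_tokens)
assert rebuilt == tree
print("\nround trip tree -> actions -> tree: identical")
print("rendered:", tree_to_sql(rebuilt, schema).text)
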