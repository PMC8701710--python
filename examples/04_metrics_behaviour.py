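"""Why two accuracies: logic form vs execution, plus component scores.

Evaluates the bundled five-pair diagnostic suite: each pair fails the exact
logic-form match for a different reason, but only the join-order swap still
returns the right answer, so Acc_LF = 0.0 while Acc_EX = 0.2. The component
breakdown shows which part of each query went wrong.
"""

from emrsql.casestudy import CASE_STUDY_PAIRS, case_study_fixture
from emrsql.evaluation import evaluate

db = case_study_fixture()
gold = [g for _, g, _ in CASE_STUDY_PAIRS]
pred = [p for _, _, p in CASE_STUDY_PAIRS]

for i, (question, g, p) in enumerate(CASE_STUDY_PAIRS, 1):
    print(f"pair {i}: {question}")

report = evaluate(pred, gold, db)
print(f"\nAcc_LF = {report.acc_lf:.1f}   (no prediction matches exactly)")
print(f"Acc_EX = {report.acc_ex:.1f}   (only the join-order swap executes "
      "to the gold answer)")
print("components:", {k: round(v, 2) for k, v in report.components.items()})
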