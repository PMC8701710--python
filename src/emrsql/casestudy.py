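"""A bundled five-pair diagnostic suite illustrating metric behaviour.

Five gold/predicted SQL pairs over the bundled schema, each exercising a
characteristic disagreement mode between logic-form and execution accuracy:

1. swapped join-table order — different logical form, same execution result;
2. swapped select-column order — the result columns come back in a
   different order, so execution accuracy fails too;
3. wrong condition value (a numeric flag);
4. wrong condition column (semantically close year columns) and value;
5. wrong comparison operator (> vs <), returning the opposite cohort.

``case_study_fixture`` builds a small population on which pairs 3-5
provably return different results, so an evaluation over the five pairs
yields Acc_LF = 0/5 and Acc_EX = 1/5, with pair 5 scoring the
condition-column+operator component wrong while its condition value is
right.
"""

from __future__ import annotations

from .schema import Database, DatabaseSchema, build_fixture_db, bundled_schema

__all__ = ["CASE_STUDY_PAIRS", "case_study_fixture"]

# (question, gold SQL, predicted SQL)
CASE_STUDY_PAIRS: list[tuple[str, str, str]] = [
    (
        "let me know the short title and icd9 codes of diagnoses for "
        "patient john gartman",
        'select diagnoses."icd9_code", diagnoses."short_title" '
        "from demographic inner join diagnoses "
        "on demographic.hadm_id = diagnoses.hadm_id "
        'where demographic."name" = "john gartman"',
        'select diagnoses."icd9_code", diagnoses."short_title" '
        "from diagnoses inner join demographic "
        "on diagnoses.hadm_id = demographic.hadm_id "
        'where demographic."name" = "john gartman"',
    ),
    (
        "tell me which primary disease the patient walter locher is "
        "suffering from and whether he is still alive or not",
        'select demographic."expire_flag", demographic."diagnosis" '
        'from demographic where demographic."name" = "walter locher"',
        'select demographic."diagnosis", demographic."expire_flag" '
        'from demographic where demographic."name" = "walter locher"',
    ),
    (
        "calculate the number of dead patients who were admitted to "
        "hospital before 2123",
        'select count(distinct demographic."subject_id") from demographic '
        'where demographic."expire_flag" = "1" and '
        'demographic."admityear" < "2123"',
        'select count(distinct demographic."subject_id") from demographic '
        'where demographic."expire_flag" = "0" and '
        'demographic."admityear" < "2123"',
    ),
    (
        "how many american indian/alaska native ethnic background patients "
        "were born before 2148?",
        'select count(distinct demographic."subject_id") from demographic '
        'where demographic."ethnicity" = "american indian/alaska native" '
        'and demographic."admityear" < "2148"',
        'select count(distinct demographic."subject_id") from demographic '
        'where demographic."ethnicity" = "american indian/alaska native" '
        'and demographic."dob_year" < "2184"',
    ),
    (
        "find the minimum number of days of hospital stay for patients "
        "born before the year 2200",
        'select min(demographic."days_stay") from demographic '
        'where demographic."dob_year" > "2200"',
        'select min(demographic."days_stay") from demographic '
        'where demographic."dob_year" < "2200"',
    ),
]


def _demo_row(subject_id, hadm_id, name, ethnicity, dob_year, admityear,
              days_stay, expire_flag, diagnosis):
    return {
        "subject_id": subject_id, "hadm_id": hadm_id, "name": name,
        "ethnicity": ethnicity, "dob_year": dob_year, "admityear": admityear,
        "days_stay": days_stay, "expire_flag": expire_flag,
        "diagnosis": diagnosis, "age": admityear - dob_year,
        "insurance": "private", "gender": "female", "marital_status": "single",
    }


def case_study_fixture(path: str = ":memory:",
                       schema: DatabaseSchema | None = None) -> Database:
    """Synthetic population separating the five diagnostic pairs."""
    schema = schema or bundled_schema()
    records = {
        "demographic": [
            _demo_row(1, 101, "john gartman", "white", 2100, 2150, 5, 0,
                      "sepsis"),
            _demo_row(2, 102, "walter locher", "white", 2090, 2140, 8, 1,
                      "coronary artery disease"),
            _demo_row(3, 103, "alice novak", "white", 2080, 2100, 4, 1,
                      "pneumonia"),
            _demo_row(4, 104, "robert vance", "white", 2085, 2110, 6, 1,
                      "renal failure"),
            _demo_row(5, 105, "maria duarte", "white", 2095, 2105, 9, 0,
                      "chest pain"),
            _demo_row(6, 106, "henry pruitt", "american indian/alaska native",
                      2190, 2140, 2, 0, "fever"),
            _demo_row(7, 107, "grace mercer", "white", 2210, 2245, 7, 0,
                      "sepsis"),
            _demo_row(8, 108, "peter novak", "white", 2150, 2180, 3, 0,
                      "fever"),
        ],
        "diagnoses": [
            {"subject_id": 1, "hadm_id": 101, "icd9_code": "4019",
             "short_title": "hypertension nos",
             "long_title": "unspecified essential hypertension"},
            {"subject_id": 1, "hadm_id": 101, "icd9_code": "4280",
             "short_title": "chf nos",
             "long_title": "congestive heart failure unspecified"},
        ],
    }
    return build_fixture_db(schema, records, path)
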