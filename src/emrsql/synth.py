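"""Synthetic EMR question-SQL corpus generator.

Emulates how a template-generated clinical text-to-SQL corpus is built:
a five-table schema (demographics plus diagnoses / procedures /
prescriptions / laboratory tests, 23/5/5/7/9 columns, star-joined on the
admission key), synthetic patient records with referential integrity, and
question-SQL pairs instantiated from a suite of natural-language templates
whose slots are filled from the stored content. Every condition value
appears verbatim in the question text (so value extraction by pointing is
always possible), every gold query parses under the IR grammar, converts
to a gold action sequence, and executes on the paired fixture database.

Optional paraphrase noise emulates crowd-sourced rephrasing: seeded
synonym substitution and filler-word dropout applied to the template text
around the value slots, never to the values themselves.

Template sampling weights aim the corpus statistics at roughly 1.1 select
columns and 1.7 where-conditions per query on average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GenerationError
from .grammar import tree_to_actions
from .linking import link, tokenize
from .schema import Database, DatabaseSchema, build_fixture_db, bundled_schema
from .sqlgen import sql_to_tree, tree_to_sql
from .training import TrainExample

__all__ = ["GenConfig", "make_schema", "sample_records", "generate_pairs"]


@dataclass(frozen=True)
class GenConfig:
    n_pairs: int = 1000
    n_patients: int = 100
    seed: int = 0
    paraphrase_rate: float = 0.3
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    db_path: str = ":memory:"

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise GenerationError("split ratios must sum to 1")
        if not 0.0 <= self.paraphrase_rate <= 1.0:
            raise GenerationError("paraphrase rate must lie in [0, 1]")


def make_schema() -> DatabaseSchema:
    """The bundled five-table EMR-style schema."""
    return bundled_schema()


# ---------------------------------------------------------------------------
# content pools (lower-case; chosen to avoid column/table name words so
# schema linking never swallows a value span)

FIRST = ["james", "walter", "grace", "henry", "alice", "robert", "maria",
         "peter", "linda", "frank", "susan", "david", "karen", "thomas",
         "nancy", "george", "hannah", "oliver", "ruth", "samuel", "julia",
         "edward", "clara", "martin", "diana", "victor", "sofia", "albert",
         "irene", "philip"]
LAST = ["sloan", "gartman", "locher", "mercer", "whitfield", "ramos",
        "oduya", "kellerman", "novak", "fontaine", "barrett", "ishikawa",
        "vance", "duarte", "holloway", "pruitt", "ness", "calloway",
        "bergstrom", "okafor", "lindqvist", "marchetti", "beaumont",
        "castellanos", "thorne", "aldridge", "valdez", "mcewen", "soriano",
        "pemberton"]
MARITAL = ["married", "single", "divorced", "widowed", "separated"]
GENDER = ["female", "male"]
LANGUAGE = ["engl", "span", "russ", "port", "cant"]
RELIGION = ["catholic", "protestant quaker", "jewish", "buddhist",
            "not specified"]
ADMISSION_TYPE = ["emergency", "elective", "urgent", "newborn"]
INSURANCE = ["private", "medicare", "medicaid", "government", "self pay"]
ETHNICITY = ["white", "black/african american", "hispanic or latino",
             "asian", "american indian/alaska native",
             "middle eastern", "other"]
ADMIT_LOC = ["emergency room admit", "transfer from hosp/extram",
             "clinic referral/premature", "phys referral/normal deliveri"]
DISCH_LOC = ["home", "home health care", "snf", "dead/expired",
             "rehab/distinct part hosp"]
DIAGNOSIS_TEXT = ["coronary artery disease", "sepsis", "pneumonia",
                  "congestive heart failure", "gastrointestinal bleed",
                  "intracranial hemorrhage", "altered mental status",
                  "chest pain", "renal failure", "fever"]
DIAG_ROWS = [("4019", "hypertension nos", "unspecified essential hypertension"),
             ("4280", "chf nos", "congestive heart failure unspecified"),
             ("5849", "acute kidney failure nos", "acute kidney failure unspecified"),
             ("51881", "acute respiratry failure", "acute respiratory failure"),
             ("2724", "hyperlipidemia nec/nos", "other and unspecified hyperlipidemia"),
             ("41401", "crnry athrscl natve vssl", "coronary atherosclerosis of native coronary artery"),
             ("25000", "dmii wo cmp nt st uncntr", "diabetes mellitus without mention of complication"),
             ("5990", "urin tract infection nos", "urinary tract infection site not specified"),
             ("2859", "anemia nos", "anemia unspecified"),
             ("42731", "atrial fibrillation", "atrial fibrillation")]
PROC_ROWS = [("3893", "venous cath nec", "venous catheterization not elsewhere classified"),
             ("9604", "insert endotracheal tube", "insertion of endotracheal tube"),
             ("9671", "cont inv mec ven <96 hrs", "continuous invasive mechanical ventilation"),
             ("3995", "hemodialysis", "hemodialysis"),
             ("8856", "coronar arteriogr-2 cath", "coronary arteriography using two catheters"),
             ("9904", "packed cell transfusion", "transfusion of packed cells"),
             ("3615", "1 int mam-cor art bypass", "single internal mammary coronary artery bypass"),
             ("4513", "sm bowel endoscopy nec", "other endoscopy of small intestine"),
             ("5491", "percu abdominal drainage", "percutaneous abdominal drainage"),
             ("3324", "closed bronchial biopsy", "closed endoscopic biopsy of bronchus")]
DRUGS = [("potassium chloride", "kcl20", "po"), ("insulin", "ins", "sc"),
         ("furosemide", "furo40", "iv"), ("metoprolol", "metop25", "po"),
         ("aspirin", "asa81", "po"), ("heparin sodium", "heparin5", "iv"),
         ("vancomycin", "vanc1f", "iv"), ("morphine sulfate", "morph2", "iv"),
         ("warfarin", "warf5", "po"), ("lisinopril", "lisin10", "po")]
DRUG_TYPE = ["main", "base", "additive"]
LAB_ROWS = [("hematocrit", "blood", "hematology", "%"),
            ("hemoglobin", "blood", "hematology", "g/dl"),
            ("platelet count", "blood", "hematology", "k/ul"),
            ("potassium", "blood", "chemistry", "meq/l"),
            ("sodium", "blood", "chemistry", "meq/l"),
            ("creatinine", "blood", "chemistry", "mg/dl"),
            ("glucose", "blood", "chemistry", "mg/dl"),
            ("white blood cells", "blood", "hematology", "k/ul"),
            ("bicarbonate", "blood", "chemistry", "meq/l"),
            ("ph", "urine", "chemistry", "units")]
LAB_FLAG = ["normal", "abnormal", "delta"]


def sample_records(
    schema: DatabaseSchema, n_patients: int, seed: int
) -> dict[str, list[dict]]:
    """Synthetic patient rows for every table, deterministic under seed.

    One admission per patient; each satellite table holds 1-3 rows per
    admission keyed by the same hadm_id (referential integrity).
    """
    if n_patients < 1:
        raise GenerationError("need at least one patient")
    rng = np.random.default_rng(seed)
    records: dict[str, list[dict]] = {t.name: [] for t in schema.tables}
    for i in range(n_patients):
        subject_id = i + 1
        hadm_id = 100000 + i
        name = f"{FIRST[int(rng.integers(len(FIRST)))]} " \
               f"{LAST[int(rng.integers(len(LAST)))]}"
        age = int(rng.integers(18, 90))
        admityear = int(rng.integers(2100, 2206))
        dob_year = admityear - age
        expire_flag = int(rng.random() < 0.3)
        days_stay = int(rng.integers(1, 41))
        records["demographic"].append({
            "subject_id": subject_id, "hadm_id": hadm_id, "name": name,
            "marital_status": str(rng.choice(MARITAL)),
            "age": age, "dob": f"{dob_year}-{int(rng.integers(1,13)):02d}-"
                                f"{int(rng.integers(1,29)):02d}",
            "gender": str(rng.choice(GENDER)),
            "language": str(rng.choice(LANGUAGE)),
            "religion": str(rng.choice(RELIGION)),
            "admission_type": str(rng.choice(ADMISSION_TYPE)),
            "days_stay": days_stay,
            "insurance": str(rng.choice(INSURANCE)),
            "ethnicity": str(rng.choice(ETHNICITY)),
            "expire_flag": expire_flag,
            "admission_location": str(rng.choice(ADMIT_LOC)),
            "discharge_location": ("dead/expired" if expire_flag
                                   else str(rng.choice(DISCH_LOC[:3]))),
            "diagnosis": str(rng.choice(DIAGNOSIS_TEXT)),
            "dod": f"{dob_year + age}-01-01" if expire_flag else None,
            "dob_year": dob_year,
            "dod_year": dob_year + age if expire_flag else None,
            "admittime": f"{admityear}-{int(rng.integers(1,13)):02d}-01",
            "dischtime": f"{admityear}-{int(rng.integers(1,13)):02d}-{days_stay:02d}",
            "admityear": admityear,
        })
        for code, short, long_ in _pick_rows(rng, DIAG_ROWS):
            records["diagnoses"].append({
                "subject_id": subject_id, "hadm_id": hadm_id,
                "icd9_code": code, "short_title": short, "long_title": long_,
            })
        for code, short, long_ in _pick_rows(rng, PROC_ROWS):
            records["procedures"].append({
                "subject_id": subject_id, "hadm_id": hadm_id,
                "icd9_code": code, "short_title": short, "long_title": long_,
            })
        for drug, cd, route in _pick_rows(rng, DRUGS):
            records["prescriptions"].append({
                "subject_id": subject_id, "hadm_id": hadm_id,
                "icustay_id": 200000 + i,
                "drug_type": str(rng.choice(DRUG_TYPE)), "drug": drug,
                "formulary_drug_cd": cd, "route": route,
            })
        for label, fluid, category, unit in _pick_rows(rng, LAB_ROWS):
            records["lab"].append({
                "subject_id": subject_id, "hadm_id": hadm_id,
                "itemid": int(rng.integers(50800, 51500)),
                "charttime": f"{admityear}-01-{int(rng.integers(1,29)):02d}",
                "flag": str(rng.choice(LAB_FLAG)),
                "value_unit": unit, "label": label, "fluid": fluid,
                "category": category,
            })
    return records


def _pick_rows(rng, pool, lo=1, hi=3):
    k = int(rng.integers(lo, hi + 1))
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# question templates

# column -> natural phrase used in questions (words overlap the column name
# where a real question naturally would, which is what schema linking keys on)
COL_PHRASE = {
    "insurance": "insurance",
    "marital_status": "marital status",
    "religion": "religion",
    "language": "language",
    "admission_type": "admission type",
    "ethnicity": "ethnicity",
    "age": "age",
    "days_stay": "days of hospital stay",
    "diagnosis": "primary disease",
    "admission_location": "admission location",
    "discharge_location": "discharge location",
    "gender": "gender",
    "dob": "date of birth",
}
LOOKUP_COLS = list(COL_PHRASE)

# (question phrase builder, sql condition) pairs keep values verbatim
_SYNONYMS = {
    "tell": "show", "list": "display", "calculate": "compute",
    "find": "give", "patients": "subjects", "number": "count",
}
_FILLERS = {"me", "the", "please"}


@dataclass
class _Cond:
    phrase: str  # contains {v} / {v2} slots already filled
    table: str
    column: str
    op: str
    values: tuple[str, ...]
    or_with: Optional["_Cond"] = None  # second branch of an "or"

    def sql(self) -> str:
        def one(c):
            col = f'{c.table}."{c.column}"'
            if c.op == "between":
                return f'{col} between "{c.values[0]}" and "{c.values[1]}"'
            op = "not like" if c.op == "not_like" else c.op
            return f'{col} {op} "{c.values[0]}"'

        if self.or_with is not None:
            return f"{one(self)} or {one(self.or_with)}"
        return one(self)


class _Gen:
    """Stateful template sampler over one record set."""

    def __init__(self, schema, records, rng):
        self.schema = schema
        self.records = records
        self.rng = rng
        self.demo = records["demographic"]

    def _patient(self):
        return self.demo[int(self.rng.integers(len(self.demo)))]

    def _year(self, lo=2100, hi=2205):
        return str(int(self.rng.integers(lo, hi)))

    def _name_cond(self):
        p = self._patient()
        return _Cond(f"of patient {p['name']}", "demographic", "name",
                     "=", (p["name"],))

    def _extra_cond(self):
        """A second demographic condition whose value is spoken verbatim."""
        r = self.rng.random()
        if r < 0.25:
            y = self._year()
            return _Cond(f"born before the year {y}", "demographic",
                         "dob_year", "<", (y,))
        if r < 0.5:
            y = self._year()
            return _Cond(f"admitted after the year {y}", "demographic",
                         "admityear", ">", (y,))
        if r < 0.75:
            ins = str(self.rng.choice(INSURANCE))
            return _Cond(f"with {ins} insurance", "demographic",
                         "insurance", "=", (ins,))
        g = str(self.rng.choice(GENDER))
        return _Cond(f"whose gender is {g}", "demographic", "gender",
                     "=", (g,))

    def _fancy_cond(self):
        """Conditions exercising the rarer operators."""
        r = self.rng.random()
        if r < 0.2:
            y1 = int(self.rng.integers(2100, 2150))
            y2 = y1 + int(self.rng.integers(5, 40))
            return _Cond(f"born between {y1} and {y2}", "demographic",
                         "dob_year", "between", (str(y1), str(y2)))
        if r < 0.35:
            ins = str(self.rng.choice(INSURANCE))
            return _Cond(f"who do not have {ins} insurance", "demographic",
                         "insurance", "!=", (ins,))
        if r < 0.5:
            d = str(self.rng.choice(DIAGNOSIS_TEXT))
            return _Cond(f"whose primary disease is like {d}",
                         "demographic", "diagnosis", "like", (d,))
        if r < 0.6:
            d = str(self.rng.choice(DIAGNOSIS_TEXT))
            return _Cond(f"whose primary disease is not like {d}",
                         "demographic", "diagnosis", "not_like", (d,))
        if r < 0.75:
            y = self._year()
            return _Cond(f"admitted in or after the year {y}",
                         "demographic", "admityear", ">=", (y,))
        if r < 0.9:
            y = self._year()
            return _Cond(f"admitted in or before the year {y}",
                         "demographic", "admityear", "<=", (y,))
        i1, i2 = [str(x) for x in
                  self.rng.choice(INSURANCE, size=2, replace=False)]
        first = _Cond(f"with {i1} or {i2} insurance", "demographic",
                      "insurance", "=", (i1,))
        first.or_with = _Cond("", "demographic", "insurance", "=", (i2,))
        return first

    def _satellite_cond(self):
        r = self.rng.random()
        if r < 0.3:
            row = self.records["prescriptions"][
                int(self.rng.integers(len(self.records["prescriptions"])))]
            return _Cond(f"who were prescribed {row['drug']}",
                         "prescriptions", "drug", "=", (row["drug"],))
        if r < 0.6:
            row = self.records["diagnoses"][
                int(self.rng.integers(len(self.records["diagnoses"])))]
            return _Cond(f"diagnosed with {row['short_title']}",
                         "diagnoses", "short_title", "=",
                         (row["short_title"],))
        if r < 0.8:
            flag = str(self.rng.choice(LAB_FLAG))
            return _Cond(f"with a lab test flagged {flag}", "lab", "flag",
                         "=", (flag,))
        row = self.records["procedures"][
            int(self.rng.integers(len(self.records["procedures"])))]
        return _Cond(f"who underwent {row['short_title']}",
                     "procedures", "short_title", "=", (row["short_title"],))

    # -- families ----------------------------------------------------------

    def build(self) -> tuple[str, str]:
        """Return (question text, sql text) for one sampled template."""
        fam = self.rng.choice(
            ["A", "B", "C", "D", "E", "F", "G", "H"],
            p=[0.14, 0.10, 0.05, 0.38, 0.12, 0.15, 0.03, 0.03],
        )
        return getattr(self, f"_family_{fam}")()

    def _select_sql(self, items, conds):
        cols = ", ".join(
            f'{t}."{c}"' if agg == "none"
            else (f'count(distinct {t}."{c}")' if agg == "count_distinct"
                  else f'{agg}({t}."{c}")')
            for agg, c, t in items
        )
        tables = []
        for _, _, t in items:
            if t not in tables:
                tables.append(t)
        for c in conds:
            for cc in (c, c.or_with):
                if cc is not None and cc.table not in tables:
                    tables.append(cc.table)
        frm = tables[0]
        for t in tables[1:]:
            frm += (f" inner join {t} on {tables[0]}.hadm_id = {t}.hadm_id")
        where = ""
        if conds:
            where = " where " + " and ".join(c.sql() for c in conds)
        return f"select {cols} from {frm}{where}"

    def _family_A(self):
        """Attribute lookup of one patient: 1-3 demographic columns."""
        k = int(self.rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        cols = [str(c) for c in
                self.rng.choice(LOOKUP_COLS, size=k, replace=False)]
        phrases = [COL_PHRASE[c] for c in cols]
        if k == 1:
            sel_text = f"the {phrases[0]}"
        elif k == 2:
            sel_text = f"the {phrases[0]} and {phrases[1]}"
        else:
            sel_text = f"the {phrases[0]}, {phrases[1]} and {phrases[2]}"
        cond = self._name_cond()
        opener = str(self.rng.choice(
            ["tell me", "what is", "give me", "show"]))
        q = f"{opener} {sel_text} {cond.phrase}"
        sql = self._select_sql(
            [("none", c, "demographic") for c in cols], [cond])
        return q, sql

    def _family_B(self):
        """Satellite attribute lookup for one patient (join)."""
        choice = self.rng.random()
        cond = self._name_cond()
        if choice < 0.3:
            k2 = self.rng.random() < 0.4
            items = [("none", "short_title", "diagnoses")]
            sel = "the short title of diagnoses"
            if k2:
                items.append(("none", "icd9_code", "diagnoses"))
                sel = "the short title and icd9 code of diagnoses"
        elif choice < 0.55:
            items = [("none", "short_title", "procedures")]
            sel = "the short title of procedures"
        elif choice < 0.8:
            items = [("none", "drug", "prescriptions")]
            sel = "the prescribed drug"
            if self.rng.random() < 0.3:
                items.append(("none", "route", "prescriptions"))
                sel = "the prescribed drug and its route"
        else:
            items = [("none", "label", "lab")]
            sel = "the lab test label"
        q = f"tell me {sel} {cond.phrase}"
        return q, self._select_sql(items, [cond])

    def _family_C(self):
        """Count of patients under one condition."""
        cond = self._extra_cond()
        q = f"how many patients {cond.phrase} are there"
        sql = self._select_sql(
            [("count_distinct", "subject_id", "demographic")], [cond])
        return q, sql

    def _family_D(self):
        """Count of patients under two and-ed conditions."""
        c1 = self._extra_cond()
        for _ in range(8):
            c2 = self._extra_cond() if self.rng.random() < 0.6 \
                else self._satellite_cond()
            if (c2.table, c2.column) != (c1.table, c1.column):
                break
        opener = str(self.rng.choice(
            ["how many patients", "calculate the number of patients",
             "count the number of patients"]))
        q = f"{opener} {c1.phrase} {c2.phrase}"
        sql = self._select_sql(
            [("count_distinct", "subject_id", "demographic")], [c1, c2])
        return q, sql

    def _family_E(self):
        """Counts with the rarer operators (or/between/!=/like/>=/<=)."""
        cond = self._fancy_cond()
        q = f"how many patients {cond.phrase} are there"
        sql = self._select_sql(
            [("count_distinct", "subject_id", "demographic")], [cond])
        return q, sql

    def _family_F(self):
        """Aggregates over numeric demographics with 1-2 conditions."""
        agg, col, phrase = [
            ("min", "days_stay", "the minimum number of days of hospital stay"),
            ("max", "days_stay", "the maximum number of days of hospital stay"),
            ("avg", "age", "the average age"),
            ("max", "age", "the maximum age"),
            ("min", "age", "the minimum age"),
            ("sum", "days_stay", "the total number of days of hospital stay"),
        ][int(self.rng.integers(6))]
        conds = [self._extra_cond()]
        if self.rng.random() < 0.8:
            for _ in range(8):
                c2 = self._extra_cond()
                if (c2.table, c2.column) != (conds[0].table, conds[0].column):
                    conds.append(c2)
                    break
        cond_text = " ".join(c.phrase for c in conds)
        q = f"find {phrase} for patients {cond_text}"
        return q, self._select_sql([(agg, col, "demographic")], conds)

    def _family_G(self):
        """No-where counts (plain count aggregator coverage)."""
        if self.rng.random() < 0.5:
            q = "how many admission records are there in total"
            items = [("count", "hadm_id", "demographic")]
        else:
            q = "count the number of distinct patients on record"
            items = [("count_distinct", "subject_id", "demographic")]
        return q, self._select_sql(items, [])

    def _family_H(self):
        """Satellite attribute keyed by a satellite value."""
        r = self.rng.random()
        if r < 0.4:
            drug, _, _ = DRUGS[int(self.rng.integers(len(DRUGS)))]
            q = f"what is the route of the drug {drug}"
            items = [("none", "route", "prescriptions")]
            cond = _Cond("", "prescriptions", "drug", "=", (drug,))
        elif r < 0.7:
            code, _, _ = DIAG_ROWS[int(self.rng.integers(len(DIAG_ROWS)))]
            q = f"show the long title of diagnoses with icd9 code {code}"
            items = [("none", "long_title", "diagnoses")]
            cond = _Cond("", "diagnoses", "icd9_code", "=", (code,))
        else:
            label, _, _, _ = LAB_ROWS[int(self.rng.integers(len(LAB_ROWS)))]
            q = f"tell me the fluid and category of the lab test {label}"
            items = [("none", "fluid", "lab"), ("none", "category", "lab")]
            cond = _Cond("", "lab", "label", "=", (label,))
        return q, self._select_sql(items, [cond])


def _paraphrase(question: str, protected: list[str], rng) -> str:
    """Seeded synonym substitution / filler dropout away from value spans."""
    masked = question
    placeholders = {}
    for i, val in enumerate(sorted(set(protected), key=len, reverse=True)):
        ph = f"\x00{i}\x00"
        placeholders[ph] = val
        masked = masked.replace(val, ph)
    words = masked.split(" ")
    out = []
    for w in words:
        if w in _SYNONYMS and rng.random() < 0.5:
            out.append(_SYNONYMS[w])
        elif w in _FILLERS and rng.random() < 0.3:
            continue
        else:
            out.append(w)
    result = " ".join(out)
    for ph, val in placeholders.items():
        result = result.replace(ph, val)
    return result


def _condition_values(tree) -> list[str]:
    return [v.text for v in tree.leaves("V") if v.text]


def generate_pairs(
    schema: DatabaseSchema,
    records: dict[str, list[dict]],
    cfg: GenConfig,
) -> tuple[list[TrainExample], Database]:
    """Instantiate ``cfg.n_pairs`` template pairs over ``records``.

    Returns the examples (with train/val/test splits assigned) and the
    populated fixture database every gold query executes on.
    """
    rng = np.random.default_rng(cfg.seed)
    db = build_fixture_db(schema, records, cfg.db_path)
    gen = _Gen(schema, records, rng)
    examples: list[TrainExample] = []
    attempts = 0
    while len(examples) < cfg.n_pairs:
        attempts += 1
        if attempts > cfg.n_pairs * 20:
            raise GenerationError("template/slot exhaustion")
        question, sql = gen.build()
        tree = sql_to_tree(sql, schema)
        sql = tree_to_sql(tree, schema).text  # canonical rendering
        values = _condition_values(tree)
        if rng.random() < cfg.paraphrase_rate:
            question = _paraphrase(question, values, rng)
        tokens = tokenize(question)
        mq = link(tokens, schema)
        try:
            actions = tree_to_actions(tree, mq)
        except Exception:
            continue  # a paraphrase or slot clash broke the value span
        if not db.executes_ok(sql):
            continue
        examples.append(TrainExample(
            question=question, sql=sql, marked_question=mq, actions=actions,
        ))
    # deterministic split assignment
    idx = rng.permutation(len(examples))
    n_train = int(round(cfg.split_ratios[0] * len(examples)))
    n_val = int(round(cfg.split_ratios[1] * len(examples)))
    for rank, i in enumerate(idx):
        if rank < n_train:
            examples[i].split = "train"
        elif rank < n_train + n_val:
            examples[i].split = "val"
        else:
            examples[i].split = "test"
    return examples, db
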