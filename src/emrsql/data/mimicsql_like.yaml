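# Five-table EMR-style schema: demographics plus four satellite tables
# (diagnoses, procedures, prescriptions, laboratory tests) all joined to
# demographics on the admission key hadm_id. Column counts 23/5/5/7/9.
tables:
  - name: demographic
    columns:
      - {name: subject_id, kind: numeric}
      - {name: hadm_id, kind: numeric, join_key: true}
      - {name: name, kind: text}
      - {name: marital_status, kind: text}
      - {name: age, kind: numeric}
      - {name: dob, kind: text}
      - {name: gender, kind: text}
      - {name: language, kind: text}
      - {name: religion, kind: text}
      - {name: admission_type, kind: text}
      - {name: days_stay, kind: numeric}
      - {name: insurance, kind: text}
      - {name: ethnicity, kind: text}
      - {name: expire_flag, kind: numeric}
      - {name: admission_location, kind: text}
      - {name: discharge_location, kind: text}
      - {name: diagnosis, kind: text}
      - {name: dod, kind: text}
      - {name: dob_year, kind: numeric}
      - {name: dod_year, kind: numeric}
      - {name: admittime, kind: text}
      - {name: dischtime, kind: text}
      - {name: admityear, kind: numeric}
  - name: diagnoses
    columns:
      - {name: subject_id, kind: numeric}
      - {name: hadm_id, kind: numeric, join_key: true}
      - {name: icd9_code, kind: text}
      - {name: short_title, kind: text}
      - {name: long_title, kind: text}
  - name: procedures
    columns:
      - {name: subject_id, kind: numeric}
      - {name: hadm_id, kind: numeric, join_key: true}
      - {name: icd9_code, kind: text}
      - {name: short_title, kind: text}
      - {name: long_title, kind: text}
  - name: prescriptions
    columns:
      - {name: subject_id, kind: numeric}
      - {name: hadm_id, kind: numeric, join_key: true}
      - {name: icustay_id, kind: numeric}
      - {name: drug_type, kind: text}
      - {name: drug, kind: text}
      - {name: formulary_drug_cd, kind: text}
      - {name: route, kind: text}
  - name: lab
    columns:
      - {name: subject_id, kind: numeric}
      - {name: hadm_id, kind: numeric, join_key: true}
      - {name: itemid, kind: numeric}
      - {name: charttime, kind: text}
      - {name: flag, kind: text}
      - {name: value_unit, kind: text}
      - {name: label, kind: text}
      - {name: fluid, kind: text}
      - {name: category, kind: text}
joins:
  - [demographic, diagnoses, hadm_id]
  - [demographic, procedures, hadm_id]
  - [demographic, prescriptions, hadm_id]
  - [demographic, lab, hadm_id]
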