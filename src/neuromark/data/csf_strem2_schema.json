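{
  "description": "CSF soluble-TREM2 table: one row per subject (46 sporadic ALS, 20 controls).",
  "columns": {
    "subject_id": "unique row identifier",
    "group": "ALS or Control",
    "sex": "M or F",
    "onset_age_years": "age at symptom onset; empty if unavailable (one ALS row) or Control",
    "duration_years": "onset-to-death disease duration in years; empty if unavailable or Control",
    "sampling_age_printed": "age at CSF sampling as printed; control entries are kept verbatim but are not parseable consistently and are excluded from all computation",
    "percent_course": "percent of the onset-to-death course elapsed at CSF sampling (0-100); empty if unavailable or Control",
    "strem2_ng_ml": "soluble TREM2 concentration in CSF, ng/ml"
  },
  "sha256": "15cc6ea825db3773ed02dbb6acf85631b1df919fa08748852067ded303edb78c"
}
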