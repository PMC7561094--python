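{
  "schema_version": 1,
  "name": "P-POSSUM",
  "version": "ppossum_v1",
  "link": "logit",
  "provenance": "Portsmouth-POSSUM mortality equation, transcribed from Prytherch et al., Br J Surg 1998;85:1217-1220; sub-score banding per Copeland et al., Br J Surg 1991;78:355-360. Expedited urgency maps to the non-emergency (elective) mode-of-surgery band; cardiac and respiratory signs are derived from the comorbidity flags (cardiac failure > coronary artery disease on medication > none; COPD scores as mild chronic airways disease).",
  "intercept": -9.065,
  "variables": {
    "possum_physiology": {
      "type": "possum_score",
      "items": [
        {"name": "age", "kind": "numeric_bands", "source": "age_years",
         "bands": [{"hi": 61, "points": 1}, {"hi": 71, "points": 2}, {"points": 4}]},
        {"name": "cardiac", "kind": "flags_max", "default": 1,
         "rules": [{"flag": "cardiac_failure", "points": 4},
                   {"flag": "coronary_artery_disease", "points": 2}]},
        {"name": "respiratory", "kind": "flags_max", "default": 1,
         "rules": [{"flag": "copd", "points": 2}]},
        {"name": "systolic_bp", "kind": "numeric_bands", "source": "systolic_bp",
         "bands": [{"hi": 90, "points": 8}, {"hi": 100, "points": 4},
                   {"hi": 110, "points": 2}, {"hi": 131, "points": 1},
                   {"hi": 171, "points": 2}, {"points": 4}]},
        {"name": "pulse", "kind": "numeric_bands", "source": "pulse",
         "bands": [{"hi": 40, "points": 8}, {"hi": 50, "points": 2},
                   {"hi": 81, "points": 1}, {"hi": 101, "points": 2},
                   {"hi": 121, "points": 4}, {"points": 8}]},
        {"name": "gcs", "kind": "numeric_bands", "source": "gcs",
         "bands": [{"hi": 9, "points": 8}, {"hi": 12, "points": 4},
                   {"hi": 15, "points": 2}, {"points": 1}]},
        {"name": "haemoglobin", "kind": "numeric_bands", "source": "haemoglobin",
         "bands": [{"hi": 10.0, "points": 8}, {"hi": 11.5, "points": 4},
                   {"hi": 13.0, "points": 2}, {"hi": 16.1, "points": 1},
                   {"hi": 17.1, "points": 2}, {"hi": 18.1, "points": 4},
                   {"points": 8}]},
        {"name": "wbc", "kind": "numeric_bands", "source": "wbc",
         "bands": [{"hi": 3.1, "points": 4}, {"hi": 4.0, "points": 2},
                   {"hi": 10.1, "points": 1}, {"hi": 20.1, "points": 2},
                   {"points": 4}]},
        {"name": "urea", "kind": "numeric_bands", "source": "urea",
         "bands": [{"hi": 7.6, "points": 1}, {"hi": 10.1, "points": 2},
                   {"hi": 15.1, "points": 4}, {"points": 8}]},
        {"name": "sodium", "kind": "numeric_bands", "source": "sodium",
         "bands": [{"hi": 126, "points": 8}, {"hi": 131, "points": 4},
                   {"hi": 136, "points": 2}, {"points": 1}]},
        {"name": "potassium", "kind": "numeric_bands", "source": "potassium",
         "bands": [{"hi": 2.9, "points": 8}, {"hi": 3.2, "points": 4},
                   {"hi": 3.5, "points": 2}, {"hi": 5.1, "points": 1},
                   {"hi": 5.4, "points": 2}, {"hi": 6.0, "points": 4},
                   {"points": 8}]},
        {"name": "ecg", "kind": "categorical", "source": "ecg",
         "map": {"normal": 1, "af_60_90": 4, "other_abnormal": 8}}
      ]
    },
    "possum_operative": {
      "type": "possum_score",
      "items": [
        {"name": "severity", "kind": "categorical", "source": "severity",
         "map": {"minor": 1, "intermediate": 2, "major": 4, "xmajor": 8,
                 "complex": 8}},
        {"name": "procedure_count", "kind": "categorical",
         "source": "procedure_count",
         "map": {"one": 1, "two": 4, "gt2": 8}},
        {"name": "blood_loss", "kind": "categorical", "source": "blood_loss",
         "map": {"le_100": 1, "101_500": 2, "501_999": 4, "ge_1000": 8}},
        {"name": "peritoneal_soiling", "kind": "categorical",
         "source": "peritoneal_soiling",
         "map": {"none": 1, "serous": 2, "local_pus": 4,
                 "free_pus_blood_faeces": 8}},
        {"name": "malignancy", "kind": "categorical", "source": "malignancy",
         "map": {"none": 1, "primary": 2, "nodal": 4, "metastatic": 8}},
        {"name": "mode_of_surgery", "kind": "categorical", "source": "urgency",
         "map": {"elective": 1, "expedited": 1, "urgent": 4, "immediate": 8}}
      ]
    }
  },
  "terms": [
    {"variable": "possum_physiology", "linear": true, "coef": 0.1692},
    {"variable": "possum_operative", "linear": true, "coef": 0.155}
  ]
}
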