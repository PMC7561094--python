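{
  "schema_version": 1,
  "name": "SORT",
  "version": "sort_v1",
  "link": "logit",
  "provenance": "Surgical Outcome Risk Tool, transcribed from Protopapa et al., Br J Surg 2014;101:1774-1783 (development on NCEPOD 'Knowing the Risk' cohort). Expedited urgency is a native SORT category and needs no remapping.",
  "intercept": -7.366,
  "variables": {
    "asa": {
      "type": "categorical",
      "source": "asa_ps",
      "map": {"1": "I_II", "2": "I_II", "3": "III", "4": "IV", "5": "V"}
    },
    "urgency": {
      "type": "categorical",
      "source": "urgency",
      "map": {
        "elective": "elective",
        "expedited": "expedited",
        "urgent": "urgent",
        "immediate": "immediate"
      }
    },
    "high_risk_specialty": {
      "type": "flag_in",
      "source": "specialty",
      "levels": ["gastrointestinal", "thoracic_cardiac", "vascular"],
      "true_level": "yes",
      "false_level": "no"
    },
    "severity_xmajor_complex": {
      "type": "flag_in",
      "source": "severity",
      "levels": ["xmajor", "complex"],
      "true_level": "yes",
      "false_level": "no"
    },
    "cancer": {
      "type": "flag_in",
      "source": "malignancy",
      "levels": ["primary", "nodal", "metastatic"],
      "true_level": "yes",
      "false_level": "no"
    },
    "age_band": {
      "type": "band",
      "source": "age_years",
      "edges": [65, 80],
      "levels": ["lt65", "65_79", "ge80"]
    }
  },
  "terms": [
    {"variable": "asa", "level": "III", "coef": 1.411},
    {"variable": "asa", "level": "IV", "coef": 2.388},
    {"variable": "asa", "level": "V", "coef": 4.081},
    {"variable": "urgency", "level": "expedited", "coef": 0.712},
    {"variable": "urgency", "level": "urgent", "coef": 1.657},
    {"variable": "urgency", "level": "immediate", "coef": 2.452},
    {"variable": "high_risk_specialty", "level": "yes", "coef": 0.381},
    {"variable": "severity_xmajor_complex", "level": "yes", "coef": 0.921},
    {"variable": "cancer", "level": "yes", "coef": 0.118},
    {"variable": "age_band", "level": "65_79", "coef": 0.777},
    {"variable": "age_band", "level": "ge80", "coef": 1.591}
  ]
}
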