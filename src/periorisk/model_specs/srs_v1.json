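{
  "schema_version": 1,
  "name": "SRS",
  "version": "srs_v1",
  "link": "logit",
  "provenance": "Surgical Risk Scale, transcribed from Sutton et al., Br J Surg 2002;89:763-768: score = CEPOD urgency grade (1-4) + BUPA procedure-severity grade (1-5) + ASA-PS (1-5); mortality via the published logistic conversion logit(p) = 0.84*SRS - 9.81. Expedited urgency (post-dates the original CEPOD classification) maps to the 'scheduled' grade 2.",
  "intercept": -9.81,
  "variables": {
    "srs_score": {
      "type": "score_sum",
      "components": [
        {"source": "urgency",
         "map": {"elective": 1, "expedited": 2, "urgent": 3, "immediate": 4}},
        {"source": "severity",
         "map": {"minor": 1, "intermediate": 2, "major": 3, "xmajor": 4,
                 "complex": 5}},
        {"source": "asa_ps",
         "map": {"1": 1, "2": 2, "3": 3, "4": 4, "5": 5}}
      ]
    }
  },
  "terms": [
    {"variable": "srs_score", "linear": true, "coef": 0.84}
  ]
}
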