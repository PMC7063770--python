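{
  "name": "revised_ckdepi_9var",
  "description": "Revised 9-variable CKD-EPI-style equation (age, sex, serum creatinine, serum cystatin C, BMI, blood urea nitrogen, albumin, uric acid, hemoglobin). eGFR in mL/min/1.73 m^2; scr in mg/dL; scys in mg/L; bun in mg/dL; alb in g/dL; ua in mg/dL; hgb in g/dL.",
  "female": {
    "intercept": 154.0,
    "scr_knot": 0.7,
    "scys_knot": 0.9,
    "scr_exp_low": -0.262,
    "scr_exp_high": -0.320,
    "scys_exp_low": -0.045,
    "scys_exp_high": -0.374,
    "age_factor": 0.996,
    "aux_terms": [
      {"variable": "bmi", "kind": "factor", "value": 0.985},
      {"variable": "bun", "kind": "power", "value": 0.006},
      {"variable": "alb", "kind": "factor", "value": 0.985},
      {"variable": "ua", "kind": "factor", "value": 0.997},
      {"variable": "hgb", "kind": "factor", "value": 1.012}
    ]
  },
  "male": {
    "intercept": 103.0,
    "scr_knot": 0.9,
    "scys_knot": 0.9,
    "scr_exp_low": -0.347,
    "scr_exp_high": -0.391,
    "scys_exp_low": -0.099,
    "scys_exp_high": -0.405,
    "age_factor": 0.996,
    "aux_terms": [
      {"variable": "bmi", "kind": "factor", "value": 0.982},
      {"variable": "bun", "kind": "power", "value": 0.125},
      {"variable": "alb", "kind": "factor", "value": 0.949},
      {"variable": "ua", "kind": "factor", "value": 0.996},
      {"variable": "hgb", "kind": "factor", "value": 1.027}
    ]
  }
}
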