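{
  "name": "revised_ckdepi_4var",
  "description": "Revised 4-variable CKD-EPI-style equation (age, sex, serum creatinine, serum cystatin C). eGFR in mL/min/1.73 m^2; scr in mg/dL; scys in mg/L.",
  "female": {
    "intercept": 122.0,
    "scr_knot": 0.7,
    "scys_knot": 0.9,
    "scr_exp_low": -0.236,
    "scr_exp_high": -0.330,
    "scys_exp_low": -0.078,
    "scys_exp_high": -0.381,
    "age_factor": 0.995,
    "aux_terms": []
  },
  "male": {
    "intercept": 107.0,
    "scr_knot": 0.9,
    "scys_knot": 0.9,
    "scr_exp_low": -0.292,
    "scr_exp_high": -0.358,
    "scys_exp_low": -0.045,
    "scys_exp_high": -0.397,
    "age_factor": 0.996,
    "aux_terms": []
  }
}
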