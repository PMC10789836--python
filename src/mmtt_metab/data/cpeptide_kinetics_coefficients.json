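{
  "description": "Population C-peptide kinetic coefficients for the standard two-compartment model (Van Cauter et al., Diabetes 1992). The plasma decay after a C-peptide bolus is F*exp(-a*t) + (1-F)*exp(-b*t) with a = ln2/short_halflife_min and b = ln2/long_halflife_min; the long half-life is a linear function of age and the central distribution volume a linear function of Du Bois body surface area.",
  "classes": {
    "normal": {"fraction": 0.76, "short_halflife_min": 4.95},
    "obese": {"fraction": 0.78, "short_halflife_min": 4.55},
    "type2_diabetes": {"fraction": 0.78, "short_halflife_min": 4.52}
  },
  "long_halflife_min": {"slope_per_year": 0.14, "intercept": 29.2},
  "volume_l": {"slope_per_m2": 1.92, "intercept": 0.64},
  "reference_case": {
    "comment": "Self-consistency row used by the test suite: a 60-year-old man, 170 cm, 70 kg, with type 2 diabetes. BSA (Du Bois) = 1.8096 m2.",
    "age": 60, "sex": "M", "height_cm": 170.0, "weight_kg": 70.0,
    "diabetes": true, "obese": false
  }
}
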