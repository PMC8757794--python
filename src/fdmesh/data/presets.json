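{
  "note": "Illustrative braided flow-diverter presets. Brand labels follow the emulated cohort; strut dimensions, wire counts and braiding angles are NOT manufacturer data — they are calibrated so nominal porosities fall in the plausible 0.65-0.80 band and deployed porosity/mesh angle at ~87% expansion lands near the cohort averages.",
  "devices": [
    {
      "brand_label": "Derivo",
      "phi_nom_mm": 4.0,
      "L_nom_mm": 20.0,
      "n_wires": 48,
      "strut_len_mm": 0.30,
      "strut_width_mm": 0.0465,
      "alpha_nom_deg": 62.0
    },
    {
      "brand_label": "P64",
      "phi_nom_mm": 4.0,
      "L_nom_mm": 18.0,
      "n_wires": 64,
      "strut_len_mm": 0.28,
      "strut_width_mm": 0.0436,
      "alpha_nom_deg": 61.0
    },
    {
      "brand_label": "Pipeline",
      "phi_nom_mm": 4.0,
      "L_nom_mm": 20.0,
      "n_wires": 48,
      "strut_len_mm": 0.32,
      "strut_width_mm": 0.0420,
      "alpha_nom_deg": 63.0
    },
    {
      "brand_label": "Surpass",
      "phi_nom_mm": 4.5,
      "L_nom_mm": 25.0,
      "n_wires": 72,
      "strut_len_mm": 0.30,
      "strut_width_mm": 0.0445,
      "alpha_nom_deg": 63.0
    }
  ]
}
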