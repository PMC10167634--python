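{
  "description": "Panel-selected per-drug AUC0-24 target ranges (mg.h/L) and the mg/kg dose bounds they were derived from (median exposure in children up to 25 kg at each dose bound).",
  "derivation_population": "children <= 25 kg",
  "weight_cap_kg": 25,
  "targets": {
    "rifampicin":   {"dose_low_mg_kg": 22.5, "dose_high_mg_kg": 30.0, "auc_low": 54.5, "auc_high": 78.2},
    "isoniazid":    {"dose_low_mg_kg": 15.0, "dose_high_mg_kg": 20.0, "auc_low": 47.6, "auc_high": 59.4},
    "pyrazinamide": {"dose_low_mg_kg": 32.0, "dose_high_mg_kg": 44.0, "auc_low": 389.0, "auc_high": 535.0},
    "ethionamide":  {"dose_low_mg_kg": 16.0, "dose_high_mg_kg": 22.0, "auc_low": 21.9, "auc_high": 30.1}
  }
}
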