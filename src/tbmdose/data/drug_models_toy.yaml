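# Toy parameter set with round numbers; used by the unit-test suite so that
# structural tests never depend on the reference transcription/calibration.
profile: toy
drugs:
  rifampicin:
    cl_typical: null
    v_typical: 50.0
    f_typical: 1.0
    ka: 1.0
    size_metric: total_weight
    reference_size: 70.0
    allometric_exp_cl: 0.75
    allometric_exp_v: 1.0
    maturation: {tm50_weeks: 50.0, hill: 3.0}
    age_on_f: {fraction_at_birth: 0.5, plateau_years: 2.0}
    nat2_cl_multipliers: null
    saturation: {vmax: 200.0, km: 20.0}
    ddi_cl_multiplier: null
    bsv: {cl: 0.0, f: 0.0}
  isoniazid:
    cl_typical: 20.0
    v_typical: 50.0
    f_typical: 1.0
    ka: 2.0
    size_metric: total_weight
    reference_size: 70.0
    allometric_exp_cl: 0.75
    allometric_exp_v: 1.0
    maturation: null
    age_on_f: null
    nat2_cl_multipliers: {slow: 0.5, intermediate: 0.70710678, fast: 1.0}
    saturation: null
    ddi_cl_multiplier: null
    bsv: {cl: 0.0, f: 0.0}
  pyrazinamide:
    cl_typical: 4.0
    v_typical: 35.0
    f_typical: 1.0
    ka: 1.5
    size_metric: total_weight
    reference_size: 70.0
    allometric_exp_cl: 0.75
    allometric_exp_v: 1.0
    maturation: null
    age_on_f: null
    nat2_cl_multipliers: null
    saturation: null
    ddi_cl_multiplier: null
    bsv: {cl: 0.0, f: 0.0}
  ethionamide:
    cl_typical: 40.0
    v_typical: 90.0
    f_typical: 1.0
    ka: 1.5
    size_metric: total_weight
    reference_size: 70.0
    allometric_exp_cl: 0.75
    allometric_exp_v: 1.0
    maturation: null
    age_on_f: null
    nat2_cl_multipliers: null
    saturation: null
    ddi_cl_multiplier: 0.8
    bsv: {cl: 0.0, f: 0.0}
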