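"""Simulate steady-state AUC0-24 for all four drugs in one weight band.

Doses are the child-friendly tablet counts for the 12-13 kg band
(4 x RH 75/50, 3 x Z 150, 2 x Eto 125); the percentile spread shows the
between-subject variability the dosing strategy has to live with.
"""

import tbmdose as t

models = t.load_drug_models("reference")
formulary = t.load_formulations()
targets = t.load_panel_targets()

band = t.sample_band(12, 13, 2000, seed=7, age_stratum="over_3_months")
doses = t.dose_from_tablets({"RH_75_50": 4, "Z_150": 3, "Eto_125": 2}, formulary)

print("drug           dose(mg)  p5     p25    p50    p75    p95   target window")
for drug in t.DRUGS:
    res = t.simulate_exposures(band, models[drug], float(doses[drug]), seed=7)
    s = t.summarize(res, "drug").iloc[0]
    tr = targets[drug]
    print(f"{drug:13s} {float(doses[drug]):7.1f} "
          f"{s.p5:7.1f}{s.p25:7.1f}{s.p50:7.1f}{s.p75:7.1f}{s.p95:7.1f}"
          f"   [{tr.auc_low:g}, {tr.auc_high:g}] mg·h/L")
# the median should sit inside the target window; the p5-p95 spread is the
# log-normal between-subject variability (isoniazid widest: NAT2 trimodality)
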