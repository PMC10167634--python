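"""Reduce tablet burden with the RHZ 75/50/150 FDC at identical doses.

A 21 kg child on the child-friendly table takes 7 x RH 75/50 + 5 x Z 150 +
3 x Eto 125 = 15 tablets.  The substitution calculator finds the minimal
whole-tablet mix of the RHZ FDC, the RH FDC and the ethionamide tablet that
delivers exactly the same per-drug milligrams.
"""

import tbmdose as t

formulary = t.load_formulations()
current = {"RH_75_50": 7, "Z_150": 5, "Eto_125": 3}
doses = t.dose_from_tablets(current, formulary)

print("per-drug daily doses:",
      {d: f"{float(v):g} mg" for d, v in sorted(doses.items())})
print(f"current counts {current} -> burden {t.tablet_burden(current)}")

forms = [formulary.formulations[n] for n in ("RHZ_75_50_150", "RH_75_50", "Eto_125")]
sub = t.find_fdc_substitution(doses, forms, whole_tablets_only=True)
sub_f = {k: float(v) for k, v in sub.items()}
print(f"substitution  {sub_f} -> burden {t.tablet_burden(sub_f)}")
assert t.dose_from_tablets(sub, formulary) == doses  # identical milligrams
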