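"""Generate a virtual paediatric population and inspect its coherence.

The PK models need joint (age, weight, height, sex) covariates plus NAT2
acetylator class; weights are uniform per 1-kg band by design.
"""

import numpy as np

import tbmdose as t

spec = t.PopulationSpec(weight_min=3, weight_max=15, subjects_per_band=1000, seed=1)
pop = t.generate_population(spec)
df = pop.df

print(f"subjects: {len(pop)} ({spec.subjects_per_band} per 1-kg band, "
      f"{df.sex.eq('female').mean():.0%} female)")
print(f"age span: {df.age_years.min() * 12:.1f} months to {df.age_years.max():.1f} years")
print(f"corr(weight, age) = {np.corrcoef(df.weight_kg, df.age_years)[0, 1]:.2f}, "
      f"corr(weight, height) = {np.corrcoef(df.weight_kg, df.height_cm)[0, 1]:.2f}")
print("NAT2 fractions:", df.nat2.value_counts(normalize=True).round(3).to_dict())
print(f"infants (<3 months): {df.under_3_months.mean():.1%}, "
      f"heaviest infant {df.weight_kg[df.under_3_months].max():.1f} kg")
# positive correlations and the infant weight cap are what make the
# covariates usable in allometric/maturation PK models
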