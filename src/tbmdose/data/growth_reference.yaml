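# Sex-specific growth reference used to draw coherent (age, weight, height)
# triples for the virtual paediatric population.
#
# Medians are an approximate compilation in the style of the WHO child growth
# standards (0-5 y) and the WHO 2007 school-age reference (5-15 y), rounded to
# one decimal. They are editable: swapping in another reference only requires
# replacing the tables below (ages must be strictly increasing, medians
# strictly increasing with age).
#
# weight_log_sd is the log-scale dispersion of weight-for-age. It is set wider
# than the healthy-reference spread so that clinically common underweight
# children (TB populations in high-burden settings) are represented; see
# docs/methods.md.
ages_years: [0.0, 0.0833, 0.1667, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0,
             5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
male:
  weight_median_kg: [3.3, 4.5, 5.6, 6.4, 7.9, 8.9, 9.6, 10.9, 12.2, 14.3,
                     16.3, 18.3, 20.5, 22.9, 25.4, 28.1, 31.2, 34.7, 38.8,
                     43.4, 48.3, 53.0]
  height_median_cm: [49.9, 54.7, 58.4, 61.4, 67.6, 71.0, 75.7, 82.3, 87.1,
                     96.1, 103.3, 110.0, 116.0, 121.7, 127.3, 132.6, 137.8,
                     143.1, 149.1, 156.0, 163.2, 169.0]
female:
  weight_median_kg: [3.2, 4.2, 5.1, 5.8, 7.3, 8.3, 8.9, 10.2, 11.5, 13.9,
                     16.1, 18.2, 20.2, 22.4, 25.0, 28.2, 31.9, 36.2, 40.5,
                     44.4, 47.6, 50.5]
  height_median_cm: [49.1, 53.7, 57.1, 59.8, 65.7, 69.2, 74.0, 80.7, 85.7,
                     95.1, 102.7, 109.4, 115.1, 120.8, 126.6, 132.5, 138.6,
                     145.0, 151.2, 157.1, 160.4, 162.0]
weight_log_sd: 0.15
height_log_sd: 0.035
# Fat-free mass equation (pluggable; see population.fat_free_mass):
#   al-sallami: paediatric maturation-adjusted form, reduces to the
#   janmahasatian adult equation at high age.
ffm_equation: al-sallami
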