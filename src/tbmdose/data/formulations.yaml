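# Globally available formulation catalogue at the time of dosing-table
# development. Dispersible (child-friendly) tablets are scored or can be
# given as aliquots after dispersion, so halving is allowed; adult
# film-coated/uncoated tablets are given whole. Quarter tablets are never
# representable (counts are multiples of 0.5 at most).
formulations:
  - name: RH_75_50
    contents: {rifampicin: 75, isoniazid: 50}
    class: child_friendly
    splittable: halves_allowed
  - name: RHZ_75_50_150
    contents: {rifampicin: 75, isoniazid: 50, pyrazinamide: 150}
    class: child_friendly
    splittable: halves_allowed
  - name: H_100
    contents: {isoniazid: 100}
    class: child_friendly
    splittable: halves_allowed
  - name: Z_150
    contents: {pyrazinamide: 150}
    class: child_friendly
    splittable: halves_allowed
  - name: Eto_125
    contents: {ethionamide: 125}
    class: child_friendly
    splittable: halves_allowed
  - name: RH_150_75
    contents: {rifampicin: 150, isoniazid: 75}
    class: adult
    splittable: whole_only
  - name: RH_300_150
    contents: {rifampicin: 300, isoniazid: 150}
    class: adult
    splittable: whole_only
  - name: H_300
    contents: {isoniazid: 300}
    class: adult
    splittable: whole_only
  - name: Z_400
    contents: {pyrazinamide: 400}
    class: adult
    splittable: whole_only
  - name: Z_500
    contents: {pyrazinamide: 500}
    class: adult
    splittable: whole_only
  - name: Eto_250
    contents: {ethionamide: 250}
    class: adult
    splittable: whole_only
# Named formulation selections used by the dosing tables.
selections:
  child: [RH_75_50, Z_150, Eto_125]
  adult400: [RH_150_75, Z_400, Eto_250]
  adult500: [RH_150_75, Z_500, Eto_250]
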