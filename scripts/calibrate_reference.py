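#!/usr/bin/env python
"""Re-derive the calibrated values of the reference drug-model set.

The reference set anchors two things (see docs/methods.md):

1. shape — maturation (tm50, hill) and the infant-bioavailability fraction,
   fitted to the per-band median AUCs of the packaged published
   child-friendly dosing table (scale profiled out, linear proxy);
2. scale — typical clearances (Vmax/Km for rifampicin) solved so that the
   derived exposure-target windows match the packaged panel targets.

Run after editing structural assumptions to refresh the numbers:
    python scripts/calibrate_reference.py
It prints suggested values; the YAML is updated by hand so that each change
is reviewed.
"""

from dataclasses import replace

import numpy as np
from scipy.optimize import minimize, root

import tbmdose as t
from tbmdose.drug_models import Saturation, allometric_factor


def fit_shape(models, bands, pub, formulary):
    doses = {}
    for _, r in pub.iterrows():
        counts = {c: r[c] for c in ("RH_75_50", "Z_150", "Eto_125") if r[c] > 0}
        dd = t.dose_from_tablets(counts, formulary)
        doses[(r.weight_low, r.stratum)] = {d: float(v) for d, v in dd.items()}

    prep = {}
    for b in bands:
        key = (b.weight_low, b.age_stratum)
        prep[key] = {}
        for drug, m in models.items():
            df = b.dose_response[drug].population.df
            size = (df["ffm_kg"] if m.size_metric == "fat_free_mass" else df["weight_kg"]).to_numpy()
            base = allometric_factor(size, m.reference_size, 0.75)
            if m.nat2_cl_multipliers:
                base = base * df["nat2"].map(m.nat2_cl_multipliers).to_numpy(float)
            prep[key][drug] = (base, df["pma_weeks"].to_numpy(), df["age_years"].to_numpy())

    for drug, use_f in [("rifampicin", True), ("isoniazid", True),
                        ("pyrazinamide", False), ("ethionamide", False)]:
        m = models[drug]
        plateau = m.age_on_f.plateau_years if m.age_on_f else 2.0
        printed = {(r.weight_low, r.stratum): float(r[f"auc_{drug}"]) for _, r in pub.iterrows()}

        def obj(x):
            tm50, hill = np.exp(x[:2])
            frac0 = 1 / (1 + np.exp(-x[2])) if use_f else 1.0
            lr = []
            for key, target in printed.items():
                base, pma, age = prep[key][drug]
                mat = pma ** hill / (tm50 ** hill + pma ** hill)
                f = frac0 + (1 - frac0) * np.minimum(age, plateau) / plateau
                med = doses[key][drug] * np.median(f / (base * mat))
                lr.append(np.log(med / target))
            lr = np.array(lr)
            return np.sum((lr - lr.mean()) ** 2)

        x0 = [np.log(m.maturation.tm50_weeks), np.log(m.maturation.hill)] + ([0.0] if use_f else [])
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000})
        tm50, hill = np.exp(res.x[:2])
        msg = f"{drug:13s} tm50={tm50:6.1f} hill={hill:5.2f}"
        if use_f:
            msg += f" fraction_at_birth={1 / (1 + np.exp(-res.x[2])):.2f}"
        print(msg, f"(rms log-error {np.sqrt(res.fun / len(printed)):.3f})")


def fit_scale(models, pop, panel):
    ranges = t.panel_dose_ranges()

    def derived(model, drug):
        lo, hi = ranges[drug]
        tr = t.derive_target_range(pop, model, lo, hi, weight_cap=25.0, seed=7)
        return tr.auc_low, tr.auc_high

    for drug in ("isoniazid", "pyrazinamide", "ethionamide"):
        m = models[drug]
        lo, hi = derived(m, drug)
        tgt = panel[drug]
        scale = np.sqrt(lo * hi) / np.sqrt(tgt.auc_low * tgt.auc_high)
        print(f"{drug:13s} cl_typical -> {m.cl_typical * scale:.3f}")

    m = models["rifampicin"]
    tgt = panel["rifampicin"]

    def resid(x):
        vmax, km = np.exp(x)
        lo, hi = derived(replace(m, saturation=Saturation(vmax, km)), "rifampicin")
        return [np.log(lo / tgt.auc_low), np.log(hi / tgt.auc_high)]

    sol = root(resid, np.log([m.saturation.vmax, m.saturation.km]), method="hybr", tol=1e-5)
    vmax, km = np.exp(sol.x)
    print(f"rifampicin    vmax -> {vmax:.1f}, km -> {km:.2f} (converged={sol.success})")


def main():
    models = t.load_drug_models("reference")
    formulary = t.load_formulations()
    pub = t.published_tables()["child_friendly"]
    bands = t.make_weight_bands(models, subjects_per_band=400, seed=5)
    print("== shape (maturation / infant F) fitted to published band medians")
    fit_shape(models, bands, pub, formulary)
    pop = t.generate_population(t.PopulationSpec(subjects_per_band=1000, seed=101))
    print("== scale (clearances) solved against the panel target windows")
    fit_scale(models, pop, t.load_panel_targets())


if __name__ == "__main__":
    main()
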