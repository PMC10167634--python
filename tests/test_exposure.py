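"""Exposure engine: closed form vs ODE oracle, saturation behaviour,
steady-state mass balance, percentile summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import tbmdose as t
from tbmdose.exposure import auc_saturable

from conftest import make_subject


@pytest.mark.parametrize("dose,f,cl,expected", [
    (100, 1.0, 5.0, 20.0),
    (0, 1.0, 5.0, 0.0),
    (200, 0.5, 5.0, 20.0),
])
def test_auc_linear_arithmetic(dose, f, cl, expected):
    assert t.auc_linear(dose, f, cl) == expected


def test_auc_linear_rejects_nonpositive_cl():
    with pytest.raises(ValueError):
        t.auc_linear(100, 1.0, 0.0)


@pytest.mark.parametrize("dose,cl,v,ka", [
    (100, 2.0, 30.0, 1.0),
    (600, 8.0, 50.0, 0.8),
    (1500, 20.0, 90.0, 2.5),
])
def test_ode_matches_closed_form_in_linear_limit(dose, cl, v, ka):
    """With km >> concentrations and vmax/km = CL the ODE reproduces F*D/CL
    within 0.1 % (oracle equivalence)."""
    km = 1e5
    ref = t.auc_linear(dose, 0.9, cl)
    ode = auc_saturable(dose, 0.9, ka, v, cl * km, km)
    assert ode == pytest.approx(ref, rel=1e-3)


def test_batch_integrator_matches_scalar_oracle():
    """Vectorized RK4 agrees with the adaptive scalar integrator in the
    saturating regime."""
    rng = np.random.default_rng(3)
    n = 12
    dose = rng.uniform(100, 900, n)
    f = rng.uniform(0.5, 1.0, n)
    ka = rng.uniform(0.5, 2.0, n)
    v = rng.uniform(20, 60, n)
    vmax = rng.uniform(50, 400, n)
    km = rng.uniform(2, 40, n)
    batch = t.auc_saturable_batch(dose, f, ka, v, vmax, km)
    scalar = [auc_saturable(*args) for args in zip(dose, f, ka, v, vmax, km)]
    assert np.allclose(batch, scalar, rtol=1e-3)


def test_saturation_dose_doubling_superlinear():
    """Near km the dose-exposure relation is supra-proportional."""
    lo = auc_saturable(300, 1.0, 1.0, 50.0, 100.0, 10.0)
    hi = auc_saturable(600, 1.0, 1.0, 50.0, 100.0, 10.0)
    assert hi / lo > 2.0


def test_zero_dose_gives_zero_auc():
    assert auc_saturable(0, 1.0, 1.0, 50.0, 100.0, 10.0) == 0.0
    assert t.auc_saturable_batch([0.0, 100.0], 1.0, 1.0, 50.0, 100.0, 10.0)[0] == 0.0


def test_auc_strictly_monotone_in_dose():
    doses = np.linspace(50, 2000, 12)
    aucs = [auc_saturable(d, 0.9, 1.0, 42.0, 400.0, 20.0) for d in doses]
    assert np.all(np.diff(aucs) > 0)


def test_steady_state_mass_balance():
    """At steady state the amount eliminated per interval equals F * dose."""
    dose, f = 450.0, 0.85
    _, info = auc_saturable(dose, f, 1.2, 40.0, 300.0, 15.0,
                            rel_tol=1e-6, full_output=True)
    assert info["eliminated_last"] == pytest.approx(f * dose, rel=1e-4)


def test_simulate_exposures_hand_computed(toy_models):
    """One subject, BSV=0, linear model: AUC == F*dose/CL."""
    subj = make_subject(weight=20, height=110, age=5.0)
    pop = t.Population(pd.DataFrame([{
        "id": 0, "weight_kg": subj.weight, "age_years": subj.age,
        "pma_weeks": subj.postmenstrual_age, "height_cm": subj.height,
        "sex": subj.sex, "ffm_kg": subj.fat_free_mass, "nat2": subj.nat2,
        "under_3_months": False,
    }]))
    model = toy_models["pyrazinamide"]
    res = t.simulate_exposures(pop, model, 800.0)
    pk = t.individual_parameters(subj, model)
    assert res.auc_mg_h_per_L[0] == pytest.approx(pk.f * 800.0 / pk.cl, rel=1e-12)


def test_simulate_exposures_deterministic(small_pop, toy_models):
    a = t.simulate_exposures(small_pop, toy_models["rifampicin"], 150.0, seed=4)
    b = t.simulate_exposures(small_pop, toy_models["rifampicin"], 150.0, seed=4)
    assert a.equals(b)


def test_allometric_cancellation(small_pop, toy_models):
    """dose ∝ weight^0.75 with no maturation and BSV=0 gives weight-invariant
    AUC (the allometric consequence behind mg/kg underdosing)."""
    model = toy_models["pyrazinamide"]
    w = small_pop.df.weight_kg.to_numpy()
    doses = 100.0 * (w / 70.0) ** 0.75
    res = t.simulate_exposures(small_pop, model, doses)
    assert np.allclose(res.auc_mg_h_per_L, res.auc_mg_h_per_L.iloc[0], rtol=1e-12)


def test_mgkg_dosing_underexposes_small_children(small_pop, toy_models):
    """At equal mg/kg, simulated AUC decreases with decreasing weight for a
    linear drug in mature children (BSV=0)."""
    model = toy_models["pyrazinamide"]
    w = small_pop.df.weight_kg.to_numpy()
    res = t.simulate_exposures(small_pop, model, 30.0 * w)
    order = np.argsort(w)
    auc_sorted = res.auc_mg_h_per_L.to_numpy()[order]
    assert auc_sorted[0] < auc_sorted[-1]
    assert np.corrcoef(w, res.auc_mg_h_per_L)[0, 1] > 0.99


def test_summarize_percentiles():
    df = pd.DataFrame({
        "band": ["a"] * 100 + ["b"] * 3,
        "auc_mg_h_per_L": list(range(1, 101)) + [7.0, 7.0, 7.0],
    })
    out = t.summarize(df, "band").set_index("band")
    assert out.loc["a", "p50"] == pytest.approx(50.5)  # linear interpolation
    assert out.loc["a", "p5"] == pytest.approx(np.percentile(range(1, 101), 5))
    # identical values collapse every percentile
    assert (out.loc["b", ["p5", "p25", "p50", "p75", "p95"]] == 7.0).all()
    # percentiles nondecreasing
    for _, r in out.iterrows():
        assert r.p5 <= r.p25 <= r.p50 <= r.p75 <= r.p95
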