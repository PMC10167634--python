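"""Structural and covariate model components: allometry, maturation,
bioavailability, NAT2, DDI, and parameter-set loading."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tbmdose as t
from tbmdose.drug_models import Saturation, _parse_model

from conftest import make_subject


@pytest.mark.parametrize("size,ref,exp,expected", [
    (70, 70, 0.75, 1.0),
    (35, 70, 1.0, 0.5),
    (8.75, 70, 0.75, 0.2102),
])
def test_allometric_factor_values(size, ref, exp, expected):
    assert t.allometric_factor(size, ref, exp) == pytest.approx(expected, abs=5e-5)


def test_allometric_factor_rejects_nonpositive():
    with pytest.raises(ValueError):
        t.allometric_factor(-1, 70, 0.75)
    with pytest.raises(ValueError):
        t.allometric_factor(10, 0, 0.75)


def test_maturation_midpoint_and_plateau():
    assert t.maturation_factor(50.0, 50.0, 3.0) == pytest.approx(0.5)
    assert t.maturation_factor(500.0, 50.0, 3.0) == pytest.approx(1000 / 1001, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(pma=st.floats(20, 500), delta=st.floats(1, 100),
       tm50=st.floats(30, 80), hill=st.floats(1, 5))
def test_maturation_monotone_in_pma(pma, delta, tm50, hill):
    assert t.maturation_factor(pma, tm50, hill) < t.maturation_factor(pma + delta, tm50, hill)


def test_bioavailability_age_effect(toy_models, ref_models):
    rif = ref_models["rifampicin"]
    assert t.bioavailability(0.1, rif) <= t.bioavailability(5.0, rif)
    # at/after the plateau age F equals f_typical
    plateau = rif.age_on_f.plateau_years
    assert t.bioavailability(plateau, rif) == pytest.approx(rif.f_typical)
    assert t.bioavailability(plateau + 3, rif) == pytest.approx(rif.f_typical)
    # no age effect -> constant F
    pza = toy_models["pyrazinamide"]
    ages = np.array([0.0, 0.5, 2.0, 10.0])
    assert np.allclose(t.bioavailability(ages, pza), pza.f_typical)


def test_individual_cl_at_reference_is_typical(toy_models, reference_adult):
    """BSV=0, reference size, no maturation, fast NAT2 -> CL == cl_typical."""
    inh = toy_models["isoniazid"]
    pk = t.individual_parameters(reference_adult, inh)
    assert pk.cl == pytest.approx(inh.cl_typical, rel=1e-12)
    assert pk.v == pytest.approx(inh.v_typical, rel=1e-12)


def test_nat2_slow_to_fast_clearance_ratio(toy_models):
    inh = toy_models["isoniazid"]
    slow = t.individual_parameters(make_subject(nat2="slow"), inh)
    fast = t.individual_parameters(make_subject(nat2="fast"), inh)
    inter = t.individual_parameters(make_subject(nat2="intermediate"), inh)
    assert slow.cl / fast.cl == pytest.approx(0.5, rel=1e-12)
    # intermediate sits at the geometric mean of slow and fast
    assert inter.cl == pytest.approx(np.sqrt(slow.cl * fast.cl), rel=1e-6)


def test_missing_nat2_raises(toy_models):
    subj = make_subject(nat2=None)
    with pytest.raises(ValueError, match="NAT2"):
        t.individual_parameters(subj, toy_models["isoniazid"])


def test_ddi_multiplier_applies_only_with_rifampicin(toy_models, reference_adult):
    eto = toy_models["ethionamide"]
    alone = t.individual_parameters(reference_adult, eto, coadministered_rifampicin=False)
    combo = t.individual_parameters(reference_adult, eto, coadministered_rifampicin=True)
    assert combo.cl / alone.cl == pytest.approx(eto.ddi_cl_multiplier, rel=1e-12)


def test_parameters_deterministic_given_covariates(toy_models, small_pop):
    """With BSV=0 the parameter frame is a pure function of the subjects."""
    f1 = t.individual_parameters_frame(small_pop, toy_models["pyrazinamide"], seed=1)
    f2 = t.individual_parameters_frame(small_pop, toy_models["pyrazinamide"], seed=99)
    assert f1.equals(f2)


def test_bsv_lognormal_on_cl(small_pop, toy_models):
    noisy = dataclasses.replace(toy_models["pyrazinamide"], bsv=t.drug_models.BSV(cl=0.3))
    f1 = t.individual_parameters_frame(small_pop, noisy, seed=5)
    f2 = t.individual_parameters_frame(small_pop, noisy, seed=5)
    f3 = t.individual_parameters_frame(small_pop, noisy, seed=6)
    assert f1.equals(f2) and not f1.equals(f3)
    eta = np.log(f1["cl"] / t.individual_parameters_frame(small_pop, toy_models["pyrazinamide"]).cl)
    assert eta.std() == pytest.approx(0.3, rel=0.15)


def test_reference_config_validates(ref_models):
    """The packaged reference set satisfies the model invariants at load."""
    assert set(ref_models) == set(t.DRUGS)
    sat_drugs = [d for d, m in ref_models.items() if m.saturation is not None]
    assert sat_drugs == ["rifampicin"]
    for m in ref_models.values():
        assert m.allometric_exp_cl == 0.75
        assert m.allometric_exp_v == 1.0


def test_loader_rejects_bad_configs():
    with pytest.raises(ValueError, match="missing required"):
        _parse_model("isoniazid", {"f_typical": 1.0})
    base = dict(v_typical=50.0, f_typical=1.0, ka=1.0,
                size_metric="total_weight", reference_size=70.0, cl_typical=10.0)
    bad_nat2 = _parse_model("isoniazid", {
        **base, "nat2_cl_multipliers": {"slow": 0.6, "intermediate": 0.8, "fast": 1.0}})
    with pytest.raises(ValueError, match="half"):
        bad_nat2.validate()
    sat = _parse_model("pyrazinamide", {**base, "saturation": {"vmax": 10, "km": 1}})
    with pytest.raises(ValueError, match="rifampicin"):
        sat.validate(reference_profile=True)


def test_individual_pk_invariants():
    with pytest.raises(ValueError):
        t.IndividualPK(subject_id=0, cl=-1, v=10, f=0.5, ka=1)
    with pytest.raises(ValueError):
        t.IndividualPK(subject_id=0, cl=1, v=10, f=1.5, ka=1)


def test_saturable_model_scales_vmax(toy_models):
    """Vmax carries the allometric/maturation chain; km is size-independent."""
    rif = dataclasses.replace(toy_models["rifampicin"], maturation=None, age_on_f=None)
    big = t.individual_parameters(make_subject(weight=70), rif)
    small = t.individual_parameters(make_subject(weight=35, height=140), rif)
    assert big.km == small.km
    assert small.vmax / big.vmax == pytest.approx(0.5 ** 0.75, rel=1e-9)
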