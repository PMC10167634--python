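import numpy as np
import pytest

import tbmdose as t


@pytest.fixture(scope="session")
def toy_models():
    return t.load_drug_models("toy")


@pytest.fixture(scope="session")
def ref_models():
    return t.load_drug_models("reference")


@pytest.fixture(scope="session")
def panel_targets():
    return t.load_panel_targets()


@pytest.fixture(scope="session")
def formulary():
    return t.load_formulations()


@pytest.fixture(scope="session")
def small_pop():
    spec = t.PopulationSpec(weight_min=3, weight_max=10, subjects_per_band=150, seed=42)
    return t.generate_population(spec)


@pytest.fixture(scope="session")
def published():
    return t.published_tables()


def make_subject(weight=70.0, age=25.0, height=176.0, sex="male", nat2="fast",
                 ffm=None, subject_id=0):
    """Hand-built subject (unconstrained by the growth reference)."""
    if ffm is None:
        ffm = t.fat_free_mass(weight, height, sex)
    return t.Subject(
        id=subject_id, weight=weight, age=age,
        postmenstrual_age=40.0 + age * 52.1775, height=height, sex=sex,
        fat_free_mass=ffm, nat2=nat2, under_3_months=age < 0.25,
    )


@pytest.fixture()
def reference_adult():
    return make_subject()
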