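"""Virtual paediatric population with coherent demographics.

The dose simulations need children whose age, weight, height and sex are
jointly plausible, because the PK models use body size (total weight or
fat-free mass) and postmenstrual age as covariates.  Weights are drawn
uniformly per 1-kg band (the study design), and age is then sampled by
inverting a packaged sex-specific weight-for-age reference: a log-normal
deviation from the median weight-for-age curve is drawn (truncated to the
admissible age window) and the median curve is inverted to obtain the age at
which the subject's weight corresponds to that deviation.  Height follows
from a height-for-age reference conditional on the drawn age.

The growth reference is editable YAML (see ``data/growth_reference.yaml``),
so an alternative reference can be swapped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from . import _data

WEEKS_PER_YEAR = 52.1775
#: Postmenstrual age at birth assumed for every subject (term gestation).
TERM_GESTATION_WEEKS = 40.0

NAT2_CLASSES = ("slow", "intermediate", "fast")

#: Column order of the serialized population CSV.
POPULATION_COLUMNS = [
    "id", "weight_kg", "age_years", "pma_weeks", "height_cm",
    "sex", "ffm_kg", "nat2", "under_3_months",
]


class InfeasibleBandError(ValueError):
    """No plausible age exists for a weight band under the growth reference."""


class GrowthReference:
    """Sex-specific weight-for-age and height-for-age median curves.

    Medians must be strictly increasing with age so the weight-for-age curve
    can be inverted.
    """

    def __init__(self, config: dict):
        self.ages = np.asarray(config["ages_years"], dtype=float)
        self.weight_log_sd = float(config["weight_log_sd"])
        self.height_log_sd = float(config["height_log_sd"])
        self.ffm_equation = config.get("ffm_equation", "al-sallami")
        self._weight = {}
        self._height = {}
        for sex in ("male", "female"):
            w = np.asarray(config[sex]["weight_median_kg"], dtype=float)
            h = np.asarray(config[sex]["height_median_cm"], dtype=float)
            if w.shape != self.ages.shape or h.shape != self.ages.shape:
                raise ValueError(f"growth reference arrays for {sex} do not match ages")
            if np.any(np.diff(w) <= 0) or np.any(np.diff(self.ages) <= 0):
                raise ValueError(f"growth reference medians for {sex} must increase with age")
            self._weight[sex] = w
            self._height[sex] = h

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "GrowthReference":
        if path is None:
            text = _data.read_text("growth_reference.yaml")
        else:
            text = Path(path).read_text()
        return cls(yaml.safe_load(text))

    def median_weight(self, age, sex: str):
        return np.interp(age, self.ages, self._weight[sex])

    def median_height(self, age, sex: str):
        return np.interp(age, self.ages, self._height[sex])

    def age_at_median_weight(self, weight, sex: str):
        """Inverse of the (monotone) weight-for-age median curve."""
        return np.interp(weight, self._weight[sex], self.ages)

    @property
    def age_max(self) -> float:
        return float(self.ages[-1])


class PopulationSpec(BaseModel):
    """Design of the virtual population (study defaults)."""

    weight_min: float = 3.0
    weight_max: float = 35.0
    subjects_per_band: int = 5000
    band_width: float = 1.0
    female_fraction: float = 0.5
    nat2_proportions: tuple[float, float, float] = (0.44, 0.42, 0.14)
    age_min: float = 0.0
    age_max: float = 15.0
    #: subjects heavier than this are never assigned an age below 3 months
    under3m_weight_cap: float = 6.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if not self.weight_min < self.weight_max:
            raise ValueError("weight_min must be < weight_max")
        if self.band_width <= 0:
            raise ValueError("band_width must be > 0")
        if self.subjects_per_band <= 0:
            raise ValueError("subjects_per_band must be > 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if abs(sum(self.nat2_proportions) - 1.0) > 1e-9:
            raise ValueError("nat2_proportions must sum to 1")
        if any(p < 0 for p in self.nat2_proportions):
            raise ValueError("nat2_proportions must be nonnegative")
        return self

    def n_bands(self) -> int:
        return int(round((self.weight_max - self.weight_min) / self.band_width))


@dataclass(frozen=True)
class Subject:
    """One virtual child."""

    id: int
    weight: float           # kg
    age: float              # years
    postmenstrual_age: float  # weeks
    height: float           # cm
    sex: str                # "female" | "male"
    fat_free_mass: float    # kg
    nat2: str | None        # "slow" | "intermediate" | "fast"
    under_3_months: bool


class Population:
    """DataFrame-backed container for the virtual population.

    Columns follow :data:`POPULATION_COLUMNS`.  Iteration and indexing yield
    :class:`Subject` records.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"population frame missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i: int) -> Subject:
        r = self.df.iloc[i]
        return Subject(
            id=int(r["id"]), weight=float(r["weight_kg"]), age=float(r["age_years"]),
            postmenstrual_age=float(r["pma_weeks"]), height=float(r["height_cm"]),
            sex=str(r["sex"]), fat_free_mass=float(r["ffm_kg"]),
            nat2=None if pd.isna(r["nat2"]) else str(r["nat2"]),
            under_3_months=bool(r["under_3_months"]),
        )

    def __iter__(self) -> Iterator[Subject]:
        return (self[i] for i in range(len(self)))

    def subjects(self) -> list[Subject]:
        return list(self)

    def subset(self, mask) -> "Population":
        return Population(self.df.loc[np.asarray(mask)].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df[POPULATION_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Population":
        return cls(pd.read_csv(path))


def fat_free_mass(weight, height_cm, sex, age=None):
    """Fat-free mass (kg) from weight, height and sex.

    Uses the maturation-adjusted paediatric equation (BMI-based, with an
    age-dependent factor) when ``age`` is given; with ``age=None`` the adult
    limit of the same equation is used.  The choice of equation is recorded in
    the growth-reference config; swapping it means replacing this function via
    the ``ffm_equation`` hook.  Tests assert only structural properties
    (0 < FFM < weight, monotone in weight), not specific values.
    """
    weight = np.asarray(weight, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be positive")
    sex_arr = np.asarray(sex)
    male = sex_arr == "male"
    if not np.all(male | (sex_arr == "female")):
        raise ValueError("sex must be 'male' or 'female'")
    bmi = weight / (height_cm / 100.0) ** 2
    base_m = 9270.0 * weight / (6680.0 + 216.0 * bmi)
    base_f = 9270.0 * weight / (8780.0 + 244.0 * bmi)
    if age is None:
        factor_m = 1.0
        factor_f = 1.0
    else:
        age = np.asarray(age, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            factor_m = 0.88 + 0.12 / (1.0 + (np.maximum(age, 1e-9) / 13.4) ** -12.7)
            factor_f = 1.11 - 0.11 / (1.0 + (np.maximum(age, 1e-9) / 7.1) ** -1.1)
    ffm = np.where(male, factor_m * base_m, factor_f * base_f)
    ffm = np.minimum(ffm, 0.99 * weight)  # guard: FFM must stay below weight
    if ffm.ndim == 0:
        return float(ffm)
    return ffm


def _sample_band_frame(
    rng: np.random.Generator,
    growth: GrowthReference,
    weight_low: float,
    weight_high: float,
    n: int,
    female_fraction: float,
    age_lo: float,
    age_hi: float,
    under3m_weight_cap: float,
) -> pd.DataFrame:
    """Sample one weight band; deterministic sex split (females rounded up)."""
    n_female = math.ceil(n * female_fraction) if female_fraction > 0 else 0
    n_female = min(n_female, n)
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    weights = rng.uniform(weight_low, weight_high, size=n)

    sd = growth.weight_log_sd
    ages = np.empty(n)
    band_name = f"[{weight_low:g}, {weight_high:g}) kg"
    for sex in ("female", "male"):
        m = sexes == sex
        if not m.any():
            continue
        w = weights[m]
        lo_age = np.where(w > under3m_weight_cap, np.maximum(age_lo, 0.25), age_lo)
        hi_age = min(age_hi, growth.age_max)
        m_lo = growth.median_weight(lo_age, sex)
        m_hi = growth.median_weight(hi_age, sex)
        # log-deviation bounds (in SD units) implied by the admissible age window
        a = np.maximum(np.log(w / m_hi) / sd, -6.0)
        b = np.minimum(np.log(w / m_lo) / sd, 6.0)
        if np.any(a >= b):
            raise InfeasibleBandError(
                f"no plausible age in [{age_lo:g}, {age_hi:g}] y for weights in band "
                f"{band_name} ({sex}) under the growth reference"
            )
        dev = stats.truncnorm.rvs(a, b, size=w.size, random_state=rng) * sd
        target_median = w / np.exp(dev)
        ages[m] = growth.age_at_median_weight(target_median, sex)

    h_dev = stats.truncnorm.rvs(-3.0, 3.0, size=n, random_state=rng) * growth.height_log_sd
    heights = np.where(
        sexes == "male",
        growth.median_height(ages, "male"),
        growth.median_height(ages, "female"),
    ) * np.exp(h_dev)

    pma = TERM_GESTATION_WEEKS + ages * WEEKS_PER_YEAR
    ffm = fat_free_mass(weights, heights, sexes, age=ages)
    return pd.DataFrame({
        "weight_kg": weights,
        "age_years": ages,
        "pma_weeks": pma,
        "height_cm": heights,
        "sex": sexes,
        "ffm_kg": ffm,
        "under_3_months": ages < 0.25,
    })


def sample_band(
    weight_low: float,
    weight_high: float,
    n: int,
    *,
    seed: int | np.random.Generator = 0,
    female_fraction: float = 0.5,
    nat2_proportions: Sequence[float] = (0.44, 0.42, 0.14),
    age_stratum: str | None = None,
    age_min: float = 0.0,
    age_max: float = 15.0,
    under3m_weight_cap: float = 6.0,
    growth: GrowthReference | None = None,
) -> Population:
    """Sample one weight band, optionally conditioned on an age stratum.

    ``age_stratum`` may be ``"under_3_months"`` or ``"over_3_months"``; the
    dosing tables treat infants below 3 months (immature clearance) as
    separate rows, which requires stratum-conditional sampling.
    """
    growth = growth or GrowthReference.from_yaml()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    age_lo, age_hi = age_min, age_max
    cap = under3m_weight_cap
    if age_stratum == "under_3_months":
        age_hi = min(age_hi, 0.25)
        cap = float("inf")  # the stratum itself constrains age; cap is moot
    elif age_stratum == "over_3_months":
        age_lo = max(age_lo, 0.25)
    elif age_stratum is not None:
        raise ValueError(f"unknown age stratum {age_stratum!r}")
    frame = _sample_band_frame(
        rng, growth, weight_low, weight_high, n, female_fraction,
        age_lo, age_hi, cap,
    )
    frame.insert(0, "id", np.arange(n))
    frame["nat2"] = _draw_nat2(rng, n, nat2_proportions)
    return Population(frame[POPULATION_COLUMNS])


def _draw_nat2(rng: np.random.Generator, n: int, proportions) -> np.ndarray:
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("NAT2 proportions must sum to 1")
    return rng.choice(np.array(NAT2_CLASSES), size=n, p=proportions)


def assign_nat2(population: Population, proportions, seed: int | np.random.Generator = 0) -> Population:
    """Assign NAT2 acetylator classes by independent draws at the given proportions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = population.df.copy()
    df["nat2"] = _draw_nat2(rng, len(df), proportions)
    return Population(df)


def generate_population(spec: PopulationSpec, growth: GrowthReference | None = None) -> Population:
    """Generate the virtual population band by band.

    Exactly ``subjects_per_band`` subjects per band; the sex split per band is
    deterministic (females rounded up).  Fully reproducible for a fixed
    ``spec.seed``.
    """
    growth = growth or GrowthReference.from_yaml()
    rng = np.random.default_rng(spec.seed)
    frames = []
    edges = spec.weight_min + spec.band_width * np.arange(spec.n_bands() + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        frames.append(_sample_band_frame(
            rng, growth, float(lo), float(hi), spec.subjects_per_band,
            spec.female_fraction, spec.age_min, spec.age_max,
            spec.under3m_weight_cap,
        ))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", np.arange(len(df)))
    df["nat2"] = _draw_nat2(rng, len(df), spec.nat2_proportions)
    return Population(df[POPULATION_COLUMNS])
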