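"""Per-drug AUC0-24 target ranges derived from mg/kg dose bounds.

With no established PK-PD target for paediatric TB meningitis, the
acceptable exposure window for each drug is defined operationally: simulate
the population (children up to 25 kg by default, infants under 3 months
excluded) at the lower and upper bound of the panel-endorsed mg/kg dose
range and take the overall median AUC at each bound.  mg/kg doses are exact
here (not rounded to tablet counts): this step translates a dose policy into
an exposure window, against which tablet regimens are scored later.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _data
from .drug_models import DrugModel, individual_parameters_frame
from .exposure import simulate_exposures
from .population import Population

#: Panel-endorsed mg/kg daily dose ranges (drug -> (low, high)).
PANEL_DOSE_RANGES = {
    "rifampicin": (22.5, 30.0),
    "isoniazid": (15.0, 20.0),
    "pyrazinamide": (32.0, 44.0),
    "ethionamide": (16.0, 22.0),
}

DEFAULT_WEIGHT_CAP = 25.0


@dataclass(frozen=True)
class TargetRange:
    drug: str
    dose_low: float    # mg/kg
    dose_high: float   # mg/kg
    auc_low: float     # mg.h/L
    auc_high: float    # mg.h/L
    derivation_population: str = "children <= 25 kg"

    def __post_init__(self):
        if not self.dose_low < self.dose_high:
            raise ValueError("dose_low must be < dose_high")
        if not self.auc_low < self.auc_high:
            raise ValueError("auc_low must be < auc_high")

    def to_dict(self) -> dict:
        return asdict(self)


def panel_dose_ranges() -> dict[str, tuple[float, float]]:
    """The packaged mg/kg dose ranges endorsed for the four drugs."""
    return dict(PANEL_DOSE_RANGES)


def load_panel_targets() -> dict[str, TargetRange]:
    """The packaged exposure targets (the printed per-drug AUC windows)."""
    cfg = json.loads(_data.read_text("panel_targets.json"))
    out = {}
    for drug, t in cfg["targets"].items():
        out[drug] = TargetRange(
            drug=drug, dose_low=t["dose_low_mg_kg"], dose_high=t["dose_high_mg_kg"],
            auc_low=t["auc_low"], auc_high=t["auc_high"],
            derivation_population=cfg["derivation_population"],
        )
    return out


def derive_target_range(
    population: Population,
    model: DrugModel,
    dose_low: float,
    dose_high: float,
    weight_cap: float = DEFAULT_WEIGHT_CAP,
    seed: int | np.random.Generator = 0,
    include_under_3_months: bool = False,
    coadministered_rifampicin: bool = True,
) -> TargetRange:
    """Median-exposure window between two mg/kg dose bounds.

    The same realized random effects are reused at both bounds (common random
    numbers), so for a linear drug the derived window scales exactly with the
    dose bounds up to the single Monte Carlo draw.
    """
    if not dose_low < dose_high:
        raise ValueError("dose_low must be < dose_high")
    mask = population.df["weight_kg"].to_numpy() <= weight_cap
    if not include_under_3_months:
        mask &= ~population.df["under_3_months"].to_numpy().astype(bool)
    sub = population.subset(mask)
    if len(sub) == 0:
        raise ValueError(f"no subjects at or below {weight_cap} kg to derive a target from")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = individual_parameters_frame(sub, model, coadministered_rifampicin, rng)
    weights = sub.df["weight_kg"].to_numpy()
    medians = []
    for mgkg in (dose_low, dose_high):
        res = simulate_exposures(sub, model, mgkg * weights, params=params)
        medians.append(float(np.median(res["auc_mg_h_per_L"])))
    return TargetRange(
        drug=model.drug, dose_low=dose_low, dose_high=dose_high,
        auc_low=medians[0], auc_high=medians[1],
        derivation_population=f"children <= {weight_cap:g} kg",
    )


def derive_all_targets(
    population: Population,
    models: dict[str, DrugModel],
    weight_cap: float = DEFAULT_WEIGHT_CAP,
    seed: int = 0,
    dose_ranges: dict[str, tuple[float, float]] | None = None,
) -> dict[str, TargetRange]:
    """Derive target ranges for every drug at the panel dose bounds."""
    dose_ranges = dose_ranges or panel_dose_ranges()
    ss = np.random.SeedSequence(seed)
    out = {}
    for (drug, (lo, hi)), child in zip(sorted(dose_ranges.items()), ss.spawn(len(dose_ranges))):
        out[drug] = derive_target_range(
            population, models[drug], lo, hi, weight_cap=weight_cap,
            seed=np.random.default_rng(child),
        )
    return out
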