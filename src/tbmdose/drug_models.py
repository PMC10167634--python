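"""Population-PK structural and covariate models for the 6HRZEto drugs.

Each drug is described by a :class:`DrugModel`: a typical clearance and
volume at a reference body size, allometric scaling with fixed exponents
(0.75 on CL, 1 on V), optional sigmoid maturation of clearance on
postmenstrual age, an optional age effect on oral bioavailability, optional
NAT2 acetylator clearance multipliers (isoniazid; slow acetylators have half
the clearance of fast ones), optional Michaelis-Menten (saturable) hepatic
elimination (rifampicin), and an optional clearance multiplier applied when
rifampicin is co-administered (ethionamide).

Parameter sets live in YAML; the loader validates structure and invariants
at load time.  Two sets ship with the package: ``reference`` (calibrated to
the panel exposure targets, see docs/methods.md) and ``toy`` (round numbers
for structural testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _data
from .population import Population, Subject

DRUGS = ("rifampicin", "isoniazid", "pyrazinamide", "ethionamide")
SIZE_METRICS = ("total_weight", "fat_free_mass")


@dataclass(frozen=True)
class Maturation:
    tm50_weeks: float
    hill: float


@dataclass(frozen=True)
class AgeOnF:
    """Linear rise of bioavailability from birth to a plateau age."""
    fraction_at_birth: float
    plateau_years: float


@dataclass(frozen=True)
class Saturation:
    vmax: float  # mg/h at reference size
    km: float    # mg/L


@dataclass(frozen=True)
class BSV:
    """Log-scale between-subject SDs (log-normal random effects)."""
    cl: float = 0.0
    f: float = 0.0


@dataclass(frozen=True)
class DrugModel:
    drug: str
    v_typical: float
    f_typical: float
    ka: float
    size_metric: str
    reference_size: float
    cl_typical: float | None = None
    allometric_exp_cl: float = 0.75
    allometric_exp_v: float = 1.0
    maturation: Maturation | None = None
    age_on_f: AgeOnF | None = None
    nat2_cl_multipliers: dict[str, float] | None = None
    saturation: Saturation | None = None
    ddi_cl_multiplier: float | None = None
    bsv: BSV = field(default_factory=BSV)

    def validate(self, reference_profile: bool = False) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.size_metric not in SIZE_METRICS:
            raise ValueError(f"unknown size metric {self.size_metric!r}")
        if self.saturation is None and (self.cl_typical is None or self.cl_typical <= 0):
            raise ValueError(f"{self.drug}: cl_typical must be positive for linear elimination")
        if self.saturation is not None and (self.saturation.vmax <= 0 or self.saturation.km <= 0):
            raise ValueError(f"{self.drug}: saturation vmax and km must be positive")
        if not 0 < self.f_typical <= 1:
            raise ValueError(f"{self.drug}: f_typical must be in (0, 1]")
        if self.v_typical <= 0 or self.reference_size <= 0 or self.ka <= 0:
            raise ValueError(f"{self.drug}: v_typical, reference_size and ka must be positive")
        if self.nat2_cl_multipliers is not None:
            m = self.nat2_cl_multipliers
            if set(m) != {"slow", "intermediate", "fast"}:
                raise ValueError(f"{self.drug}: NAT2 multipliers must cover slow/intermediate/fast")
            if abs(m["slow"] - 0.5 * m["fast"]) > 1e-9:
                raise ValueError(f"{self.drug}: slow NAT2 multiplier must be half the fast one")
        if reference_profile and self.saturation is not None and self.drug != "rifampicin":
            raise ValueError(f"{self.drug}: saturable elimination is reserved for rifampicin "
                             "in the reference configuration")

    @property
    def cl_low_concentration(self) -> float:
        """Typical clearance in the linear (low-concentration) limit."""
        if self.saturation is not None:
            return self.saturation.vmax / self.saturation.km
        assert self.cl_typical is not None
        return self.cl_typical


@dataclass(frozen=True)
class IndividualPK:
    """Realized per-subject PK parameters used by the exposure engine."""
    subject_id: int
    cl: float   # L/h (low-concentration limit when saturation present)
    v: float    # L
    f: float    # proportion
    ka: float   # 1/h
    vmax: float | None = None  # mg/h, individual (saturable models only)
    km: float | None = None    # mg/L

    def __post_init__(self):
        if self.cl <= 0 or self.v <= 0:
            raise ValueError("cl and v must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")


def allometric_factor(size, reference, exponent):
    """(size / reference) ** exponent; equals 1 at the reference size."""
    size = np.asarray(size, dtype=float)
    if np.any(size <= 0) or reference <= 0:
        raise ValueError("size and reference must be positive")
    out = (size / reference) ** exponent
    return float(out) if out.ndim == 0 else out


def maturation_factor(pma_weeks, tm50_weeks, hill):
    """Sigmoid (Hill) maturation of clearance on postmenstrual age, in (0, 1]."""
    pma = np.asarray(pma_weeks, dtype=float)
    if np.any(pma <= 0):
        raise ValueError("postmenstrual age must be positive")
    out = pma ** hill / (tm50_weeks ** hill + pma ** hill)
    return float(out) if out.ndim == 0 else out


def bioavailability(age, model: DrugModel):
    """Oral bioavailability at a given age (years).

    Rises linearly from ``fraction_at_birth * f_typical`` at birth to
    ``f_typical`` at the plateau age; constant when the model has no age
    effect on F.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be nonnegative")
    if model.age_on_f is None:
        out = np.full_like(age, model.f_typical, dtype=float)
    else:
        a0 = model.age_on_f.fraction_at_birth
        frac = a0 + (1.0 - a0) * np.minimum(age, model.age_on_f.plateau_years) / model.age_on_f.plateau_years
        out = model.f_typical * frac
    return float(out) if out.ndim == 0 else out


def _nat2_multiplier(model: DrugModel, nat2: np.ndarray) -> np.ndarray:
    m = model.nat2_cl_multipliers
    assert m is not None
    mapped = pd.Series(nat2).map(m)
    if mapped.isna().any():
        raise ValueError(f"{model.drug}: every subject needs a NAT2 class (slow/intermediate/fast)")
    return mapped.to_numpy(dtype=float)


def individual_parameters_frame(
    population: Population,
    model: DrugModel,
    coadministered_rifampicin: bool = False,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Vectorized realization of per-subject PK parameters.

    CL_i = CL_typ * (size/ref)^0.75 * maturation(PMA) * NAT2 * DDI * exp(eta);
    V_i scales with exponent 1; for saturable models the same covariate chain
    applies to Vmax and ``cl`` reports the low-concentration limit Vmax_i/Km.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = population.df
    n = len(df)
    size = df["ffm_kg"].to_numpy() if model.size_metric == "fat_free_mass" else df["weight_kg"].to_numpy()

    chain = allometric_factor(size, model.reference_size, model.allometric_exp_cl)
    if model.maturation is not None:
        chain = chain * maturation_factor(
            df["pma_weeks"].to_numpy(), model.maturation.tm50_weeks, model.maturation.hill
        )
    if model.nat2_cl_multipliers is not None:
        chain = chain * _nat2_multiplier(model, df["nat2"].to_numpy())
    if model.ddi_cl_multiplier is not None and coadministered_rifampicin:
        chain = chain * model.ddi_cl_multiplier
    eta_cl = rng.normal(0.0, model.bsv.cl, size=n) if model.bsv.cl > 0 else np.zeros(n)
    chain = chain * np.exp(eta_cl)

    v = model.v_typical * allometric_factor(size, model.reference_size, model.allometric_exp_v)
    f = bioavailability(df["age_years"].to_numpy(), model)
    if model.bsv.f > 0:
        f = np.minimum(f * np.exp(rng.normal(0.0, model.bsv.f, size=n)), 1.0)

    out = pd.DataFrame({
        "subject_id": df["id"].to_numpy(),
        "v": v,
        "f": np.asarray(f, dtype=float),
        "ka": np.full(n, model.ka),
    })
    if model.saturation is not None:
        out["vmax"] = model.saturation.vmax * chain
        out["km"] = np.full(n, model.saturation.km)
        out["cl"] = out["vmax"] / out["km"]
    else:
        out["cl"] = model.cl_typical * chain
        out["vmax"] = np.nan
        out["km"] = np.nan
    return out


def individual_parameters(
    subject: Subject,
    model: DrugModel,
    coadministered_rifampicin: bool = False,
    seed: int | np.random.Generator = 0,
) -> IndividualPK:
    """Per-subject PK parameters (scalar convenience wrapper)."""
    frame = pd.DataFrame([{
        "id": subject.id, "weight_kg": subject.weight, "age_years": subject.age,
        "pma_weeks": subject.postmenstrual_age, "height_cm": subject.height,
        "sex": subject.sex, "ffm_kg": subject.fat_free_mass, "nat2": subject.nat2,
        "under_3_months": subject.under_3_months,
    }])
    row = individual_parameters_frame(Population(frame), model, coadministered_rifampicin, seed).iloc[0]
    sat = model.saturation is not None
    return IndividualPK(
        subject_id=int(row["subject_id"]), cl=float(row["cl"]), v=float(row["v"]),
        f=float(row["f"]), ka=float(row["ka"]),
        vmax=float(row["vmax"]) if sat else None,
        km=float(row["km"]) if sat else None,
    )


def _parse_model(drug: str, cfg: dict) -> DrugModel:
    required = {"v_typical", "f_typical", "ka", "size_metric", "reference_size"}
    missing = required - set(k for k, v in cfg.items() if v is not None)
    if missing:
        raise ValueError(f"{drug}: missing required fields {sorted(missing)}")
    mat = cfg.get("maturation")
    aof = cfg.get("age_on_f")
    sat = cfg.get("saturation")
    bsv = cfg.get("bsv") or {}
    return DrugModel(
        drug=drug,
        cl_typical=cfg.get("cl_typical"),
        v_typical=float(cfg["v_typical"]),
        f_typical=float(cfg["f_typical"]),
        ka=float(cfg["ka"]),
        size_metric=cfg["size_metric"],
        reference_size=float(cfg["reference_size"]),
        allometric_exp_cl=float(cfg.get("allometric_exp_cl", 0.75)),
        allometric_exp_v=float(cfg.get("allometric_exp_v", 1.0)),
        maturation=Maturation(float(mat["tm50_weeks"]), float(mat["hill"])) if mat else None,
        age_on_f=AgeOnF(float(aof["fraction_at_birth"]), float(aof["plateau_years"])) if aof else None,
        nat2_cl_multipliers={k: float(v) for k, v in cfg["nat2_cl_multipliers"].items()}
        if cfg.get("nat2_cl_multipliers") else None,
        saturation=Saturation(float(sat["vmax"]), float(sat["km"])) if sat else None,
        ddi_cl_multiplier=(float(cfg["ddi_cl_multiplier"])
                           if cfg.get("ddi_cl_multiplier") is not None else None),
        bsv=BSV(cl=float(bsv.get("cl", 0.0)), f=float(bsv.get("f", 0.0))),
    )


def load_drug_models(source: str | Path = "reference") -> dict[str, DrugModel]:
    """Load and validate a drug-model parameter set.

    ``source`` is either a packaged set name (``"reference"``, ``"toy"``) or a
    path to a YAML file with the same schema.
    """
    if source in ("reference", "toy"):
        text = _data.read_text(f"drug_models_{source}.yaml")
    else:
        text = Path(source).read_text()
    cfg = yaml.safe_load(text)
    if "drugs" not in cfg:
        raise ValueError("drug model file must contain a top-level 'drugs' mapping")
    reference_profile = cfg.get("profile") == "reference"
    models = {}
    for drug, sub in cfg["drugs"].items():
        model = _parse_model(drug, sub)
        model.validate(reference_profile=reference_profile)
        models[drug] = model
    return models
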