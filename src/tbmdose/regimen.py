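"""Weight-band tablet-count optimization and dosing tables.

This is the computational core behind the dosing tables: per-1-kg-band
median exposure as a function of dose, enumeration of feasible tablet counts
under formulation constraints (whole tablets; halves only for dispersible,
scoreable products; never quarters), deviation scoring against the exposure
targets, merging of adjacent bands with identical counts, and the
fixed-dose-combination substitution calculator.

Tablet arithmetic is exact (``fractions.Fraction``), so half-tablet doses
never accumulate floating error and dose identities between alternative
formulation mixes can be asserted exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import _data
from .drug_models import DRUGS, DrugModel, individual_parameters_frame
from .exposure import auc_saturable_batch
from .population import Population, sample_band, GrowthReference
from .targets import TargetRange

HALF = Fraction(1, 2)


# ---------------------------------------------------------------------------
# formulations


@dataclass(frozen=True)
class Formulation:
    """A tablet product: per-drug mg contents and handling constraints."""

    name: str
    contents: dict[str, int]              # drug -> mg per tablet
    product_class: str                    # "child_friendly" | "adult"
    splittable: str                       # "halves_allowed" | "whole_only"

    def __post_init__(self):
        if not self.contents or any(mg <= 0 for mg in self.contents.values()):
            raise ValueError(f"{self.name}: contents must be nonempty with positive mg")
        if self.product_class not in ("child_friendly", "adult"):
            raise ValueError(f"{self.name}: unknown class {self.product_class!r}")
        if self.splittable not in ("halves_allowed", "whole_only"):
            raise ValueError(f"{self.name}: unknown splittability {self.splittable!r}")


class Formulary:
    """The formulation catalogue plus named selections."""

    def __init__(self, formulations: dict[str, Formulation], selections: dict[str, list[str]]):
        self.formulations = formulations
        self.selections = selections

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "Formulary":
        text = _data.read_text("formulations.yaml") if path is None else Path(path).read_text()
        cfg = yaml.safe_load(text)
        forms = {}
        for f in cfg["formulations"]:
            forms[f["name"]] = Formulation(
                name=f["name"],
                contents={d: int(mg) for d, mg in f["contents"].items()},
                product_class=f["class"],
                splittable=f["splittable"],
            )
        return cls(forms, {k: list(v) for k, v in cfg.get("selections", {}).items()})

    def selection(self, which) -> list[Formulation]:
        """Resolve a named selection or an explicit list of formulation names."""
        names = self.selections[which] if isinstance(which, str) else list(which)
        return [self.formulations[n] for n in names]


def load_formulations(path: str | Path | None = None) -> Formulary:
    return Formulary.from_yaml(path)


# ---------------------------------------------------------------------------
# exact tablet arithmetic


def _as_count(count) -> Fraction:
    c = Fraction(count).limit_denominator(1000)
    if c < 0:
        raise ValueError("tablet counts must be nonnegative")
    if (2 * c).denominator != 1:
        raise ValueError(f"tablet count {count} is not a multiple of 0.5 "
                         "(quarter tablets are never representable)")
    return c


def dose_from_tablets(tablet_counts: dict[str, float], formulary: Formulary | dict) -> dict[str, Fraction]:
    """Per-drug daily dose (mg, exact) delivered by a set of tablet counts."""
    forms = formulary.formulations if isinstance(formulary, Formulary) else formulary
    doses: dict[str, Fraction] = {}
    for name, count in tablet_counts.items():
        c = _as_count(count)
        if c == 0:
            continue
        f = forms[name]
        if c.denominator == 2 and f.splittable != "halves_allowed":
            raise ValueError(f"{name}: half tablets are not allowed for a "
                             f"{f.splittable} formulation")
        for drug, mg in f.contents.items():
            doses[drug] = doses.get(drug, Fraction(0)) + c * mg
    return doses


def tablet_burden(tablet_counts: dict[str, float]) -> int:
    """Number of physical tablets handled per day.

    A half tablet counts as one tablet toward the burden when given alone,
    but halves of the same product combine first: burden is the sum of
    per-formulation counts rounded up (e.g. counts 1.5 + 0.5 + 0.5 give
    2 + 1 + 1 = 4).
    """
    total = 0
    for count in tablet_counts.values():
        c = _as_count(count)
        if c > 0:
            total += math.ceil(c)
    return total


def deviation_from_range(auc: float, target: TargetRange) -> float:
    """Signed percent distance of an exposure from the target window.

    0 inside the window; above: percent relative to the upper bound; below:
    percent (negative) relative to the lower bound.  Unrounded — display
    rounding to one decimal happens at rendering time.
    """
    if target.auc_low <= auc <= target.auc_high:
        return 0.0
    if auc > target.auc_high:
        return 100.0 * (auc - target.auc_high) / target.auc_high
    return 100.0 * (auc - target.auc_low) / target.auc_low


def deviation_status(deviation_pct: float) -> str:
    """Colour semantics: green within, yellow below, purple above the range."""
    if deviation_pct == 0.0:
        return "green"
    return "purple" if deviation_pct > 0 else "yellow"


# ---------------------------------------------------------------------------
# FDC substitution calculator


def find_fdc_substitution(
    target_doses: dict,
    formulations: list[Formulation],
    whole_tablets_only: bool = True,
    max_per_formulation: int = 40,
) -> dict[str, Fraction] | None:
    """Minimal-tablet combination delivering *exactly* the given per-drug doses.

    Used for the FDC-substitution question: e.g. replacing RH + Z single
    tablets by the RHZ FDC with an RH top-up at identical per-drug milligrams.
    Returns the counts, or None when no exact combination exists.
    """
    targets = {d: Fraction(v) for d, v in target_doses.items()}
    order = sorted(formulations, key=lambda f: -len(f.contents))  # FDCs first
    best: dict[str, Fraction] | None = None
    best_total = Fraction(max_per_formulation * len(order) + 1)

    def recurse(idx: int, remaining: dict[str, Fraction], counts: dict[str, Fraction], total: Fraction):
        nonlocal best, best_total
        if total >= best_total:
            return
        if idx == len(order):
            if all(v == 0 for v in remaining.values()):
                best, best_total = dict(counts), total
            return
        f = order[idx]
        step = Fraction(1) if (whole_tablets_only or f.splittable == "whole_only") else HALF
        cap = min(
            (remaining.get(d, Fraction(0)) / mg for d, mg in f.contents.items()),
            default=Fraction(0),
        )
        cap = min(cap, Fraction(max_per_formulation))
        c = (cap // step) * step
        while c >= 0:
            nxt = dict(remaining)
            ok = True
            for d, mg in f.contents.items():
                nxt[d] = nxt.get(d, Fraction(0)) - c * mg
                if nxt[d] < 0:
                    ok = False
                    break
            if ok:
                counts[f.name] = c
                recurse(idx + 1, nxt, counts, total + c)
                del counts[f.name]
            c -= step

    recurse(0, targets, {}, Fraction(0))
    if best is None:
        return None
    return {k: v for k, v in best.items() if v > 0}


# ---------------------------------------------------------------------------
# per-band dose-response


class DoseResponse:
    """Median band AUC0-24 as a monotone function of daily dose (mg).

    For linear elimination the per-subject AUC is dose * F_i/CL_i, so the
    band median is dose * median(F/CL) exactly.  For saturable elimination
    the band median is evaluated by the batch integrator and cached per dose.
    """

    def __init__(
        self,
        band_population: Population,
        model: DrugModel,
        seed: int | np.random.Generator = 0,
        coadministered_rifampicin: bool = True,
    ):
        self.model = model
        self.population = band_population
        self.params = individual_parameters_frame(
            band_population, model, coadministered_rifampicin, seed
        )
        f = self.params["f"].to_numpy()
        cl = self.params["cl"].to_numpy()  # low-concentration limit if saturable
        self._linear_ratio = float(np.median(f / cl))
        self._cache: dict[float, float] = {}
        if model.saturation is not None:
            # steady state only exists while absorbed amount stays below the
            # daily Michaelis-Menten elimination capacity; keep a margin so
            # convergence stays fast for every subject in the band
            vmax = self.params["vmax"].to_numpy()
            self.max_feasible_dose = float(0.8 * 24.0 * np.min(vmax / f))
        else:
            self.max_feasible_dose = float("inf")

    @property
    def saturable(self) -> bool:
        return self.model.saturation is not None

    def median_auc(self, dose: float) -> float:
        dose = float(dose)
        if dose < 0:
            raise ValueError("dose must be nonnegative")
        if not self.saturable:
            return self._linear_ratio * dose
        if dose not in self._cache:
            auc = auc_saturable_batch(
                dose, self.params["f"].to_numpy(), self.params["ka"].to_numpy(),
                self.params["v"].to_numpy(), self.params["vmax"].to_numpy(),
                self.params["km"].to_numpy(),
            )
            self._cache[dose] = float(np.median(auc))
        return self._cache[dose]

    def dose_for_auc(self, auc: float) -> float:
        """Inverse of the monotone median dose-exposure map."""
        if auc <= 0:
            raise ValueError("target AUC must be positive")
        d_lin = auc / self._linear_ratio
        if not self.saturable:
            return d_lin
        # saturation means the true dose is at most the linear-limit estimate
        lo, hi = 1e-6 * d_lin, min(1.05 * d_lin, self.max_feasible_dose)
        g = lambda d: self.median_auc(d) - auc
        if g(hi) < 0:  # pathological: even the linear estimate undershoots
            raise RuntimeError(f"{self.model.drug}: no dose up to {hi:.0f} mg reaches AUC {auc}")
        return float(brentq(g, lo, hi, xtol=1e-3 * d_lin, rtol=1e-4))

    def auc_per_subject(self, dose: float) -> np.ndarray:
        if not self.saturable:
            return dose * self.params["f"].to_numpy() / self.params["cl"].to_numpy()
        return auc_saturable_batch(
            float(dose), self.params["f"].to_numpy(), self.params["ka"].to_numpy(),
            self.params["v"].to_numpy(), self.params["vmax"].to_numpy(),
            self.params["km"].to_numpy(),
        )


def estimate_band_doses(
    band_population: Population,
    model: DrugModel,
    target: TargetRange,
    seed: int | np.random.Generator = 0,
    coadministered_rifampicin: bool = True,
) -> tuple[float, float]:
    """Continuous dose interval (mg) whose band median AUC spans the target."""
    dr = DoseResponse(band_population, model, seed, coadministered_rifampicin)
    return dr.dose_for_auc(target.auc_low), dr.dose_for_auc(target.auc_high)


# ---------------------------------------------------------------------------
# band contexts and regimen search


@dataclass
class WeightBand:
    """One 1-kg band of one age stratum, with its dose-response per drug."""

    weight_low: float
    weight_high: float
    age_stratum: str                       # "under_3_months" | "over_3_months"
    dose_response: dict[str, DoseResponse]

    @property
    def label(self) -> str:
        return f"{self.weight_low:g}-{self.weight_high:g} kg ({self.age_stratum})"


@dataclass(frozen=True)
class BandRegimen:
    """Tablet counts for one (possibly merged) display weight band."""

    weight_low: float
    weight_high: float
    age_stratum: str
    tablet_counts: dict[str, float]
    per_drug_dose: dict[str, float]        # mg
    tablet_burden: int
    all_within_target: bool = True


@dataclass
class SearchOptions:
    """Knobs of the band search; defaults formalize the published trade-offs."""

    #: |deviation| (percent) still counted as on-target during the search
    dev_tolerance: float = 1e-6
    #: fallback merging: a band may join its run while its worst deviation
    #: stays within this many percentage points of the run's first band
    merge_slack: float = 8.0
    #: drugs for which an above-range exposure disqualifies a candidate
    #: (the panel preferred isoniazid-below over rifampicin-above for the
    #: adult-formulation tables)
    forbid_above: tuple[str, ...] = ()
    #: enumeration window: counts dosing any drug above this multiple of the
    #: dose achieving the upper AUC bound are not considered
    max_dose_factor: float = 1.5


def make_weight_bands(
    models: dict[str, DrugModel],
    weight_min: float = 3.0,
    weight_max: float = 35.0,
    subjects_per_band: int = 500,
    seed: int = 0,
    under3m_max_weight: float = 5.0,
    growth: GrowthReference | None = None,
    nat2_proportions=(0.44, 0.42, 0.14),
    female_fraction: float = 0.5,
) -> list[WeightBand]:
    """Build per-1-kg band populations (under-3-month strata first) and their
    dose-responses.  Seeding is per band and drug, so bands are independent of
    how many other bands are built."""
    growth = growth or GrowthReference.from_yaml()
    bands: list[WeightBand] = []
    edges = np.arange(weight_min, weight_max + 0.5, 1.0)
    specs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= under3m_max_weight:
            specs.append((float(lo), float(hi), "under_3_months"))
    for lo, hi in zip(edges[:-1], edges[1:]):
        specs.append((float(lo), float(hi), "over_3_months"))

    root = np.random.SeedSequence(seed)
    for (lo, hi, stratum), band_ss in zip(specs, root.spawn(len(specs))):
        pop_ss, *drug_ss = band_ss.spawn(1 + len(models))
        pop = sample_band(
            lo, hi, subjects_per_band,
            seed=np.random.default_rng(pop_ss),
            female_fraction=female_fraction,
            nat2_proportions=nat2_proportions,
            age_stratum=stratum,
            growth=growth,
        )
        dr = {
            drug: DoseResponse(pop, models[drug], seed=np.random.default_rng(ss))
            for (drug, ss) in zip(sorted(models), drug_ss)
        }
        bands.append(WeightBand(lo, hi, stratum, dr))
    return bands


@dataclass
class _Component:
    """Connected set of formulations sharing drugs; searched independently."""

    formulations: list[Formulation]
    drugs: list[str] = field(default_factory=list)

    def __post_init__(self):
        drugs = set()
        for f in self.formulations:
            drugs |= set(f.contents)
        self.drugs = sorted(drugs)


def _components(formulations: list[Formulation]) -> list[_Component]:
    remaining = list(formulations)
    comps = []
    while remaining:
        group = [remaining.pop(0)]
        drugs = set(group[0].contents)
        changed = True
        while changed:
            changed = False
            for f in list(remaining):
                if drugs & set(f.contents):
                    group.append(f)
                    drugs |= set(f.contents)
                    remaining.remove(f)
                    changed = True
        comps.append(_Component(group))
    return comps


def _count_options(form: Formulation, max_count: float) -> list[Fraction]:
    step = HALF if form.splittable == "halves_allowed" else Fraction(1)
    out = [Fraction(0)]
    c = step
    while c <= max_count:
        out.append(c)
        c += step
    return out


def _candidate_vectors(band: WeightBand, comp: _Component, targets, options: SearchOptions):
    """Enumerate count vectors for one component in one band.

    Only drugs with a target are scored; a co-formulated drug without a
    target does not constrain the counts.
    """
    scored = [d for d in comp.drugs if d in targets]
    window_hi = {}
    for drug in scored:
        dr = band.dose_response[drug]
        d_hi = targets[drug].auc_high / dr._linear_ratio  # linear-limit bound (>= true dose)
        window_hi[drug] = min(d_hi * options.max_dose_factor, dr.max_feasible_dose)
    per_form = []
    for f in comp.formulations:
        caps = [window_hi[d] / mg for d, mg in f.contents.items() if d in window_hi]
        per_form.append(_count_options(f, min(caps)))
    vectors = []
    for combo in itertools.product(*per_form):
        doses = {}
        for f, c in zip(comp.formulations, combo):
            for d, mg in f.contents.items():
                doses[d] = doses.get(d, 0.0) + float(c) * mg
        if any(doses.get(d, 0.0) <= 0 for d in scored):
            continue
        if any(doses[d] > window_hi[d] for d in scored):
            continue
        vectors.append((combo, doses))
    if not vectors:
        # best effort: even the smallest administrable counts overshoot the
        # window, so offer them anyway; the caller flags the band off-target
        combo = tuple(
            (HALF if f.splittable == "halves_allowed" else Fraction(1))
            if any(d in scored for d in f.contents) else Fraction(0)
            for f in comp.formulations
        )
        doses = {}
        for f, c in zip(comp.formulations, combo):
            for d, mg in f.contents.items():
                doses[d] = doses.get(d, 0.0) + float(c) * mg
        vectors.append((combo, doses))
    return vectors


_FORBID_PENALTY = 1e6


def _worst(band: WeightBand, comp: _Component, doses, targets, options: SearchOptions) -> float:
    worst = 0.0
    for drug in (d for d in comp.drugs if d in targets):
        auc = band.dose_response[drug].median_auc(doses[drug])
        dev = deviation_from_range(auc, targets[drug])
        mag = abs(dev)
        if dev > options.dev_tolerance and drug in options.forbid_above:
            mag += _FORBID_PENALTY
        worst = max(worst, mag)
    return worst


def _n_halves(combo) -> int:
    return sum(1 for c in combo if c.denominator == 2)


def _combo_burden(combo) -> int:
    return sum(math.ceil(c) for c in combo if c > 0)


def _greedy_component(bands: list[WeightBand], comp: _Component, targets, options: SearchOptions):
    """Greedy left-to-right maximal-run search for one component.

    At each band, prefer the count vector that stays fully on-target for the
    longest stretch of consecutive bands (ties: whole tablets over halves,
    lower burden, lexicographic counts).  When no vector is on-target, fall
    back to the minimax-deviation vector and let it run while its worst
    deviation stays within ``merge_slack`` of its value at the run start.
    """
    n = len(bands)
    chosen = [None] * n
    on_target = [True] * n
    has_on_target_cache: dict[int, bool] = {}

    def has_on_target(j: int) -> bool:
        if j not in has_on_target_cache:
            vecs = _candidate_vectors(bands[j], comp, targets, options)
            has_on_target_cache[j] = any(
                _worst(bands[j], comp, d, targets, options) <= options.dev_tolerance
                for _, d in vecs)
        return has_on_target_cache[j]

    i = 0
    while i < n:
        vectors = _candidate_vectors(bands[i], comp, targets, options)
        scored = [(combo, doses, _worst(bands[i], comp, doses, targets, options))
                  for combo, doses in vectors]
        within = [(combo, doses) for combo, doses, w in scored if w <= options.dev_tolerance]
        if within:
            best = None
            for combo, doses in within:
                run = 1
                while i + run < n and _worst(bands[i + run], comp, doses, targets, options) <= options.dev_tolerance:
                    run += 1
                key = (-run, _n_halves(combo), _combo_burden(combo), combo)
                if best is None or key < best[0]:
                    best = (key, combo, doses, run, True)
        else:
            best = None
            for combo, doses, w in scored:
                key = (w, _n_halves(combo), _combo_burden(combo), combo)
                if best is None or key < best[0]:
                    best = (key, combo, doses, 1, False)
            # extend the fallback run under the merge-slack heuristic
            _, combo, doses, _, _ = best
            w0 = best[0][0]
            run = 1
            while i + run < n:
                wj = _worst(bands[i + run], comp, doses, targets, options)
                if wj > min(w0, _FORBID_PENALTY - 1) + options.merge_slack:
                    break
                # never swallow a band that could be dosed on-target by a
                # different count vector
                if wj > options.dev_tolerance and has_on_target(i + run):
                    break
                run += 1
            best = (best[0], combo, doses, run, False)
        _, combo, doses, run, ok = best
        for j in range(i, i + run):
            chosen[j] = combo
            on_target[j] = on_target[j] and ok
        i += run
    return chosen, on_target


def search_regimen(
    bands: list[WeightBand],
    formulations: list[Formulation],
    targets: dict[str, TargetRange],
    options: SearchOptions | None = None,
) -> list[BandRegimen]:
    """Optimize tablet counts over a sequence of 1-kg bands and merge.

    Strata are searched independently; within a stratum, each connected group
    of formulations (e.g. the RH FDC vs the single-drug tablets) is searched
    independently since their deviations do not interact.  Adjacent 1-kg
    bands with identical full count vectors are merged for display — merging
    is a pure grouping and never changes any dose.
    """
    options = options or SearchOptions()
    covered = set()
    for f in formulations:
        covered |= set(f.contents)
    missing = [d for d in targets if d not in covered]
    if missing:
        raise ValueError(f"formulation selection covers no product for: {missing}")

    comps = [c for c in _components(formulations) if any(d in targets for d in c.drugs)]
    regimens: list[BandRegimen] = []
    for stratum in ("under_3_months", "over_3_months"):
        sbands = [b for b in bands if b.age_stratum == stratum]
        if not sbands:
            continue
        per_comp = [_greedy_component(sbands, comp, targets, options) for comp in comps]
        counts_by_band = []
        ok_by_band = []
        for j in range(len(sbands)):
            counts = {}
            ok = True
            for comp, (chosen, on_target) in zip(comps, per_comp):
                for f, c in zip(comp.formulations, chosen[j]):
                    if c > 0:
                        counts[f.name] = float(c)
                ok = ok and on_target[j]
            counts_by_band.append(counts)
            ok_by_band.append(ok)
        regimens.extend(merge_bands(sbands, counts_by_band, ok_by_band, formulations))
    return regimens


def merge_bands(
    sbands: list[WeightBand],
    counts_by_band: list[dict[str, float]],
    ok_by_band: list[bool],
    formulations: list[Formulation],
) -> list[BandRegimen]:
    """Group adjacent 1-kg bands with identical tablet counts into display bands."""
    formulary = {f.name: f for f in formulations}
    out: list[BandRegimen] = []
    i = 0
    while i < len(sbands):
        j = i
        while (j + 1 < len(sbands)
               and counts_by_band[j + 1] == counts_by_band[i]
               and sbands[j + 1].weight_low == sbands[j].weight_high):
            j += 1
        counts = counts_by_band[i]
        doses = {d: float(v) for d, v in dose_from_tablets(counts, formulary).items()}
        out.append(BandRegimen(
            weight_low=sbands[i].weight_low,
            weight_high=sbands[j].weight_high,
            age_stratum=sbands[i].age_stratum,
            tablet_counts=dict(counts),
            per_drug_dose=doses,
            tablet_burden=tablet_burden(counts),
            all_within_target=all(ok_by_band[i:j + 1]),
        ))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# dosing-table assembly


def build_dosing_table(
    bands: list[WeightBand],
    formulations: list[Formulation],
    targets: dict[str, TargetRange],
    options: SearchOptions | None = None,
) -> tuple[pd.DataFrame, list[BandRegimen]]:
    """Search the regimen and report per-1-kg-band simulated exposures.

    Returns the table (one row per 1-kg band, formulation counts, burden,
    per-drug simulated median AUC, signed percent deviation and colour
    status) plus the merged display regimens.
    """
    regimens = search_regimen(bands, formulations, targets, options)
    form_names = [f.name for f in formulations]
    by_key = {}
    for r in regimens:
        for b in bands:
            if (b.age_stratum == r.age_stratum
                    and b.weight_low >= r.weight_low - 1e-9
                    and b.weight_high <= r.weight_high + 1e-9):
                by_key[(b.age_stratum, b.weight_low)] = r
    rows = []
    for b in bands:
        r = by_key[(b.age_stratum, b.weight_low)]
        row = {
            "weight_low": b.weight_low, "weight_high": b.weight_high,
            "stratum": b.age_stratum, "display_band": f"{r.weight_low:g}-{r.weight_high:g}",
        }
        for name in form_names:
            row[name] = r.tablet_counts.get(name, 0.0)
        row["burden"] = r.tablet_burden
        for drug in sorted(targets):
            dose = r.per_drug_dose.get(drug, 0.0)
            auc = b.dose_response[drug].median_auc(dose)
            dev = deviation_from_range(auc, targets[drug])
            row[f"dose_{drug}"] = dose
            row[f"auc_{drug}"] = auc
            row[f"dev_{drug}"] = dev
            row[f"status_{drug}"] = deviation_status(dev)
        rows.append(row)
    order = {"under_3_months": 0, "over_3_months": 1}
    rows.sort(key=lambda r: (order[r["stratum"]], r["weight_low"]))
    return pd.DataFrame(rows), regimens


def _display_auc(drug: str, auc: float) -> str:
    if drug == "pyrazinamide":  # three significant figures
        return f"{float(f'{auc:.3g}'):g}"
    return f"{auc:.1f}"


def format_markdown(table: pd.DataFrame, form_names: list[str], drugs=DRUGS) -> str:
    """Render a dosing table as Markdown with the display rounding rules
    (AUC to one decimal, pyrazinamide to three significant figures,
    deviations to one decimal)."""
    head = (["Weight band (kg)", "Stratum"] + form_names + ["Tablet burden"]
            + [f"{d} AUC (mg·h/L)" for d in drugs] + [f"{d} dev (%)" for d in drugs])
    lines = ["| " + " | ".join(head) + " |",
             "|" + "|".join(["---"] * len(head)) + "|"]
    for _, r in table.iterrows():
        cells = [f"{r['weight_low']:g}-{r['weight_high']:g}", r["stratum"]]
        cells += [f"{r[n]:g}" for n in form_names]
        cells += [str(int(r["burden"]))]
        cells += [_display_auc(d, r[f"auc_{d}"]) for d in drugs]
        cells += [f"{r[f'dev_{d}']:+.1f}" if r[f"dev_{d}"] != 0 else "0.0" for d in drugs]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
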