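"""End-to-end pipeline runs, reproducibility manifest, and table audits.

``run_pipeline`` chains the stages (population → PK models → targets →
band search → dosing table → exposure summaries) and writes every artifact
plus a manifest (config echo, seeds, package version, SHA-256 of each
output), so a run can be replayed and compared byte for byte.

``recheck_printed_tables`` re-derives every percent-deviation and
tablet-burden cell of the packaged copies of the published dosing tables
from the printed AUCs/counts and the packaged target bounds — an arithmetic
audit that is independent of any PK model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__, _data
from .drug_models import DRUGS, load_drug_models
from .exposure import PERCENTILES
from .population import PopulationSpec, generate_population
from .regimen import (
    SearchOptions, build_dosing_table, deviation_from_range, format_markdown,
    load_formulations, make_weight_bands, tablet_burden,
)
from .targets import TargetRange, derive_all_targets, load_panel_targets

log = logging.getLogger("tbmdose")

PUBLISHED_TABLES = {
    "child_friendly": "published_child_friendly.csv",
    "adult_z400": "published_adult_z400.csv",
    "adult_z500": "published_adult_z500.csv",
}

_RESERVED = {"weight_low", "weight_high", "stratum", "burden"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """Configuration of a full pipeline run."""

    seed: int = 1
    out_dir: str = "tbmdose_run"
    model_set: str = "reference"
    formulation_set: str | list[str] = "child"
    target_source: str = "packaged"          # "packaged" | "derive"
    weight_min: float = 3.0
    weight_max: float = 35.0
    #: subjects per 1-kg band for the dosing-table simulations
    band_subjects: int = 500
    #: subjects per 1-kg band for target derivation (when target_source=derive)
    derive_subjects_per_band: int = 1000
    target_weight_cap: float = 25.0
    under3m_max_weight: float = 5.0
    nat2_proportions: tuple[float, float, float] = (0.44, 0.42, 0.14)
    female_fraction: float = 0.5
    #: drugs whose above-range exposure disqualifies a candidate regimen;
    #: None selects the panel convention (rifampicin for adult formulations)
    forbid_above: list[str] | None = None
    #: also write subject-level exposure results (one row per subject x drug)
    export_subject_exposures: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def published_tables() -> dict[str, pd.DataFrame]:
    """Packaged transcriptions of the published dosing tables."""
    return {name: pd.read_csv(_data.path("tables", fn)) for name, fn in PUBLISHED_TABLES.items()}


def recheck_printed_tables(targets: dict[str, TargetRange] | None = None) -> tuple[pd.DataFrame, dict]:
    """Audit every deviation and burden cell of the published tables.

    Deviations are recomputed from the *printed* (rounded) AUCs, so a handful
    of cells differ by one unit in the last decimal from the published values
    (which were computed from unrounded exposures); the audit reports these
    as mismatches rather than hiding them.
    """
    targets = targets or load_panel_targets()
    cells = []
    burden_rows = []
    for tname, df in published_tables().items():
        form_cols = [c for c in df.columns
                     if c not in _RESERVED and not c.startswith(("auc_", "dev_"))]
        for _, row in df.iterrows():
            counts = {c: row[c] for c in form_cols if row[c] > 0}
            burden_rows.append({
                "table": tname, "weight_low": row["weight_low"], "stratum": row["stratum"],
                "printed_burden": int(row["burden"]),
                "recomputed_burden": tablet_burden(counts),
            })
            for drug in DRUGS:
                dev = deviation_from_range(float(row[f"auc_{drug}"]), targets[drug])
                cells.append({
                    "table": tname, "weight_low": row["weight_low"],
                    "weight_high": row["weight_high"], "stratum": row["stratum"],
                    "drug": drug,
                    "printed_auc": float(row[f"auc_{drug}"]),
                    "printed_dev": float(row[f"dev_{drug}"]),
                    "recomputed_dev": round(dev, 1),
                })
    cell_df = pd.DataFrame(cells)
    cell_df["match"] = np.isclose(cell_df["printed_dev"], cell_df["recomputed_dev"], atol=0.051)
    burden_df = pd.DataFrame(burden_rows)
    burden_df["match"] = burden_df["printed_burden"] == burden_df["recomputed_burden"]
    report = cell_df.merge(burden_df, how="left", on=["table", "weight_low", "stratum"],
                           suffixes=("", "_burden"))
    summary = {
        "n_cells": int(len(cell_df)),
        "n_dev_match": int(cell_df["match"].sum()),
        "dev_match_fraction": float(cell_df["match"].mean()),
        "n_burden_rows": int(len(burden_df)),
        "n_burden_match": int(burden_df["match"].sum()),
        "burden_all_match": bool(burden_df["match"].all()),
    }
    return report, summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    ss = np.random.SeedSequence(config.seed)
    seed_pop, seed_targets, seed_bands = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    def stage(name):
        log.info("stage %s (seed=%d)", name, config.seed)

    try:
        stage("population")
        spec = PopulationSpec(
            weight_min=config.weight_min, weight_max=config.weight_max,
            subjects_per_band=config.band_subjects,
            female_fraction=config.female_fraction,
            nat2_proportions=config.nat2_proportions, seed=seed_pop,
        )
        population = generate_population(spec)
        artifacts["population"] = out / "population.csv"
        population.to_csv(artifacts["population"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("population", str(e)) from e

    try:
        stage("drug_models")
        models = load_drug_models(config.model_set)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("drug_models", str(e)) from e

    try:
        stage("targets")
        if config.target_source == "packaged":
            targets = load_panel_targets()
        elif config.target_source == "derive":
            dspec = spec.model_copy(update={
                "subjects_per_band": config.derive_subjects_per_band, "seed": seed_targets,
            })
            dpop = generate_population(dspec)
            targets = derive_all_targets(dpop, models, weight_cap=config.target_weight_cap,
                                         seed=seed_targets)
        else:
            raise ValueError(f"unknown target_source {config.target_source!r}")
        artifacts["targets"] = out / "targets.json"
        artifacts["targets"].write_text(json.dumps(
            {d: t.to_dict() for d, t in sorted(targets.items())}, indent=2) + "\n")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("targets", str(e)) from e

    try:
        stage("regimen")
        formulary = load_formulations()
        selected = formulary.selection(config.formulation_set)
        forbid = config.forbid_above
        if forbid is None:
            adult = any(f.product_class == "adult" for f in selected)
            forbid = ["rifampicin"] if adult else []
        options = SearchOptions(forbid_above=tuple(forbid))
        lo = config.weight_min
        hi = config.weight_max
        if isinstance(config.formulation_set, str) and config.formulation_set.startswith("adult"):
            lo = max(lo, 25.0)
        bands = make_weight_bands(
            models, weight_min=lo, weight_max=hi,
            subjects_per_band=config.band_subjects, seed=seed_bands,
            under3m_max_weight=config.under3m_max_weight if lo < config.under3m_max_weight else lo,
            nat2_proportions=config.nat2_proportions,
            female_fraction=config.female_fraction,
        )
        table, regimens = build_dosing_table(bands, selected, targets, options)
        artifacts["dosing_table"] = out / "dosing_table.csv"
        table.to_csv(artifacts["dosing_table"], index=False)
        artifacts["dosing_table_md"] = out / "dosing_table.md"
        artifacts["dosing_table_md"].write_text(
            format_markdown(table, [f.name for f in selected]))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("regimen", str(e)) from e

    try:
        stage("summaries")
        srows = []
        xrows = []
        for b in bands:
            trow = table[(table["stratum"] == b.age_stratum)
                         & (table["weight_low"] == b.weight_low)].iloc[0]
            for drug in DRUGS:
                dose = float(trow[f"dose_{drug}"])
                aucs = b.dose_response[drug].auc_per_subject(dose)
                pct = np.percentile(aucs, PERCENTILES)
                srows.append({
                    "weight_low": b.weight_low, "weight_high": b.weight_high,
                    "stratum": b.age_stratum, "drug": drug, "dose_mg": dose,
                    **{f"p{p}": v for p, v in zip(PERCENTILES, pct)},
                    "n": len(aucs),
                })
                if config.export_subject_exposures:
                    ids = b.dose_response[drug].population.df["id"].to_numpy()
                    xrows.append(pd.DataFrame({
                        "weight_low": b.weight_low, "stratum": b.age_stratum,
                        "subject_id": ids, "drug": drug, "dose_mg": dose,
                        "auc_mg_h_per_L": aucs,
                    }))
        artifacts["exposure_summaries"] = out / "exposure_summaries.csv"
        pd.DataFrame(srows).to_csv(artifacts["exposure_summaries"], index=False)
        if xrows:
            artifacts["exposures"] = out / "exposures.csv"
            pd.concat(xrows, ignore_index=True).to_csv(artifacts["exposures"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("summaries", str(e)) from e

    stage("manifest")
    manifest = {
        "package": "tbmdose",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"population": seed_pop, "targets": seed_targets, "bands": seed_bands},
        "config": json.loads(config.model_dump_json()),
        "targets": {d: t.to_dict() for d, t in sorted(targets.items())},
        "regimens": [
            {**asdict(r)} for r in regimens
        ],
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
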