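"""One-command study pipeline: cohort -> split -> features -> score
construction (plus LMIC, no-metabolic, ablation) -> scoring -> landmark
evaluation -> calibration, with stage-level logging and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import build_cohort, split_cohort
from .ehr_model import (
    EhrTables,
    SplitSpec,
    SuspicionWindowSpec,
    load_concept_dictionary,
    load_score_definition,
    read_tables,
)
from .evaluation import calibrate, overtime_eval, per_level_mortality
from .features import build_feature_matrix
from .score_builder import ThresholdSearchSpec, ablation_study, build_score
from .scorer import score_stays
from .synth_ehr import generate, site_config

logger = logging.getLogger(__name__)

__all__ = ["DatasetSpec", "StudyConfig", "run_full_study"]


class DatasetSpec(BaseModel):
    """One input dataset: a synthetic site preset or a table directory."""

    name: str
    role: str = "development"  # development | validation
    preset: str | None = None  # synthetic site preset name
    n_stays: int = 2000
    path: str | None = None  # directory of long-format tables
    format: str = "csv"
    split: bool = True  # split dev datasets 60/40; validation-only skips


class StudyConfig(BaseModel):
    """Configuration of a full study run."""

    datasets: list[DatasetSpec]
    seed: int = 0
    dev_fraction: float = 0.60
    landmark_grid: list[float] = Field(default_factory=lambda: list(range(6, 25, 2)))
    bootstrap_B: int = 200
    build_T: float = 24.0
    domains: list[str] = Field(
        default_factory=lambda: [
            "liver", "renal", "cns", "metabolic", "cardiovascular",
            "respiratory", "coagulation",
        ]
    )
    search: ThresholdSearchSpec = Field(default_factory=ThresholdSearchSpec)
    run_ablation: bool = True
    ablation_max_removed: int = 2
    plant_signal: bool = False

    def validate_roles(self) -> None:
        n_dev = sum(1 for d in self.datasets if d.role == "development")
        n_val = sum(1 for d in self.datasets if d.role == "validation")
        if n_dev < 1 or (n_val < 1 and not any(
            d.role == "development" and d.split for d in self.datasets
        )):
            raise ValueError(
                "study config needs at least one development dataset and one "
                "source of validation data (a validation dataset or a split)"
            )


def _config_hash(config: StudyConfig) -> str:
    return hashlib.sha256(
        config.model_dump_json().encode()
    ).hexdigest()[:16]


def _load_dataset(dspec: DatasetSpec, seed: int, plant_signal: bool) -> EhrTables:
    if dspec.path is not None:
        return read_tables(dspec.path, fmt=dspec.format)
    if dspec.preset is None:
        raise ValueError(f"dataset {dspec.name!r} needs a preset or a path")
    cfg = site_config(dspec.preset, n_stays=dspec.n_stays, seed=seed)
    if plant_signal:
        from .synth_ehr import plant_score_signal

        cfg = plant_score_signal(cfg, load_score_definition("sepsis_sofa"))
    return generate(cfg).tables


def run_full_study(config: StudyConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write report CSVs plus a manifest."""
    config.validate_roles()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    dictionary = load_concept_dictionary()
    rng = np.random.default_rng(config.seed)

    # --- stage: load + cohort ------------------------------------------------
    dev_sets: list[tuple[str, EhrTables, pd.DataFrame]] = []
    val_sets: list[tuple[str, EhrTables, pd.DataFrame]] = []
    for k, dspec in enumerate(config.datasets):
        tables = _load_dataset(dspec, seed=config.seed + 17 * k + 1,
                               plant_signal=config.plant_signal)
        cohort = build_cohort(
            tables.stays, tables.medications, tables.samplings, SuspicionWindowSpec()
        )
        n_inc = int(cohort["included"].sum())
        logger.info("dataset %s: %d stays, %d included", dspec.name, len(cohort), n_inc)
        included = cohort[cohort["included"]].reset_index(drop=True)
        if dspec.role == "development" and dspec.split:
            dev, val = split_cohort(
                included, tables.stays,
                SplitSpec(dev_fraction=config.dev_fraction, seed=config.seed + k),
            )
            logger.info("dataset %s: split %d dev / %d val", dspec.name, len(dev), len(val))
            dev_sets.append((dspec.name, tables, dev))
            val_sets.append((dspec.name, tables, val))
        elif dspec.role == "development":
            dev_sets.append((dspec.name, tables, included))
        else:
            val_sets.append((dspec.name, tables, included))
    if not dev_sets or not val_sets:
        raise ValueError("stage cohort: no development or no validation cohort produced")

    # --- stage: features -----------------------------------------------------
    template = load_score_definition("sepsis_sofa")

    def matrices(sets, role):
        out_m = []
        for name, tables, cohort in sets:
            X = build_feature_matrix(
                cohort, tables, dictionary, config.build_T, template
            )
            X.attrs["cohort_role"] = role
            y = (
                tables.stays.set_index("stay_id")
                .loc[X["stay_id"], "hospital_death"].to_numpy().astype(int)
            )
            logger.info("features %s (%s): %d stays", name, role, len(X))
            out_m.append((name, X, y))
        return out_m

    dev_m = matrices(dev_sets, "development")
    val_m = matrices(val_sets, "validation")

    # --- stage: score construction ------------------------------------------
    dev_pairs = [(X, y) for _, X, y in dev_m]
    built = build_score(config.domains, dev_pairs, dictionary, config.search,
                        name="data_driven")
    built_lmic = build_score(config.domains, dev_pairs, dictionary, config.search,
                             constraints="lmic", name="data_driven_lmic")
    built_nometab = build_score(config.domains, dev_pairs, dictionary, config.search,
                                constraints="no_metabolic", name="data_driven_no_metabolic")
    for sdef in (built, built_lmic, built_nometab):
        path = out / f"score_{sdef.name}.json"
        path.write_text(sdef.model_dump_json(indent=2))
        logger.info("built score %s: %d components", sdef.name, len(sdef.components))

    if config.run_ablation:
        ablation = ablation_study(
            built, dev_pairs, [(X, y) for _, X, y in val_m], dictionary,
            config.search, max_removed=config.ablation_max_removed,
        )
        ablation.to_csv(out / "ablation.csv", index=False)

    # --- stage: landmark evaluation -----------------------------------------
    score_defs = {
        "data_driven": built,
        "sepsis_sofa": template,
        "sofa_baseline": load_score_definition("sofa_baseline"),
    }
    reports = []
    for name, tables, cohort in val_sets:
        rep = overtime_eval(
            cohort, tables, dictionary, score_defs,
            T_grid=config.landmark_grid, B=config.bootstrap_B,
            seed=int(rng.integers(2**31)),
        )
        rep.insert(0, "cohort", name)
        reports.append(rep)
    eval_report = pd.concat(reports, ignore_index=True)
    eval_report.to_csv(out / "evaluation.csv", index=False)

    # --- stage: per-level mortality + calibration ---------------------------
    pl_rows = []
    for name, X, y in val_m:
        scored = score_stays(X, built)
        pl = per_level_mortality(scored, y)
        pl.insert(0, "cohort", name)
        pl_rows.append(pl)
    pd.concat(pl_rows, ignore_index=True).to_csv(out / "per_level_mortality.csv", index=False)

    cal_rows = []
    for dev_name, Xd, yd in dev_m:
        dev_total = score_stays(Xd, built)["total"].to_numpy()
        for val_name, Xv, yv in val_m:
            val_total = score_stays(Xv, built)["total"].to_numpy()
            rep = calibrate(dev_total, yd, val_total, yv)
            cal_rows.append(
                {"fit_cohort": dev_name, "eval_cohort": val_name,
                 "intercept": rep.intercept,
                 "intercept_lo": rep.intercept_ci[0], "intercept_hi": rep.intercept_ci[1],
                 "slope": rep.slope,
                 "slope_lo": rep.slope_ci[0], "slope_hi": rep.slope_ci[1],
                 "calibrated": rep.calibrated}
            )
    pd.DataFrame(cal_rows).to_csv(out / "calibration.csv", index=False)

    manifest = {
        "command": "run_full_study",
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": sorted(p.name for p in out.iterdir()),
        "package_version": __version__,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
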