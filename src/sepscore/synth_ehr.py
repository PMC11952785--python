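"""Seeded synthetic ICU EHR generator.

Emulates the statistical structure the scoring framework assumes — without
any claim of matching a real database's marginals: per-stay admission and
discharge times, an in-hospital mortality label driven by a latent severity,
sparse irregularly-timed biomarker measurements whose distributions shift
with that severity, antibiotic and body-fluid-sampling events placed so that
a configured fraction of stays qualifies as suspected infection, vasopressor
infusions, and sedation episodes.

Generative model, per stay i:

* latent severity ``z_i ~ Normal(0, 1)``;
* ICU length of stay lognormal, mildly increasing in z;
* death ``~ Bernoulli(sigmoid(a + b * x_i))`` where ``x_i = z_i`` by default,
  or the *true* banded score of a planted score definition (see
  :func:`plant_score_signal`); the intercept ``a`` is solved so the marginal
  death rate matches ``mortality_base_rate``;
* each biomarker has a per-stay tendency ``normal_value +/- loading * z``
  (sign per worst direction) observed at homogeneous-Poisson times with
  Gaussian observation noise, clipped to a plausible range; a stay misses a
  biomarker entirely with the configured probability;
* sedated stays receive a propofol infusion during which recorded GCS
  values are low and RASS readings are <= -2.

All randomness flows through one counter-based Philox generator keyed by the
seed, so a given (config, seed) reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .ehr_model import (
    ConceptDictionary,
    EhrTables,
    NeqTable,
    ScoreDefinition,
    load_concept_dictionary,
    load_neq_table,
)
from .scorer import band_level

__all__ = ["ConceptGenSpec", "GeneratorConfig", "SynthData", "generate",
           "plant_score_signal", "SITE_PRESETS", "site_config"]


class ConceptGenSpec(BaseModel):
    """Measurement process for one biomarker."""

    rate_per_day: float = Field(ge=0)
    noise_sd: float = Field(ge=0)
    severity_loading: float
    missing_prob: float = Field(default=0.0, ge=0, le=1)
    lo: float = -np.inf
    hi: float = np.inf
    integer: bool = False


DEFAULT_CONCEPTS: dict[str, ConceptGenSpec] = {
    "map": ConceptGenSpec(rate_per_day=24, noise_sd=8, severity_loading=7,
                          missing_prob=0.01, lo=30, hi=130),
    "pf_ratio": ConceptGenSpec(rate_per_day=4, noise_sd=40, severity_loading=80,
                               missing_prob=0.15, lo=40, hi=620),
    "sf_ratio": ConceptGenSpec(rate_per_day=6, noise_sd=30, severity_loading=60,
                               missing_prob=0.05, lo=90, hi=500),
    "platelets": ConceptGenSpec(rate_per_day=1.5, noise_sd=20, severity_loading=45,
                                missing_prob=0.05, lo=5, hi=700),
    "ast": ConceptGenSpec(rate_per_day=1.0, noise_sd=15, severity_loading=70,
                          missing_prob=0.25, lo=5, hi=4000),
    "bilirubin": ConceptGenSpec(rate_per_day=0.8, noise_sd=0.3, severity_loading=0.5,
                                missing_prob=0.25, lo=0.1, hi=30),
    "gcs": ConceptGenSpec(rate_per_day=6, noise_sd=1.0, severity_loading=1.8,
                          missing_prob=0.02, lo=3, hi=15, integer=True),
    "rass": ConceptGenSpec(rate_per_day=4, noise_sd=0.5, severity_loading=0.0,
                           missing_prob=0.10, lo=-5, hi=4, integer=True),
    "bun": ConceptGenSpec(rate_per_day=1.0, noise_sd=4, severity_loading=9,
                          missing_prob=0.05, lo=2, hi=200),
    "creatinine": ConceptGenSpec(rate_per_day=1.0, noise_sd=0.25, severity_loading=0.45,
                                 missing_prob=0.05, lo=0.2, hi=15),
    "lactate": ConceptGenSpec(rate_per_day=2.0, noise_sd=0.4, severity_loading=1.3,
                              missing_prob=0.10, lo=0.3, hi=25),
    "bicarbonate": ConceptGenSpec(rate_per_day=2.0, noise_sd=1.5, severity_loading=2.8,
                                  missing_prob=0.05, lo=5, hi=45),
}


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic dataset."""

    n_stays: int = Field(default=1000, ge=1)
    seed: int = 0
    site: str = "site_a"
    mortality_base_rate: float = Field(default=0.11, gt=0, lt=1)
    severity_effect: float = 1.3  # log-odds of death per unit latent severity
    los_median_days: float = 2.8
    los_log_sd: float = 0.9
    los_severity_coef: float = 0.12  # log-LOS shift per unit severity
    age_mean: float = 65.0
    age_sd: float = 14.0
    minor_fraction: float = Field(default=0.02, ge=0, le=1)
    repeat_fraction: float = Field(default=0.05, ge=0, le=1)
    suspected_fraction: float = Field(default=0.70, ge=0, le=1)
    vasopressor_fraction: float = Field(default=0.30, ge=0, le=1)
    sedation_fraction: float = Field(default=0.25, ge=0, le=1)
    pre_icu_measurement_fraction: float = 0.04
    concepts: dict[str, ConceptGenSpec] = Field(
        default_factory=lambda: dict(DEFAULT_CONCEPTS)
    )
    planted_score: ScoreDefinition | None = None
    planted_effect: float = 0.55  # log-odds of death per true-score point

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if self.suspected_fraction > 1:
            raise ValueError("suspected_fraction must be <= 1")
        return self


# Structural site presets: a large, mostly medical, lower-mortality cohort
# with short stays; a surgical cohort with long stays and high mortality; and
# a smaller surgical cohort in between.  Values are structural presets for
# cross-site tests, not claims about any real database.
SITE_PRESETS: dict[str, dict] = {
    "site_a": {"mortality_base_rate": 0.11, "los_median_days": 2.2,
               "suspected_fraction": 0.75},
    "site_b": {"mortality_base_rate": 0.22, "los_median_days": 5.5,
               "suspected_fraction": 0.55, "vasopressor_fraction": 0.45},
    "site_c": {"mortality_base_rate": 0.21, "los_median_days": 4.3,
               "suspected_fraction": 0.60, "vasopressor_fraction": 0.40},
}


def site_config(site: str, n_stays: int, seed: int, **overrides) -> GeneratorConfig:
    """Config for one of the shipped site presets."""
    if site not in SITE_PRESETS:
        raise ValueError(f"unknown site preset: {site!r} (have {sorted(SITE_PRESETS)})")
    params = {**SITE_PRESETS[site], **overrides}
    return GeneratorConfig(n_stays=n_stays, seed=seed, site=site, **params)


def plant_score_signal(
    config: GeneratorConfig,
    score_def: ScoreDefinition,
    effect_per_point: float | None = None,
) -> GeneratorConfig:
    """Make mortality logistic in the *true* score under ``score_def``.

    The true score is computed from the per-stay biomarker tendencies (the
    noiseless severity-driven values), so threshold-recovery experiments have
    a well-defined target.
    """
    update: dict = {"planted_score": score_def}
    if effect_per_point is not None:
        update["planted_effect"] = effect_per_point
    return config.model_copy(update=update)


@dataclass
class SynthData:
    """Generated tables plus the generating truth per stay."""

    tables: EhrTables
    truth: pd.DataFrame


def _solve_intercept(x: np.ndarray, target_rate: float) -> float:
    """Intercept a with mean(sigmoid(a + x)) = target_rate on the sample."""

    def gap(a: float) -> float:
        return float(expit(a + x).mean() - target_rate)

    return brentq(gap, -30.0, 30.0)


def _true_scores(
    config: GeneratorConfig,
    tendencies: dict[str, np.ndarray],
    neq_tendency: np.ndarray,
    dictionary: ConceptDictionary,
) -> np.ndarray:
    sdef = config.planted_score
    assert sdef is not None
    n = len(neq_tendency)
    total = np.zeros(n, dtype=int)
    for comp in sdef.components:
        if comp.concept_id == "map_adjusted":
            map_t = tendencies.get("map", np.full(n, dictionary["map"].normal_value))
            vals = map_t - sdef.map_adjustment_beta * neq_tendency
        else:
            # concepts the config does not generate contribute their normal
            # value, i.e. band 0 (matches the imputation rule downstream)
            vals = tendencies.get(
                comp.concept_id,
                np.full(n, dictionary[comp.concept_id].normal_value),
            )
        if comp.kind == "bands":
            total += np.asarray(band_level(vals, comp.thresholds, comp.inequality))
    return total


def generate(
    config: GeneratorConfig,
    dictionary: ConceptDictionary | None = None,
    neq_table: NeqTable | None = None,
) -> SynthData:
    """Generate one synthetic dataset (stays, measurements, medications,
    samplings) plus a per-stay truth table (z, death probability, true score)."""
    dictionary = dictionary or load_concept_dictionary()
    neq_table = neq_table or load_neq_table()
    rng = np.random.Generator(np.random.Philox(config.seed))
    n = config.n_stays

    # --- stays -------------------------------------------------------------
    z = rng.standard_normal(n)
    los_h = 24.0 * config.los_median_days * np.exp(
        config.los_log_sd * rng.standard_normal(n) + config.los_severity_coef * z
    )
    los_h = np.clip(los_h, 6.0, 24.0 * 60)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 19.0, 99.0)
    minor = rng.random(n) < config.minor_fraction
    age[minor] = rng.uniform(12.0, 18.0, minor.sum())

    subject_idx = np.arange(n)
    is_repeat = rng.random(n) < config.repeat_fraction
    is_repeat[0] = False
    for i in np.flatnonzero(is_repeat):
        subject_idx[i] = subject_idx[rng.integers(0, i)]

    # --- vasopressors and sedation (needed before death/tendencies) --------
    on_vaso = rng.random(n) < config.vasopressor_fraction
    vaso_rate = np.where(
        on_vaso,
        np.clip(0.02 + 0.08 * np.exp(0.5 * z) + rng.normal(0, 0.02, n), 0.01, 1.5),
        0.0,
    )
    vaso_drug_u = rng.random(n)
    vaso_start = rng.uniform(0.0, np.minimum(12.0, los_h * 0.5))
    vaso_dur = rng.uniform(6.0, 48.0, n)
    vaso_end = np.minimum(vaso_start + vaso_dur, los_h)

    sedated = rng.random(n) < config.sedation_fraction
    sed_start = rng.uniform(0.0, np.minimum(12.0, los_h * 0.5))
    sed_end = np.minimum(sed_start + rng.uniform(4.0, 36.0, n), los_h)

    # --- per-stay biomarker tendencies --------------------------------------
    tendencies: dict[str, np.ndarray] = {}
    for cid, cspec in config.concepts.items():
        concept = dictionary[cid]
        sign = 1.0 if concept.worst_direction == "higher_worse" else -1.0
        mu = concept.normal_value + sign * cspec.severity_loading * z
        tendencies[cid] = np.clip(mu, cspec.lo, cspec.hi)

    # --- death -------------------------------------------------------------
    # NEQ tendency uses each stay's assigned infusion (norepinephrine-scale).
    neq_tendency = vaso_rate.copy()
    if config.planted_score is not None:
        true_score = _true_scores(config, tendencies, neq_tendency, dictionary)
        x_raw = config.planted_effect * true_score.astype(float)
    else:
        x_raw = config.severity_effect * z
        true_score = np.full(n, -1)
    a = _solve_intercept(x_raw, config.mortality_base_rate)
    p_death = expit(a + x_raw)
    died = rng.random(n) < p_death
    death_time = np.full(n, np.nan)
    death_time[died] = los_h[died] * rng.uniform(0.3, 1.5, died.sum())
    icu_discharge = los_h.copy()
    in_icu_death = died & (death_time < icu_discharge)
    icu_discharge[in_icu_death] = death_time[in_icu_death]

    stay_ids = np.array([f"s{i:06d}" for i in range(n)])
    subject_ids = np.array([f"p{j:06d}" for j in subject_idx])
    stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "subject_id": subject_ids,
            "icu_admit": 0.0,
            "icu_discharge": icu_discharge,
            "hospital_death": died,
            "death_time": death_time,
            "age_years": age,
        }
    )

    # --- measurements -------------------------------------------------------
    meas_parts: list[pd.DataFrame] = []
    for cid in sorted(config.concepts):
        cspec = config.concepts[cid]
        missing = rng.random(n) < cspec.missing_prob
        lam = cspec.rate_per_day * icu_discharge / 24.0
        counts = rng.poisson(np.where(missing, 0.0, lam))
        total = int(counts.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(n), counts)
        times = rng.uniform(0.0, 1.0, total) * icu_discharge[owner]
        pre = rng.random(total) < config.pre_icu_measurement_fraction
        times[pre] = -rng.uniform(0.0, 12.0, int(pre.sum()))
        values = tendencies[cid][owner] + rng.normal(0.0, cspec.noise_sd, total)
        if cid == "gcs":
            in_sed = sedated[owner] & (times >= sed_start[owner]) & (times <= sed_end[owner])
            values[in_sed] = rng.integers(3, 9, int(in_sed.sum())).astype(float)
        if cid == "rass":
            in_sed = sedated[owner] & (times >= sed_start[owner]) & (times <= sed_end[owner])
            values[in_sed] = -rng.integers(2, 5, int(in_sed.sum())).astype(float)
        values = np.clip(values, cspec.lo, cspec.hi)
        if cspec.integer:
            values = np.round(values)
        meas_parts.append(
            pd.DataFrame(
                {"stay_id": stay_ids[owner], "concept_id": cid,
                 "time": times, "value": values}
            )
        )
    measurements = (
        pd.concat(meas_parts, ignore_index=True)
        if meas_parts
        else pd.DataFrame(columns=["stay_id", "concept_id", "time", "value"])
    )

    # --- antibiotics and samplings ------------------------------------------
    suspected = rng.random(n) < config.suspected_fraction
    t0 = rng.uniform(0.0, 40.0, n)
    samp_offset = rng.uniform(0.0, 20.0, n)
    abx_days = 1 + rng.poisson(3.0, n)
    nonsusp_kind = rng.random(n)  # <.4 none, <.7 abx only, <.9 sampling only, else bad pair

    med_rows: list[dict] = []
    samp_rows: list[dict] = []
    for i in range(n):
        sid = stay_ids[i]
        if suspected[i]:
            for k in range(int(abx_days[i])):
                start = t0[i] + 24.0 * k
                if k > 0 and start >= los_h[i]:
                    break
                med_rows.append(
                    {"stay_id": sid, "drug_id": "cefepime", "start": start,
                     "end": start + 1.0, "rate": np.nan, "rate_unit": "dose",
                     "route": "iv", "drug_class": "antibiotic"}
                )
            samp_rows.append(
                {"stay_id": sid, "time": t0[i] + samp_offset[i], "specimen": "blood"}
            )
        else:
            u = nonsusp_kind[i]
            if u < 0.4:
                pass
            elif u < 0.7:
                med_rows.append(
                    {"stay_id": sid, "drug_id": "cefepime", "start": t0[i],
                     "end": t0[i] + 1.0, "rate": np.nan, "rate_unit": "dose",
                     "route": "iv", "drug_class": "antibiotic"}
                )
            elif u < 0.9:
                samp_rows.append({"stay_id": sid, "time": t0[i], "specimen": "urine"})
            else:
                samp_rows.append({"stay_id": sid, "time": t0[i], "specimen": "blood"})
                med_rows.append(
                    {"stay_id": sid, "drug_id": "cefepime", "start": t0[i] + 80.0,
                     "end": t0[i] + 81.0, "rate": np.nan, "rate_unit": "dose",
                     "route": "iv", "drug_class": "antibiotic"}
                )

        if on_vaso[i]:
            u = vaso_drug_u[i]
            if u < 0.80:
                drug, rate, unit = "norepinephrine", vaso_rate[i], "ug/kg/min"
            elif u < 0.90:
                drug, rate, unit = "epinephrine", vaso_rate[i], "ug/kg/min"
            elif u < 0.95:
                drug, rate, unit = "dopamine", vaso_rate[i] / 0.01, "ug/kg/min"
            else:
                drug, rate, unit = "vasopressin", vaso_rate[i] / 2.5, "U/min"
            med_rows.append(
                {"stay_id": sid, "drug_id": drug, "start": vaso_start[i],
                 "end": vaso_end[i], "rate": rate, "rate_unit": unit,
                 "route": "iv", "drug_class": "vasopressor"}
            )
        if sedated[i]:
            med_rows.append(
                {"stay_id": sid, "drug_id": "propofol", "start": sed_start[i],
                 "end": sed_end[i], "rate": 30.0, "rate_unit": "ug/kg/min",
                 "route": "iv", "drug_class": "sedative"}
            )

    medications = pd.DataFrame(
        med_rows,
        columns=["stay_id", "drug_id", "start", "end", "rate", "rate_unit",
                 "route", "drug_class"],
    )
    samplings = pd.DataFrame(samp_rows, columns=["stay_id", "time", "specimen"])

    # sort to the canonical on-disk order so write/read round-trips are exact
    measurements = measurements.sort_values(
        ["stay_id", "concept_id"], kind="mergesort"
    ).reset_index(drop=True)
    medications = medications.sort_values(
        ["stay_id", "drug_id"], kind="mergesort"
    ).reset_index(drop=True)
    samplings = samplings.sort_values(
        ["stay_id", "time"], kind="mergesort"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {"stay_id": stay_ids, "z": z, "p_death": p_death,
         "true_score": true_score, "suspected": suspected}
    )
    tables = EhrTables(
        stays=stays, measurements=measurements,
        medications=medications, samplings=samplings,
    )
    return SynthData(tables=tables, truth=truth)
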