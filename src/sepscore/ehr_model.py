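"""Data model and file I/O for ICU event tables and score configurations.

All tables are plain :class:`pandas.DataFrame` objects in long format with a
fixed column contract (see the ``*_COLUMNS`` constants).  All times are
fractional hours relative to ICU admission (t = 0 at admission); general
windows are half-open ``[start, end)`` while suspected-infection windows are
boundary-inclusive.

Configuration objects (concept dictionary, score definitions, NEQ conversion
tables) are pydantic models loaded from YAML; the package ships defaults for
the data-driven Sepsis SOFA score, its LMIC variant, and a classic SOFA
baseline comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Domain",
    "WorstDirection",
    "Concept",
    "ConceptDictionary",
    "ScoreComponent",
    "ScoreDefinition",
    "NeqTable",
    "SuspicionWindowSpec",
    "SplitSpec",
    "EhrTables",
    "SchemaError",
    "STAY_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "MEDICATION_COLUMNS",
    "SAMPLING_COLUMNS",
    "load_concept_dictionary",
    "load_neq_table",
    "load_score_definition",
    "read_tables",
    "write_tables",
    "validate_tables",
]

Domain = Literal[
    "respiratory", "cardiovascular", "coagulation", "liver", "cns", "renal", "metabolic"
]
WorstDirection = Literal["higher_worse", "lower_worse"]
GcsPolicy = Literal["set_max_15", "carry_forward", "raw"]

DOMAINS: tuple[str, ...] = (
    "respiratory", "cardiovascular", "coagulation", "liver", "cns", "renal", "metabolic"
)

STAY_COLUMNS = [
    "stay_id", "subject_id", "icu_admit", "icu_discharge",
    "hospital_death", "death_time", "age_years",
]
MEASUREMENT_COLUMNS = ["stay_id", "concept_id", "time", "value"]
MEDICATION_COLUMNS = [
    "stay_id", "drug_id", "start", "end", "rate", "rate_unit", "route", "drug_class",
]
SAMPLING_COLUMNS = ["stay_id", "time", "specimen"]

_TABLE_SCHEMAS: dict[str, list[str]] = {
    "stays": STAY_COLUMNS,
    "measurements": MEASUREMENT_COLUMNS,
    "medications": MEDICATION_COLUMNS,
    "samplings": SAMPLING_COLUMNS,
}

DRUG_CLASSES = ("antibiotic", "vasopressor", "sedative", "other")


class SchemaError(ValueError):
    """A table or config file violates its declared schema."""


class Concept(BaseModel):
    """Metadata for one clinical concept (biomarker)."""

    concept_id: str
    name: str
    unit: str
    worst_direction: WorstDirection
    normal_value: float
    requires_blood_gas: bool = False
    domain: Domain


class ConceptDictionary(BaseModel):
    """Per-concept metadata: units, worst direction, imputation value, domain."""

    concepts: dict[str, Concept]

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept_id: {concept_id!r}") from None

    @property
    def concept_ids(self) -> list[str]:
        return list(self.concepts)

    def by_domain(self, domain: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.domain == domain]

    def direction_sign(self, concept_id: str) -> int:
        """+1 if higher values are worse, -1 if lower values are worse."""
        return 1 if self[concept_id].worst_direction == "higher_worse" else -1


class ScoreComponent(BaseModel):
    """One organ-domain component: a concept banded at four thresholds.

    ``inequality="ge"`` means sub-score k is reached when value >= t_k
    (thresholds strictly increasing); ``"lt"`` means value < t_k (thresholds
    strictly decreasing).  ``kind="sofa_cardiovascular"`` marks the classic
    SOFA cardiovascular component, which bands on vasopressor dose rather
    than on the value alone (its thresholds carry only the hypotension cut).
    """

    domain: Domain
    concept_id: str
    thresholds: list[float] = Field(min_length=4, max_length=4)
    inequality: Literal["ge", "lt"]
    unit: str = ""
    kind: Literal["bands", "sofa_cardiovascular"] = "bands"

    @model_validator(mode="after")
    def _check_threshold_order(self) -> "ScoreComponent":
        if self.kind != "bands":
            return self
        t = self.thresholds
        if self.inequality == "ge" and not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError(
                f"component {self.domain}/{self.concept_id}: 'ge' thresholds must be "
                f"strictly increasing, got {t}"
            )
        if self.inequality == "lt" and not all(a > b for a, b in zip(t, t[1:])):
            raise ValueError(
                f"component {self.domain}/{self.concept_id}: 'lt' thresholds must be "
                f"strictly decreasing, got {t}"
            )
        return self


class NeqTable(BaseModel):
    """Norepinephrine-equivalence factors per vasopressor drug_id."""

    name: str = "neq"
    factors: dict[str, float]

    @field_validator("factors")
    @classmethod
    def _check_factors(cls, v: dict[str, float]) -> dict[str, float]:
        bad = [d for d, f in v.items() if f <= 0]
        if bad:
            raise ValueError(f"NEQ factors must be > 0; offending drugs: {bad}")
        if v.get("norepinephrine", 1.0) != 1.0:
            raise ValueError("norepinephrine factor must be exactly 1.0")
        return v

    def factor(self, drug_id: str) -> float:
        try:
            return self.factors[drug_id]
        except KeyError:
            raise KeyError(
                f"drug {drug_id!r} missing from NEQ table {self.name!r}"
            ) from None


class ScoreDefinition(BaseModel):
    """A named score: one component per organ domain plus adjustment policy."""

    name: str
    components: list[ScoreComponent]
    map_adjustment_beta: float = 200.0
    gcs_policy: GcsPolicy = "set_max_15"
    neq_table: str = "neq_default"

    @model_validator(mode="after")
    def _one_component_per_domain(self) -> "ScoreDefinition":
        seen: set[str] = set()
        for comp in self.components:
            if comp.domain in seen:
                raise ValueError(f"score {self.name!r}: duplicate domain {comp.domain!r}")
            seen.add(comp.domain)
        return self

    @property
    def max_total(self) -> int:
        return 4 * len(self.components)

    @property
    def domains(self) -> list[str]:
        return [c.domain for c in self.components]

    def component(self, domain: str) -> ScoreComponent:
        for comp in self.components:
            if comp.domain == domain:
                return comp
        raise KeyError(f"score {self.name!r} has no component for domain {domain!r}")

    @property
    def concept_ids(self) -> list[str]:
        return [c.concept_id for c in self.components]


class SuspicionWindowSpec(BaseModel):
    """Windows of the suspected-infection rule.

    A (antibiotic, sampling) pair qualifies when the sampling occurs within
    ``sampling_after_abx_h`` after the antibiotic, or the antibiotic occurs
    within ``abx_after_sampling_h`` after the sampling.  The suspicion time
    must fall within the first ``max_suspicion_day`` ICU days.
    """

    sampling_after_abx_h: float = 24.0
    abx_after_sampling_h: float = 72.0
    max_suspicion_day: int = 2
    boundary_inclusive: bool = True

    @model_validator(mode="after")
    def _positive(self) -> "SuspicionWindowSpec":
        if min(self.sampling_after_abx_h, self.abx_after_sampling_h) <= 0:
            raise ValueError("suspicion windows must be > 0")
        if self.max_suspicion_day <= 0:
            raise ValueError("max_suspicion_day must be > 0")
        return self

    @property
    def max_suspicion_h(self) -> float:
        return 24.0 * self.max_suspicion_day


class SplitSpec(BaseModel):
    """Development/validation split parameters (subject-level)."""

    dev_fraction: float = 0.60
    seed: int = 0

    @field_validator("dev_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("dev_fraction must lie in (0, 1)")
        return v


@dataclass
class EhrTables:
    """The four long-format event tables of one dataset."""

    stays: pd.DataFrame
    measurements: pd.DataFrame
    medications: pd.DataFrame
    samplings: pd.DataFrame

    def __iter__(self):
        return iter((self.stays, self.measurements, self.medications, self.samplings))


# ---------------------------------------------------------------------------
# config loading


def _config_text(filename: str) -> str:
    return resources.files("sepscore.configs").joinpath(filename).read_text()


_SHIPPED_SCORES = {
    "sepsis_sofa": "score_sepsis_sofa.yaml",
    "sepsis_sofa_lmic": "score_sepsis_sofa_lmic.yaml",
    "sofa_baseline": "score_sofa_baseline.yaml",
}


def load_concept_dictionary(path: str | Path | None = None) -> ConceptDictionary:
    """Load a concept dictionary from YAML; default = the shipped dictionary."""
    text = Path(path).read_text() if path is not None else _config_text("concepts.yaml")
    raw = yaml.safe_load(text)
    concepts = {
        cid: Concept(concept_id=cid, **entry) for cid, entry in raw["concepts"].items()
    }
    return ConceptDictionary(concepts=concepts)


def load_neq_table(path_or_name: str | Path = "neq_default") -> NeqTable:
    """Load an NEQ conversion table by shipped name or YAML path."""
    if isinstance(path_or_name, str) and path_or_name == "neq_default":
        raw = yaml.safe_load(_config_text("neq_default.yaml"))
    else:
        raw = yaml.safe_load(Path(path_or_name).read_text())
    return NeqTable(**raw)


def load_score_definition(
    name_or_path: str | Path,
    dictionary: ConceptDictionary | None = None,
) -> ScoreDefinition:
    """Load a score definition by shipped name or from a YAML config file.

    Shipped names: ``sepsis_sofa``, ``sepsis_sofa_lmic``, ``sofa_baseline``.
    When a dictionary is supplied, the definition is cross-validated against
    it: every concept must exist and every normal imputation value must score
    zero in the component that uses it.
    """
    if isinstance(name_or_path, str) and name_or_path in _SHIPPED_SCORES:
        raw = yaml.safe_load(_config_text(_SHIPPED_SCORES[name_or_path]))
    else:
        raw = yaml.safe_load(Path(name_or_path).read_text())
    score = ScoreDefinition(**raw)
    if dictionary is not None:
        _validate_score_against_dictionary(score, dictionary)
    return score


def _validate_score_against_dictionary(
    score: ScoreDefinition, dictionary: ConceptDictionary
) -> None:
    for comp in score.components:
        if comp.concept_id not in dictionary:
            raise SchemaError(
                f"score {score.name!r}: unknown concept {comp.concept_id!r}"
            )
        concept = dictionary[comp.concept_id]
        if comp.kind != "bands":
            continue
        expected = "ge" if concept.worst_direction == "higher_worse" else "lt"
        if comp.inequality != expected:
            raise SchemaError(
                f"score {score.name!r}: component {comp.domain} uses inequality "
                f"{comp.inequality!r} but {comp.concept_id!r} is {concept.worst_direction}"
            )
        nv = concept.normal_value
        in_band_1 = nv >= comp.thresholds[0] if comp.inequality == "ge" else nv < comp.thresholds[0]
        if in_band_1:
            raise SchemaError(
                f"score {score.name!r}: normal value {nv} of {comp.concept_id!r} falls "
                f"in the abnormal region of the {comp.domain} component"
            )


# ---------------------------------------------------------------------------
# table I/O


def _check_columns(df: pd.DataFrame, table: str) -> None:
    expected = _TABLE_SCHEMAS[table]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing column(s): {missing}")


def validate_tables(
    tables: EhrTables, dictionary: ConceptDictionary | None = None
) -> EhrTables:
    """Validate schemas and invariants; raises :class:`SchemaError` on violation."""
    for name in _TABLE_SCHEMAS:
        _check_columns(getattr(tables, name), name)
    stays = tables.stays
    if stays["stay_id"].duplicated().any():
        dupes = stays.loc[stays["stay_id"].duplicated(), "stay_id"].tolist()
        raise SchemaError(f"duplicate stay_id(s): {dupes}")
    if (stays["icu_discharge"] <= stays["icu_admit"]).any():
        bad = stays.loc[stays["icu_discharge"] <= stays["icu_admit"], "stay_id"].tolist()
        raise SchemaError(f"icu_discharge must exceed icu_admit; offending stays: {bad}")
    if (stays["age_years"] <= 0).any():
        raise SchemaError("age_years must be > 0")
    death = stays["death_time"]
    bad_death = death.notna() & (death < stays["icu_admit"])
    if bad_death.any():
        raise SchemaError(
            f"death_time precedes ICU admission for stays: "
            f"{stays.loc[bad_death, 'stay_id'].tolist()}"
        )
    meas = tables.measurements
    if len(meas) and not pd.to_numeric(meas["value"], errors="coerce").notna().all():
        raise SchemaError("measurement values must be finite numbers")
    if dictionary is not None and len(meas):
        unknown = sorted(set(meas["concept_id"]) - set(dictionary.concept_ids))
        if unknown:
            raise SchemaError(f"unknown concept_id(s) in measurements: {unknown}")
    meds = tables.medications
    if len(meds):
        if (meds["end"] < meds["start"]).any():
            raise SchemaError("medication end must be >= start")
        bad_class = sorted(set(meds["drug_class"]) - set(DRUG_CLASSES))
        if bad_class:
            raise SchemaError(f"unknown drug_class value(s): {bad_class}")
        vaso = meds[meds["drug_class"] == "vasopressor"]
        if len(vaso) and vaso["rate"].isna().any():
            raise SchemaError("vasopressor events must carry a rate")
    return tables


def _read_one(path: Path, fmt: str) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "parquet":
        return pd.read_parquet(path)
    raise ValueError(f"unsupported format: {fmt!r} (use 'csv' or 'parquet')")


def read_tables(
    paths: Mapping[str, str | Path] | str | Path,
    fmt: str = "csv",
    dictionary: ConceptDictionary | None = None,
) -> EhrTables:
    """Read the four event tables from files and validate them.

    ``paths`` is either a mapping ``{table_name: path}`` or a directory
    containing ``stays.<fmt>`` etc.  Times are expected already normalised to
    hours since ICU admission.
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {name: root / f"{name}.{fmt}" for name in _TABLE_SCHEMAS}
    frames: dict[str, pd.DataFrame] = {}
    for name in _TABLE_SCHEMAS:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"table {name!r}: no such file {path}")
        df = _read_one(path, fmt)
        _check_columns(df, name)
        frames[name] = df[_TABLE_SCHEMAS[name]].sort_values(
            _TABLE_SCHEMAS[name][:2], kind="mergesort"
        ).reset_index(drop=True)
    # normalise dtypes so CSV and Parquet round-trips agree
    frames["stays"] = frames["stays"].astype(
        {"icu_admit": float, "icu_discharge": float, "hospital_death": bool,
         "death_time": float, "age_years": float}
    )
    frames["measurements"] = frames["measurements"].astype({"time": float, "value": float})
    frames["medications"] = frames["medications"].astype(
        {"start": float, "end": float, "rate": float}
    )
    frames["samplings"] = frames["samplings"].astype({"time": float})
    return validate_tables(EhrTables(**frames), dictionary=dictionary)


def write_tables(tables: EhrTables, out_dir: str | Path, fmt: str = "csv") -> dict[str, Path]:
    """Write the four tables to ``out_dir``; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in _TABLE_SCHEMAS:
        df = getattr(tables, name)
        path = out_dir / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False)
        elif fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            raise ValueError(f"unsupported format: {fmt!r}")
        written[name] = path
    return written
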