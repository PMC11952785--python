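"""Suspected-infection cohort construction.

A stay has *suspected infection* when an antibiotic administration and a
body-fluid sampling co-occur: the sampling within 24 h after the antibiotic,
or the antibiotic within 72 h after the sampling.  The suspicion time is the
time of the earlier event of the qualifying pair (the Sepsis-3 convention).
Cohort inclusion further requires age > 18 years, a first (non-repeat) ICU
admission, and suspicion within the first two ICU days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr_model import SchemaError, SplitSpec, SuspicionWindowSpec

__all__ = [
    "EXCLUSION_REASONS",
    "detect_suspicion",
    "build_cohort",
    "filter_sustained_antibiotics",
    "split_cohort",
]

EXCLUSION_REASONS = ("none", "age", "repeat_admission", "no_suspicion", "suspicion_too_late")

COHORT_COLUMNS = ["stay_id", "suspicion_time", "included", "exclusion_reason"]


def detect_suspicion(
    abx_times: np.ndarray | list[float],
    sampling_times: np.ndarray | list[float],
    spec: SuspicionWindowSpec | None = None,
) -> float | None:
    """Earliest suspicion time for one stay, or ``None`` if no pair qualifies.

    A pair (antibiotic at ``ta``, sampling at ``ts``) qualifies when
    ``ta <= ts <= ta + 24`` or ``ts <= ta <= ts + 72`` (boundaries inclusive
    by default).  The suspicion time of a qualifying pair is ``min(ta, ts)``;
    the earliest such time over all pairs is returned.
    """
    spec = spec or SuspicionWindowSpec()
    ta = np.asarray(abx_times, dtype=float)
    ts = np.asarray(sampling_times, dtype=float)
    if ta.size == 0 or ts.size == 0:
        return None
    delta = ts[None, :] - ta[:, None]  # sampling minus antibiotic
    if spec.boundary_inclusive:
        ok = ((delta >= 0) & (delta <= spec.sampling_after_abx_h)) | (
            (delta <= 0) & (-delta <= spec.abx_after_sampling_h)
        )
    else:
        ok = ((delta >= 0) & (delta < spec.sampling_after_abx_h)) | (
            (delta <= 0) & (-delta < spec.abx_after_sampling_h)
        )
    if not ok.any():
        return None
    pair_start = np.minimum(ta[:, None], ts[None, :])
    return float(pair_start[ok].min())


def build_cohort(
    stays: pd.DataFrame,
    medications: pd.DataFrame,
    samplings: pd.DataFrame,
    spec: SuspicionWindowSpec | None = None,
) -> pd.DataFrame:
    """One cohort record per stay with inclusion flag and exclusion reason.

    Exclusion precedence: age, repeat admission, no suspicion, suspicion too
    late.  Repeat admissions keep the subject's earliest stay; with all times
    relative to each stay's own admission, stays of a subject are ordered by
    (icu_admit, stay_id).
    """
    spec = spec or SuspicionWindowSpec()
    if stays["stay_id"].duplicated().any():
        raise SchemaError("duplicate stay_id in stays table")

    abx = medications[medications["drug_class"] == "antibiotic"]
    abx_by_stay = {k: v["start"].to_numpy() for k, v in abx.groupby("stay_id")}
    samp_by_stay = {k: v["time"].to_numpy() for k, v in samplings.groupby("stay_id")}

    order = stays.sort_values(["subject_id", "icu_admit", "stay_id"], kind="mergesort")
    first_stay = set(order.drop_duplicates("subject_id", keep="first")["stay_id"])

    records = []
    for row in stays.itertuples(index=False):
        t_susp = detect_suspicion(
            abx_by_stay.get(row.stay_id, []), samp_by_stay.get(row.stay_id, []), spec
        )
        if row.age_years <= 18:
            reason = "age"
        elif row.stay_id not in first_stay:
            reason = "repeat_admission"
        elif t_susp is None:
            reason = "no_suspicion"
        elif t_susp >= spec.max_suspicion_h:
            reason = "suspicion_too_late"
        else:
            reason = "none"
        records.append(
            {
                "stay_id": row.stay_id,
                "suspicion_time": np.nan if t_susp is None else t_susp,
                "included": reason == "none",
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame.from_records(records, columns=COHORT_COLUMNS)


def _abx_day_runs(starts: np.ndarray, ends: np.ndarray) -> int:
    """Longest run of consecutive calendar days (day k = [24(k-1), 24k) h,
    anchored at ICU admission) touched by any antibiotic interval."""
    days: set[int] = set()
    for s, e in zip(starts, ends):
        days.update(range(int(np.floor(s / 24.0)), int(np.floor(e / 24.0)) + 1))
    if not days:
        return 0
    run = best = 1
    ordered = sorted(days)
    for prev, cur in zip(ordered, ordered[1:]):
        run = run + 1 if cur == prev + 1 else 1
        best = max(best, run)
    return best


def filter_sustained_antibiotics(
    cohort: pd.DataFrame, medications: pd.DataFrame, min_days: int = 4
) -> pd.DataFrame:
    """Restrict to stays with antibiotics on >= ``min_days`` consecutive days."""
    abx = medications[medications["drug_class"] == "antibiotic"]
    runs = {
        stay: _abx_day_runs(g["start"].to_numpy(), g["end"].to_numpy())
        for stay, g in abx.groupby("stay_id")
    }
    keep = cohort["stay_id"].map(lambda s: runs.get(s, 0) >= min_days)
    return cohort[keep].reset_index(drop=True)


def split_cohort(
    cohort: pd.DataFrame,
    stays: pd.DataFrame,
    spec: SplitSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded subject-level split into development and validation cohorts.

    Subjects are shuffled with a seeded generator; the first
    ``round(dev_fraction * n_subjects)`` subjects form the development set.
    Returns ``(development, validation)`` cohort tables (disjoint, exhaustive).
    """
    if len(cohort) < 2:
        raise ValueError("cannot split a cohort with fewer than 2 stays")
    subject_of = stays.set_index("stay_id")["subject_id"]
    subjects = np.sort(subject_of.loc[cohort["stay_id"]].unique())
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(subjects)
    n_dev = int(round(spec.dev_fraction * len(subjects)))
    dev_subjects = set(subjects[:n_dev])
    is_dev = cohort["stay_id"].map(lambda s: subject_of.loc[s] in dev_subjects)
    dev = cohort[is_dev].reset_index(drop=True)
    val = cohort[~is_dev].reset_index(drop=True)
    return dev, val
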