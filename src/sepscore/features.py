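"""Per-stay feature extraction: windowed worst values with normal-range
imputation, vasopressor-adjusted MAP, and sedation-adjusted GCS.

The scoring features at landmark time T are the *worst* values over the
lookback window (T - 24 h, T]: the maximum for higher-worse markers and the
minimum for lower-worse markers.  Stays with no observation of a concept in
the window receive the concept's clinically normal value, flagged imputed.

Two derived concepts are computed before worst-value extraction:

* ``map_adjusted`` — at each MAP measurement time t, the instantaneous
  norepinephrine-equivalent infusion rate NEQ(t) is evaluated (an infusion is
  active iff start <= t < end) and the adjusted value is MAP - beta * NEQ(t),
  beta = 200 mmHg per ug/kg/min by default.  Negative values are kept: they
  simply land in the worst band.
* ``gcs`` — raw readings are modified inside sedation windows according to
  the configured policy: set to the maximum of 15, carried forward from the
  last pre-window reading, or left untouched.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ehr_model import (
    ConceptDictionary,
    EhrTables,
    NeqTable,
    ScoreDefinition,
    load_neq_table,
)

__all__ = [
    "SEDATIVE_DRUGS",
    "VASOPRESSOR_DRUGS",
    "worst_value",
    "neq_rate",
    "neq_at_times",
    "adjusted_map",
    "sedation_windows",
    "sedation_adjusted_gcs",
    "build_feature_matrix",
]

# Sedative drug list used by the drug-based sedation criterion.
SEDATIVE_DRUGS = (
    "propofol", "fentanyl", "diazepam", "lorazepam", "midazolam",
    "oxazepam", "methadone", "morphine", "hydromorphone",
)

VASOPRESSOR_DRUGS = (
    "norepinephrine", "epinephrine", "dopamine", "phenylephrine", "vasopressin",
)

# auxiliary (non-concept) columns carried by every feature matrix
AUX_COLUMNS = ("neq_max", "dopamine_rate_max", "catecholamine_rate_max")


def worst_value(
    measurements: pd.DataFrame,
    concept_id: str,
    window: tuple[float, float],
    dictionary: ConceptDictionary,
) -> tuple[float, bool]:
    """Worst value of one concept in a half-open-below window (start, end].

    Returns ``(value, imputed)``: the max (higher-worse) or min (lower-worse)
    of the in-window observations, or the dictionary normal value with
    ``imputed=True`` when none exist.
    """
    concept = dictionary[concept_id]  # raises KeyError for unknown concepts
    start, end = window
    rows = measurements[measurements["concept_id"] == concept_id]
    vals = rows.loc[(rows["time"] > start) & (rows["time"] <= end), "value"]
    if vals.empty:
        return concept.normal_value, True
    worst = vals.max() if concept.worst_direction == "higher_worse" else vals.min()
    return float(worst), False


def neq_rate(active_events: pd.DataFrame, neq_table: NeqTable) -> float:
    """Total norepinephrine-equivalent rate of concurrently active infusions."""
    if len(active_events) == 0:
        return 0.0
    factors = active_events["drug_id"].map(neq_table.factor)
    return float((active_events["rate"] * factors).sum())


def neq_at_times(
    vaso_events: pd.DataFrame, times: np.ndarray, neq_table: NeqTable
) -> np.ndarray:
    """NEQ(t) for an array of times against one stay's vasopressor events.

    An infusion contributes at t iff ``start <= t < end``.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for ev in vaso_events.itertuples(index=False):
        factor = neq_table.factor(ev.drug_id)
        active = (times >= ev.start) & (times < ev.end)
        out[active] += ev.rate * factor
    return out


def adjusted_map(map_mmHg: float, neq: float, beta: float = 200.0) -> float:
    """Vasopressor-adjusted MAP: ``map - beta * neq`` (may be negative)."""
    return map_mmHg - beta * neq


def _merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def sedation_windows(
    medications: pd.DataFrame,
    rass_measurements: pd.DataFrame | None = None,
    source: Literal["drug_list", "rass"] = "drug_list",
    stay_end: float | None = None,
) -> list[tuple[float, float]]:
    """Merged sedation intervals for one stay.

    ``drug_list``: the union of [start, end] intervals of listed sedative
    drugs (any administration overlap counts, bolus or infusion).
    ``rass``: carry-forward intervals from each RASS reading <= -2 until the
    next reading (or ``stay_end``).
    """
    if source == "drug_list":
        sed = medications[
            (medications["drug_class"] == "sedative")
            | (medications["drug_id"].isin(SEDATIVE_DRUGS))
        ]
        return _merge_intervals(zip(sed["start"], sed["end"]))
    if source == "rass":
        if rass_measurements is None or rass_measurements.empty:
            return []
        rass = rass_measurements.sort_values("time")
        times = rass["time"].to_numpy()
        vals = rass["value"].to_numpy()
        intervals = []
        for i, (t, v) in enumerate(zip(times, vals)):
            if v <= -2:
                nxt = times[i + 1] if i + 1 < len(times) else (
                    stay_end if stay_end is not None else times[-1]
                )
                intervals.append((float(t), float(nxt)))
        return _merge_intervals(intervals)
    raise ValueError(f"unknown sedation source: {source!r}")


def _in_windows(times: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in windows:
        mask |= (times >= s) & (times <= e)
    return mask


def sedation_adjusted_gcs(
    gcs_series: pd.DataFrame,
    windows: Sequence[tuple[float, float]],
    policy: Literal["set_max_15", "carry_forward", "raw"],
) -> pd.DataFrame:
    """Apply a sedation-adjustment policy to a (time, value) GCS series.

    * ``set_max_15`` — readings inside a sedation window become 15.
    * ``carry_forward`` — readings inside a window are replaced by the last
      reading strictly before the window start (dropped if none exists).
    * ``raw`` — unchanged.
    """
    if len(gcs_series) and not gcs_series["value"].between(3, 15).all():
        bad = gcs_series.loc[~gcs_series["value"].between(3, 15), "value"].tolist()
        raise ValueError(f"GCS values outside [3, 15]: {bad}")
    out = gcs_series.sort_values("time").reset_index(drop=True).copy()
    if policy == "raw" or not windows or out.empty:
        return out
    times = out["time"].to_numpy()
    if policy == "set_max_15":
        out.loc[_in_windows(times, windows), "value"] = 15.0
        return out
    if policy == "carry_forward":
        drop: list[int] = []
        for s, e in windows:
            inside = np.flatnonzero((times >= s) & (times <= e))
            if inside.size == 0:
                continue
            before = out.loc[out["time"] < s]
            if before.empty:
                drop.extend(inside.tolist())
            else:
                out.loc[inside, "value"] = before["value"].iloc[-1]
        if drop:
            out = out.drop(index=drop).reset_index(drop=True)
        return out
    raise ValueError(f"unknown GCS policy: {policy!r}")


def _vaso_extrema_in_window(
    vaso: pd.DataFrame,
    window: tuple[float, float],
    neq_table: NeqTable,
) -> tuple[float, float, float]:
    """(max NEQ, max dopamine rate, max norepi+epi rate) over a window.

    NEQ(t) is piecewise constant, so its maximum over the window is attained
    at the window start or at an event start inside the window.
    """
    start, end = window
    overlap = vaso[(vaso["start"] < end) & (vaso["end"] > start)]
    if overlap.empty:
        return 0.0, 0.0, 0.0
    cand = np.unique(np.clip(overlap["start"].to_numpy(), start, np.nextafter(end, start)))
    cand = np.append(cand, start)
    neq_max = float(neq_at_times(overlap, cand, neq_table).max())
    dopa = overlap[overlap["drug_id"] == "dopamine"]
    cat = overlap[overlap["drug_id"].isin(["norepinephrine", "epinephrine"])]
    dopa_max = float(dopa["rate"].max()) if len(dopa) else 0.0
    cat_max = float(cat["rate"].max()) if len(cat) else 0.0
    return neq_max, dopa_max, cat_max


def build_feature_matrix(
    cohort: pd.DataFrame,
    tables: EhrTables,
    dictionary: ConceptDictionary,
    T: float,
    score_def: ScoreDefinition,
    lookback: float = 24.0,
    neq_table: NeqTable | None = None,
    sedation_source: Literal["drug_list", "rass"] = "drug_list",
) -> pd.DataFrame:
    """Landmark feature matrix at time ``T`` for the included cohort stays.

    Rows: included stays still alive and in the ICU at T (icu_discharge > T
    and death, if any, after T).  Columns: one worst value per dictionary
    concept (plus ``<concept>_imputed`` flags) over the window (T - lookback,
    T], with ``map_adjusted`` and ``gcs`` computed from the score
    definition's beta / sedation policy before extraction, plus auxiliary
    vasopressor-dose columns used by the classic SOFA cardiovascular banding.
    """
    if T <= 0:
        raise ValueError("landmark time T must be > 0")
    neq_table = neq_table or load_neq_table(score_def.neq_table)
    window = (T - lookback, T)

    stays = tables.stays.set_index("stay_id")
    included = stays.loc[cohort.loc[cohort["included"], "stay_id"]]
    alive_mask = (included["icu_discharge"] > T) & (
        included["death_time"].isna() | (included["death_time"] > T)
    )
    alive = included.index[alive_mask]
    alive_pos = pd.Series(np.arange(len(alive)), index=alive)
    n = len(alive)

    meas = tables.measurements
    meas_w = meas[
        (meas["time"] > window[0])
        & (meas["time"] <= window[1])
        & meas["stay_id"].isin(alive)
    ]
    meds = tables.medications
    vaso_all = meds[meds["drug_class"] == "vasopressor"]
    vaso_by_stay = dict(tuple(vaso_all[vaso_all["stay_id"].isin(alive)].groupby("stay_id")))

    out = pd.DataFrame({"stay_id": alive, "T": T}).reset_index(drop=True)

    # plain concepts: grouped max/min, imputation for absent groups
    plain_concepts = [
        c for c in dictionary.concept_ids if c not in ("map_adjusted", "gcs")
    ]
    agg = (
        meas_w[meas_w["concept_id"].isin(plain_concepts)]
        .groupby(["stay_id", "concept_id"])["value"]
        .agg(["max", "min"])
    )
    for cid in plain_concepts:
        concept = dictionary[cid]
        col = np.full(n, concept.normal_value)
        imputed = np.ones(n, dtype=bool)
        if cid in agg.index.get_level_values("concept_id"):
            sub = agg.xs(cid, level="concept_id")
            pos = alive_pos.loc[sub.index].to_numpy()
            which = "max" if concept.worst_direction == "higher_worse" else "min"
            col[pos] = sub[which].to_numpy()
            imputed[pos] = False
        out[cid] = col
        out[f"{cid}_imputed"] = imputed

    # vasopressor-adjusted MAP, NEQ evaluated at each MAP measurement time
    map_rows = meas_w[meas_w["concept_id"] == "map"].reset_index(drop=True)
    adj_col = np.full(n, dictionary["map_adjusted"].normal_value)
    adj_imp = np.ones(n, dtype=bool)
    if len(map_rows):
        neq = np.zeros(len(map_rows))
        if len(vaso_all):
            merged = map_rows.reset_index().merge(
                vaso_all[["stay_id", "drug_id", "start", "end", "rate"]], on="stay_id"
            )
            active = merged[(merged["time"] >= merged["start"]) & (merged["time"] < merged["end"])]
            if len(active):
                contrib = active["rate"] * active["drug_id"].map(neq_table.factor)
                sums = contrib.groupby(active["index"]).sum()
                neq[sums.index.to_numpy()] = sums.to_numpy()
        adj = map_rows["value"].to_numpy() - score_def.map_adjustment_beta * neq
        worst = pd.Series(adj).groupby(map_rows["stay_id"].to_numpy()).min()
        pos = alive_pos.loc[worst.index].to_numpy()
        adj_col[pos] = worst.to_numpy()
        adj_imp[pos] = False
    out["map_adjusted"] = adj_col
    out["map_adjusted_imputed"] = adj_imp

    # sedation-adjusted GCS
    gcs_rows = meas_w[meas_w["concept_id"] == "gcs"]
    gcs_col = np.full(n, dictionary["gcs"].normal_value)
    gcs_imp = np.ones(n, dtype=bool)
    if len(gcs_rows):
        policy = score_def.gcs_policy
        if policy == "raw":
            worst = gcs_rows.groupby("stay_id")["value"].min()
        elif policy == "set_max_15" and sedation_source == "drug_list":
            # vectorised: a reading inside any sedative interval becomes 15
            sed = meds[
                (meds["drug_class"] == "sedative")
                | (meds["drug_id"].isin(SEDATIVE_DRUGS))
            ]
            g = gcs_rows.reset_index(drop=True)
            vals = g["value"].to_numpy().copy()
            if len(sed):
                merged = g.reset_index().merge(
                    sed[["stay_id", "start", "end"]], on="stay_id"
                )
                hit = merged.loc[
                    (merged["time"] >= merged["start"]) & (merged["time"] <= merged["end"]),
                    "index",
                ].unique()
                vals[hit] = 15.0
            worst = pd.Series(vals).groupby(g["stay_id"].to_numpy()).min()
        else:
            # carry_forward / RASS-based: per-stay interval logic
            med_by_stay = dict(tuple(meds[meds["stay_id"].isin(alive)].groupby("stay_id")))
            empty_meds = meds.iloc[0:0]
            worst_d: dict = {}
            for sid, g in meas_w.groupby("stay_id"):
                grows = g.loc[g["concept_id"] == "gcs", ["time", "value"]]
                if grows.empty:
                    continue
                stay_meds = med_by_stay.get(sid, empty_meds)
                if sedation_source == "rass":
                    rass_rows = g.loc[g["concept_id"] == "rass", ["time", "value"]]
                    windows = sedation_windows(
                        stay_meds, rass_rows, source="rass",
                        stay_end=float(stays.loc[sid, "icu_discharge"]),
                    )
                else:
                    windows = sedation_windows(stay_meds, source="drug_list")
                adj_gcs = sedation_adjusted_gcs(grows, windows, policy)
                if not adj_gcs.empty:
                    worst_d[sid] = float(adj_gcs["value"].min())
            worst = pd.Series(worst_d, dtype=float)
        if len(worst):
            pos = alive_pos.loc[worst.index].to_numpy()
            gcs_col[pos] = worst.to_numpy()
            gcs_imp[pos] = False
    out["gcs"] = gcs_col
    out["gcs_imputed"] = gcs_imp

    # vasopressor dose extrema (classic SOFA cardiovascular inputs)
    neq_max = np.zeros(n)
    dopa_max = np.zeros(n)
    cat_max = np.zeros(n)
    for sid, vaso in vaso_by_stay.items():
        i = alive_pos.loc[sid]
        neq_max[i], dopa_max[i], cat_max[i] = _vaso_extrema_in_window(
            vaso, window, neq_table
        )
    out["neq_max"] = neq_max
    out["dopamine_rate_max"] = dopa_max
    out["catecholamine_rate_max"] = cat_max

    columns = ["stay_id", "T"]
    for cid in dictionary.concept_ids:
        columns += [cid, f"{cid}_imputed"]
    columns += list(AUX_COLUMNS)
    out = out[columns]
    out.attrs["landmark_T"] = T
    return out
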