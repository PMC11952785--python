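"""Application of score definitions to feature matrices.

Each organ-domain component maps the worst value of its biomarker to a
sub-score in {0..4}: the highest level k whose band condition holds
(``ge``: value >= t_k; ``lt``: value < t_k), zero if none.  The total is the
sum of sub-scores.  Imputed normal values are scored like real values; the
dictionary invariant guarantees they land in band 0.

The classic SOFA cardiovascular component (``kind="sofa_cardiovascular"``)
bands on vasopressor dose instead: hypotension (MAP below the level-1 cut)
scores 1; dopamine <= 5 ug/kg/min scores 2; dopamine > 5 or
norepinephrine/epinephrine <= 0.1 scores 3; dopamine > 15 or
norepinephrine/epinephrine > 0.1 scores 4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ehr_model import ScoreComponent, ScoreDefinition, load_score_definition

__all__ = ["band_level", "component_score", "score_stays", "sofa_baseline"]


def band_level(
    values: np.ndarray | float,
    thresholds: list[float] | np.ndarray,
    inequality: str,
) -> np.ndarray | int:
    """Vectorised band level: number of threshold conditions satisfied.

    Thresholds must be ordered so that the conditions nest (increasing for
    ``ge``, decreasing for ``lt``); duplicate thresholds yield degenerate
    (skipped) levels, which is deliberate.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if inequality == "ge":
        level = (v[..., None] >= t).sum(axis=-1)
    elif inequality == "lt":
        level = (v[..., None] < t).sum(axis=-1)
    else:
        raise ValueError(f"unknown inequality: {inequality!r}")
    return level if level.ndim else int(level)


def component_score(value: float, component: ScoreComponent) -> int:
    """Sub-score (0-4) of a single worst value under one band component."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite value for component {component.domain}")
    if component.kind != "bands":
        raise ValueError(
            "dose-based cardiovascular components need score_stays (they use "
            "vasopressor columns, not a single value)"
        )
    return int(band_level(value, component.thresholds, component.inequality))


def _sofa_cardio_level(features: pd.DataFrame, component: ScoreComponent) -> np.ndarray:
    map_cut = component.thresholds[0]
    hypo = features["map"].to_numpy() < map_cut
    dopa = features["dopamine_rate_max"].to_numpy()
    cat = features["catecholamine_rate_max"].to_numpy()
    level = np.zeros(len(features), dtype=int)
    level[hypo] = 1
    level[(dopa > 0) & (dopa <= 5)] = 2
    level[(dopa > 5) | ((cat > 0) & (cat <= 0.1))] = 3
    level[(dopa > 15) | (cat > 0.1)] = 4
    return level


def score_stays(features: pd.DataFrame, score_def: ScoreDefinition) -> pd.DataFrame:
    """Score every stay in a feature matrix under one score definition.

    Returns a frame with ``stay_id``, ``T``, one sub-score column per domain
    and the ``total``.
    """
    out = pd.DataFrame({"stay_id": features["stay_id"], "T": features["T"]})
    total = np.zeros(len(features), dtype=int)
    for comp in score_def.components:
        if comp.kind == "sofa_cardiovascular":
            needed = ["map", "dopamine_rate_max", "catecholamine_rate_max"]
            missing = [c for c in needed if c not in features.columns]
            if missing:
                raise KeyError(f"feature matrix is missing column(s) {missing}")
            level = _sofa_cardio_level(features, comp)
        else:
            if comp.concept_id not in features.columns:
                raise KeyError(
                    f"feature matrix is missing concept column {comp.concept_id!r} "
                    f"needed by the {comp.domain} component"
                )
            level = np.asarray(
                band_level(
                    features[comp.concept_id].to_numpy(), comp.thresholds, comp.inequality
                )
            )
        out[comp.domain] = level
        total += level
    out["total"] = total
    out.attrs["score_name"] = score_def.name
    return out


def sofa_baseline(features: pd.DataFrame) -> pd.DataFrame:
    """Score stays with the shipped classic-SOFA comparator definition."""
    return score_stays(features, load_score_definition("sofa_baseline"))
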