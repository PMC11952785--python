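"""Data-driven score construction: biomarker ranking, AUROC-maximising
threshold search, per-domain feature selection, constrained (LMIC) builds,
and the ablation procedure.

The constructor turns each organ domain into a single-biomarker component
with four thresholds by maximising the AUROC of the induced 0-4 ordinal
sub-score for in-hospital mortality on the development cohorts.  Candidate
thresholds come from a quantile grid of the development distribution; the
search enumerates threshold multisets exhaustively when the space is small
and otherwise uses a beam search over nested multisets (the exhaustive mode
doubles as the test oracle for the beam).  Duplicate thresholds are allowed
during the search (they create degenerate, skipped levels); ties are broken
toward the least-extreme thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from sklearn.metrics import roc_auc_score

from .ehr_model import ConceptDictionary, ScoreComponent, ScoreDefinition

__all__ = [
    "ThresholdSearchSpec",
    "ThresholdResult",
    "rank_biomarkers",
    "optimize_thresholds",
    "select_domain_feature",
    "build_score",
    "ablation_study",
]

logger = logging.getLogger(__name__)

# Concepts that are never score candidates (instruments, not organ markers).
NON_CANDIDATE_CONCEPTS = ("rass",)

LabeledMatrix = tuple[pd.DataFrame, np.ndarray]


class ThresholdSearchSpec(BaseModel):
    """Parameters of the AUROC-maximising threshold search."""

    n_thresholds: int = Field(default=4, ge=1)
    n_quantiles: int = Field(default=99, ge=1)  # grid at k/(n_quantiles+1) quantiles
    search_mode: Literal["auto", "exhaustive", "beam"] = "auto"
    beam_width: int = Field(default=50, ge=1)
    exhaustive_limit: int = 20000  # max multisets before auto switches to beam


@dataclass
class ThresholdResult:
    """Outcome of one threshold search (thresholds on the original scale)."""

    thresholds: tuple[float, ...]
    inequality: Literal["ge", "lt"]
    auroc: float


def _ordinal_auroc(levels: np.ndarray, n_pos_at: np.ndarray | None, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC for small-integer scores via level/label counts."""
    K = levels.max() + 1
    pos = np.bincount(levels[labels == 1], minlength=K).astype(float)
    neg = np.bincount(levels[labels == 0], minlength=K).astype(float)
    P, N = pos.sum(), neg.sum()
    cum_neg = np.concatenate(([0.0], np.cumsum(neg)[:-1]))
    return float((pos * (cum_neg + 0.5 * neg)).sum() / (P * N))


def oriented_values(values: np.ndarray, direction: str) -> np.ndarray:
    """Map values so that larger always means worse."""
    values = np.asarray(values, dtype=float)
    return values if direction == "higher_worse" else -values


def candidate_grid(values: np.ndarray, spec: ThresholdSearchSpec) -> np.ndarray:
    """Strictly sorted, deduplicated quantile grid (original scale)."""
    qs = np.arange(1, spec.n_quantiles + 1) / (spec.n_quantiles + 1)
    return np.unique(np.quantile(np.asarray(values, float), qs))


def _level_matrix(values: np.ndarray, grid: np.ndarray, inequality: str) -> np.ndarray:
    """Boolean (n, m): does value i satisfy the band condition at grid point j."""
    v = values[:, None]
    g = grid[None, :]
    return (v >= g) if inequality == "ge" else (v < g)


def _search(
    ind: np.ndarray, labels: np.ndarray, K: int, spec: ThresholdSearchSpec
) -> tuple[tuple[int, ...], float]:
    """Find the multiset of K grid columns maximising ordinal AUROC.

    Ties break toward the lexicographically smallest index tuple, which (with
    the grid ordered from least to most extreme) is the least-extreme choice.
    """
    n, m = ind.shape
    n_multisets = comb(m + K - 1, K)
    exhaustive = spec.search_mode == "exhaustive" or (
        spec.search_mode == "auto" and n_multisets <= spec.exhaustive_limit
    )
    icols = ind.astype(np.int8)
    if exhaustive:
        best: tuple[float, tuple[int, ...]] | None = None
        for combo in combinations_with_replacement(range(m), K):
            levels = icols[:, combo].sum(axis=1, dtype=np.int64)
            a = _ordinal_auroc(levels, None, labels)
            key = (-a, combo)
            if best is None or key < best:
                best = key
        assert best is not None
        return best[1], -best[0]
    # beam search over nested multisets (indices non-decreasing) ...
    beam: list[tuple[float, tuple[int, ...], np.ndarray]] = [
        (0.0, (), np.zeros(n, dtype=np.int64))
    ]
    for depth in range(K):
        expansions: list[tuple[float, tuple[int, ...]]] = []
        lev_cache: dict[tuple[int, ...], np.ndarray] = {}
        for _, combo, levels in beam:
            start = combo[-1] if combo else 0
            for j in range(start, m):
                new_combo = combo + (j,)
                new_levels = levels + icols[:, j]
                a = _ordinal_auroc(new_levels, None, labels)
                expansions.append((a, new_combo))
                lev_cache[new_combo] = new_levels
        expansions.sort(key=lambda t: (-t[0], t[1]))
        beam = [
            (a, combo, lev_cache[combo]) for a, combo in expansions[: spec.beam_width]
        ]
    # ... then cyclic coordinate ascent on the best beam states: the greedy
    # nesting can strand a good low threshold behind a poor prefix, and the
    # refinement recovers it at O(K * m) evaluations per pass.
    results: list[tuple[float, tuple[int, ...]]] = []
    for a, combo, levels in beam[: min(5, len(beam))]:
        combo_l = list(combo)
        improved = True
        while improved:
            improved = False
            for pos in range(K):
                base = levels - icols[:, combo_l[pos]]
                best_j, best_a = combo_l[pos], a
                for j in range(m):
                    cand_a = _ordinal_auroc(base + icols[:, j], None, labels)
                    if cand_a > best_a + 1e-12:
                        best_j, best_a = j, cand_a
                if best_j != combo_l[pos]:
                    levels = base + icols[:, best_j]
                    combo_l[pos] = best_j
                    a = best_a
                    improved = True
        results.append((a, tuple(sorted(combo_l))))
    results.sort(key=lambda t: (-t[0], t[1]))
    return results[0][1], results[0][0]


def optimize_thresholds(
    values: Sequence[float],
    outcome: Sequence[int],
    direction: str,
    spec: ThresholdSearchSpec | None = None,
    grid: np.ndarray | None = None,
) -> ThresholdResult:
    """AUROC-maximising K-threshold banding of one biomarker.

    The induced ordinal score of a value is the number of band conditions it
    satisfies (``>= t_k`` for higher-worse markers, ``< t_k`` strictly for
    lower-worse markers).  Returns thresholds on the original scale, ordered
    for their inequality (increasing for ``ge``, decreasing for ``lt``),
    possibly with duplicates, plus the achieved AUROC.
    """
    spec = spec or ThresholdSearchSpec()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(outcome, dtype=int)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if labels.min() == labels.max():
        raise ValueError("outcome must contain both classes")
    if grid is None:
        grid = candidate_grid(values, spec)
    else:
        grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size < 1:
        raise ValueError("candidate grid must contain at least one point")

    inequality = "ge" if direction == "higher_worse" else "lt"
    # order the grid least-extreme-first so lexicographic tie-break is
    # least-extreme-first: ascending for ge, descending for lt
    ordered = grid if inequality == "ge" else grid[::-1]
    ind = _level_matrix(values, ordered, inequality)
    combo, auc = _search(ind, labels, spec.n_thresholds, spec)
    thresholds = tuple(float(ordered[j]) for j in combo)
    return ThresholdResult(thresholds=thresholds, inequality=inequality, auroc=auc)


def rank_biomarkers(
    dev_matrices: Sequence[LabeledMatrix],
    dictionary: ConceptDictionary,
    concepts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank biomarkers by mean single-feature AUROC across development cohorts.

    Each feature is oriented by its worst direction before the AUROC is
    computed, so predictive lower-worse markers also score above 0.5.
    """
    if len(dev_matrices) == 0:
        raise ValueError("at least one development cohort is required")
    concepts = list(concepts) if concepts is not None else [
        c for c in dictionary.concept_ids
        if c not in NON_CANDIDATE_CONCEPTS
        and all(c in X.columns for X, _ in dev_matrices)
    ]
    rows = []
    for cid in concepts:
        per_cohort = []
        for X, y in dev_matrices:
            y = np.asarray(y, int)
            if y.min() == y.max():
                raise ValueError("outcome must contain both classes")
            v = oriented_values(X[cid].to_numpy(), dictionary[cid].worst_direction)
            per_cohort.append(float(roc_auc_score(y, v)))
        rows.append(
            {"concept_id": cid,
             **{f"auroc_{i}": a for i, a in enumerate(per_cohort)},
             "mean_auroc": float(np.mean(per_cohort))}
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_auroc", "concept_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _strictify(thresholds: tuple[float, ...], inequality: str) -> list[float]:
    """Separate duplicate thresholds by the smallest representable step so the
    component validates; the induced scoring is unchanged on observed data."""
    out: list[float] = []
    for t in thresholds:
        while out and (t <= out[-1] if inequality == "ge" else t >= out[-1]):
            t = np.nextafter(out[-1], np.inf if inequality == "ge" else -np.inf)
        out.append(float(t))
    return out


def _fit_component(
    cid: str,
    domain: str,
    dev_matrices: Sequence[LabeledMatrix],
    dictionary: ConceptDictionary,
    spec: ThresholdSearchSpec,
) -> tuple[ScoreComponent, float]:
    """Optimise thresholds on pooled development data, score by mean
    per-cohort AUROC of the fitted component."""
    pooled_v = np.concatenate([X[cid].to_numpy() for X, _ in dev_matrices])
    pooled_y = np.concatenate([np.asarray(y, int) for _, y in dev_matrices])
    direction = dictionary[cid].worst_direction
    res = optimize_thresholds(pooled_v, pooled_y, direction, spec)
    comp = ScoreComponent(
        domain=domain,
        concept_id=cid,
        thresholds=_strictify(res.thresholds, res.inequality),
        inequality=res.inequality,
        unit=dictionary[cid].unit,
    )
    from .scorer import band_level  # local import avoids a cycle

    per_cohort = [
        _ordinal_auroc(
            np.asarray(band_level(X[cid].to_numpy(), comp.thresholds, comp.inequality)),
            None,
            np.asarray(y, int),
        )
        for X, y in dev_matrices
    ]
    return comp, float(np.mean(per_cohort))


def _domain_candidates(
    domain: str,
    dictionary: ConceptDictionary,
    available: set[str],
    lmic: bool = False,
    exclude: Sequence[str] = (),
) -> list[str]:
    out = []
    for c in dictionary.by_domain(domain):
        if c.concept_id in NON_CANDIDATE_CONCEPTS or c.concept_id in exclude:
            continue
        if c.concept_id not in available:
            continue
        if lmic and c.requires_blood_gas:
            continue
        out.append(c.concept_id)
    return out


def select_domain_feature(
    domain: str,
    candidate_concepts: Sequence[str],
    dev_matrices: Sequence[LabeledMatrix],
    dictionary: ConceptDictionary,
    spec: ThresholdSearchSpec | None = None,
) -> tuple[ScoreComponent, pd.DataFrame]:
    """Best banded component for one domain among candidate concepts.

    Returns the winning component plus a ranking frame (concept, mean dev
    AUROC) whose runner-ups feed the ablation study.
    """
    spec = spec or ThresholdSearchSpec()
    if len(candidate_concepts) == 0:
        raise ValueError(f"domain {domain!r} has no candidate concepts")
    fits = []
    for cid in candidate_concepts:
        comp, mean_auc = _fit_component(cid, domain, dev_matrices, dictionary, spec)
        fits.append((mean_auc, cid, comp))
    fits.sort(key=lambda t: (-t[0], t[1]))
    ranking = pd.DataFrame(
        [{"concept_id": cid, "mean_auroc": a} for a, cid, _ in fits]
    )
    return fits[0][2], ranking


def _check_development_role(dev_matrices: Sequence[LabeledMatrix]) -> None:
    for X, _ in dev_matrices:
        role = X.attrs.get("cohort_role")
        if role == "validation":
            raise ValueError(
                "build_score received a feature matrix tagged as validation; "
                "score construction must use development cohorts only"
            )


def build_score(
    domains: Sequence[str],
    dev_matrices: Sequence[LabeledMatrix],
    dictionary: ConceptDictionary,
    spec: ThresholdSearchSpec | None = None,
    constraints: str | None = None,
    exclude: Mapping[str, Sequence[str]] | None = None,
    name: str = "data_driven",
    map_adjustment_beta: float = 200.0,
    gcs_policy: str = "set_max_15",
    allow_empty_domains: bool = False,
) -> ScoreDefinition:
    """Construct a multi-domain score on development feature matrices.

    ``constraints``: ``None``/"none" (unrestricted), ``"lmic"`` (exclude
    blood-gas concepts), ``"no_metabolic"`` (drop the metabolic domain).
    ``exclude`` removes specific concepts per domain (the ablation hook).
    With ``allow_empty_domains`` a domain whose candidate set empties is
    dropped with a warning instead of failing.
    """
    spec = spec or ThresholdSearchSpec()
    _check_development_role(dev_matrices)
    constraints = constraints or "none"
    if constraints not in ("none", "lmic", "no_metabolic"):
        raise ValueError(f"unknown constraint set: {constraints!r}")
    domains = [d for d in domains if not (constraints == "no_metabolic" and d == "metabolic")]
    exclude = exclude or {}
    available = set(dev_matrices[0][0].columns)
    components = []
    for domain in domains:
        cands = _domain_candidates(
            domain, dictionary, available,
            lmic=constraints == "lmic", exclude=exclude.get(domain, ()),
        )
        if not cands:
            if allow_empty_domains:
                logger.warning("domain %r has no eligible candidates; dropped", domain)
                continue
            raise ValueError(f"domain {domain!r} has no eligible candidate concepts")
        comp, _ = select_domain_feature(domain, cands, dev_matrices, dictionary, spec)
        components.append(comp)
    return ScoreDefinition(
        name=name,
        components=components,
        map_adjustment_beta=map_adjustment_beta,
        gcs_policy=gcs_policy,
    )


def _total_score(X: pd.DataFrame, score_def: ScoreDefinition) -> np.ndarray:
    from .scorer import score_stays

    return score_stays(X, score_def)["total"].to_numpy()


def ablation_study(
    score_def: ScoreDefinition,
    dev_matrices: Sequence[LabeledMatrix],
    val_matrices: Sequence[LabeledMatrix],
    dictionary: ConceptDictionary,
    spec: ThresholdSearchSpec | None = None,
    max_removed: int = 6,
) -> pd.DataFrame:
    """Remove winning biomarkers in combinations and rebuild with replacements.

    For every subset (up to ``max_removed``) of the removable domain winners
    (CNS is never removed), the affected domains are re-selected with the
    winner excluded and the rebuilt score is evaluated on the validation
    cohorts.  Reports the mean validation AUROC and the delta against the
    unrestricted score.  A domain left with no replacement candidates is
    dropped with a logged warning.
    """
    spec = spec or ThresholdSearchSpec()
    _check_development_role(dev_matrices)
    winners = {c.domain: c for c in score_def.components}
    removable = [d for d in score_def.domains if d != "cns"]
    available = set(dev_matrices[0][0].columns)

    # one replacement fit per domain: the best component with the winner excluded
    replacements: dict[str, ScoreComponent | None] = {}
    for domain in removable:
        cands = _domain_candidates(
            domain, dictionary, available, exclude=[winners[domain].concept_id]
        )
        if not cands:
            logger.warning("ablation: domain %r has no replacement; dropped", domain)
            replacements[domain] = None
            continue
        comp, _ = select_domain_feature(domain, cands, dev_matrices, dictionary, spec)
        replacements[domain] = comp

    def mean_val_auroc(sdef: ScoreDefinition) -> float:
        aucs = []
        for X, y in val_matrices:
            total = _total_score(X, sdef)
            aucs.append(float(roc_auc_score(np.asarray(y, int), total)))
        return float(np.mean(aucs))

    base_auroc = mean_val_auroc(score_def)
    rows = []
    for k in range(0, min(max_removed, len(removable)) + 1):
        for removed in combinations(removable, k):
            comps = []
            for comp in score_def.components:
                if comp.domain in removed:
                    repl = replacements[comp.domain]
                    if repl is not None:
                        comps.append(repl)
                else:
                    comps.append(comp)
            sdef = ScoreDefinition(
                name=f"{score_def.name}_ablate_{'-'.join(removed) or 'none'}",
                components=comps,
                map_adjustment_beta=score_def.map_adjustment_beta,
                gcs_policy=score_def.gcs_policy,
                neq_table=score_def.neq_table,
            )
            val_auroc = mean_val_auroc(sdef)
            rows.append(
                {"removed": ",".join(removed), "n_removed": k,
                 "n_components": len(comps), "val_auroc": val_auroc,
                 "delta_auroc": val_auroc - base_auroc}
            )
    return pd.DataFrame(rows)
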