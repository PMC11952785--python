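"""Score evaluation: discrimination, landmark-time analysis, per-level
mortality, and logistic recalibration.

Discrimination is measured by AUROC (Mann-Whitney, with the standard 1/2
credit for ties) and AUPRC (average precision, the non-interpolated
step-wise integral of the precision-recall curve).  Confidence intervals are
seeded percentile-bootstrap intervals over stay-level resamples.

Calibration follows the two-stage recalibration convention: a logistic model
of death on the total score is fitted on the development cohort, and a
second logistic model of validation outcomes on the stage-1 linear predictor
yields the calibration intercept and slope with Wald 95% CIs.  A score is
flagged calibrated when the intercept CI contains 0 and the slope CI
contains 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import average_precision_score, roc_auc_score

from .ehr_model import ConceptDictionary, EhrTables, NeqTable, ScoreDefinition
from .features import build_feature_matrix
from .scorer import score_stays

__all__ = [
    "auroc",
    "auprc",
    "bootstrap_ci",
    "compare_auroc",
    "overtime_eval",
    "per_level_mortality",
    "CalibrationReport",
    "calibrate",
]

DEFAULT_T_GRID = tuple(range(6, 25, 2))


def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("at least one positive label is required")
    return float(average_precision_score(labels, scores))


def _weighted_auroc(pos_w: np.ndarray, neg_w: np.ndarray) -> float:
    """AUROC from per-score-group positive/negative weights (ascending order)."""
    P, N = pos_w.sum(), neg_w.sum()
    cum_neg = np.concatenate(([0.0], np.cumsum(neg_w)[:-1]))
    return float((pos_w * (cum_neg + 0.5 * neg_w)).sum() / (P * N))


def _weighted_ap(pos_w: np.ndarray, neg_w: np.ndarray) -> float:
    """Average precision from per-group weights (groups ascending by score)."""
    tp = np.cumsum(pos_w[::-1])
    fp = np.cumsum(neg_w[::-1])
    P = tp[-1]
    denom = tp + fp
    precision = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
    recall_step = pos_w[::-1] / P
    return float((precision * recall_step).sum())


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a (scores, labels) metric.

    Resamples stays with replacement; a resample that loses one outcome
    class is redrawn (at most 10 retries, then failure).  For the built-in
    AUROC/AUPRC metrics the resample is carried as multinomial weights over
    tied-score groups, which is algebraically identical to recomputing the
    metric on the resampled rows but much cheaper.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(scores)
    stats = np.empty(B)
    fast = metric_fn is auroc or metric_fn is auprc
    if fast:
        _, gid = np.unique(scores, return_inverse=True)  # ascending groups
        G = gid.max() + 1
        wfn = _weighted_auroc if metric_fn is auroc else _weighted_ap
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
        else:
            raise ValueError("bootstrap resample degenerate: one class after 10 retries")
        if fast:
            g = gid[idx]
            pos_w = np.bincount(g[lab == 1], minlength=G).astype(float)
            neg_w = np.bincount(g[lab == 0], minlength=G).astype(float)
            stats[b] = wfn(pos_w, neg_w)
        else:
            stats[b] = metric_fn(scores[idx], lab)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def compare_auroc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired-bootstrap two-sided test for AUROC(a) - AUROC(b).

    Returns ``(delta, p_value)`` where delta is the observed difference and
    the p-value comes from centring the bootstrap distribution of the paired
    difference at zero.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    delta = auroc(a, labels) - auroc(b, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    diffs = np.empty(B)
    for i in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        else:
            raise ValueError("bootstrap resample degenerate")
        diffs[i] = auroc(a[idx], labels[idx]) - auroc(b[idx], labels[idx])
    p = 2 * min(np.mean(diffs - delta >= delta), np.mean(diffs - delta <= delta))
    return float(delta), float(min(1.0, p))


def overtime_eval(
    cohort: pd.DataFrame,
    tables: EhrTables,
    dictionary: ConceptDictionary,
    score_defs: Mapping[str, ScoreDefinition],
    T_grid: Sequence[float] = DEFAULT_T_GRID,
    lookback: float = 24.0,
    B: int = 1000,
    seed: int = 0,
    bootstrap: bool = True,
) -> pd.DataFrame:
    """Landmark evaluation over a grid of times (default 6..24 h, step 2).

    At every T, stays alive and in the ICU form the landmark cohort; all
    score definitions are evaluated on that same set of stays.  Returns one
    row per (score, T) with AUROC/AUPRC and optional bootstrap CIs; empty
    landmark cohorts yield n = 0 rows with null metrics.
    """
    if len(T_grid) == 0:
        raise ValueError("T grid must be non-empty")
    death = tables.stays.set_index("stay_id")["hospital_death"]
    rng = np.random.default_rng(seed)
    rows = []
    for T in T_grid:
        # features are policy-dependent; build once per distinct policy signature
        matrices: dict[tuple, pd.DataFrame] = {}
        for name, sdef in score_defs.items():
            key = (sdef.map_adjustment_beta, sdef.gcs_policy, sdef.neq_table)
            if key not in matrices:
                matrices[key] = build_feature_matrix(
                    cohort, tables, dictionary, T, sdef, lookback=lookback
                )
            feats = matrices[key]
            if feats.empty:
                rows.append(
                    {"score": name, "T": T, "n": 0, "prevalence": np.nan,
                     "auroc": np.nan, "auroc_lo": np.nan, "auroc_hi": np.nan,
                     "auprc": np.nan, "auprc_lo": np.nan, "auprc_hi": np.nan}
                )
                continue
            scored = score_stays(feats, sdef)
            labels = death.loc[scored["stay_id"]].to_numpy().astype(int)
            total = scored["total"].to_numpy()
            rec = {
                "score": name, "T": T, "n": len(labels),
                "prevalence": float(labels.mean()),
                "auroc": auroc(total, labels), "auprc": auprc(total, labels),
                "auroc_lo": np.nan, "auroc_hi": np.nan,
                "auprc_lo": np.nan, "auprc_hi": np.nan,
            }
            if bootstrap:
                rec["auroc_lo"], rec["auroc_hi"] = bootstrap_ci(
                    auroc, total, labels, B=B, seed=rng
                )
                rec["auprc_lo"], rec["auprc_hi"] = bootstrap_ci(
                    auprc, total, labels, B=B, seed=rng
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def per_level_mortality(scored: pd.DataFrame, labels: Sequence[int]) -> pd.DataFrame:
    """Empirical death fraction per (domain, sub-score level).

    Levels with no stays are absent from the output.
    """
    labels = np.asarray(labels, dtype=int)
    domains = [
        c for c in scored.columns if c not in ("stay_id", "T", "total")
    ]
    rows = []
    for domain in domains:
        levels = scored[domain].to_numpy()
        for level in np.unique(levels):
            mask = levels == level
            rows.append(
                {"domain": domain, "level": int(level), "n": int(mask.sum()),
                 "mortality": float(labels[mask].mean())}
            )
    return pd.DataFrame(rows, columns=["domain", "level", "n", "mortality"])


@dataclass
class CalibrationReport:
    """Two-stage logistic recalibration result."""

    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    stage1_coef: tuple[float, float] = (np.nan, np.nan)  # (const, per-point)

    @property
    def calibrated(self) -> bool:
        return (
            self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1]
            and self.slope_ci[0] <= 1.0 <= self.slope_ci[1]
        )


def calibrate(
    dev_scores: Sequence[float],
    dev_labels: Sequence[int],
    val_scores: Sequence[float],
    val_labels: Sequence[int],
) -> CalibrationReport:
    """Logistic recalibration of a score fitted on development data.

    Stage 1 fits ``death ~ total score`` on the development cohort; stage 2
    refits validation outcomes on the stage-1 linear predictor.  Perfect
    transport gives intercept 0 and slope 1.
    """
    dev_scores = np.asarray(dev_scores, float)
    dev_labels = np.asarray(dev_labels, int)
    val_scores = np.asarray(val_scores, float)
    val_labels = np.asarray(val_labels, int)
    _check_classes(dev_labels)
    _check_classes(val_labels)

    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x1 = sm.add_constant(dev_scores)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            stage1 = sm.Logit(dev_labels, x1).fit(disp=0)
    except (PerfectSeparationWarning, Exception) as exc:
        if "separation" in str(exc).lower() or isinstance(exc, PerfectSeparationWarning):
            raise ValueError(f"stage-1 logistic fit is separated: {exc}") from exc
        raise ValueError(f"stage-1 logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(stage1.bse)):
        raise ValueError("stage-1 logistic fit is separated (infinite standard errors)")
    lp_val = stage1.params[0] + stage1.params[1] * val_scores

    x2 = sm.add_constant(lp_val)
    stage2 = sm.Logit(val_labels, x2).fit(disp=0)
    ci = stage2.conf_int(alpha=0.05)
    return CalibrationReport(
        intercept=float(stage2.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope=float(stage2.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        stage1_coef=(float(stage1.params[0]), float(stage1.params[1])),
    )
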