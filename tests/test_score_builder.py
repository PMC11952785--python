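"""Threshold search, biomarker ranking, domain selection, constrained builds,
and the ablation procedure."""

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import pytest

from sepscore.score_builder import (
    ThresholdSearchSpec,
    _ordinal_auroc,
    ablation_study,
    build_score,
    candidate_grid,
    optimize_thresholds,
    rank_biomarkers,
    select_domain_feature,
)

DOMAINS = ["liver", "renal", "cns", "metabolic", "cardiovascular",
           "respiratory", "coagulation"]


def _labeled_matrix(dictionary, n=800, seed=0, informative=True):
    """A development feature matrix whose markers carry severity signal."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-2.2 + 1.5 * z)))).astype(int)
    X = pd.DataFrame({"stay_id": [f"s{i}" for i in range(n)], "T": 24.0})
    for cid in dictionary.concept_ids:
        c = dictionary[cid]
        sign = 1.0 if c.worst_direction == "higher_worse" else -1.0
        load = 1.0 if informative else 0.0
        scale = max(abs(c.normal_value) * 0.3, 1.0)
        X[cid] = c.normal_value + sign * load * scale * z + rng.normal(0, scale * 0.5, n)
        X[f"{cid}_imputed"] = False
    X["neq_max"] = 0.0
    X["dopamine_rate_max"] = 0.0
    X["catecholamine_rate_max"] = 0.0
    return X, y


def exhaustive_best(values, labels, grid, K, inequality):
    """Brute-force oracle: enumerate every threshold multiset on the grid."""
    ordered = np.sort(grid) if inequality == "ge" else np.sort(grid)[::-1]
    ind = (values[:, None] >= ordered[None, :]) if inequality == "ge" else (
        values[:, None] < ordered[None, :]
    )
    best = None
    for combo in combinations_with_replacement(range(len(ordered)), K):
        lev = ind[:, combo].sum(axis=1)
        a = _ordinal_auroc(lev.astype(np.int64), None, labels)
        key = (-a, combo)
        if best is None or key < best:
            best = key
    return -best[0], tuple(float(ordered[j]) for j in best[1])


def test_rank_biomarkers_perfect_noise_and_mean(dictionary):
    rng = np.random.default_rng(1)
    n = 400
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"stay_id": range(n), "T": 24.0})
    X["lactate"] = y.astype(float)                      # perfect marker
    X["platelets"] = rng.normal(250, 50, n)             # pure noise (lower_worse)
    out = rank_biomarkers([(X, y)], dictionary, concepts=["lactate", "platelets"])
    by = out.set_index("concept_id")
    assert by.loc["lactate", "mean_auroc"] == 1.0
    assert by.loc["lactate", "rank"] == 1
    assert abs(by.loc["platelets", "mean_auroc"] - 0.5) < 0.08


def test_rank_biomarkers_null_feature_near_half(dictionary):
    rng = np.random.default_rng(2)
    n = 2000
    y = rng.integers(0, 2, n)
    X = pd.DataFrame({"stay_id": range(n), "T": 24.0, "lactate": rng.normal(2, 1, n)})
    out = rank_biomarkers([(X, y)], dictionary, concepts=["lactate"])
    assert abs(out.loc[0, "mean_auroc"] - 0.5) <= 0.03


def test_rank_biomarkers_averages_across_cohorts(dictionary):
    # two cohorts engineered to known per-cohort AUROCs average arithmetically
    X1 = pd.DataFrame({"stay_id": range(4), "T": 24.0, "lactate": [1.0, 2.0, 3.0, 4.0]})
    y1 = np.array([0, 0, 1, 1])   # AUROC 1.0
    X2 = pd.DataFrame({"stay_id": range(4), "T": 24.0, "lactate": [1.0, 2.0, 3.0, 4.0]})
    y2 = np.array([0, 1, 0, 1])   # AUROC 0.75
    out = rank_biomarkers([(X1, y1), (X2, y2)], dictionary, concepts=["lactate"])
    assert out.loc[0, "mean_auroc"] == pytest.approx((1.0 + 0.75) / 2)


def test_rank_biomarkers_single_class_fails(dictionary):
    X = pd.DataFrame({"stay_id": range(4), "T": 24.0, "lactate": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError, match="both classes"):
        rank_biomarkers([(X, np.zeros(4, int))], dictionary, concepts=["lactate"])


def test_optimize_thresholds_matches_exhaustive_enumeration():
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, 60)
    labels = (rng.random(60) < 1 / (1 + np.exp(-2 * values))).astype(int)
    grid = np.quantile(values, np.linspace(0.1, 0.9, 8))
    for K, direction in [(2, "higher_worse"), (2, "lower_worse")]:
        spec = ThresholdSearchSpec(n_thresholds=K, search_mode="beam", beam_width=50)
        res = optimize_thresholds(values, labels, direction, spec, grid=grid)
        ineq = "ge" if direction == "higher_worse" else "lt"
        oracle_auc, oracle_ths = exhaustive_best(values, labels, grid, K, ineq)
        assert res.auroc == pytest.approx(oracle_auc, abs=1e-12)
        spec_ex = ThresholdSearchSpec(n_thresholds=K, search_mode="exhaustive")
        res_ex = optimize_thresholds(values, labels, direction, spec_ex, grid=grid)
        assert res_ex.auroc == pytest.approx(oracle_auc, abs=1e-12)
        assert res_ex.thresholds == oracle_ths


def test_planted_single_cut_recovered():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 10, 5000)
    y = (rng.random(5000) < np.where(x >= 5.0, 0.9, 0.1)).astype(int)
    res = optimize_thresholds(x, y, "higher_worse")
    assert min(abs(t - 5.0) for t in res.thresholds) <= 0.5
    assert res.auroc > 0.85


def test_null_outcome_gives_near_half_auroc():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 2000)
    y = rng.integers(0, 2, 2000)
    res = optimize_thresholds(x, y, "higher_worse")
    assert res.auroc <= 0.55


def test_threshold_search_spaces_nest():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
    grid = np.quantile(x, np.linspace(0.05, 0.95, 12))
    res1 = optimize_thresholds(
        x, y, "higher_worse", ThresholdSearchSpec(n_thresholds=1, search_mode="exhaustive"),
        grid=grid,
    )
    res4 = optimize_thresholds(
        x, y, "higher_worse", ThresholdSearchSpec(n_thresholds=4, search_mode="exhaustive"),
        grid=grid,
    )
    assert res4.auroc >= res1.auroc - 1e-12


def test_monotone_transform_invariance():
    rng = np.random.default_rng(7)
    x = rng.uniform(0.5, 4, 400)
    y = (rng.random(400) < 1 / (1 + np.exp(-(x - 2)))).astype(int)
    grid = np.quantile(x, np.linspace(0.1, 0.9, 9))
    spec = ThresholdSearchSpec(n_thresholds=3, search_mode="exhaustive")
    res = optimize_thresholds(x, y, "higher_worse", spec, grid=grid)
    res_t = optimize_thresholds(np.exp(x), y, "higher_worse", spec, grid=np.exp(grid))
    assert res_t.auroc == pytest.approx(res.auroc, abs=1e-12)
    assert np.allclose(np.log(res_t.thresholds), res.thresholds, atol=1e-9)


def test_select_domain_feature_prefers_signal(dictionary):
    rng = np.random.default_rng(8)
    n = 1500
    z = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-2 + 1.5 * z)))).astype(int)
    X = pd.DataFrame({"stay_id": range(n), "T": 24.0})
    X["lactate"] = 2.0 + 1.0 * z + rng.normal(0, 0.5, n)      # informative
    X["bicarbonate"] = rng.normal(24, 3, n)                   # pure noise
    comp, ranking = select_domain_feature(
        "metabolic", ["lactate", "bicarbonate"], [(X, y)], dictionary
    )
    assert comp.concept_id == "lactate"
    assert ranking.loc[0, "concept_id"] == "lactate"
    assert len(ranking) == 2

    single, _ = select_domain_feature("metabolic", ["bicarbonate"], [(X, y)], dictionary)
    assert single.concept_id == "bicarbonate"
    with pytest.raises(ValueError, match="no candidate"):
        select_domain_feature("metabolic", [], [(X, y)], dictionary)


@pytest.fixture(scope="module")
def dev_matrix(dictionary):
    return _labeled_matrix(dictionary, n=900, seed=10)


def test_build_score_constraints(dictionary, dev_matrix):
    spec = ThresholdSearchSpec(n_quantiles=19, search_mode="beam", beam_width=20)
    X, y = dev_matrix
    full = build_score(DOMAINS, [(X, y)], dictionary, spec)
    assert len(full.components) == 7 and full.max_total == 28

    no_metab = build_score(DOMAINS, [(X, y)], dictionary, spec, constraints="no_metabolic")
    assert len(no_metab.components) == 6 and no_metab.max_total == 24
    assert "metabolic" not in no_metab.domains

    lmic = build_score(DOMAINS, [(X, y)], dictionary, spec, constraints="lmic")
    for comp in lmic.components:
        assert not dictionary[comp.concept_id].requires_blood_gas
    assert lmic.component("metabolic").concept_id == "bicarbonate"
    assert lmic.component("respiratory").concept_id == "sf_ratio"


def test_build_score_fails_without_candidates(dictionary, dev_matrix):
    X, y = dev_matrix
    stripped = X.drop(columns=["sf_ratio", "sf_ratio_imputed"])
    with pytest.raises(ValueError, match="respiratory"):
        build_score(
            DOMAINS, [(stripped, y)], dictionary,
            ThresholdSearchSpec(n_quantiles=9), constraints="lmic",
        )


def test_build_score_refuses_validation_matrices(dictionary, dev_matrix):
    X, y = dev_matrix
    Xv = X.copy()
    Xv.attrs["cohort_role"] = "validation"
    with pytest.raises(ValueError, match="validation"):
        build_score(DOMAINS, [(Xv, y)], dictionary, ThresholdSearchSpec(n_quantiles=9))


def test_constrained_dev_auroc_never_exceeds_unconstrained(dictionary, dev_matrix):
    from sklearn.metrics import roc_auc_score

    from sepscore.scorer import score_stays

    spec = ThresholdSearchSpec(n_quantiles=19, search_mode="beam", beam_width=20)
    X, y = dev_matrix
    full = build_score(DOMAINS, [(X, y)], dictionary, spec)
    lmic = build_score(DOMAINS, [(X, y)], dictionary, spec, constraints="lmic")
    auc_full = roc_auc_score(y, score_stays(X, full)["total"])
    auc_lmic = roc_auc_score(y, score_stays(X, lmic)["total"])
    assert auc_lmic <= auc_full + 1e-9


def test_ablation_identity_and_near_duplicate(dictionary):
    # metabolic winner has a near-duplicate replacement: removing it should
    # cost almost nothing; the empty removal set is exactly the base score
    rng = np.random.default_rng(11)
    n = 1600
    z = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-2 + 1.6 * z)))).astype(int)

    def mk(seed):
        r = np.random.default_rng(seed)
        X = pd.DataFrame({"stay_id": range(n), "T": 24.0})
        X["lactate"] = 2.0 + 1.2 * z + r.normal(0, 0.3, n)
        X["bicarbonate"] = 24 - 3.0 * z + r.normal(0, 0.8, n)  # near-duplicate signal
        X["gcs"] = np.clip(13 - 1.5 * z + r.normal(0, 1, n), 3, 15)
        return X

    Xd, Xv = mk(12), mk(13)
    spec = ThresholdSearchSpec(n_quantiles=19, search_mode="beam", beam_width=20)
    sdef = build_score(["metabolic", "cns"], [(Xd, y)], dictionary, spec)
    assert sdef.component("metabolic").concept_id in ("lactate", "bicarbonate")
    report = ablation_study(sdef, [(Xd, y)], [(Xv, y)], dictionary, spec, max_removed=1)
    base = report[report["removed"] == ""].iloc[0]
    assert base["delta_auroc"] == 0.0
    removed = report[report["removed"] == "metabolic"].iloc[0]
    assert removed["delta_auroc"] >= -0.01
    # CNS is never in the removable set
    assert not (report["removed"].str.contains("cns")).any()
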