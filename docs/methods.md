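# Methods

This note documents the models and procedures implemented by `sepscore`,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Time and table conventions

All times are fractional hours relative to each stay's ICU admission
(t = 0). General windows are half-open `(start, end]` for worst-value
extraction — an observation exactly at the landmark time T belongs to the
window ending at T — while the suspected-infection windows are
boundary-inclusive ("within 24 h" includes exactly 24 h). Measurements may
precede ICU admission (negative times); they are kept and participate in
lookback windows that extend before admission. Platelet counts are in
10⁹/L; vasopressor rates in µg/kg/min except vasopressin (U/min).

Because all times are stay-relative, stays of the same subject cannot be
ordered by admission timestamp; repeat-admission removal keeps the stay
with the lowest `(icu_admit, stay_id)`, and the synthetic generator assigns
stay ids in admission order.

## Suspected-infection cohort

A stay qualifies when an antibiotic administration at `ta` and a body-fluid
sampling at `ts` satisfy `ta ≤ ts ≤ ta + 24 h` or `ts ≤ ta ≤ ts + 72 h`.
The suspicion time is `min(ta, ts)` of the earliest qualifying pair (the
Sepsis-3 convention; the choice of the earlier event is a design decision).
Inclusion further requires age strictly greater than 18 years, a first ICU
admission, and suspicion before 48 h. Exclusion reasons are assigned with
precedence age → repeat admission → no suspicion → suspicion too late, so
they are mutually exclusive and exhaustive.

The sustained-antibiotics filter bins antibiotic exposure into calendar
days anchored at admission (day k = `[24(k−1), 24k)` h; an interval marks
every day it overlaps) and retains stays whose longest run of consecutive
exposed days is at least 4 — the simplest reproducible reading of
"antibiotics on at least 4 consecutive days".

The development/validation split is subject-level: subjects are shuffled
with a seeded generator and the first `round(0.6·n_subjects)` form the
development set, so no subject contributes stays to both sides.

## Features

The scoring feature of a biomarker at landmark T is its *worst* value over
`(T − 24 h, T]`: maximum for higher-worse markers, minimum for lower-worse
markers. A stay with no observation in the window receives the concept's
clinically normal value, flagged imputed. The shipped normal values are
standard reference-range midpoints; a load-time invariant guarantees each
one scores 0 in every shipped component that uses the concept, so imputed
values need no special-casing in the scorer.

**Vasopressor-adjusted MAP.** At each MAP measurement time t the
norepinephrine-equivalent rate NEQ(t) is the sum over active infusions
(`start ≤ t < end`) of rate × drug factor; the adjusted value is
`MAP − β·NEQ(t)` with β = 200 mmHg per µg/kg/min (fixed by the shipped
score, exposed as a config knob). The worst adjusted MAP is the minimum of
these paired values — pairing at measurement timestamps is a design choice;
no interpolation or drug half-life modelling is attempted. Negative
adjusted values are kept (no flooring); they simply land in the worst band.
The default conversion factors (norepinephrine 1.0, epinephrine 1.0,
dopamine 0.01, phenylephrine 0.1, vasopressin 2.5 per U/min) follow the
commonly cited norepinephrine-equivalence literature and are fully
overridable.

**Sedation-adjusted GCS.** Sedation windows are the union of
administration intervals of the listed sedatives (propofol, fentanyl,
diazepam, lorazepam, midazolam, oxazepam, methadone, morphine,
hydromorphone) — any overlap counts, bolus or infusion. Alternatively,
windows can be derived from RASS readings ≤ −2, carried forward until the
next reading or the end of stay. Three policies: `set_max_15` (readings in
a window become 15; the shipped default), `carry_forward` (replaced by the
last pre-window reading, dropped if none exists), `raw`. GCS values are
validated to [3, 15].

The landmark cohort at T contains included stays with discharge after T
and death (if any) after T; death or discharge exactly at T excludes the
stay.

## Score construction

Each domain component is a single biomarker with four thresholds. The
builder searches a candidate grid — by default the 1%…99% percentiles of
the pooled development distribution — for the multiset of K = 4 thresholds
maximising the Mann–Whitney AUROC of the induced 0–4 sub-score against
in-hospital mortality. Duplicate thresholds are permitted during the
search (degenerate, skipped levels); when a built component is exported,
duplicates are separated by the smallest representable float step so the
strictly-ordered config invariant holds without changing the scoring of
observed data.

Two search modes share one interface: exhaustive enumeration of all
`C(m+K−1, K)` multisets (used automatically when that count is ≤ 20 000,
and as the test oracle), and a beam search (default width 50) over nested
multisets followed by cyclic coordinate ascent on the top beam states. The
refinement exists because the greedy nesting can strand a good low
threshold behind a poor prefix; one ascent pass costs K·m AUROC
evaluations, each O(n) via level/label counts. Ties break toward the
least-extreme thresholds, then lexicographically, for determinism.
Threshold orientation follows the biomarker's worst direction: `≥` bands
(inclusive) for higher-worse markers, strict `<` bands for lower-worse
markers.

Feature selection is per-domain (greedy), not joint: for every candidate
concept in a domain the thresholds are optimised on the pooled development
data, candidates are ranked by the mean per-cohort AUROC of the fitted
component, and the best one wins. Constraint sets: `lmic` removes
blood-gas-dependent candidates, `no_metabolic` drops the metabolic domain,
and per-domain exclusion lists drive the ablation. The CNS domain has GCS
as its only candidate and is never ablated. Feature matrices tagged as
validation are refused by the builder.

The ablation study fits, once per domain, the best replacement component
with the domain winner excluded, then evaluates every removal subset (up
to `max_removed`) on the validation cohorts, reporting the AUROC delta
against the unrestricted score. A domain with no replacement candidates is
dropped with a logged warning.

## Evaluation

AUROC is the Mann–Whitney statistic (ties get half credit); AUPRC is
average precision, the non-interpolated step-wise PR integral — chosen as
the non-optimistic convention. Confidence intervals are seeded percentile
bootstrap over stay-level resamples (default B = 1000); a resample that
loses an outcome class is redrawn, at most 10 times. For the built-in
metrics the resample is carried as multinomial weights over tied-score
groups, algebraically identical to recomputing on resampled rows. Score
comparisons use a two-sided paired-bootstrap difference test.

The landmark analysis evaluates every score definition on the identical
stay set at each T in {6, 8, …, 24} h, with worst values over the
preceding 24 h. Empty landmark cohorts are reported with n = 0 and null
metrics.

Calibration is two-stage logistic recalibration: a logistic model of death
on the total score, fitted on development data, produces a linear
predictor; validation outcomes are refit on that predictor, and the
stage-2 intercept and slope are reported with Wald 95% CIs. A score is
flagged calibrated when the intercept CI contains 0 and the slope CI
contains 1. Perfect separation in stage 1 fails loudly. The full
calibration-belt curve is out of scope; the slope/intercept pair carries
the transportability conclusion.

The classic SOFA comparator lives entirely in config (thresholds from the
original 1996 publication, with citation metadata in the file), with two
simplifications: respiratory levels 3–4 do not condition on ventilatory
support and the renal domain uses creatinine only. Its cardiovascular
domain keeps the original dose-based banding (hypotension → 1; dopamine
≤ 5 → 2; dopamine > 5 or norepinephrine/epinephrine ≤ 0.1 → 3; dopamine
> 15 or norepinephrine/epinephrine > 0.1 µg/kg/min → 4), driven by the
per-window vasopressor dose maxima in the feature matrix. The data-driven
respiratory bands are unconditional P/F bands — whether concurrent
ventilatory support should be required is left open by the shipped table,
and the unconditional reading is implemented.

## Synthetic EHR generator

The generator emulates the *structure* the framework assumes, not any real
database's marginals. Per stay: latent severity z ~ N(0, 1); lognormal
length of stay (median 2.2–5.5 days depending on site preset) mildly
increasing in z; death ~ Bernoulli(sigmoid(a + b·x)) with x = z (effect
b = 1.3 log-odds per SD) or, in planted mode, x = the true banded score of
a supplied definition computed from the noiseless biomarker tendencies
(0.55 log-odds per point by default); the intercept a is solved by root
finding so the realised marginal death rate matches the preset (0.11–0.22).
Each biomarker has a per-stay tendency `normal ± loading·z` observed at
homogeneous-Poisson times (rates 0.8–24 events/day by concept) with
Gaussian noise, clipped to a plausible range — so worst-value extraction
sees realistic within-stay variation. Antibiotic/sampling pairs are placed
so that the configured fraction of stays (0.55–0.75 by site) qualifies
under the 24 h / 72 h rule, with a mix of antibiotics-only, sampling-only
and non-qualifying-pair stays among the rest; antibiotic courses run
1 + Poisson(3) consecutive days. Vasopressor infusions (mostly
norepinephrine, rate increasing in z) and propofol sedation episodes, with
GCS readings forced low and RASS ≤ −2 inside them, cover the configured
fractions. Randomness flows through one counter-based Philox generator, so
a (config, seed) pair reproduces byte-identical tables.

Three site presets ship with different admission mixes, stay lengths and
mortality, for cross-site calibration experiments; the values are
structural presets only.

What the generator does *not* emulate: inter-marker correlation beyond the
single severity factor, unit quirks, documentation artefacts, treatment
feedback (sicker patients being measured more often), or informative
missingness. Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline under its assumed data model, not
performance on any real cohort.

## Problem sizes used in the shipped experiments

The test-suite experiments use 10 000 observations for threshold recovery,
5000 for calibration recovery, 200 × 2000 for bootstrap coverage, and
synthetic cohorts of 2000–2500 stays (two development sites, one
validation site) for the end-to-end landmark comparison; these sizes give
stable results for the properties asserted while keeping the suite quick
to run.

## Known limitations

- The threshold search is a reconstruction of an AUROC-maximisation
  procedure specified only by its contract (four thresholds per feature,
  AUROC objective); the beam + refinement optimiser is deterministic and
  oracle-checked on small grids but is not guaranteed to find the global
  optimum on large ones.
- Near-optimal score multiplicity is real: on data with several correlated
  informative markers, different seeds or sites can select different
  domain winners with nearly identical performance. The ablation report
  quantifies this.
- Exact recovery of planted cutpoints requires each band to carry
  non-trivial probability mass and effect; thresholds in sparse tails are
  only weakly identified at realistic sample sizes.
- No urine-output renal scoring, no microbiology interpretation, no
  drug-half-life modelling.
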