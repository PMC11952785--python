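# sepscore

Data-driven construction, application and evaluation of organ-failure
severity scores for ICU patients with suspected sepsis.

Organ dysfunction in suspected sepsis is conventionally graded with the
Sequential Organ Failure Assessment (SOFA): six organ domains, each scored
0–4 from expert-chosen thresholds. `sepscore` implements a statistical
framework that rebuilds such a score from electronic-health-record data:
for each organ domain it selects the most predictive biomarker and the four
thresholds `t1 < t2 < t3 < t4` that maximise the AUROC of the induced
ordinal sub-score

    s(x) = #{k : x ≥ t_k}        (higher-worse markers)
    s(x) = #{k : x < t_k}        (lower-worse markers)

for in-hospital mortality on development cohorts, and evaluates the total
score `S = Σ_domains s_d` on held-out validation cohorts.

The package ships, as declarative configs:

- **Sepsis SOFA** — a seven-domain data-driven score (respiratory P/F
  ratio, vasopressor-adjusted MAP, platelets, AST, sedation-adjusted GCS,
  blood urea nitrogen, plus a metabolic lactate domain);
- **Sepsis SOFA-LMIC** — the same score with blood-gas-dependent markers
  replaced (lactate → bicarbonate, PaO2/FiO2 → SpO2/FiO2) for
  resource-limited settings;
- **classic SOFA** — the 1996 six-domain comparator.

Two derived features do most of the clinical work. The *vasopressor-adjusted
MAP* penalises blood pressure by the amount of support needed to maintain
it: `MAP − β·NEQ`, where NEQ is the total norepinephrine-equivalent infusion
rate (µg/kg/min) and β = 200 mmHg per unit. The *sedation-adjusted GCS*
neutralises coma-scale readings taken under sedation (set to the maximum of
15, carried forward, or left raw).

The toolkit covers the full pipeline:

| module | what it does |
|---|---|
| `sepscore.ehr_model` | long-format table schemas, CSV/Parquet I/O, score/dictionary configs |
| `sepscore.cohort` | suspected-infection detection (antibiotics + body-fluid sampling within 24 h / 72 h windows), inclusion filters, subject-level 60/40 split |
| `sepscore.features` | windowed worst values with normal-range imputation, NEQ, adjusted MAP, sedation-adjusted GCS, landmark feature matrices |
| `sepscore.score_builder` | biomarker ranking, AUROC-maximising threshold search, LMIC-constrained builds, ablation study |
| `sepscore.scorer` | applies any score definition; ships the three configs above |
| `sepscore.evaluation` | AUROC/AUPRC with bootstrap CIs, landmark-time evaluation, per-level mortality, logistic recalibration |
| `sepscore.synth_ehr` | seeded synthetic EHR generator with latent-severity structure and plantable score signals |
| `sepscore.workflows` / `sepscore.cli` | one-command study pipeline and `sepscore` CLI |

No connectors to real clinical databases are included; users export their
data to the long table format documented in `ehr_model`.

## Worked example

Generate a synthetic 1000-stay cohort, build the suspected-infection
cohort, extract landmark features at 24 h, and score with the shipped
Sepsis SOFA:

```bash
sepscore synth --preset site_a --n 1000 --seed 7 --out-dir demo
sepscore cohort --tables-dir demo --out demo/cohort.csv
# -> 696 of 1000 stays included -> demo/cohort.csv
sepscore features --cohort-path demo/cohort.csv --tables-dir demo \
    --at-hours 24 --score sepsis_sofa --out demo/features.csv
# -> 533 stays -> demo/features.csv   (alive and in the ICU at 24 h)
sepscore score --features-path demo/features.csv --score sepsis_sofa \
    --out demo/scored.csv
```

`demo/scored.csv` holds one row per stay with the seven sub-scores and the
total, e.g.

```
stay_id    T  liver  renal  cns  metabolic  cardiovascular  respiratory  coagulation  total
s000000 24.0      0      0    0          0               1            0            0      1
s000002 24.0      0      0    1          1               1            1            0      4
```

Evaluating the total against in-hospital mortality:

```python
>>> from sepscore.evaluation import auroc, auprc, bootstrap_ci
AUROC 0.762 (95% CI 0.693-0.834), AUPRC 0.302, n=533, mortality 0.090
```

i.e. on this synthetic validation set a randomly chosen decedent outscores
a randomly chosen survivor 76% of the time. The same functions drive the
landmark analysis (`overtime_eval`, every 2 h from 6 h to 24 h) and the
two-stage logistic recalibration (`calibrate`), and
`sepscore run --config study.yaml --out results/` chains the whole study
(cohort → split → build → LMIC/no-metabolic variants → ablation →
evaluation → calibration) with a run manifest.

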