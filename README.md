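# audpipe

Behavioral phenotyping of alcohol use disorder (AUD)-prone and AUD-resistant
mice from IntelliCage-style home-cage event logs.

Automated group cages log every corner **visit**, door **nosepoke** and
bottle **lick** per transponder-tagged mouse across months-long alcohol
protocols. `audpipe` turns such event logs into the standard composite
addiction phenotype used in this field, for researchers running (or
simulating) multi-phase operant drinking experiments:

1. **Five behavioral indices** per animal, larger = more AUD-like:
   motivation **M** (the fixed-ratio level reached on the progressive-ratio
   ladder 2, 4, 8, …, 36, where a "set" is a burst of requirement-many pokes
   spaced < 1 s within one visit and the requirement advances after 10
   sets), extinction **E** (mean daily reward-corner nosepokes over 7
   extinction days), cue relapse **CR** (nosepokes during the 24-h cue
   test), alcohol relapse **AR** (first-day intake in g/kg/day via
   licks × lick volume × alcohol fraction × 1 g/ml / body weight), and
   persistence **P** (nosepokes during signalled non-active periods).
2. **Criterion scoring**: an animal is positive for a criterion when its
   index is in the uppermost 35% of the cohort; the AUD index counts
   criteria (0–5); ≥ 2 criteria ⇒ **AUD-prone**, < 2 ⇒ **AUD-resistant**;
   the continuous AUD score is the z-sum AS_i = Σ_b (V_ib − mean_b)/SD_b.
3. **Group structure**: Spearman correlation matrices and a correlation-
   matrix PCA of the five behaviors within each group — prone cohorts show
   mutually correlated behaviors loading on a single dominant component,
   resistant cohorts do not — plus the binomial reference
   Σ_{j≥k} C(5,j) q^j (1−q)^{5−j} for the ≥ k-criteria fraction expected
   under independent criteria.
4. A **synthetic cohort generator** with latent ground truth (class and
   5 correlated traits per animal), so the whole pipeline is testable
   end-to-end without proprietary cage exports.

## Worked example

```python
from audpipe import (build_behavior_matrix, default_config,
                     independence_null, score_cohort, simulate_cohort)

log, truth = simulate_cohort(default_config(12, 7))   # 12 mice, seed 7
matrix = build_behavior_matrix(log)
print(matrix.to_frame().round(2).to_string(index=False))
result = score_cohort(matrix)
print(result.table[["animal_id", "aud_index", "aud_score", "class"]]
      .round(2).to_string(index=False))
print("prone fraction:", round(result.prone_fraction, 3))
print("independence null:", round(independence_null(0.35, 5, 2), 4))
```

prints

```
animal_id    M     E    CR    AR     P
    M0001  2.0  4.00  42.0  0.47  30.0
    M0002 36.0 67.00  77.0 12.88 167.0
    M0003  8.0 11.86  21.0  3.18  17.0
    M0004  2.0  4.86  25.0  3.35   9.0
    M0005  4.0  6.43  35.0  2.87  31.0
    M0006 36.0 64.29  86.0  6.60 186.0
    M0007 24.0 70.57  58.0  9.41 155.0
    M0008 16.0 19.29  40.0  4.50  27.0
    M0009 24.0 50.86 117.0 13.73 124.0
    M0010 36.0 25.43 117.0 10.67 199.0
    M0011 16.0 36.29  25.0  1.59   8.0
    M0012  4.0  9.43  19.0  1.82  32.0
animal_id  aud_index  aud_score     class
    M0001          0      -4.38 resistant
    M0002          5       5.98     prone
    M0003          0      -3.81 resistant
    M0004          0      -4.47 resistant
    M0005          0      -3.81 resistant
    M0006          4       5.02     prone
    M0007          3       3.80     prone
    M0008          0      -1.99 resistant
    M0009          3       5.22     prone
    M0010          4       5.43     prone
    M0011          0      -2.63 resistant
    M0012          0      -4.35 resistant
prone fraction: 0.417
independence null: 0.5716
```

Five of twelve animals met ≥ 2 of the uppermost-35% criteria and are
classified prone; their indices are high across the board (e.g. M0002:
breakpoint 36, 67 extinction nosepokes/day, 12.9 g/kg relapse intake), and
the AUD score separates the groups cleanly. The 0.417 prone fraction sits
well below the 0.572 expected if criteria were independent — criteria
co-occur in a subpopulation instead of scattering.

The same analysis runs from the shell on CSV files
(`events.csv` / `registry.csv` / `schedule.csv`, dialect documented in
`audpipe.event_model`):

```bash
audpipe simulate --n 58 --seed 1 --out-dir cohort/
audpipe indices  --events cohort/events.csv --schedule cohort/schedule.csv \
                 --registry cohort/registry.csv --out behavior_matrix.csv
audpipe score    --matrix behavior_matrix.csv --q 0.35 --k 2 --out aud_results.csv
audpipe structure --matrix behavior_matrix.csv --results aud_results.csv \
                  --out report.json
audpipe run      --n 58 --seed 1 --out-dir full_run/   # everything at once
```

`audpipe run` writes a reproducible bundle (`behavior_matrix.csv`,
`aud_results.csv`, `report.json`, `run_manifest.json` with SHA-256
checksums); identical config and seed give byte-identical bundles.

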