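# dntp

Predictive-biomarker screening and the **differential neoadjuvant treatment
predictive (DNTP) score** for choosing between neoadjuvant chemo-hormonal
therapy (NCHT, docetaxel + androgen deprivation) and neoadjuvant hormonal
therapy alone (NHT) in locally advanced prostate cancer.

The package is aimed at biostatisticians and computational biologists who
work with treatment-selection signatures built from bulk RNA-seq and
right-censored outcomes. It implements the full analysis path as a tested
library with a thin CLI:

* **Interaction screening.** For each gene *g*, a Cox proportional-hazards
  model for biochemical progression-free survival (bPFS)

  ```
  h_i(t) = h0(t) · exp(β₁ tᵢ + β₂ gᵢ + β₃ tᵢ gᵢ)
  ```

  with treatment tᵢ (0 = NCHT, 1 = NHT) and log2(TPM+1) expression gᵢ.
  The Wald statistic z = β̂₃/se(β̂₃) tests the *predictive* (treatment-modifying)
  effect: z > 0 means high expression favours NCHT, z < 0 favours NHT.
  Genes with interaction p < 0.05 are selected.
* **Signature scoring.** The DNTP score is the z-weighted sum of the selected
  genes' expression; the packaged published 10-gene signature is
  `score = 3.74·GNAS − 3.65·COX15 − 3.693·NMRK1 − 4.332·CLYBL − 3.629·PNCK
  − 3.75·MMS19 − 3.514·COL4A5 − 3.569·ZNF774 − 3.654·HBA1 − 3.496·DBNDD2`
  with cutoff −95.798 (score ≥ cutoff ⇒ NCHT-preferable).
* **Cutoff scan and subgroup evaluation.** Candidate cutoffs are scanned for
  the minimal group×treatment interaction p; subgroups are compared per arm by
  Kaplan–Meier curves and the log-rank test.
* **Pathway regulation consistency.** Per-pathway Jaccard statistics
  (`level1_consis`, `level2_consis`, `level1_coef`, `consis_coef`) comparing
  up-/down-regulated gene sets between the two treatments.
* **Cohort tables.** Exact Fisher tests (2×2 and enumerated r×c), Wilcoxon
  rank-sum, Wilson score intervals, and a formatted baseline table.
* **Synthetic cohorts.** A generator that emulates the target study design
  (64 patients, exact 32/32 arms, ~58% event rate, median bPFS ≈ 10 months)
  with configurable planted gene-by-treatment interactions, so the whole
  pipeline is testable without patient-level data.

## Worked example

```python
from dntp import (SyntheticConfig, generate_cohort, screen_genes,
                  build_signature, score_samples, scan_cutoff,
                  evaluate_subgroups)

cfg = SyntheticConfig(n_patients=64, n_genes=30,
                      beta_inter={"G0001": 1.5, "G0002": -1.5}, seed=202)
cohort = generate_cohort(cfg)
res = screen_genes(cohort.expression, cohort.clinical, alpha=0.05)
print(res.summary().head(3)[["gene", "z", "p", "favor", "selected"]])

sig = build_signature(res, alpha=0.05)
scores = score_samples(cohort.expression, sig)
scan = scan_cutoff(scores, cohort.clinical)
report = evaluate_subgroups(scores, cohort.clinical, scan.cutoff)
print(f"cutoff={scan.cutoff:.2f}  interaction p={report.interaction_p:.2e}")
for name, blk in report.groups.items():
    print(name, blk.n_per_arm, f"log-rank p={blk.logrank_p:.3f}")
```

prints (seed 202):

```
    gene         z         p favor  selected
0  G0001  4.077415  0.000046  NCHT      True
1  G0002 -2.623362  0.008707   NHT      True
2  G0023  2.461512  0.013835  NCHT      True
cutoff=15.48  interaction p=2.24e-05
high {'NCHT': 7, 'NHT': 9} log-rank p=0.003
low {'NCHT': 25, 'NHT': 23} log-rank p=0.047
```

The two planted genes rank first with the correct preference directions
(positive β₃ inflates the NHT hazard with expression, so high expression
favours NCHT; G0023 is a false positive at raw p < 0.05), and stratifying
at the scanned cutoff yields significant treatment benefits in opposite
directions in the two subgroups.

The same pipeline runs from the shell:

```sh
dntp run --out-dir out --seed 202          # simulate → screen → signature → evaluate
dntp screen --expr E.tsv --clinical C.csv --out screen.tsv
dntp score --expr E.tsv --signature sig.json --out scores.tsv
```

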