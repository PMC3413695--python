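# brushdx

Semi-quantitative RT-PCR marker panels for diagnosing malignant biliary
strictures from intraductal brush cytology specimens.

Distinguishing benign from malignant biliary strictures is notoriously
hard: routine brush cytology is specific but insensitive (roughly 40%
sensitivity in practice).  One remedy is to measure the mRNA of
tumor-associated genes — IGF2BP3, HOXB7, NEK2 (and the less informative
FOXM1, KIF2C) — in the same brush specimen by real-time RT-PCR and to
call malignancy when expression is high, alone or in combination with
the cytologic read-out.  `brushdx` implements that entire analysis as a
reusable, tested library for biostatisticians and molecular
diagnosticians:

- **ΔCt / ΔΔCt quantification** — normalization against a housekeeping
  gene (GAPDH), ΔCt = Ct_target − Ct_ref; group-level over-expression as
  ΔΔCt = median ΔCt(benign) − median ΔCt(malignant) with fold change
  2^ΔΔCt; Welch t-tests and within-group Spearman correlation matrices.
- **ROC analysis** — empirical ROC of ΔCt as a malignancy classifier
  (lower ΔCt = test-positive), AUC = Mann–Whitney concordance with
  Hanley–McNeil SE and 95% CI, Youden-index optimal cutoffs, and the
  binormal closed form Φ(Δμ/√(σ₁²+σ₂²)) as an analytic reference.
- **Panel rules** — Boolean combination of marker positivity
  (ΔCt ≤ cutoff): any-one, all, m-of-n voting; dichotomized cytology
  (malignant-only or suspicious-plus-malignant positive) and logical OR
  of cytology with the gene panel.
- **Diagnostic performance** — 2×2 sensitivity/specificity/PPV/NPV/
  accuracy with Wilson (or Clopper–Pearson) CIs, and Bayes predictive
  values at a stated prevalence.
- **Synthetic cohorts** — a seeded Gaussian-copula generator calibrated
  to the published study conditions (72 malignant / 47 benign patients,
  per-group ΔCt means/SDs, within-group Spearman correlations, cytology
  category frequencies), so every stage is testable without patient
  data.

## Worked example

`examples/03_panel_performance.py` simulates a study-calibrated cohort
(seed 1) and evaluates every combination rule at the reference cutoffs
HOXB7 ≤ 9.4, IGF2BP3 ≤ 11.46, NEK2 ≤ 9.27 cycles:

```text
rule                    sens%  spec%   PPV%   NPV%   acc%
cytology_M               15.3   83.0   57.9   39.0   42.0
cytology_SM              34.7   83.0   75.8   45.3   53.8
single_HOXB7             58.3   78.7   80.8   55.2   66.4
single_IGF2BP3           72.2   78.7   83.9   64.9   74.8
single_NEK2              61.1   63.8   72.1   51.7   62.2
1_of_3                   88.9   46.8   71.9   73.3   72.3
2_of_3                   70.8   76.6   82.3   63.2   73.1
3_of_3                   31.9   97.9   95.8   48.4   58.0
cytology_or_2_of_3       77.8   61.7   75.7   64.4   71.4
```

Reading the table: requiring more concordant markers (1-of-3 → 3-of-3)
trades sensitivity for specificity, exactly the behaviour that makes a
2-of-3 vote a good operating point; OR-ing cytology into the panel
recovers cytology's missed cancers at modest specificity cost.  The
other examples print the per-marker fold changes (e.g. IGF2BP3 ~9-fold
over-expressed in this replicate, Welch p ≈ 3×10⁻¹⁰) and the ROC table
(AUC 0.816 ± 0.038 for IGF2BP3, Youden cutoff ΔCt ≤ 12.31).

The same analysis is scriptable from a shell:

```sh
brushdx simulate --seed 1 --out cohort.csv
brushdx report --input cohort.csv \
    --cutoffs 'HOXB7=9.4,IGF2BP3=11.46,NEK2=9.27' \
    --out-json report.json
```

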