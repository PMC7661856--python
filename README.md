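# benefitscore

Stratifying immunotherapy outcomes by a per-tumor **benefit score** —
tumor mutational burden (TMB) integrated with mutant-allele tumor
heterogeneity (MATH).

TMB alone is an imperfect predictor of response to immune checkpoint
inhibition: a high mutational load only helps if the resulting
neoantigens are shared by the whole tumor, and high intratumoral
heterogeneity dilutes them into subclone-private antigens. The benefit
score combines both axes in one number per tumor:

```
MATH = 100 · 1.4826 · median(|vaf_i − median(vaf)|) / median(vaf)
B    = TMB / MATH          (MATH replaced by 1 when exactly 0)
```

where `vaf_i` are the tumor's variant allele fractions and TMB is the
raw count of nonsynonymous somatic mutations. High `B` means a high
burden, low heterogeneity, or both.

The package is for computational oncologists working with MAF-style
somatic mutation tables, right-censored survival data, per-mutation
cancer-cell-fraction (CCF) annotations, and immune-cell-fraction
estimates. It provides:

* **mutation_io** — MAF reading (GDC dialect by default, remappable),
  VAF/coverage derivation, quality filters (VAF < 0.05 or coverage
  ≤ 30 excluded), nonsynonymous selection;
* **burden** — TMB, MATH, benefit score, and clonal TMB under two
  CCF-based clonality rules (lower CI > 0.95, or CCF = 1 /
  P(clonal) > P(subclonal));
* **survival** — Kaplan–Meier, log-rank, maximally selected log-rank
  cutpoints (with a selection-adjusted p alongside the conventional
  naive one), multivariate Cox via lifelines;
* **association** — Spearman correlations; Wilcoxon rank-sum /
  signed-rank contrasts of immune-cell fractions between and within
  benefit-score groups;
* **simulate** — synthetic cohorts with known clonal architecture,
  binomially read-sampled VAFs, group-linked survival and
  compositional immune fractions, for calibration and recovery
  testing;
* **pipeline** + `benefitscore` CLI — the whole analysis from files
  or in-memory tables, every stage persisted as TSV/JSON.

## Worked example

Score a simulated 80-patient cohort and stratify survival:

```python
from benefitscore import score_cohort, analyze
from benefitscore.simulate import SimulationConfig, simulate_cohort
from benefitscore.pipeline import compare_markers

cohort = simulate_cohort(SimulationConfig(n_patients=80, seed=11))
scores = score_cohort(cohort.mutation_table)
print(scores.head(4))

report = analyze(cohort.mutation_table, cohort.survival_table,
                 clonality=cohort.clonal_annotations,
                 immune=cohort.immune_fractions)
print(compare_markers(report))
```

which prints

```
sample_id  tmb      math  math_substituted  benefit_score  n_vafs_used  valid
    S0000  172 61.441491             False       2.799411          229   True
    S0001  172 77.032181             False       2.232833          227   True
    S0002  136 67.274968             False       2.021554          189   True
    S0003   50 77.610022             False       0.644247           75   True

       marker  threshold  n_high  n_low  chi_square  naive_p  adjusted_p  hr_low_vs_high
          tmb  70.500000      41     38    5.353969 0.020675    0.274290        1.868730
         math  62.422977      33     46    2.099303 0.147366    0.851170        1.477620
benefit_score   1.591508      46     33    3.260984 0.070947    0.602911        1.636298
```

Each sample gets its TMB (count), MATH (dimensionless dispersion),
and benefit score; `valid=False` flags samples whose MATH is
inestimable (fewer than 5 usable mutations) — they are reported, not
silently dropped. The marker table shows, per marker, the
maximally-selected cutpoint, group sizes, the conventional log-rank p
at that cutpoint (`naive_p` — biased low by the selection), the
selection-adjusted p, and the univariate hazard ratio of the
low-marker group (here: low-benefit patients die ~1.6× faster). The
multivariate Cox adjusting for age, sex and stage gives
`HR = 1.79 [1.01, 3.16], p = 0.046` for the low-benefit group, and the
benefit score correlates strongly with clonal TMB
(`rho = 0.923, p < 1e-33`) while TMB and MATH are uncorrelated
(`rho = 0.122, p = 0.29`) — the independence that motivates combining
them.

The same pipeline runs from files:

```sh
benefitscore simulate --seed 11 --n 80 --out cohort/
benefitscore score --maf cohort/mutations.maf.tsv --out scores.tsv
benefitscore cutpoint --scores scores.tsv --clinical cohort/clinical.tsv --out cut.json
```

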