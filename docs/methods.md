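# Methods

## The benefit score

For one tumor with $n$ nonsynonymous somatic mutations (TMB, a raw
count) and mutant-allele tumor heterogeneity

$$\mathrm{MATH} = 100 \cdot \frac{1.4826 \cdot
\mathrm{median}_i\,\lvert v_i - \mathrm{median}(v)\rvert}
{\mathrm{median}(v)},$$

where $v_1,\dots,v_m$ are the tumor's variant allele fractions (VAFs),
the benefit score is

$$B = \frac{\mathrm{TMB}}{\max(\mathrm{MATH}, [\mathrm{MATH}=0])}
\quad\text{i.e. } \mathrm{TMB}/\mathrm{MATH},\ \text{with MATH
replaced by } 1 \text{ when it is exactly } 0.$$

The substitution keeps zero-dispersion tumors (all VAFs equal, MAD
$= 0$) at a finite score equal to their TMB. A high score means a high
mutational load, low intratumoral heterogeneity, or both — the profile
expected to respond to immune checkpoint inhibition, because clonal
neoantigens shared by all tumor cells drive immune surveillance while
subclone-private antigens dilute it.

Conventions and their rationale:

* **Coverage** is `t_alt_count + t_ref_count`, the only read-count
  fields universally present in MAF exports. Records with VAF
  strictly below 0.05 or coverage at or below 30 reads are excluded
  before any scoring (strict `< 0.05`, inclusive `<= 30`).
* **TMB** counts the standard protein-altering MAF classes
  (missense, nonsense, nonstop, splice site, frameshift and in-frame
  indels, translation start site), configurable per cohort. It is a
  raw count, not per-megabase: cutpoints are cohort-specific, so a
  constant exome size would cancel.
* **MATH** uses all quality-passing VAFs, not only nonsynonymous ones
  (the convention of MAF-analysis toolkits); a switch restricts it to
  the nonsynonymous set. Both TMB and MATH are computed after the
  quality filters by default, with a switch for pre-filter TMB, since
  the ordering is a genuine analytical degree of freedom.
* **Minimum mutations for MATH**: 5. A median/MAD summary of fewer
  fractions is not meaningful; samples below the minimum are retained
  in score tables with `valid = False` and excluded from
  stratification, and every such exclusion is reported.

## Clonal TMB

Cancer cell fraction (CCF) annotations are consumed, never estimated
here. Two classification rules cover the conventions of published
cohorts:

* **Confidence-interval rule** (`ci`): clonal iff the lower 95% CCF
  bound strictly exceeds 0.95.
* **Point-estimate rule** (`ccf`): clonal iff CCF equals 1 (tolerance
  1e-9) or the clonal probability strictly exceeds the subclonal
  probability when both are given.

Clonal TMB is the count of clonal mutations among the
quality-passing nonsynonymous set; by construction it never exceeds
TMB.

## Survival stratification

A continuous marker is dichotomized at the threshold maximizing the
absolute standardized two-group log-rank statistic over all admissible
splits (maximally selected log-rank). Candidates are midpoints between
consecutive distinct marker values — stable against floating-point
representation of observed values; a split is admissible when each
group holds at least `minprop` (default 0.1) of the cohort; ties go to
the smallest threshold; "high" means strictly above the threshold,
consistent with midpoint candidates.

The log-rank p-value at the selected threshold ignores the selection
and is anti-conservative — the acceptance suite demonstrates >10%
rejection at nominal 5% under a null marker. It is reported because it
is what this style of analysis conventionally quotes, side by side
with a selection-adjusted p-value from the asymptotic distribution of
the maximally selected statistic (the improved Bonferroni-type
approximation for the supremum of a standardized Brownian bridge over
the admissible band, floored at the two-sided normal tail). The
adjusted value is the honest one.

Kaplan–Meier estimation and Cox partial-likelihood maximization use
lifelines (Efron tie handling, Wald confidence intervals). Categorical
covariates are treatment-coded against a declared or modal reference
level; constant covariates are dropped and listed; non-convergence is
reported through a flag with the solver diagnostic. Survival time
units are whatever the cohort supplies and are never converted —
only within-cohort comparisons are made.

## Association statistics

Spearman correlation (average ranks for ties, two-sided p) relates
TMB to MATH and the benefit score to clonal TMB. Immune-cell-fraction
contrasts disambiguate "two-tailed Wilcoxon" by data structure:
rank-sum (unpaired) between high/low groups at baseline; signed-rank
(paired, zero differences dropped) for within-group change from
baseline to on-treatment. Exact null distributions up to 25
observations per side, continuity-corrected normal approximation
beyond. Unadjusted p-values are primary (matching field convention for
per-cell-type reporting); a Benjamini–Hochberg column is emitted
alongside, labeled.

## The synthetic cohort generator

The generator produces cohorts with the structure the analysis
assumes, with full ground truth:

* **Clones.** 1–4 clones per tumor: a truncal clone at CCF 1 and
  subclones occupying stratified bands of the subclonal CCF range
  (default 0.15–0.6). A branching architecture yields ordered,
  distinct subclone CCFs; stratification encodes that deeper
  architectures cover more of the CCF spectrum. The truncal clone
  carries a fixed share of mutations (default 0.4, the shared
  ancestral load); subclones split the remainder equally. Under this
  design median MATH grows strictly with clone count, which a naive
  iid-CCF/uniform-assignment design does not deliver (a 50/50
  two-cluster VAF mixture already nearly maximizes MAD/median).
* **Reads.** Diploid, copy-neutral: expected VAF is
  `purity x CCF / 2`. Depth is Poisson (mean 150, clipped at 1 read);
  alt counts are binomial; zero-alt-read draws go uncalled, which
  slightly biases very low expected VAFs upward — tests account for
  this truncation. Purity is uniform on 0.3–0.9.
* **Burden.** Negative binomial per tumor (mean 200, dispersion 0.9),
  spanning roughly 10–1,000 nonsynonymous mutations as melanoma
  exomes do; 75% of calls are nonsynonymous.
* **Groups and survival.** The true group is defined by a benefit
  propensity — generated nonsynonymous count per clone — above the
  cohort median, so high-group tumors genuinely combine high burden
  with low heterogeneity. Overall survival is exponential (baseline
  hazard 0.03/month) with the low group's hazard multiplied by
  `exp(group_log_hr)` (default log 2), censored by an independent
  uniform draw over 6–60 months (≈50% events). Tying the hazard to
  the true label rather than the continuous score gives an
  unambiguous generative hazard ratio for recovery tests.
* **Immune fractions.** Eight cell types, Dirichlet draws at two
  timepoints; the high group's concentrations are shifted (+2
  activated NK, −2 M2 macrophages) and its on-treatment CD8 T cell
  concentration is boosted (+2.5). Fractions sum to 1 exactly.
* **CCF annotations.** Moment estimate `2 x VAF / purity` (clipped to
  [0, 1]) with a binomial standard error, a normal lower bound, and
  clonal/subclonal probabilities from the normal tail above CCF 0.95.

One master seed fans out through `SeedSequence.spawn` to independent
per-stage generators (mutations, clinical covariates, survival,
immune), so stages are individually reproducible.

What the generator does **not** emulate: copy-number variation and
its effect on VAF (so MATH here is cleaner than in aneuploid tumors),
sequencing error and mapping artifacts, non-proportional hazards,
informative censoring, correlated immune compositions across
timepoints beyond the mean shift, and the batch structure of real
CIBERSORT output. Passing tests therefore demonstrate internal
consistency and statistical calibration of the machinery, not
clinical validity on real cohorts.

## Calibration and recovery checks — problem sizes

Oracle and calibration checks run at sizes chosen to make their
statistics stable: MATH against a brute-force median/MAD
implementation on 1,000 random VAF vectors (tolerance 1e-9); the
cutpoint against an exhaustive matrix-algebra scan on 100 instances
of up to 200 subjects; log-rank and rank-sum p-values against
10,000-replicate permutation oracles on 10 fixtures (within 3
Monte-Carlo SE); null calibration of the log-rank test over 500
simulated 100-patient cohorts with no group effect (rejection within
3–7% at nominal 5%) plus 200 cutpoint scans demonstrating the naive
p's anti-conservatism; Cox recovery of a true hazard ratio 0.5 at
n = 400 over 100 replicates (estimate within [0.35, 0.7] at least 90
times). Null-calibration and recovery checks exercise the survival
stage of the generator directly, since the marker–survival link is
all they measure.

## Known limitations

* The maximally selected statistic's adjusted p is an asymptotic
  approximation; for very small cohorts a permutation of the whole
  selection procedure would be preferable.
* MATH from a single tumor region understates multi-region
  heterogeneity; nothing in the score corrects for that.
* The bivariate "benefit score + clonal TMB" Cox model offered by the
  pipeline is the nearest defined interpretation of a joint analysis;
  the two markers are strongly correlated by construction, so its
  coefficients should be read with the usual collinearity caution.
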