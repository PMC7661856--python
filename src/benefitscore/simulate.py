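"""Synthetic melanoma-like cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

* **Clonal architecture.** Each tumor carries 1–4 clones: one truncal
  clone at cancer cell fraction (CCF) 1 and subclones occupying
  *stratified* CCF bands within a configurable range (a branching
  architecture yields ordered, distinct subclone CCFs, so deeper
  architectures cover more of the CCF spectrum). The truncal clone
  holds a fixed share of the mutations (the shared ancestral load);
  subclones split the remainder equally as private mutations. This
  makes measured heterogeneity grow with the number of clones, as it
  should.
* **Read sampling.** Under a diploid, copy-neutral model the expected
  variant allele fraction of a mutation is ``purity * CCF / 2``.
  Sequencing depth is Poisson; alt reads are binomial at that expected
  fraction. Mutations with zero observed alt reads go uncalled.
* **Mutational burden.** Per-tumor mutation counts are negative
  binomial, spanning roughly 10–1,000 as melanoma exomes do.
* **Survival.** Overall survival is exponential with the hazard raised
  by ``exp(group_log_hr)`` in the low-benefit group, censored by an
  independent uniform draw. Linking the hazard to the *true* group label
  (rather than the continuous score) gives an unambiguous generative
  hazard ratio for recovery tests.
* **Immune composition.** Cell-type fractions are Dirichlet draws at two
  timepoints (pre / on treatment); the high-benefit group gets additive
  concentration shifts (more activated NK, fewer M2 macrophages) and an
  on-treatment CD8 T cell boost.

The true group is defined by a per-tumor benefit propensity — the
generated nonsynonymous mutation count over the number of clones — being
above the cohort median, so that high-group tumors genuinely carry a
high burden and/or low heterogeneity.

One master seed fans out to independent per-stage generators (mutations,
clinical covariates, survival, immune), so any stage can be rerun
reproducibly on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from benefitscore.errors import ConfigurationError

CELL_TYPES = [
    "B cells",
    "T cells CD4",
    "T cells CD8",
    "NK cells activated",
    "Monocytes",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells",
]

#: baseline Dirichlet concentrations per cell type (order of CELL_TYPES)
BASE_ALPHA = np.array([6.0, 10.0, 6.0, 2.0, 5.0, 3.0, 4.0, 3.0])

NONSYN_SUBTYPES = ["Missense_Mutation", "Nonsense_Mutation", "Splice_Site", "Frame_Shift_Del"]
NONSYN_SUBTYPE_P = [0.80, 0.10, 0.05, 0.05]


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Defaults describe a mid-sized immunotherapy melanoma cohort:
    ~100 patients, exome burdens spanning orders of magnitude
    (negative binomial, mean 200, dispersion 0.9), purity 0.3–0.9,
    ~150x mean depth, three-quarters of calls nonsynonymous, a monthly
    baseline hazard of 0.03 with the low-benefit group's hazard doubled
    (log-HR 0.693), and administrative censoring uniform over 6–60
    months of follow-up.
    """

    n_patients: int = 100
    seed: int = 0
    clones_per_tumor: tuple[int, int] = (1, 4)
    subclone_ccf_range: tuple[float, float] = (0.15, 0.6)
    mutations_mean: float = 200.0
    mutations_dispersion: float = 0.9
    truncal_mutation_share: float = 0.4
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 150.0
    nonsynonymous_fraction: float = 0.75
    baseline_hazard: float = 0.03  # events per month in the high group
    group_log_hr: float = float(np.log(2.0))  # extra log-hazard of the low group
    censoring_window: tuple[float, float] = (6.0, 60.0)  # months
    immune_shift: dict = field(
        default_factory=lambda: {"NK cells activated": 2.0, "Macrophages M2": -2.0}
    )
    cd8_on_treatment_shift: float = 2.5  # concentration boost, high group on-treatment

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.clones_per_tumor
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid clones_per_tumor range {self.clones_per_tumor}")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ConfigurationError(f"invalid purity_range {self.purity_range}")
        if not (0 <= self.subclone_ccf_range[0] <= self.subclone_ccf_range[1] <= 1):
            raise ConfigurationError(f"invalid subclone_ccf_range {self.subclone_ccf_range}")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if self.censoring_window[0] <= 0 or self.censoring_window[1] <= self.censoring_window[0]:
            raise ConfigurationError(f"invalid censoring_window {self.censoring_window}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.nonsynonymous_fraction <= 1:
            raise ConfigurationError("nonsynonymous_fraction must be in [0, 1]")
        if not 0 < self.truncal_mutation_share <= 1:
            raise ConfigurationError("truncal_mutation_share must be in (0, 1]")


@dataclass
class SimulatedCohort:
    mutation_table: pd.DataFrame
    clonal_annotations: pd.DataFrame
    survival_table: pd.DataFrame
    immune_fractions: pd.DataFrame
    truth: dict  # {'samples': DataFrame, 'group_log_hr': float, 'config': dict}


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_survival(
    is_high: np.ndarray,
    baseline_hazard: float,
    group_log_hr: float,
    censoring_window: tuple[float, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential survival with the low group's hazard multiplied by
    ``exp(group_log_hr)``, right-censored by an independent uniform draw.
    Returns a frame with ``time`` and ``event`` columns."""
    is_high = np.asarray(is_high, dtype=bool)
    hazard = baseline_hazard * np.exp(group_log_hr * (~is_high))
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(*censoring_window, size=is_high.size)
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"time": time, "event": t_event <= t_cens})


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort: mutation table (MAF-style columns),
    per-mutation clonality annotations, clinical/survival table, immune
    fractions at two timepoints, and the generative truth.

    Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    config.validate()
    rng_mut, rng_clin, rng_surv, rng_imm = _rngs(config.seed, 4)

    sample_ids = [f"S{i:04d}" for i in range(config.n_patients)]
    mut_rows = []
    ann_rows = []
    truth_rows = []
    position_counter = 1

    for sid in sample_ids:
        n_clones = int(rng_mut.integers(config.clones_per_tumor[0], config.clones_per_tumor[1] + 1))
        if n_clones == 1:
            clone_ccfs = np.array([1.0])
        else:
            # one subclone per CCF stratum: a k-clone branching architecture
            # occupies k-1 distinct bands of the subclonal CCF range
            edges = np.linspace(*config.subclone_ccf_range, n_clones)
            subs = np.array(
                [rng_mut.uniform(edges[i], edges[i + 1]) for i in range(n_clones - 1)]
            )
            clone_ccfs = np.concatenate([[1.0], np.sort(subs)[::-1]])
        purity = float(rng_mut.uniform(*config.purity_range))
        k = config.mutations_dispersion
        p_nb = k / (k + config.mutations_mean)
        n_mut = max(1, int(rng_mut.negative_binomial(k, p_nb)))

        if n_clones == 1:
            clone_idx = np.zeros(n_mut, dtype=int)
        else:
            w0 = config.truncal_mutation_share
            weights = np.concatenate([[w0], np.full(n_clones - 1, (1 - w0) / (n_clones - 1))])
            clone_idx = rng_mut.choice(n_clones, size=n_mut, p=weights)
        is_nonsyn = rng_mut.random(n_mut) < config.nonsynonymous_fraction
        subtype_idx = rng_mut.choice(len(NONSYN_SUBTYPES), size=n_mut, p=NONSYN_SUBTYPE_P)
        depth = np.maximum(1, rng_mut.poisson(config.depth_mean, size=n_mut))
        exp_vaf = np.clip(purity * clone_ccfs[clone_idx] / 2.0, 0.0, 1.0)
        alt = rng_mut.binomial(depth, exp_vaf)

        true_tmb = int(is_nonsyn.sum())
        truth_rows.append(
            {
                "sample_id": sid,
                "n_clones": n_clones,
                "clone_ccfs": clone_ccfs.tolist(),
                "purity": purity,
                "n_mutations_generated": n_mut,
                "true_tmb": true_tmb,
            }
        )

        called = alt > 0  # zero alt reads: variant not called
        for j in np.flatnonzero(called):
            pos = position_counter
            position_counter += 1
            classification = (
                NONSYN_SUBTYPES[subtype_idx[j]] if is_nonsyn[j] else "Silent"
            )
            d, a = int(depth[j]), int(alt[j])
            ccf_true = float(clone_ccfs[clone_idx[j]])
            mut_rows.append(
                {
                    "sample_id": sid,
                    "gene_symbol": f"GENE{pos % 997}",
                    "chromosome": str(1 + pos % 22),
                    "position": pos,
                    "ref_allele": "A",
                    "alt_allele": "T",
                    "variant_classification": classification,
                    "t_alt_count": a,
                    "t_ref_count": d - a,
                    "vaf": a / d,
                    "coverage": d,
                }
            )
            if is_nonsyn[j]:
                # moment-based CCF estimate with a binomial standard error
                vaf_hat = a / d
                ccf_hat = float(np.clip(2.0 * vaf_hat / purity, 0.0, 1.0))
                se = 2.0 / purity * np.sqrt(vaf_hat * (1 - vaf_hat) / d)
                lower = float(np.clip(ccf_hat - 1.96 * se, 0.0, 1.0))
                if se > 0:
                    p_clonal = float(stats.norm.sf((0.95 - ccf_hat) / se))
                else:
                    p_clonal = 1.0 if ccf_hat >= 0.95 else 0.0
                ann_rows.append(
                    {
                        "sample_id": sid,
                        "chromosome": str(1 + pos % 22),
                        "position": pos,
                        "alt_allele": "T",
                        "ccf": ccf_hat,
                        "ccf_lower_ci": lower,
                        "p_clonal": p_clonal,
                        "p_subclonal": 1.0 - p_clonal,
                        "true_clone": int(clone_idx[j]),
                        "true_ccf": ccf_true,
                        "is_clonal_true": bool(clone_idx[j] == 0),
                    }
                )

    mutation_table = pd.DataFrame(mut_rows)
    clonal_annotations = pd.DataFrame(ann_rows)
    truth_samples = pd.DataFrame(truth_rows)

    # true group: benefit propensity (burden per clone) above cohort median
    propensity = truth_samples["true_tmb"] / truth_samples["n_clones"]
    truth_samples["benefit_propensity"] = propensity
    truth_samples["true_group"] = np.where(propensity > propensity.median(), "high", "low")

    surv = simulate_survival(
        truth_samples["true_group"].to_numpy() == "high",
        config.baseline_hazard,
        config.group_log_hr,
        config.censoring_window,
        rng_surv,
    )
    survival_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": surv["time"].to_numpy(),
            "event": surv["event"].to_numpy(),
            "age": np.round(rng_clin.normal(62, 11, size=config.n_patients), 1),
            "sex": rng_clin.choice(["Male", "Female"], size=config.n_patients),
            "stage": rng_clin.choice(["III", "IV"], size=config.n_patients, p=[0.35, 0.65]),
            "prior_treatment": rng_clin.choice(["Yes", "No"], size=config.n_patients),
        }
    )

    shift = np.zeros(len(CELL_TYPES))
    for cell, delta in config.immune_shift.items():
        shift[CELL_TYPES.index(cell)] = delta
    cd8_idx = CELL_TYPES.index("T cells CD8")
    imm_rows = []
    for sid, group in zip(sample_ids, truth_samples["true_group"]):
        alpha_pre = np.maximum(0.2, BASE_ALPHA + (shift if group == "high" else 0.0))
        alpha_on = alpha_pre.copy()
        if group == "high":
            alpha_on[cd8_idx] += config.cd8_on_treatment_shift
        for timepoint, alpha in (("pre", alpha_pre), ("on", alpha_on)):
            frac = rng_imm.dirichlet(alpha)
            for cell, f in zip(CELL_TYPES, frac):
                imm_rows.append(
                    {"sample_id": sid, "timepoint": timepoint, "cell_type": cell, "fraction": f}
                )
    immune_fractions = pd.DataFrame(imm_rows)

    truth = {
        "samples": truth_samples,
        "group_log_hr": config.group_log_hr,
        "config": asdict(config),
    }
    return SimulatedCohort(
        mutation_table=mutation_table,
        clonal_annotations=clonal_annotations,
        survival_table=survival_table,
        immune_fractions=immune_fractions,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write a simulated cohort in the exact formats the pipeline reads:
    MAF-style mutation TSV, clinical TSV, clonality TSV, immune-fraction
    TSV, plus truth.json. Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maf = cohort.mutation_table.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene_symbol": "Hugo_Symbol",
            "chromosome": "Chromosome",
            "position": "Start_Position",
            "ref_allele": "Reference_Allele",
            "alt_allele": "Tumor_Seq_Allele2",
            "variant_classification": "Variant_Classification",
        }
    ).drop(columns=["vaf", "coverage"])
    paths = {
        "mutations": outdir / "mutations.maf.tsv",
        "clinical": outdir / "clinical.tsv",
        "clonality": outdir / "clonality.tsv",
        "immune": outdir / "immune_fractions.tsv",
        "truth": outdir / "truth.json",
    }
    maf.to_csv(paths["mutations"], sep="\t", index=False)
    clinical = cohort.survival_table.copy()
    clinical["event"] = clinical["event"].astype(int)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.clonal_annotations.to_csv(paths["clonality"], sep="\t", index=False)
    cohort.immune_fractions.to_csv(paths["immune"], sep="\t", index=False)
    truth_json = {
        "samples": cohort.truth["samples"].to_dict(orient="records"),
        "group_log_hr": cohort.truth["group_log_hr"],
        "config": cohort.truth["config"],
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return {k: str(v) for k, v in paths.items()}


def truth_recovery_report(
    cohort: SimulatedCohort,
    scores: pd.DataFrame,
    cutpoint=None,
    cox=None,
) -> dict:
    """How well the pipeline recovered the generative truth.

    Reports the Spearman correlation between computed TMB and true
    mutation counts, the concordance between cutpoint groups and true
    groups, and the bias of the estimated low-group log-HR against the
    generative one (when a cutpoint / Cox fit is supplied).
    """
    truth = cohort.truth["samples"].set_index("sample_id")
    merged = scores.set_index("sample_id").join(truth, how="inner")
    if len(merged) != len(scores):
        raise ValueError("sample sets of scores and truth do not match")
    res = stats.spearmanr(merged["tmb"], merged["true_tmb"])
    report = {"tmb_spearman_rho": float(res.statistic), "n": int(len(merged))}
    if cutpoint is not None:
        agree = [
            cutpoint.group_assignment.get(sid) == g
            for sid, g in truth["true_group"].items()
            if sid in cutpoint.group_assignment
        ]
        report["group_concordance"] = float(np.mean(agree))
    if cox is not None and cox.converged:
        low_rows = cox.table[(cox.table["covariate"] == "group") & (cox.table["level"] == "low")]
        if len(low_rows):
            est = float(low_rows["coef"].iloc[0])
            report["estimated_low_group_log_hr"] = est
            report["log_hr_bias"] = est - cohort.truth["group_log_hr"]
    return report
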