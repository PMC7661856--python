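"""Per-tumor burden statistics: TMB, MATH, benefit score, clonal TMB.

TMB is the raw count of nonsynonymous somatic mutations (no per-megabase
normalisation — stratification cutpoints are cohort-specific, so the
constant genome size would cancel anyway).

MATH (mutant-allele tumor heterogeneity) summarises the spread of a
tumor's variant allele fractions:

    MATH = 100 * 1.4826 * median(|vaf_i - median(vaf)|) / median(vaf)

i.e. 100 times the consistency-scaled median absolute deviation over the
median. MATH is computed on all quality-passing VAFs by default (the
convention of MAF toolkits), switchable to nonsynonymous-only.

The benefit score is TMB / MATH, with MATH replaced by 1 when it is
exactly zero so that zero-heterogeneity tumors keep a finite score.

Clonal TMB counts nonsynonymous mutations classified clonal from cancer
cell fraction (CCF) evidence, under either of two rules seen across
published cohorts: the confidence-interval rule (lower CCF bound above
0.95) or the point-estimate/probability rule (CCF equal to 1, or clonal
probability exceeding subclonal probability).
"""

from __future__ import annotations

import logging
import math as _math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from benefitscore.errors import DataError, RuleInapplicableError
from benefitscore.mutation_io import FilterPolicy, apply_quality_filters, select_nonsynonymous

logger = logging.getLogger(__name__)

#: scaled-MAD consistency constant (MAD -> sigma under normality)
MAD_CONSTANT = 1.4826

#: fewest VAFs for which a median/MAD summary is considered estimable
DEFAULT_MIN_MUTATIONS_FOR_MATH = 5

SCORE_COLUMNS = [
    "sample_id", "tmb", "math", "math_substituted", "benefit_score",
    "n_vafs_used", "valid",
]


def compute_tmb(sample_mutations: pd.DataFrame) -> int:
    """Count mutations in a table already restricted to one sample and
    already passed through quality + nonsynonymous filters."""
    return int(len(sample_mutations))


def compute_math(
    vafs: Iterable[float], min_mutations: int = DEFAULT_MIN_MUTATIONS_FOR_MATH
) -> float:
    """MATH of a VAF list; ``nan`` when inestimable.

    Inestimable means fewer than ``min_mutations`` values (median and MAD
    are not meaningful summaries of a handful of fractions) or a zero
    median. A VAF outside [0, 1] raises :class:`DataError`.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size and ((v < 0).any() or (v > 1).any()):
        raise DataError("VAF values must lie in [0, 1]")
    if v.size < min_mutations:
        return float("nan")
    med = float(np.median(v))
    if med == 0.0:
        return float("nan")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * MAD_CONSTANT * mad / med


class BenefitScore(NamedTuple):
    score: float
    math_substituted: bool


def compute_benefit_score(tmb: int, math: float) -> BenefitScore:
    """TMB / MATH, substituting MATH=1 when MATH is exactly zero.

    A ``nan`` MATH (inestimable) propagates to a ``nan`` score.
    """
    if tmb < 0:
        raise DataError(f"tmb must be non-negative, got {tmb}")
    if _math.isnan(math):
        return BenefitScore(float("nan"), False)
    if math < 0:
        raise DataError(f"MATH must be non-negative, got {math}")
    if math == 0.0:
        return BenefitScore(float(tmb), True)
    return BenefitScore(tmb / math, False)


def classify_clonal_ci(ccf_lower_ci: float, threshold: float = 0.95) -> bool:
    """Confidence-interval clonality rule: clonal iff the lower CCF
    confidence bound strictly exceeds ``threshold``."""
    if ccf_lower_ci is None or (isinstance(ccf_lower_ci, float) and _math.isnan(ccf_lower_ci)):
        raise RuleInapplicableError(
            "ccf_lower_ci absent; use the CCF point-estimate rule (classify_clonal_ccf)"
        )
    return float(ccf_lower_ci) > threshold


def classify_clonal_ccf(
    ccf: float,
    p_clonal: float | None = None,
    p_subclonal: float | None = None,
    tol: float = 1e-9,
) -> bool:
    """Point-estimate clonality rule: clonal iff CCF equals 1 (within
    ``tol``), or both clonal/subclonal probabilities are present and the
    clonal probability is strictly larger."""
    if ccf is None or _math.isnan(ccf):
        raise RuleInapplicableError("ccf point estimate absent")
    if abs(float(ccf) - 1.0) <= tol:
        return True
    def _present(x):
        return x is not None and not (isinstance(x, float) and _math.isnan(x))
    if _present(p_clonal) and _present(p_subclonal):
        return float(p_clonal) > float(p_subclonal)
    return False


def classify_clonal(annotations: pd.DataFrame, rule: str = "ccf") -> pd.Series:
    """Apply one clonality rule to every row of an annotation table.

    ``rule='ci'`` needs a ``ccf_lower_ci`` column; ``rule='ccf'`` needs
    ``ccf`` and optionally ``p_clonal`` / ``p_subclonal``. A row lacking
    the evidence the chosen rule needs raises, naming the mutation.
    """
    if rule not in ("ci", "ccf"):
        raise DataError(f"unknown clonality rule {rule!r}; expected 'ci' or 'ccf'")
    flags = []
    for _, row in annotations.iterrows():
        try:
            if rule == "ci":
                flags.append(classify_clonal_ci(row.get("ccf_lower_ci", float("nan"))))
            else:
                flags.append(
                    classify_clonal_ccf(
                        row.get("ccf", float("nan")),
                        row.get("p_clonal"),
                        row.get("p_subclonal"),
                    )
                )
        except RuleInapplicableError as exc:
            key = tuple(row.get(k) for k in ("sample_id", "chromosome", "position", "alt_allele"))
            raise RuleInapplicableError(f"{exc} (mutation {key})") from exc
    return pd.Series(flags, index=annotations.index, dtype=bool)


def compute_clonal_tmb(sample_annotations: pd.DataFrame, rule: str = "ccf") -> int:
    """Count clonal mutations among one sample's annotations (which must
    already be joined to nonsynonymous, quality-passing mutations)."""
    if len(sample_annotations) == 0:
        return 0
    return int(classify_clonal(sample_annotations, rule=rule).sum())


def score_cohort(
    mutations: pd.DataFrame,
    policy: FilterPolicy | None = None,
    min_mutations_for_math: int = DEFAULT_MIN_MUTATIONS_FOR_MATH,
    math_on_all_mutations: bool = True,
    tmb_post_filter: bool = True,
) -> pd.DataFrame:
    """Score every sample in a cohort mutation table.

    Quality filters are applied once; TMB counts nonsynonymous records
    (post-filter by default), MATH uses all quality-passing VAFs (or
    nonsynonymous-only when ``math_on_all_mutations=False``). Every
    sample present in the input gets a row; samples whose MATH is
    inestimable are retained with ``valid=False`` and ``nan`` scores so
    downstream stages can report the exclusion.
    """
    policy = policy or FilterPolicy()
    if len(mutations) == 0:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    samples = pd.unique(mutations["sample_id"])
    filtered, _ = apply_quality_filters(mutations, policy)
    nonsyn = select_nonsynonymous(filtered, policy)
    tmb_source = nonsyn if tmb_post_filter else select_nonsynonymous(mutations, policy)
    math_source = filtered if math_on_all_mutations else nonsyn

    tmb_counts = tmb_source.groupby("sample_id").size()
    vaf_groups = math_source.groupby("sample_id")["vaf"]

    rows = []
    for sid in samples:
        vafs = vaf_groups.get_group(sid).to_numpy() if sid in vaf_groups.groups else np.array([])
        math_val = compute_math(vafs, min_mutations=min_mutations_for_math)
        tmb = int(tmb_counts.get(sid, 0))
        score, substituted = compute_benefit_score(tmb, math_val)
        rows.append(
            {
                "sample_id": sid,
                "tmb": tmb,
                "math": math_val,
                "math_substituted": substituted,
                "benefit_score": score,
                "n_vafs_used": int(vafs.size),
                "valid": not _math.isnan(math_val),
            }
        )
    scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    n_excluded = int((~scores["valid"]).sum()) if len(scores) else 0
    if n_excluded:
        logger.info("MATH inestimable for %d of %d samples", n_excluded, len(scores))
    return scores
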