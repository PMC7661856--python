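"""Marker correlations and immune-cell-fraction contrasts.

Immune fractions arrive in long format: one row per (sample_id,
timepoint, cell_type) with a ``fraction`` column; timepoints are
``pre`` (baseline) and ``on`` (on treatment). Between-group contrasts
use the unpaired two-sided Wilcoxon rank-sum test on baseline
fractions; within-group treatment change uses the paired two-sided
Wilcoxon signed-rank test on (on - pre) differences with zero
differences dropped. Exact null distributions are used up to 25
observations per side, a continuity-corrected normal approximation
beyond that.

Unadjusted p-values are what the contrasts report; a Benjamini–Hochberg
column can be appended across cell types for context, clearly labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from benefitscore.errors import DataError, DegenerateInputError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25  # exact rank tests up to this many observations per side


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class GroupComparisonResult:
    cell_type: str
    contrast: str  # 'between_groups_pre' or 'within_group_change'
    statistic: float
    p_value: float
    n_per_side: tuple
    direction: int  # sign of the median difference (high-low, or on-pre)


def spearman_corr(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties and a
    two-sided p-value. Requires n >= 3 and non-constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("inputs must have equal length")
    if x.size < 3:
        raise DataError("need at least 3 pairs for a rank correlation")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("constant input; rank correlation undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def _fraction_vector(
    fractions: pd.DataFrame, cell_type: str, timepoint: str, samples
) -> pd.Series:
    sel = fractions[
        (fractions["cell_type"] == cell_type)
        & (fractions["timepoint"] == timepoint)
        & (fractions["sample_id"].isin(samples))
    ]
    return sel.set_index("sample_id")["fraction"]


def compare_fractions_between_groups(
    fractions: pd.DataFrame,
    groups: dict,
    cell_type: str,
    timepoint: str = "pre",
) -> GroupComparisonResult:
    """Two-sided rank-sum contrast of one cell type's baseline fraction
    between the high and low marker groups."""
    high_ids = [s for s, g in groups.items() if g == "high"]
    low_ids = [s for s, g in groups.items() if g == "low"]
    hi = _fraction_vector(fractions, cell_type, timepoint, high_ids).to_numpy()
    lo = _fraction_vector(fractions, cell_type, timepoint, low_ids).to_numpy()
    for name, arr in (("high", hi), ("low", lo)):
        if arr.size == 0:
            raise DataError(
                f"group {name!r} has no {cell_type!r} fractions at timepoint {timepoint!r}"
            )
    method = "exact" if max(hi.size, lo.size) <= EXACT_N_MAX else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    return GroupComparisonResult(
        cell_type=cell_type,
        contrast="between_groups_pre",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_side=(int(hi.size), int(lo.size)),
        direction=int(np.sign(np.median(hi) - np.median(lo))),
    )


def compare_on_treatment_change(
    fractions: pd.DataFrame,
    group_members,
    cell_type: str,
) -> GroupComparisonResult:
    """Two-sided signed-rank test of one cell type's change from the
    baseline to the on-treatment timepoint, within one group.

    Samples missing either timepoint are excluded (count logged); zero
    differences are dropped per the classical signed-rank convention.
    """
    pre = _fraction_vector(fractions, cell_type, "pre", group_members)
    on = _fraction_vector(fractions, cell_type, "on", group_members)
    paired = pre.index.intersection(on.index)
    n_unpaired = len(set(group_members)) - len(paired)
    if n_unpaired:
        logger.info("%d samples lack a pre/on pair for %s; excluded", n_unpaired, cell_type)
    if len(paired) < 2:
        raise DataError(f"need >= 2 pre/on pairs for {cell_type!r}, got {len(paired)}")
    diff = (on.loc[paired] - pre.loc[paired]).to_numpy()
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        raise DegenerateInputError("all pre/on differences are zero")
    method = "exact" if nonzero.size <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return GroupComparisonResult(
        cell_type=cell_type,
        contrast="within_group_change",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_side=(int(nonzero.size),),
        direction=int(np.sign(np.median(diff))),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (reported alongside, never
    replacing, the unadjusted ones)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
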