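"""Survival stratification: Kaplan–Meier, log-rank, maximally selected
log-rank cutpoints, and multivariate Cox regression.

The cutpoint machinery dichotomizes a continuous marker at the threshold
that maximizes the absolute standardized two-group log-rank statistic
over all admissible splits (each group at least ``minprop`` of the
cohort). Candidate thresholds are midpoints between consecutive distinct
marker values; among ties the smallest threshold wins. The log-rank p at
the selected threshold ("naive") ignores the selection and is known to
be anti-conservative, so an adjusted p-value based on the asymptotic
distribution of the maximally selected statistic (Ornstein–Uhlenbeck
bridge approximation) is reported alongside it.

Kaplan–Meier estimation and Cox partial-likelihood fitting (Efron tie
handling) are delegated to lifelines; the two-group log-rank statistic
is computed in-package because the cutpoint scan evaluates it at every
candidate split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from benefitscore.errors import DataError, DegenerateInputError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutpointResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "find_optimal_cutpoint",
    "dichotomize",
    "cox_fit",
    "maxstat_adjusted_p",
]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at observed death times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1


@dataclass
class CutpointResult:
    threshold: float
    statistic: float  # maximal |standardized log-rank statistic|
    chi_square: float
    group_assignment: dict
    n_high: int
    n_low: int
    naive_logrank_p: float
    adjusted_p: float
    minprop: float


@dataclass
class CoxFit:
    """Per-level hazard ratios from a multivariate Cox model.

    ``table`` has one row per fitted coefficient: covariate, level,
    coef, hr, ci_low, ci_high, p. ``reference_levels`` records the
    baseline level of each categorical covariate; ``dropped`` lists
    covariates removed for zero variance.
    """

    table: pd.DataFrame
    reference_levels: dict
    converged: bool
    dropped: list = field(default_factory=list)
    diagnostics: str = ""
    n: int = 0
    n_events: int = 0


def _as_arrays(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=bool)
    if time.size == 0:
        raise DegenerateInputError("empty survival table")
    if (time <= 0).any():
        raise DataError("survival times must be positive")
    return time, event


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier estimate from a table with ``time`` and ``event``
    columns (event=True means death observed). Censored times reduce the
    risk set without producing a probability drop."""
    time, event = _as_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    death_rows = tbl[tbl["observed"] > 0]
    event_times = death_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = death_rows["at_risk"].to_numpy(dtype=int)
    return KMCurve(event_times=event_times, survival_prob=surv, at_risk=at_risk)


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_a: np.ndarray):
    """Observed-minus-expected deaths in group A and its hypergeometric
    variance, summed over distinct death times."""
    death_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    observed_a = 0.0
    for t in death_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = event & (time == t)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        observed_a += d_a
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e, var, observed_a


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test (chi-square with 1 df, hypergeometric
    variance). Both groups must be nonempty and at least one event must
    be observed overall."""
    time_a, event_a = _as_arrays(group_a)
    time_b, event_b = _as_arrays(group_b)
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    if not event.any():
        raise DegenerateInputError("no events observed; log-rank undefined")
    in_a = np.zeros(time.size, dtype=bool)
    in_a[: time_a.size] = True
    o_minus_e, var, _ = _logrank_oe(time, event, in_a)
    if var == 0:
        raise DegenerateInputError("zero log-rank variance (degenerate risk sets)")
    chi2 = o_minus_e**2 / var
    return LogRankResult(chi_square=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)))


def maxstat_adjusted_p(b: float, minprop: float) -> float:
    """Selection-adjusted p-value for a maximally selected log-rank
    statistic |Z|max = b, scanned over splits with group proportions in
    [minprop, 1 - minprop]; improved Bonferroni-type approximation for
    the supremum of a standardized Brownian bridge on that band."""
    if b <= 0:
        return 1.0
    eps1, eps2 = minprop, 1.0 - minprop
    phi_b = stats.norm.pdf(b)
    band = np.log((eps2 * (1 - eps1)) / ((1 - eps2) * eps1))
    p = 4 * phi_b / b + phi_b * (b - 1 / b) * band
    return float(min(1.0, max(p, 2 * stats.norm.sf(b))))


def dichotomize(marker: dict | pd.Series, threshold: float) -> dict:
    """Map each sample to 'high' (marker strictly above threshold) or
    'low' (at or below)."""
    items = marker.items() if hasattr(marker, "items") else marker
    return {sid: ("high" if value > threshold else "low") for sid, value in items}


def find_optimal_cutpoint(
    marker: dict | pd.Series,
    records: pd.DataFrame,
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected log-rank dichotomization of a continuous marker.

    ``marker`` maps sample_id to the marker value; ``records`` carries
    ``sample_id``, ``time``, ``event``. Every record must have a marker
    value. Returns the admissible threshold with the largest absolute
    standardized log-rank statistic (smallest threshold on ties), plus
    the naive and selection-adjusted p-values at that threshold.
    """
    marker = dict(marker.items() if hasattr(marker, "items") else marker)
    missing = [sid for sid in records["sample_id"] if sid not in marker]
    if missing:
        raise DataError(f"marker undefined for samples: {missing[:5]}")
    time, event = _as_arrays(records)
    values = np.array([marker[sid] for sid in records["sample_id"]], dtype=float)
    n = values.size
    if not event.any():
        raise DegenerateInputError("no events observed; cutpoint undefined")

    distinct = np.unique(values)
    if distinct.size < 2:
        raise DegenerateInputError("marker constant; no admissible split")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_group = int(np.ceil(minprop * n))

    best = None  # (|z|, threshold, chi2)
    for thr in candidates:
        high = values > thr
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group:
            continue
        o_minus_e, var, _ = _logrank_oe(time, event, high)
        if var <= 0:
            continue
        z = abs(o_minus_e) / np.sqrt(var)
        if best is None or z > best[0] + 1e-12:
            best = (z, thr, z**2)
    if best is None:
        raise DegenerateInputError(
            f"no admissible split under minprop={minprop} (n={n})"
        )
    z_max, threshold, chi2 = best
    assignment = dichotomize({sid: marker[sid] for sid in records["sample_id"]}, threshold)
    n_high = sum(1 for g in assignment.values() if g == "high")
    return CutpointResult(
        threshold=float(threshold),
        statistic=float(z_max),
        chi_square=float(chi2),
        group_assignment=assignment,
        n_high=n_high,
        n_low=len(assignment) - n_high,
        naive_logrank_p=float(stats.chi2.sf(chi2, df=1)),
        adjusted_p=maxstat_adjusted_p(float(z_max), minprop),
        minprop=float(minprop),
    )


def _build_design(
    records: pd.DataFrame, covariates: list[str], reference_levels: dict | None
) -> tuple[pd.DataFrame, dict, list, list]:
    """Expand categoricals to treatment-coded dummies; drop constants."""
    reference_levels = dict(reference_levels or {})
    design = pd.DataFrame(index=records.index)
    refs_used: dict = {}
    dropped: list[str] = []
    coef_meta: list[tuple[str, str]] = []  # (covariate, level) per column
    for cov in covariates:
        if cov not in records.columns:
            raise DataError(f"covariate {cov!r} missing from survival table")
        col = records[cov]
        if col.nunique(dropna=False) < 2:
            dropped.append(cov)
            continue
        if col.dtype == object or col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype(str)
            ref = str(reference_levels.get(cov, col.value_counts().idxmax()))
            refs_used[cov] = ref
            for level in sorted(set(col.unique()) - {ref}):
                name = f"{cov}[{level}]"
                design[name] = (col == level).astype(float)
                coef_meta.append((cov, level))
        else:
            design[cov] = col.astype(float)
            coef_meta.append((cov, ""))
    return design, refs_used, dropped, coef_meta


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    reference_levels: dict | None = None,
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Categorical covariates are treatment-coded against a declared (or
    modal) reference level. Constant covariates are dropped and listed;
    non-convergence is reported through the ``converged`` flag with the
    solver diagnostic, never silently.
    """
    time, event = _as_arrays(records)
    design, refs_used, dropped, coef_meta = _build_design(records, covariates, reference_levels)
    if design.shape[1] == 0:
        return CoxFit(
            table=pd.DataFrame(
                columns=["covariate", "level", "coef", "hr", "ci_low", "ci_high", "p"]
            ),
            reference_levels=refs_used,
            converged=False,
            dropped=dropped,
            diagnostics="no usable covariates (all constant)",
            n=int(time.size),
            n_events=int(event.sum()),
        )
    if time.size < design.shape[1] + 1:
        raise DataError("fewer subjects than parameters")
    frame = design.copy()
    frame["time"] = time
    frame["event"] = event.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
        summary = cph.summary
        rows = []
        for (cov, level), (_, srow) in zip(coef_meta, summary.iterrows()):
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "coef": float(srow["coef"]),
                    "hr": float(srow["exp(coef)"]),
                    "ci_low": float(srow["exp(coef) lower 95%"]),
                    "ci_high": float(srow["exp(coef) upper 95%"]),
                    "p": float(srow["p"]),
                }
            )
        return CoxFit(
            table=pd.DataFrame(rows),
            reference_levels=refs_used,
            converged=True,
            dropped=dropped,
            n=int(time.size),
            n_events=int(event.sum()),
        )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return CoxFit(
            table=pd.DataFrame(
                columns=["covariate", "level", "coef", "hr", "ci_low", "ci_high", "p"]
            ),
            reference_levels=refs_used,
            converged=False,
            dropped=dropped,
            diagnostics=str(exc),
            n=int(time.size),
            n_events=int(event.sum()),
        )
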