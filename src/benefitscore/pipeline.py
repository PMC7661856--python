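"""End-to-end analysis: scores -> cutpoints -> survival -> Cox ->
correlations -> immune contrasts.

``analyze`` is the in-memory core; ``run_analysis`` wraps it with file
IO (TSV inputs, TSV/JSON outputs plus a run manifest). All stage
outputs are plain text so every stage can be audited and re-run; the
data-dependent cutpoints in particular are persisted as JSON.

Each cohort is analyzed on its own — markers and cutpoints are
cohort-specific and no pooling across cohorts is performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from benefitscore.errors import ConfigurationError, DataError, DegenerateInputError
from benefitscore.mutation_io import FilterPolicy, apply_quality_filters, read_maf, select_nonsynonymous
from benefitscore.burden import classify_clonal, score_cohort
from benefitscore.survival import (
    CoxFit,
    CutpointResult,
    KMCurve,
    LogRankResult,
    cox_fit,
    find_optimal_cutpoint,
    km_estimate,
    logrank_test,
)
from benefitscore.association import (
    bh_adjust,
    compare_fractions_between_groups,
    compare_on_treatment_change,
    spearman_corr,
)

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ("tmb", "math", "benefit_score")
DEFAULT_IMMUNE_BETWEEN = ("NK cells activated", "Macrophages M2")
DEFAULT_IMMUNE_CHANGE = ("T cells CD8",)


@dataclass
class AnalysisConfig:
    """File-based configuration for :func:`run_analysis`."""

    mutations: str
    clinical: str
    outdir: str
    clonality: str | None = None
    immune: str | None = None
    markers: tuple = DEFAULT_MARKERS
    minprop: float = 0.1
    covariates: tuple = ("age", "sex", "stage")
    reference_levels: dict = field(default_factory=dict)
    clonality_rule: str = "ccf"
    min_mutations_for_math: int = 5
    min_vaf: float = 0.05
    min_coverage_exclusive: int = 30
    seed: int = 0

    def policy(self) -> FilterPolicy:
        return FilterPolicy(
            min_vaf=self.min_vaf, min_coverage_exclusive=self.min_coverage_exclusive
        )


@dataclass
class AnalysisReport:
    scores: pd.DataFrame
    survival: pd.DataFrame  # scored samples joined to clinical
    exclusions: pd.DataFrame  # sample_id, reason
    cutpoints: dict  # marker -> CutpointResult
    logrank: dict  # marker -> LogRankResult
    km_curves: dict  # marker -> {'high': KMCurve, 'low': KMCurve}
    cox: CoxFit | None
    correlations: dict  # name -> CorrelationResult
    immune_contrasts: pd.DataFrame | None
    manifest: dict


def _clonal_tmb_per_sample(
    mutations: pd.DataFrame,
    clonality: pd.DataFrame,
    policy: FilterPolicy,
    rule: str,
) -> pd.Series:
    """Clonal TMB per sample: clonality annotations joined to the
    quality-passing nonsynonymous mutation set, classified and counted."""
    filtered, _ = apply_quality_filters(mutations, policy)
    nonsyn = select_nonsynonymous(filtered, policy)
    keys = ["sample_id", "chromosome", "position", "alt_allele"]
    usable = [k for k in keys if k in nonsyn.columns and k in clonality.columns]

    def _norm(frame):
        out = frame.copy()
        for k in usable:
            if k == "position":
                out[k] = pd.to_numeric(out[k]).astype("int64")
            else:
                out[k] = out[k].astype(str)
        return out

    joined = _norm(clonality).merge(
        _norm(nonsyn)[usable].drop_duplicates(), on=usable, how="inner"
    )
    if len(joined) == 0:
        return pd.Series(dtype=int)
    joined = joined.assign(_clonal=classify_clonal(joined, rule=rule))
    return joined.groupby("sample_id")["_clonal"].sum().astype(int)


def analyze(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    clonality: pd.DataFrame | None = None,
    immune: pd.DataFrame | None = None,
    policy: FilterPolicy | None = None,
    markers: tuple = DEFAULT_MARKERS,
    minprop: float = 0.1,
    covariates: tuple = ("age", "sex", "stage"),
    reference_levels: dict | None = None,
    clonality_rule: str = "ccf",
    min_mutations_for_math: int = 5,
    group_marker: str = "benefit_score",
    immune_between: tuple = DEFAULT_IMMUNE_BETWEEN,
    immune_change: tuple = DEFAULT_IMMUNE_CHANGE,
) -> AnalysisReport:
    """Run the full analysis on in-memory tables.

    Returns a report carrying every stage result; samples excluded at
    any stage (inestimable heterogeneity, missing clinical row) are
    listed with a reason so that input samples are conserved:
    n_input = n_analyzed + n_excluded.
    """
    policy = policy or FilterPolicy()
    scores = score_cohort(
        mutations, policy, min_mutations_for_math=min_mutations_for_math
    )

    if clonality is not None and len(clonality):
        ctmb = _clonal_tmb_per_sample(mutations, clonality, policy, clonality_rule)
        scores["clonal_tmb"] = scores["sample_id"].map(ctmb).fillna(0).astype(int)

    exclusion_rows = [
        {"sample_id": sid, "reason": "heterogeneity_inestimable"}
        for sid in scores.loc[~scores["valid"], "sample_id"]
    ]
    valid = scores[scores["valid"]]
    survival = valid.merge(clinical, on="sample_id", how="inner")
    missing_clinical = set(valid["sample_id"]) - set(survival["sample_id"])
    exclusion_rows += [
        {"sample_id": sid, "reason": "no_clinical_record"} for sid in sorted(missing_clinical)
    ]
    exclusions = pd.DataFrame(exclusion_rows, columns=["sample_id", "reason"])
    survival = survival.assign(event=survival["event"].astype(bool))

    cutpoints: dict[str, CutpointResult] = {}
    logrank_results: dict[str, LogRankResult] = {}
    km_curves: dict[str, dict[str, KMCurve]] = {}
    for marker in markers:
        if marker not in survival.columns:
            logger.warning("marker %s not available; skipped", marker)
            continue
        values = survival.set_index("sample_id")[marker]
        try:
            cp = find_optimal_cutpoint(values, survival, minprop=minprop)
        except DegenerateInputError as exc:
            logger.warning("cutpoint for %s failed: %s", marker, exc)
            continue
        cutpoints[marker] = cp
        grp = survival["sample_id"].map(cp.group_assignment)
        high = survival[grp == "high"]
        low = survival[grp == "low"]
        logrank_results[marker] = logrank_test(high, low)
        km_curves[marker] = {"high": km_estimate(high), "low": km_estimate(low)}

    cox = None
    if group_marker in cutpoints:
        cp = cutpoints[group_marker]
        records = survival.assign(group=survival["sample_id"].map(cp.group_assignment))
        cov = [c for c in covariates if c in records.columns] + ["group"]
        refs = {**(reference_levels or {}), "group": "high"}
        cox = cox_fit(records, cov, reference_levels=refs)

    correlations = {}
    if len(valid) >= 3 and valid["tmb"].nunique() > 1 and valid["math"].nunique() > 1:
        correlations["tmb_vs_math"] = spearman_corr(valid["tmb"], valid["math"])
    if "clonal_tmb" in valid.columns and len(valid) >= 3 and valid["clonal_tmb"].nunique() > 1:
        correlations["benefit_score_vs_clonal_tmb"] = spearman_corr(
            valid["benefit_score"], valid["clonal_tmb"]
        )

    immune_contrasts = None
    if immune is not None and len(immune) and group_marker in cutpoints:
        groups = cutpoints[group_marker].group_assignment
        rows = []
        for cell in immune_between:
            try:
                r = compare_fractions_between_groups(immune, groups, cell)
                rows.append({"cell_type": cell, "contrast": r.contrast, "group": "high_vs_low",
                             "statistic": r.statistic, "p": r.p_value,
                             "n": r.n_per_side, "direction": r.direction})
            except (DataError, DegenerateInputError) as exc:
                logger.warning("between-group contrast for %s failed: %s", cell, exc)
        for cell in immune_change:
            for gname in ("high", "low"):
                members = [s for s, g in groups.items() if g == gname]
                try:
                    r = compare_on_treatment_change(immune, members, cell)
                    rows.append({"cell_type": cell, "contrast": r.contrast, "group": gname,
                                 "statistic": r.statistic, "p": r.p_value,
                                 "n": r.n_per_side, "direction": r.direction})
                except (DataError, DegenerateInputError) as exc:
                    logger.warning("change contrast for %s (%s) failed: %s", cell, gname, exc)
        immune_contrasts = pd.DataFrame(rows)
        if len(immune_contrasts):
            immune_contrasts["p_bh"] = bh_adjust(immune_contrasts["p"])

    from importlib.metadata import version as _pkg_version

    try:
        _version = _pkg_version("benefitscore")
    except Exception:
        _version = "unknown"
    manifest = {
        "version": _version,
        "n_input_samples": int(scores["sample_id"].nunique()),
        "n_analyzed": int(len(survival)),
        "n_excluded": int(len(exclusions)),
        "markers": [m for m in markers if m in cutpoints],
    }
    return AnalysisReport(
        scores=scores,
        survival=survival,
        exclusions=exclusions,
        cutpoints=cutpoints,
        logrank=logrank_results,
        km_curves=km_curves,
        cox=cox,
        correlations=correlations,
        immune_contrasts=immune_contrasts,
        manifest=manifest,
    )


def compare_markers(report: AnalysisReport) -> pd.DataFrame:
    """Side-by-side stratification performance of every marker that got
    a cutpoint: naive and selection-adjusted log-rank p, the univariate
    hazard ratio of the low group, and group sizes. No winner is
    declared — rank by whichever column fits the question."""
    if len(report.cutpoints) < 2:
        raise DataError("need at least two stratified markers to compare")
    rows = []
    for marker, cp in report.cutpoints.items():
        records = report.survival.assign(
            group=report.survival["sample_id"].map(cp.group_assignment)
        )
        fit = cox_fit(records, ["group"], reference_levels={"group": "high"})
        hr = float(fit.table["hr"].iloc[0]) if fit.converged and len(fit.table) else float("nan")
        rows.append(
            {
                "marker": marker,
                "threshold": cp.threshold,
                "n_high": cp.n_high,
                "n_low": cp.n_low,
                "chi_square": cp.chi_square,
                "naive_p": cp.naive_logrank_p,
                "adjusted_p": cp.adjusted_p,
                "hr_low_vs_high": hr,
            }
        )
    return pd.DataFrame(rows)


def joint_marker_cox(report: AnalysisReport, markers: tuple = ("benefit_score", "clonal_tmb")) -> CoxFit:
    """Bivariate Cox with two dichotomized markers entered together —
    the nearest defined interpretation of considering them
    simultaneously. The markers are typically strongly correlated, so
    read the coefficients with the usual collinearity caution."""
    records = report.survival.copy()
    for marker in markers:
        if marker in report.cutpoints:
            cp = report.cutpoints[marker]
        else:
            if marker not in records.columns:
                raise DataError(f"marker {marker!r} not available for a joint model")
            cp = find_optimal_cutpoint(
                records.set_index("sample_id")[marker], records, minprop=0.1
            )
        records[f"{marker}_group"] = records["sample_id"].map(cp.group_assignment)
    cols = [f"{m}_group" for m in markers]
    return cox_fit(records, cols, reference_levels={c: "high" for c in cols})


def _km_frame(km_curves: dict) -> pd.DataFrame:
    rows = []
    for group, curve in km_curves.items():
        for t, s, r in zip(curve.event_times, curve.survival_prob, curve.at_risk):
            rows.append({"group": group, "time": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, outdir) -> dict:
    """Persist every stage of a report as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _save_tsv(name, frame):
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)

    def _save_json(name, obj):
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(obj, indent=1, default=float))
        paths[name] = str(p)

    _save_tsv("scores", report.scores)
    _save_tsv("exclusions", report.exclusions)
    for marker, cp in report.cutpoints.items():
        _save_json(
            f"cutpoint_{marker}",
            {
                "threshold": cp.threshold,
                "statistic": cp.statistic,
                "chi_square": cp.chi_square,
                "n_high": cp.n_high,
                "n_low": cp.n_low,
                "naive_logrank_p": cp.naive_logrank_p,
                "adjusted_p": cp.adjusted_p,
                "minprop": cp.minprop,
            },
        )
        _save_tsv(f"km_{marker}", _km_frame(report.km_curves[marker]))
    if report.logrank:
        _save_tsv(
            "logrank",
            pd.DataFrame(
                [
                    {"marker": m, "chi_square": r.chi_square, "df": r.df, "p": r.p_value}
                    for m, r in report.logrank.items()
                ]
            ),
        )
    if report.cox is not None:
        _save_tsv("cox", report.cox.table)
        _save_json(
            "cox_meta",
            {
                "converged": report.cox.converged,
                "reference_levels": report.cox.reference_levels,
                "dropped": report.cox.dropped,
                "diagnostics": report.cox.diagnostics,
                "n": report.cox.n,
                "n_events": report.cox.n_events,
            },
        )
    if report.correlations:
        _save_json(
            "correlations",
            {k: {"rho": v.rho, "p": v.p_value, "n": v.n} for k, v in report.correlations.items()},
        )
    if report.immune_contrasts is not None:
        _save_tsv("immune_contrasts", report.immune_contrasts)
    manifest = dict(report.manifest)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    _save_json("manifest", manifest)
    return paths


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """File-based entry point: read inputs named in ``config``, run
    :func:`analyze`, persist all outputs under ``config.outdir``."""
    for attr in ("mutations", "clinical"):
        if not Path(getattr(config, attr)).exists():
            raise ConfigurationError(f"{attr} file not found: {getattr(config, attr)}")
    mutations = read_maf(config.mutations)
    clinical = _read_tsv(config.clinical)
    clonality = _read_tsv(config.clonality) if config.clonality else None
    immune = _read_tsv(config.immune) if config.immune else None
    report = analyze(
        mutations,
        clinical,
        clonality=clonality,
        immune=immune,
        policy=config.policy(),
        markers=tuple(config.markers),
        minprop=config.minprop,
        covariates=tuple(config.covariates),
        reference_levels=config.reference_levels,
        clonality_rule=config.clonality_rule,
        min_mutations_for_math=config.min_mutations_for_math,
    )
    report.manifest["config"] = asdict(config)
    write_report(report, config.outdir)
    return report
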