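"""Reading and filtering MAF-style somatic mutation tables.

Tables are held as pandas DataFrames with canonical column names
(``sample_id``, ``variant_classification``, ``t_alt_count``,
``t_ref_count``, plus derived ``vaf`` and ``coverage``). A *dialect*
maps canonical names to the header names of a particular export; the
default dialect follows GDC MAF conventions.

Coverage is defined as ``t_alt_count + t_ref_count`` — the only
read-count fields universally present in MAF exports. Records with
zero coverage have an undefined allele fraction and are dropped at read
time (the drop is logged and counted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from benefitscore.errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: canonical name -> GDC MAF header
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene_symbol": "Hugo_Symbol",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
    "t_alt_count": "t_alt_count",
    "t_ref_count": "t_ref_count",
}

REQUIRED_FIELDS = ("sample_id", "variant_classification", "t_alt_count", "t_ref_count")

#: MAF classes counted as nonsynonymous (protein-altering).
NONSYNONYMOUS_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)

#: MAF classes recognized as synonymous / non-coding (not counted, not warned).
SYNONYMOUS_CLASSES: frozenset[str] = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Splice_Region",
        "Targeted_Region",
        "lincRNA",
    }
)


@dataclass(frozen=True)
class FilterPolicy:
    """Quality and functional-class filter settings.

    ``min_vaf`` excludes records with allele fraction strictly below it;
    ``min_coverage_exclusive`` excludes records with coverage at or below
    it (coverage must strictly exceed the threshold to survive).
    """

    min_vaf: float = 0.05
    min_coverage_exclusive: int = 30
    nonsynonymous_classes: frozenset[str] = NONSYNONYMOUS_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ConfigurationError(f"min_vaf must be in [0, 1], got {self.min_vaf}")
        if self.min_coverage_exclusive < 0:
            raise ConfigurationError(
                f"min_coverage_exclusive must be >= 0, got {self.min_coverage_exclusive}"
            )


@dataclass
class FilterReport:
    """Counts from one pass of :func:`apply_quality_filters`.

    Counts are additive: ``n_in == n_removed_vaf + n_removed_coverage +
    n_out`` (coverage removals are counted among VAF-passing records).
    """

    n_in: int = 0
    n_removed_vaf: int = 0
    n_removed_coverage: int = 0
    n_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _resolve_columns(columns, dialect: dict[str, str]) -> dict[str, str]:
    resolved = {}
    for canonical in REQUIRED_FIELDS:
        header = dialect.get(canonical, canonical)
        if header not in columns:
            raise ConfigurationError(
                f"required column {header!r} (for {canonical!r}) not found in MAF header"
            )
        resolved[canonical] = header
    for canonical, header in dialect.items():
        if canonical not in resolved and header in columns:
            resolved[canonical] = header
    return resolved


def read_maf(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a MAF-style tab-separated mutation table.

    Lines starting with ``#`` are skipped; gzip compression is detected
    from the file name. Returns one row per mutation with canonical
    columns plus derived ``vaf`` and ``coverage``; rows with zero
    coverage are dropped (count logged).

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved through the dialect.
    DataError
        If a read count fails to parse as a non-negative integer.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, compression="infer", skip_blank_lines=True
    )
    resolved = _resolve_columns(raw.columns, dialect)
    table = pd.DataFrame({canon: raw[header] for canon, header in resolved.items()})

    for count_col in ("t_alt_count", "t_ref_count"):
        parsed = pd.to_numeric(table[count_col], errors="coerce")
        bad = parsed.isna() | (parsed < 0) | (parsed % 1 != 0)
        if bad.any():
            row = int(bad.idxmax())
            raise DataError(
                f"unparseable {count_col} value {table[count_col][row]!r} "
                f"at data row {row + 1} of {path}"
            )
        table[count_col] = parsed.astype(int)

    if "position" in table.columns:
        table["position"] = pd.to_numeric(table["position"], errors="coerce").astype("Int64")
    if (table["sample_id"].isna() | (table["sample_id"] == "")).any():
        raise DataError(f"empty sample_id encountered in {path}")

    table["coverage"] = table["t_alt_count"] + table["t_ref_count"]
    zero_cov = table["coverage"] == 0
    if zero_cov.any():
        logger.info("dropping %d zero-coverage records from %s", int(zero_cov.sum()), path)
        table = table.loc[~zero_cov].reset_index(drop=True)
    table["vaf"] = table["t_alt_count"] / table["coverage"]
    return table


def apply_quality_filters(
    table: pd.DataFrame, policy: FilterPolicy | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop records failing the VAF / coverage quality thresholds.

    A record survives iff ``vaf >= policy.min_vaf`` and
    ``coverage > policy.min_coverage_exclusive``. The input is not
    modified; removal counts are returned in a :class:`FilterReport`.
    """
    policy = policy or FilterPolicy()
    report = FilterReport(n_in=len(table))
    vaf_ok = table["vaf"] >= policy.min_vaf
    cov_ok = table["coverage"] > policy.min_coverage_exclusive
    report.n_removed_vaf = int((~vaf_ok).sum())
    report.n_removed_coverage = int((vaf_ok & ~cov_ok).sum())
    out = table.loc[vaf_ok & cov_ok].reset_index(drop=True)
    report.n_out = len(out)
    logger.info(
        "quality filter: %d in, %d removed (vaf), %d removed (coverage), %d out",
        report.n_in, report.n_removed_vaf, report.n_removed_coverage, report.n_out,
    )
    return out, report


def select_nonsynonymous(
    table: pd.DataFrame, policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Keep only protein-altering records (the classes TMB counts).

    Classification values outside both the nonsynonymous and the known
    synonymous vocabularies trigger a warning; such records are excluded
    either way.
    """
    policy = policy or FilterPolicy()
    classes = table["variant_classification"]
    unknown = set(classes.unique()) - set(policy.nonsynonymous_classes) - set(SYNONYMOUS_CLASSES)
    if unknown:
        warnings.warn(
            f"unknown variant_classification values excluded: {sorted(unknown)}",
            stacklevel=2,
        )
    return table.loc[classes.isin(policy.nonsynonymous_classes)].reset_index(drop=True)
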