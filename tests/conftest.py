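import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles importable as a module

from benefitscore.simulate import SimulationConfig, simulate_cohort


def make_mutation_table(rows):
    """Canonical-column mutation table from (sample, class, alt, ref) tuples."""
    records = []
    for i, (sample, classification, alt, ref) in enumerate(rows):
        cov = alt + ref
        records.append(
            {
                "sample_id": sample,
                "gene_symbol": f"G{i}",
                "chromosome": "1",
                "position": i + 1,
                "ref_allele": "A",
                "alt_allele": "T",
                "variant_classification": classification,
                "t_alt_count": alt,
                "t_ref_count": ref,
                "vaf": alt / cov if cov else float("nan"),
                "coverage": cov,
            }
        )
    return pd.DataFrame(records)


def write_maf(path, rows, header_extra=""):
    """Write a minimal GDC-dialect MAF file from (sample, class, alt, ref)."""
    lines = ["#version synthetic-fixture"]
    lines.append(
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\t"
        "Variant_Classification\tTumor_Sample_Barcode\tt_alt_count\tt_ref_count" + header_extra
    )
    for i, (sample, classification, alt, ref) in enumerate(rows):
        lines.append(f"G{i}\t1\t{i + 1}\tA\tT\t{classification}\t{sample}\t{alt}\t{ref}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-sized synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=60, seed=20260919))


@pytest.fixture()
def survival_frame():
    """Build a survival DataFrame from (time, event) pairs."""

    def _build(pairs, **extra_cols):
        frame = pd.DataFrame(
            {
                "sample_id": [f"P{i}" for i in range(len(pairs))],
                "time": [t for t, _ in pairs],
                "event": [bool(e) for _, e in pairs],
            }
        )
        for name, values in extra_cols.items():
            frame[name] = values
        return frame

    return _build


@pytest.fixture()
def rng():
    return np.random.default_rng(77)
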