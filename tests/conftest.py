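import numpy as np
import pandas as pd
import pytest

from pgx_smoke.panel_io import (
    GenotypeMatrix,
    SnpDef,
    SubjectRecord,
    load_default_allele_definitions,
    load_default_panel,
)
from pgx_smoke.synthetic_data import load_table_counts, reconstruct_from_counts


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def table_counts():
    return load_table_counts()


@pytest.fixture(scope="session")
def matrix(panel, table_counts):
    """Both cohorts reconstructed exactly from the published count tables."""
    return reconstruct_from_counts(table_counts, panel)


@pytest.fixture(scope="session")
def allele_defs():
    return load_default_allele_definitions()


def make_subject(i, cohort="e-Dec", age=35, gender="male"):
    return SubjectRecord(
        subject_id=f"S{i:03d}", cohort=cohort, age=age, gender=gender,
        cigarettes_per_day=10, years_smoking=10, onset_age=min(18, age),
        tobacco_index=5.0,
    )


def matrix_from_doses(snps, dose_rows, cohorts=None):
    """Build a GenotypeMatrix from per-subject minor-allele dose vectors."""
    cohorts = cohorts or ["e-Dec"] * len(dose_rows)
    subjects = [make_subject(i, cohort=c) for i, c in enumerate(cohorts)]
    columns = {}
    for j, snp in enumerate(snps):
        labels = {
            0: snp.major_allele * 2,
            1: "".join(sorted(snp.major_allele + snp.minor_allele)),
            2: snp.minor_allele * 2,
            None: "./.",
        }
        columns[snp.rsid] = [labels[row[j]] for row in dose_rows]
    calls = pd.DataFrame(
        columns, index=pd.Index([s.subject_id for s in subjects], name="subject_id")
    )
    return GenotypeMatrix(subjects, snps, calls)


def toy_snp(rsid="rs0", major="A", minor="G"):
    return SnpDef(rsid, "1", 1000, major, minor, "GENE", "intron", 0.2)
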