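"""Synthetic cohort generation.

Two generators feed the pipeline:

* :func:`reconstruct_from_counts` rebuilds individual-level genotype
  vectors *exactly* from published per-SNP genotype counts (cohort
  sizes 38 and 94).  Columns are reconstructed independently — the
  published tables give only marginal counts, so no within-subject
  haplotype structure across SNPs is claimed.
* :func:`simulate_hwe_cohort` / :func:`simulate_demographics` draw
  parametric cohorts: genotypes binomial(2, MAF) per SNP under
  Hardy-Weinberg equilibrium, and demographic variables from bounded
  triangular distributions parameterized by the published cohort
  medians and ranges.  The tobacco index is derived as cigarettes/day x
  years / 20 — a simulation convention for pack-years, not a formula
  taken from the source data (which reports the index as given).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pgx_smoke.panel_io import (
    MISSING_CALL,
    GenotypeMatrix,
    SnpDef,
    SubjectRecord,
    _data_path,
    load_default_panel,
    normalize_call,
)

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20210619  # publication date of the source tables

#: demographic targets per cohort: (median, min, max) per variable,
#: transcribed from the published demographics table
DEMOGRAPHIC_DEFAULTS = {
    "e-Dec": {
        "age": (35, 20, 60),
        "cigarettes_per_day": (9, 2, 30),
        "years_smoking": (12, 2, 44),
        "onset_age": (20.5, 12, 50),
        "male_fraction": 24 / 38,
    },
    "on-site": {
        "age": (36, 20, 40),
        "cigarettes_per_day": (10, 1, 60),
        "years_smoking": (16, 1, 43),
        "onset_age": (17.5, 9, 50),
        "male_fraction": 57 / 94,
    },
}

COHORT_SIZES = {"e-Dec": 38, "on-site": 94}


@dataclass
class SimConfig:
    """Parameters for the parametric simulators."""

    seed: int = DEFAULT_SEED
    n_per_cohort: tuple = (38, 94)
    maf: dict = field(default_factory=dict)  # rsid -> minor allele frequency
    demographics: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEMOGRAPHIC_DEFAULTS.items()
    })
    spread: float = 1.0  # 0 collapses every demographic draw to its median

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_cohort):
            raise ValueError("cohort sizes must be positive")
        for rsid, f in self.maf.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{rsid}: MAF {f} outside [0,1]")


def default_table_counts_path() -> Path:
    return _data_path("table_counts.tsv")


def load_table_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Load a published-counts table (published-strand letters + six counts)."""
    if path is None:
        path = default_table_counts_path()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str})
    required = {
        "rsid", "maj", "min",
        "edec_hom_maj", "edec_het", "edec_hom_min",
        "onsite_hom_maj", "onsite_het", "onsite_hom_min",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def _subject_ids(cohort: str, n: int) -> list:
    prefix = {"e-Dec": "ED", "on-site": "OS"}[cohort]
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def reconstruct_from_counts(
    counts: pd.DataFrame | None = None,
    panel: list | None = None,
    config: SimConfig | None = None,
) -> GenotypeMatrix:
    """Deterministic genotype matrix reproducing published counts exactly.

    Per SNP and cohort, subjects are filled hom-major first, then
    heterozygous, then hom-minor, in subject order; re-counting any
    column reproduces the input counts.  Demographics are simulated
    (seeded) since individual-level covariates were never published.
    """
    if counts is None:
        counts = load_table_counts()
    if panel is None:
        panel = load_default_panel()
    config = config or SimConfig()
    panel_by_rsid = {s.rsid: s for s in panel}

    cohort_cols = {
        "e-Dec": ("edec_hom_maj", "edec_het", "edec_hom_min"),
        "on-site": ("onsite_hom_maj", "onsite_het", "onsite_hom_min"),
    }
    n_by_cohort = dict(zip(("e-Dec", "on-site"), config.n_per_cohort))

    subjects = simulate_demographics(config)
    ids = {c: _subject_ids(c, n_by_cohort[c]) for c in n_by_cohort}

    snps = []
    columns: dict = {}
    for _, row in counts.iterrows():
        rsid = row["rsid"]
        if rsid not in panel_by_rsid:
            raise ValueError(f"counts table SNP {rsid} not in panel")
        snp = panel_by_rsid[rsid]
        maj, mnr = row["maj"], row["min"]
        genotypes = {0: maj + maj, 1: "".join(sorted(maj + mnr)), 2: mnr + mnr}
        col = []
        for cohort, cols in cohort_cols.items():
            c0, c1, c2 = (int(row[c]) for c in cols)
            if c0 + c1 + c2 != n_by_cohort[cohort]:
                raise ValueError(
                    f"{rsid}/{cohort}: counts {c0}+{c1}+{c2} != n={n_by_cohort[cohort]}"
                )
            block = [genotypes[0]] * c0 + [genotypes[1]] * c1 + [genotypes[2]] * c2
            col.extend(block)
        normalized = [normalize_call(call, snp) for call in col]
        if MISSING_CALL in normalized:
            raise ValueError(f"{rsid}: printed genotypes do not match panel alleles")
        snps.append(snp)
        columns[rsid] = normalized

    index = pd.Index(ids["e-Dec"] + ids["on-site"], name="subject_id")
    calls = pd.DataFrame(columns, index=index)
    return GenotypeMatrix(subjects, snps, calls)


def simulate_hwe_cohort(
    config: SimConfig, panel: list | None = None
) -> GenotypeMatrix:
    """Cohorts drawn under Hardy-Weinberg equilibrium.

    Per subject and SNP the minor-allele dose is binomial(2, MAF),
    independent across subjects and SNPs.  MAFs come from
    ``config.maf`` and default to the panel's catalogued values.
    """
    if panel is None:
        panel = load_default_panel()
    rng = np.random.default_rng(config.seed)
    subjects = simulate_demographics(config)
    n_total = len(subjects)
    index = pd.Index([s.subject_id for s in subjects], name="subject_id")
    columns = {}
    for snp in panel:
        maf = config.maf.get(snp.rsid, snp.gnomad_maf)
        doses = rng.binomial(2, maf, size=n_total)
        labels = {
            0: snp.major_allele * 2,
            1: "".join(sorted(snp.major_allele + snp.minor_allele)),
            2: snp.minor_allele * 2,
        }
        columns[snp.rsid] = [labels[int(d)] for d in doses]
    calls = pd.DataFrame(columns, index=index)
    return GenotypeMatrix(subjects, panel, calls)


def _draw_bounded(rng, median, lo, hi, size, spread):
    """Bounded draws centred on the target median.

    Triangular(lo, median, hi) scaled toward the median by ``spread``;
    spread=0 collapses to the median exactly.
    """
    if not lo <= median <= hi:
        raise ValueError(f"inconsistent bounds: {lo} <= {median} <= {hi} fails")
    if spread == 0 or lo == hi:
        return np.full(size, float(median))
    draws = rng.triangular(lo, median, hi, size=size)
    return median + spread * (draws - median)


def simulate_demographics(config: SimConfig | None = None) -> list:
    """Seeded per-subject demographics for both cohorts.

    Ages, cigarettes/day, years smoking and onset age are drawn from
    bounded distributions matching the published medians and ranges;
    gender is Bernoulli at the published male fraction.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    subjects = []
    for cohort, n in zip(("e-Dec", "on-site"), config.n_per_cohort):
        params = config.demographics[cohort]
        ids = _subject_ids(cohort, n)
        age = _draw_bounded(rng, *params["age"], n, config.spread)
        cpd = _draw_bounded(rng, *params["cigarettes_per_day"], n, config.spread)
        years = _draw_bounded(rng, *params["years_smoking"], n, config.spread)
        onset = _draw_bounded(rng, *params["onset_age"], n, config.spread)
        male = rng.random(n) < params["male_fraction"]
        for i, sid in enumerate(ids):
            cigs = float(np.round(cpd[i]))
            yrs = float(np.round(years[i]))
            age_i = int(np.round(age[i]))
            # onset cannot postdate current age in a coherent simulation
            onset_i = min(float(np.round(onset[i] * 2) / 2), float(age_i))
            subjects.append(SubjectRecord(
                subject_id=sid,
                cohort=cohort,
                age=age_i,
                gender="male" if male[i] else "female",
                cigarettes_per_day=cigs,
                years_smoking=yrs,
                onset_age=onset_i,
                tobacco_index=cigs * yrs / 20.0,  # simulation convention
            ))
    return subjects
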