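"""Genotype/allele counting, contingency tables and the polymorphism filter.

Counts are kept as exact integers; percentages are a report-layer view
(half-up rounding to two decimals, matching the published table style).
Genotype categories are ordered hom-major, het, hom-minor in terms of
the panel's declared alleles, i.e. by minor-allele dose 0/1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import lgamma, exp
from typing import Sequence

import numpy as np

from pgx_smoke.panel_io import MISSING_CALL, GenotypeMatrix, SnpDef

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of the published tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(x: float, ndigits: int = 2, trim: bool = False) -> str:
    """Percentage for report output; ``trim`` drops trailing zeros ("73.4")."""
    s = f"{round_half_up(x, ndigits):.{ndigits}f}"
    if trim and "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts for one cohort at one SNP, by minor-allele dose."""

    hom_major: int
    het: int
    hom_minor: int
    n_missing: int = 0

    @property
    def n(self) -> int:
        return self.hom_major + self.het + self.hom_minor

    @property
    def genotype_counts(self) -> tuple:
        return (self.hom_major, self.het, self.hom_minor)

    @property
    def allele_counts(self) -> tuple:
        """(major, minor) chromosome counts; major = 2*hom_major + het."""
        return (2 * self.hom_major + self.het, 2 * self.hom_minor + self.het)

    @property
    def n_distinct_genotypes(self) -> int:
        return sum(1 for c in self.genotype_counts if c > 0)

    def genotype_frequencies(self) -> tuple:
        n = self.n
        return tuple(100.0 * c / n for c in self.genotype_counts)

    def allele_frequencies(self) -> tuple:
        a = self.allele_counts
        total = sum(a)
        return tuple(100.0 * c / total for c in a)


@dataclass(frozen=True)
class FreqTable:
    """Per-cohort genotype and allele counts/frequencies for one SNP."""

    snp: SnpDef
    cohorts: dict  # cohort label -> CohortCounts

    def counts(self, cohort: str) -> CohortCounts:
        return self.cohorts[cohort]

    @property
    def cohort_labels(self) -> list:
        return list(self.cohorts)

    def is_polymorphic(self) -> bool:
        """At least two distinct observed genotypes in at least one cohort."""
        return any(c.n_distinct_genotypes >= 2 for c in self.cohorts.values())


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("contingency dimensions do not match labels")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if counts.sum() == 0:
            raise ValueError("all-zero contingency table")


def count_genotypes(matrix: GenotypeMatrix, rsid: str) -> FreqTable:
    """Tabulate genotypes per cohort with per-SNP complete-case exclusion."""
    snp = matrix.snp(rsid)
    cohorts = {}
    for cohort in matrix.cohorts:
        tallies = {0: 0, 1: 0, 2: 0}
        missing = 0
        for sid in matrix.subject_ids(cohort):
            dose = matrix.minor_dose(sid, rsid)
            if dose is None:
                missing += 1
            else:
                tallies[dose] += 1
        counts = CohortCounts(tallies[0], tallies[1], tallies[2], missing)
        if counts.n == 0:
            raise ValueError(f"{rsid}: no non-missing genotypes in cohort {cohort}")
        cohorts[cohort] = counts
    return FreqTable(snp=snp, cohorts=cohorts)


def polymorphic_filter(matrix: GenotypeMatrix, rsids: Sequence[str]) -> list:
    """SNPs with >= 2 distinct observed genotypes in at least one cohort."""
    return [r for r in rsids if count_genotypes(matrix, r).is_polymorphic()]


def to_contingency(
    freq: FreqTable, level: str, drop_empty: bool = True
) -> ContingencyTable:
    """Cohorts-by-categories table at genotype (2xk, k<=3) or allele (2x2) level."""
    labels = freq.cohort_labels
    if level == "genotype":
        cols = np.array([freq.counts(c).genotype_counts for c in labels])
        col_labels = ("hom_major", "het", "hom_minor")
        if drop_empty:
            keep = cols.sum(axis=0) > 0
            cols = cols[:, keep]
            col_labels = tuple(l for l, k in zip(col_labels, keep) if k)
    elif level == "allele":
        cols = np.array([freq.counts(c).allele_counts for c in labels])
        col_labels = (freq.snp.major_allele, freq.snp.minor_allele)
        if drop_empty:
            keep = cols.sum(axis=0) > 0
            cols = cols[:, keep]
            col_labels = tuple(l for l, k in zip(col_labels, keep) if k)
    else:
        raise ValueError(f"level must be 'genotype' or 'allele', got {level!r}")
    if (cols.sum(axis=1) == 0).any():
        raise ValueError(f"{freq.snp.rsid}: cohort with zero counts at {level} level")
    return ContingencyTable(tuple(labels), col_labels, cols)


def _log_hwe_prob(n_het: int, n_hom_rare: int, n: int, n_rare: int) -> float:
    """Log probability of a heterozygote count conditional on allele counts."""
    n_common = 2 * n - n_rare
    return (
        lgamma(n + 1)
        - lgamma(n_hom_rare + 1)
        - lgamma(n_het + 1)
        - lgamma(n - n_hom_rare - n_het + 1)
        + n_het * np.log(2.0)
        + lgamma(n_rare + 1)
        + lgamma(n_common + 1)
        - lgamma(2 * n + 1)
    )


def hwe_exact(freq: FreqTable, cohort: str) -> float:
    """Exact Hardy-Weinberg test p-value for one cohort.

    Full enumeration of heterozygote counts conditional on the observed
    allele counts; two-sided by summing configurations no more probable
    than the observed one.
    """
    counts = freq.counts(cohort)
    n = counts.n
    if n == 0:
        raise ValueError("empty cohort")
    maj, het, mnr = counts.genotype_counts
    # work with the rarer allele so the enumeration bounds are tight
    n_minor = 2 * mnr + het
    n_major = 2 * maj + het
    n_rare = min(n_minor, n_major)
    if n_rare == 0:
        return 1.0
    obs = het
    parity = n_rare % 2
    probs = []
    p_obs = None
    for h in range(parity, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        if n - hom_rare - h < 0:
            continue
        p = exp(_log_hwe_prob(h, hom_rare, n, n_rare))
        probs.append(p)
        if h == obs:
            p_obs = p
    total = sum(probs)
    if p_obs is None:  # inconsistent genotype configuration
        raise ValueError("observed heterozygote count incompatible with allele counts")
    p_value = sum(p for p in probs if p <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p_value)
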