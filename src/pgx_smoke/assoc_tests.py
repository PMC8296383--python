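"""Case-control contingency tests and the study's test-selection rule.

The battery mirrors how the source cohorts were analysed: Pearson's
chi-square on 2x3 genotype tables when both groups are informative, the
Fisher exact test on collapsed 2x2 tables when only two genotypes occur,
and a Yates-corrected chi-square for 2x2 allele tables (recomputation of
the published allele p-values shows they carry the continuity
correction).  An exact Freeman-Halton test for 2xk tables is provided
as the exact analogue of the genotype-level chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from math import lgamma, exp

import numpy as np
from scipy import stats

from pgx_smoke.freq_contingency import ContingencyTable, FreqTable, to_contingency

logger = logging.getLogger(__name__)

#: relative slack when comparing table probabilities in exact tests, so
#: float noise cannot exclude tables tied with the observed one
_EXACT_REL_TOL = 1e-9

_FREEMAN_HALTON_MAX_N = 500


@dataclass(frozen=True)
class AssocResult:
    snp: str | None
    level: str
    method: str
    statistic: float | None
    df: int | None
    p_value: float | None
    note: str = ""

    @property
    def tested(self) -> bool:
        return self.p_value is not None


def _as_2xk(table: ContingencyTable) -> np.ndarray:
    counts = np.asarray(table.counts, dtype=np.int64)
    if counts.shape[0] != 2:
        raise ValueError(f"expected 2 rows (cohorts), got {counts.shape[0]}")
    return counts


def pearson_chi2(
    table: ContingencyTable,
    yates: bool = False,
    snp: str | None = None,
    level: str = "genotype",
) -> AssocResult:
    """Pearson chi-square on a 2xk table; Yates correction only for k=2."""
    counts = _as_2xk(table)
    k = counts.shape[1]
    if k < 2:
        raise ValueError("need at least 2 columns")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / counts.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell count; use an exact test instead")
    diff = np.abs(counts - expected)
    method = "pearson_chi2"
    if yates and k == 2:
        diff = np.maximum(diff - 0.5, 0.0)
        method = "pearson_chi2_yates"
    statistic = float((diff**2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return AssocResult(snp, level, method, statistic, df, p)


def _log_table_prob(counts: np.ndarray) -> float:
    """Log hypergeometric probability of a table with fixed margins."""
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    num = sum(lgamma(m + 1) for m in row) + sum(lgamma(m + 1) for m in col)
    den = lgamma(n + 1) + sum(lgamma(c + 1) for c in counts.ravel())
    return num - den


def fisher_2x2(
    table: ContingencyTable, snp: str | None = None, level: str = "genotype"
) -> AssocResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Sums hypergeometric probabilities over all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    counts = _as_2xk(table)
    if counts.shape != (2, 2):
        raise ValueError(f"fisher_2x2 needs a 2x2 table, got {counts.shape}")
    r0, r1 = counts.sum(axis=1)
    c0 = counts.sum(axis=0)[0]
    n = counts.sum()
    p_obs = exp(_log_table_prob(counts))
    p_value = 0.0
    for a in range(max(0, c0 - r1), min(r0, c0) + 1):
        t = np.array([[a, r0 - a], [c0 - a, r1 - (c0 - a)]])
        p = exp(_log_table_prob(t))
        if p <= p_obs * (1 + _EXACT_REL_TOL):
            p_value += p
    return AssocResult(snp, level, "fisher_2x2", None, None, min(1.0, p_value))


def freeman_halton(
    table: ContingencyTable, snp: str | None = None, level: str = "genotype"
) -> AssocResult:
    """Exact (Freeman-Halton) test on a 2xk table, k<=3, by enumeration."""
    counts = _as_2xk(table)
    k = counts.shape[1]
    if k > 3:
        raise ValueError("freeman_halton supports 2x2 and 2x3 tables only")
    n = int(counts.sum())
    if n > _FREEMAN_HALTON_MAX_N:
        raise ValueError(
            f"n={n} too large for enumeration (limit {_FREEMAN_HALTON_MAX_N}); "
            "use pearson_chi2"
        )
    row0 = int(counts.sum(axis=1)[0])
    cols = counts.sum(axis=0)
    p_obs = exp(_log_table_prob(counts))
    p_value = 0.0
    ranges = [range(int(c) + 1) for c in cols[:-1]]
    for cells in product(*ranges):
        last = row0 - sum(cells)
        if last < 0 or last > cols[-1]:
            continue
        top = np.array([*cells, last])
        t = np.vstack([top, cols - top])
        p = exp(_log_table_prob(t))
        if p <= p_obs * (1 + _EXACT_REL_TOL):
            p_value += p
    return AssocResult(snp, level, "freeman_halton", None, None, min(1.0, p_value))


def select_test(
    freq: FreqTable,
    level: str,
    yates_allele: bool = True,
    exact: bool = False,
) -> AssocResult:
    """Apply the study's test-selection rule to one SNP.

    Genotype level: Pearson's chi-square (uncorrected) when one group
    shows three genotypes and the table spans three categories; the
    Fisher exact test on the collapsed 2x2 when only two genotype
    categories occur overall.  Monomorphic SNPs return a flagged null
    result.  ``exact=True`` swaps Pearson for the Freeman-Halton
    enumeration.  Allele level: 2x2 chi-square with the Yates continuity
    correction by default.
    """
    rsid = freq.snp.rsid
    if level == "genotype":
        observed = [freq.counts(c).n_distinct_genotypes for c in freq.cohort_labels]
        table = to_contingency(freq, "genotype", drop_empty=True)
        k = table.counts.shape[1]
        if k == 1:
            return AssocResult(rsid, level, "none", None, None, None,
                               note="monomorphic in both groups (NS)")
        if k == 2:
            if max(observed) < 2:
                return AssocResult(rsid, level, "none", None, None, None,
                                   note="degenerate table (NS)")
            res = fisher_2x2(table, snp=rsid, level=level)
            note = "collapsed to 2x2 (two genotype categories observed)"
            return AssocResult(rsid, level, res.method, res.statistic, res.df,
                               res.p_value, note=note)
        if exact:
            return freeman_halton(table, snp=rsid, level=level)
        return pearson_chi2(table, yates=False, snp=rsid, level=level)
    if level == "allele":
        table = to_contingency(freq, "allele", drop_empty=True)
        if table.counts.shape[1] == 1:
            return AssocResult(rsid, level, "none", None, None, None,
                               note="monomorphic in both groups (NS)")
        if exact:
            return fisher_2x2(table, snp=rsid, level=level)
        try:
            return pearson_chi2(table, yates=yates_allele, snp=rsid, level=level)
        except ValueError:
            # zero expected cell (allele absent in one cohort only): exact fallback
            res = fisher_2x2(table, snp=rsid, level=level)
            return AssocResult(rsid, level, res.method, None, None, res.p_value,
                               note="exact fallback (zero expected cell)")
    raise ValueError(f"level must be 'genotype' or 'allele', got {level!r}")


def bonferroni(p_values: list, m: int | None = None) -> list:
    """Optional family-wise correction column (not applied by default)."""
    m = m or len(p_values)
    return [None if p is None else min(1.0, p * m) for p in p_values]
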