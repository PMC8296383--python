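"""Nonparametric cohort comparisons and age/gender matching.

Mann-Whitney U compares the two recruitment cohorts variable by
variable (medians with min-max ranges, as in the demographic table);
Kruskal-Wallis extends the comparison to the three metabolizer groups.
Small samples (< 8 per group) use exact permutation enumeration, which
is cheap there and handles ties without an approximation; larger
samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from pgx_smoke.panel_io import SubjectRecord
from pgx_smoke.assoc_tests import fisher_2x2
from pgx_smoke.freq_contingency import ContingencyTable

logger = logging.getLogger(__name__)

EXACT_THRESHOLD = 8  # per-group size below which the exact MW enumeration runs


@dataclass(frozen=True)
class GroupSummary:
    """Median (min-max) style summary of one variable across groups."""

    variable: str
    groups: dict  # label -> dict(n, median, min, max, q1, q3)

    def formatted(self, label: str) -> str:
        g = self.groups[label]
        return f"{_fmt(g['median'])} ({_fmt(g['min'])}–{_fmt(g['max'])})"


def _fmt(x: float) -> str:
    return f"{x:g}"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> dict:
    """Mann-Whitney U test (two-sided by default).

    Returns dict with ``u``, ``p_value`` and ``method``.  Exact
    enumeration of all rank assignments when both groups are smaller
    than 8; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        logger.warning("all values identical across both samples; p = 1")
        return {"u": u_obs, "p_value": 1.0, "method": "degenerate"}
    if max(n, m) < EXACT_THRESHOLD:
        pooled = np.concatenate([x, y])
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for chosen in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if alternative == "two-sided":
                extreme = abs(u - mu) >= dev_obs - 1e-9
            elif alternative == "greater":
                extreme = u >= u_obs - 1e-9
            elif alternative == "less":
                extreme = u <= u_obs + 1e-9
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            if extreme:
                hits += 1
        return {"u": u_obs, "p_value": hits / total, "method": "exact_enumeration"}
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return {"u": float(res.statistic), "p_value": float(res.pvalue),
            "method": "normal_approx"}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict:
    """Tie-corrected Kruskal-Wallis H test, chi-square reference, df=k-1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across groups; p = 1")
        return {"h": 0.0, "df": len(groups) - 1, "p_value": 1.0}
    h, p = stats.kruskal(*arrays)
    return {"h": float(h), "df": len(groups) - 1, "p_value": float(p)}


def summarize(
    subjects: Sequence[SubjectRecord],
    variable: str,
    grouping: str = "cohort",
) -> GroupSummary:
    """Median, range and quartiles of a numeric subject variable per group."""
    groups: dict = {}
    labels = []
    for s in subjects:
        label = getattr(s, grouping)
        if label not in groups:
            groups[label] = []
            labels.append(label)
        groups[label].append(float(getattr(s, variable)))
    out = {}
    for label in labels:
        vals = np.array(groups[label])
        if len(vals) == 0:
            logger.warning("group %s empty for %s; omitted", label, variable)
            continue
        out[label] = {
            "n": len(vals),
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
    return GroupSummary(variable=variable, groups=out)


@dataclass
class MatchResult:
    retained: list  # SubjectRecord, both cohorts
    balance: dict = field(default_factory=dict)


def match_cohorts(
    subjects: Sequence[SubjectRecord],
    reference_cohort: str = "e-Dec",
    other_cohort: str = "on-site",
    ratio: float = 1.0,
    keys: tuple = ("gender", "age"),
) -> MatchResult:
    """Greedy nearest-age matching of the larger cohort to the reference.

    Within each exact gender stratum, reference subjects repeatedly pick
    their nearest-age unmatched candidate (ties broken by subject_id
    order) until ``round(ratio * n_reference)`` candidates are retained
    or the stratum is exhausted.  All reference subjects are always
    retained.  Deterministic: no randomness is involved.
    """
    ref = sorted((s for s in subjects if s.cohort == reference_cohort),
                 key=lambda s: s.subject_id)
    cand = sorted((s for s in subjects if s.cohort == other_cohort),
                  key=lambda s: s.subject_id)
    if not ref or not cand:
        raise ValueError("both cohorts must be present")
    target = min(len(cand), int(round(ratio * len(ref))))

    strata = sorted({s.gender for s in ref})
    pool = {g: [s for s in cand if s.gender == g] for g in strata}
    for g in strata:
        if not pool[g]:
            logger.warning("no %s candidates in stratum %r; stratum skipped",
                           other_cohort, g)
    chosen: list = []
    progressed = True
    while len(chosen) < target and progressed:
        progressed = False
        for r in ref:
            if len(chosen) >= target:
                break
            candidates = pool.get(r.gender, [])
            if not candidates:
                continue
            best = min(candidates, key=lambda s: (abs(s.age - r.age), s.subject_id))
            candidates.remove(best)
            chosen.append(best)
            progressed = True

    retained = ref + chosen
    balance = _balance_report(ref, chosen)
    return MatchResult(retained=retained, balance=balance)


def _balance_report(ref: list, matched: list) -> dict:
    out: dict = {"n_reference": len(ref), "n_matched": len(matched)}
    if not matched:
        return out
    out["age_p"] = mann_whitney([s.age for s in ref],
                                [s.age for s in matched])["p_value"]
    table = ContingencyTable(
        ("reference", "matched"),
        ("male", "female"),
        np.array([
            [sum(s.gender == "male" for s in ref), sum(s.gender == "female" for s in ref)],
            [sum(s.gender == "male" for s in matched), sum(s.gender == "female" for s in matched)],
        ]),
    )
    out["gender_p"] = fisher_2x2(table).p_value
    return out
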