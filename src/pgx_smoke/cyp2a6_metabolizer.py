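"""CYP2A6 metabolizer phenotyping.

Two classification rules are implemented side by side:

* **minor-allele count** (the study's headline rule): total minor-allele
  dose across the five polymorphic CYP2A6 SNPs (rs28399433, rs28399434,
  rs8192720, rs2431413, rs5031017) — 0 copies = normal metabolizer,
  1 = intermediate, >= 2 = slow.  rs1137115 is deliberately excluded as
  a non-specific marker of decreased-function alleles.
* **allele function** (the catalogue rule): unphased star-allele pairs
  are called from the defining SNPs, then mapped through the published
  function-pair table — normal x normal -> normal; normal x decreased
  -> intermediate; any pair containing a loss-of-function allele, or
  two decreased alleles, -> slow.

Both rules mirror the nicotine-metabolite (3HC/COT) groupings from the
literature; no metabolite measurements are modelled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pgx_smoke.panel_io import GenotypeMatrix, StarAlleleDef, SubjectRecord
from pgx_smoke.cohort_nonparam import kruskal_wallis

logger = logging.getLogger(__name__)

PHENOTYPES = ("normal", "intermediate", "slow", "unclassified")

#: the five polymorphic CYP2A6 SNPs used by the minor-allele-count rule
DEFAULT_MINOR_COUNT_SNPS = (
    "rs28399433",
    "rs28399434",
    "rs8192720",
    "rs2431413",
    "rs5031017",
)

#: deliberately excluded from the default rule (non-specific marker)
EXCLUDED_MINOR_COUNT_SNP = "rs1137115"


@dataclass(frozen=True)
class MetabolizerCall:
    subject_id: str
    rule: str  # minor_allele_count | allele_function
    phenotype: str
    evidence: tuple = ()
    note: str = ""


def _dose_class(dose: int) -> str:
    if dose == 0:
        return "normal"
    if dose == 1:
        return "intermediate"
    return "slow"


def classify_by_minor_count(
    matrix: GenotypeMatrix, snp_set: Sequence[str] | None = None
) -> list:
    """Classify each subject by total minor-allele dose across ``snp_set``.

    A subject is unclassified only when missing genotypes could change
    the class (observed dose and worst-case dose disagree).
    """
    if snp_set is None:
        snp_set = DEFAULT_MINOR_COUNT_SNPS
    snp_set = list(snp_set)
    for rsid in snp_set:
        matrix.snp(rsid)  # raises PanelError for non-panel rsIDs
    calls = []
    for subject in matrix.subjects:
        dose = 0
        n_missing = 0
        evidence = []
        for rsid in snp_set:
            d = matrix.minor_dose(subject.subject_id, rsid)
            if d is None:
                n_missing += 1
            else:
                dose += d
                if d:
                    evidence.append((rsid, d))
        lo_class = _dose_class(dose)
        hi_class = _dose_class(dose + 2 * n_missing)
        if lo_class != hi_class:
            calls.append(MetabolizerCall(
                subject.subject_id, "minor_allele_count", "unclassified",
                tuple(evidence), note=f"{n_missing} missing genotype(s)"))
        else:
            calls.append(MetabolizerCall(
                subject.subject_id, "minor_allele_count", lo_class,
                tuple(evidence)))
    return calls


def call_star_alleles(
    matrix: GenotypeMatrix,
    defs: Sequence[StarAlleleDef],
    trans_on_ambiguity: bool = True,
) -> dict:
    """Unphased star-allele pair per subject.

    Each observed minor-allele copy at a defining SNP contributes one
    copy of its star allele (for multi-SNP definitions, the copy number
    is the minimum dose across the defining SNPs); remaining haplotype
    slots are filled with *1.  Minor alleles at two different defining
    SNPs are placed in trans (one per haplotype) — the parsimony
    assumption; set ``trans_on_ambiguity=False`` to leave such subjects
    unclassified instead.  Subjects whose star-allele copies exceed two
    haplotype slots, or with missing defining genotypes, are
    unclassified with a diagnostic.
    """
    owner: dict = {}
    for d in defs:
        for rsid in d.defining_snps:
            if rsid in owner:
                raise ValueError(f"SNP {rsid} claimed by {owner[rsid]} and {d.name}")
            owner[rsid] = d.name
    by_name = {d.name: d for d in defs}
    if "*1" not in by_name:
        raise ValueError("allele definitions must include the reference allele *1")

    results: dict = {}
    for subject in matrix.subjects:
        sid = subject.subject_id
        copies: dict = {}
        missing = []
        for d in defs:
            if not d.defining_snps:
                continue
            doses = []
            for rsid, required in d.defining_snps.items():
                if rsid not in matrix.calls.columns:
                    continue
                call = matrix.call(sid, rsid)
                if call == "./.":
                    missing.append(rsid)
                    doses.append(0)
                else:
                    doses.append(call.count(required))
            if doses and min(doses) > 0:
                copies[d.name] = min(doses)
        total = sum(copies.values())
        if missing:
            results[sid] = {"pair": None, "status": "unclassified",
                            "note": f"missing genotypes: {sorted(set(missing))}"}
        elif total > 2:
            results[sid] = {"pair": None, "status": "unclassified",
                            "note": f"minor-allele dose {total} exceeds 2 haplotypes"}
        elif len(copies) == 2 and not trans_on_ambiguity:
            results[sid] = {"pair": None, "status": "unclassified",
                            "note": "ambiguous phase (two distinct star alleles)"}
        else:
            alleles = []
            for name, k in sorted(copies.items()):
                alleles.extend([name] * k)
            while len(alleles) < 2:
                alleles.append("*1")
            results[sid] = {"pair": tuple(sorted(alleles)), "status": "called",
                            "note": ""}
    return results


# the six published diplotype-function combinations
_FUNCTION_PAIRS = {
    frozenset(["normal"]): "normal",                    # normal/normal
    frozenset(["normal", "decreased"]): "intermediate",
    frozenset(["normal", "loss_of_function"]): "slow",
    frozenset(["decreased", "loss_of_function"]): "slow",
    frozenset(["decreased"]): "slow",                   # decreased/decreased
    frozenset(["loss_of_function"]): "slow",            # loss/loss
}


def classify_by_function(
    pair: tuple, defs: Sequence[StarAlleleDef], subject_id: str = ""
) -> MetabolizerCall:
    """Map an unphased star-allele pair to a metabolizer phenotype."""
    by_name = {d.name: d for d in defs}
    functions = []
    for name in pair:
        if name not in by_name:
            raise ValueError(f"undefined star allele {name}")
        functions.append(by_name[name].function_class)
    if "unknown" in functions:
        return MetabolizerCall(subject_id, "allele_function", "unclassified",
                               (tuple(pair), tuple(functions)),
                               note="allele of unknown function")
    phenotype = _FUNCTION_PAIRS[frozenset(functions)]
    return MetabolizerCall(subject_id, "allele_function", phenotype,
                           (tuple(pair), tuple(functions)))


def classify_matrix_by_function(
    matrix: GenotypeMatrix, defs: Sequence[StarAlleleDef],
    trans_on_ambiguity: bool = True,
) -> list:
    """Star-allele calling followed by function-pair classification."""
    pairs = call_star_alleles(matrix, defs, trans_on_ambiguity=trans_on_ambiguity)
    calls = []
    for subject in matrix.subjects:
        res = pairs[subject.subject_id]
        if res["status"] != "called":
            calls.append(MetabolizerCall(subject.subject_id, "allele_function",
                                         "unclassified", (), note=res["note"]))
        else:
            calls.append(classify_by_function(res["pair"], defs,
                                              subject_id=subject.subject_id))
    return calls


def phenotype_vs_smoking(
    calls: Sequence[MetabolizerCall],
    subjects: Sequence[SubjectRecord],
    variable: str = "cigarettes_per_day",
) -> dict:
    """Compare a smoking variable across metabolizer phenotype groups.

    Returns per-group n/median/IQR and an omnibus Kruskal-Wallis p-value
    across the non-empty phenotype groups (unclassified excluded).
    """
    by_id = {s.subject_id: s for s in subjects}
    groups: dict = {}
    for call in calls:
        if call.phenotype == "unclassified":
            continue
        subject = by_id.get(call.subject_id)
        if subject is None:
            continue
        groups.setdefault(call.phenotype, []).append(float(getattr(subject, variable)))
    for label in [k for k, v in groups.items() if not v]:
        logger.warning("phenotype group %s empty; dropped", label)
        del groups[label]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty phenotype groups")
    summary = {
        label: {
            "n": len(vals),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
        for label, vals in groups.items()
    }
    kw = kruskal_wallis(list(groups.values()))
    return {"variable": variable, "groups": summary, "p_value": kw["p_value"],
            "h": kw["h"]}
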