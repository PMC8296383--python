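"""Panel, genotype and allele-definition I/O.

The SNP panel covers two variant sets: fourteen CYP2A6 coding-region /
promoter variants chosen so that each (set of) SNP(s) discriminates a
named star allele, and seventeen variants in smoking-behaviour loci
(NRXN1, DRD4, HTR2A, CHRNA3, CHRNA5 and one intergenic site near CYP2A6).

Genotype calls are stored on the panel's canonical strand.  Published
genotype tables for several panel SNPs are reported on the opposite
strand (e.g. an A>C variant tabulated as T/G genotypes); input calls on
either strand are complement-mapped to canonical on load, so downstream
counting never sees mixed strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MISSING_CALL = "./."

CONSEQUENCES = ("missense", "synonymous", "intron", "upstream_2kb", "intergenic")

#: aliases accepted in panel files, mapping the descriptive table wording
#: onto the canonical consequence enumeration
_CONSEQUENCE_ALIASES = {
    "missense": "missense",
    "missense variant": "missense",
    "synonymous": "synonymous",
    "synonymous variant": "synonymous",
    "intron": "intron",
    "intron variant": "intron",
    "upstream_2kb": "upstream_2kb",
    "2kb upstream": "upstream_2kb",
    "2kb upstream variant": "upstream_2kb",
    "intergenic": "intergenic",
    "intergene": "intergenic",
}

FUNCTION_CLASSES = ("normal", "decreased", "loss_of_function", "unknown")

COHORTS = ("e-Dec", "on-site")
GENDERS = ("male", "female")


class PanelError(ValueError):
    """Malformed panel, genotype or allele-definition input."""


@dataclass(frozen=True)
class SnpDef:
    """One panel SNP.

    ``major_allele``/``minor_allele`` follow the panel's allele-change
    notation ("X > Y"); the empirical major allele in a given cohort may
    differ and is determined at the counting layer.
    """

    rsid: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    gene: str
    consequence: str
    gnomad_maf: float

    def __post_init__(self) -> None:
        if self.major_allele not in NUCLEOTIDES or self.minor_allele not in NUCLEOTIDES:
            raise PanelError(
                f"{self.rsid}: alleles must be single nucleotides, got "
                f"{self.major_allele!r}/{self.minor_allele!r}"
            )
        if self.major_allele == self.minor_allele:
            raise PanelError(f"{self.rsid}: major and minor allele are identical")
        if self.position <= 0:
            raise PanelError(f"{self.rsid}: position must be positive")
        if not 0.0 <= self.gnomad_maf <= 1.0:
            raise PanelError(f"{self.rsid}: gnomAD MAF {self.gnomad_maf} outside [0,1]")
        if self.consequence not in CONSEQUENCES:
            raise PanelError(f"{self.rsid}: unknown consequence {self.consequence!r}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.major_allele, self.minor_allele))


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject demographics; tobacco index is pack-years as given."""

    subject_id: str
    cohort: str
    age: int
    gender: str
    cigarettes_per_day: float
    years_smoking: float
    onset_age: float
    tobacco_index: float

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise PanelError(f"{self.subject_id}: unknown cohort {self.cohort!r}")
        if self.gender not in GENDERS:
            raise PanelError(f"{self.subject_id}: unknown gender {self.gender!r}")
        for name in ("cigarettes_per_day", "years_smoking", "onset_age", "tobacco_index"):
            if getattr(self, name) < 0:
                raise PanelError(f"{self.subject_id}: {name} must be >= 0")
        # age < onset happens in messy questionnaire data; flag, don't reject
        if self.age < self.onset_age:
            logger.warning(
                "subject %s: age %s < onset age %s (kept, flagged)",
                self.subject_id, self.age, self.onset_age,
            )


@dataclass(frozen=True)
class StarAlleleDef:
    """A named CYP2A6 haplotype and its catalogued function class.

    ``defining_snps`` maps rsID -> required minor allele (canonical
    strand).  The reference allele ``*1`` is the only allele with an
    empty definition: it is what remains when no panel minor allele is
    observed.
    """

    name: str
    defining_snps: Mapping[str, str]
    function_class: str

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise PanelError(
                f"star allele {self.name}: function class {self.function_class!r} "
                f"not in {FUNCTION_CLASSES}"
            )
        if not self.defining_snps and self.name != "*1":
            raise PanelError(f"star allele {self.name}: empty SNP definition")


class GenotypeMatrix:
    """Subjects x SNPs diploid calls with cohort labels.

    Calls are two-character strings of canonical-strand alleles in
    alphabetical order ("AC"), or ``"./."`` for missing.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        snps: Sequence[SnpDef],
        calls: pd.DataFrame,
    ):
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate subject IDs")
        if list(calls.index) != ids or list(calls.columns) != [s.rsid for s in snps]:
            raise PanelError("call matrix axes do not match subjects/snps")
        self.subjects = list(subjects)
        self.snps = list(snps)
        self.calls = calls
        self._snp_by_rsid = {s.rsid: s for s in self.snps}

    def snp(self, rsid: str) -> SnpDef:
        try:
            return self._snp_by_rsid[rsid]
        except KeyError:
            raise PanelError(f"SNP {rsid} not in panel") from None

    @property
    def rsids(self) -> list:
        return [s.rsid for s in self.snps]

    @property
    def cohorts(self) -> list:
        seen = []
        for s in self.subjects:
            if s.cohort not in seen:
                seen.append(s.cohort)
        return seen

    def subject_ids(self, cohort: str | None = None) -> list:
        return [s.subject_id for s in self.subjects if cohort is None or s.cohort == cohort]

    def call(self, subject_id: str, rsid: str) -> str:
        return self.calls.at[subject_id, rsid]

    def minor_dose(self, subject_id: str, rsid: str) -> int | None:
        """Copies of the panel minor allele carried; None if missing."""
        call = self.call(subject_id, rsid)
        if call == MISSING_CALL:
            return None
        return call.count(self.snp(rsid).minor_allele)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.subjects == other.subjects
            and self.snps == other.snps
            and self.calls.equals(other.calls)
        )


def parse_allele_change(text: str) -> tuple:
    """Parse an ``"X > Y"`` allele change into (X, Y)."""
    parts = [p.strip() for p in text.split(">")]
    if len(parts) != 2 or any(p not in NUCLEOTIDES for p in parts):
        raise PanelError(f"malformed allele change {text!r} (expected 'X > Y')")
    return parts[0], parts[1]


def normalize_consequence(text: str) -> str:
    key = text.strip().lower()
    if key not in _CONSEQUENCE_ALIASES:
        raise PanelError(f"unknown consequence string {text!r}")
    return _CONSEQUENCE_ALIASES[key]


def normalize_call(call: str, snp: SnpDef) -> str:
    """Map a two-letter call on either strand to canonical panel strand.

    Identity mapping is preferred; the complement is used only when the
    call does not fit the declared alleles as written.  Calls that fit
    neither strand are returned as missing.  Idempotent by construction
    (a canonical call always fits by identity).
    """
    if call == MISSING_CALL:
        return MISSING_CALL
    letters = sorted(call)
    if len(letters) != 2 or any(c not in NUCLEOTIDES for c in letters):
        return MISSING_CALL
    if set(letters) <= snp.alleles:
        return "".join(letters)
    flipped = sorted(COMPLEMENT[c] for c in letters)
    if set(flipped) <= snp.alleles:
        return "".join(flipped)
    return MISSING_CALL


def genotype_label(snp: SnpDef, dose: int, published_strand: bool = False) -> str:
    """Two-letter genotype for a minor-allele dose, optionally complemented."""
    if dose not in (0, 1, 2):
        raise ValueError(f"dose must be 0, 1 or 2, got {dose}")
    maj, mnr = snp.major_allele, snp.minor_allele
    if published_strand:
        maj, mnr = COMPLEMENT[maj], COMPLEMENT[mnr]
    return {0: maj + maj, 1: maj + mnr, 2: mnr + mnr}[dose]


def _data_path(name: str) -> Path:
    return Path(resources.files("pgx_smoke").joinpath("data", name))


def default_panel_path() -> Path:
    return _data_path("panel.tsv")


def default_allele_definitions_path() -> Path:
    return _data_path("cyp2a6_alleles.yaml")


def load_panel(path: str | Path) -> list:
    """Load the SNP panel table.

    Expected TSV header: rsid, chrom, pos, major, minor, gene,
    consequence, maf — or an ``allele_change`` column ("X > Y") in place
    of major/minor.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        logger.warning("panel file %s contains no SNPs", path)
        return []
    snps = []
    seen = set()
    for i, row in df.iterrows():
        where = f"{path} row {i + 2} ({row.get('rsid', '?')})"
        try:
            if "allele_change" in df.columns:
                major, minor = parse_allele_change(row["allele_change"])
            else:
                major, minor = row["major"].strip(), row["minor"].strip()
            snp = SnpDef(
                rsid=row["rsid"].strip(),
                chromosome=str(row["chrom"]).strip(),
                position=int(row["pos"]),
                major_allele=major,
                minor_allele=minor,
                gene=row["gene"].strip(),
                consequence=normalize_consequence(row["consequence"]),
                gnomad_maf=float(row["maf"]),
            )
        except (KeyError, ValueError) as exc:
            raise PanelError(f"bad panel row at {where}: {exc}") from exc
        if snp.rsid in seen:
            raise PanelError(f"duplicate rsID {snp.rsid} at {where}")
        seen.add(snp.rsid)
        snps.append(snp)
    return snps


def load_default_panel() -> list:
    return load_panel(default_panel_path())


def load_demographics(path: str | Path) -> list:
    """Load the per-subject demographics TSV (one row per subject)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "subject_id", "cohort", "age", "gender",
        "cigarettes_per_day", "years_smoking", "onset_age", "tobacco_index",
    }
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"demographics file missing columns: {sorted(missing)}")
    return [
        SubjectRecord(
            subject_id=row["subject_id"],
            cohort=row["cohort"],
            age=int(float(row["age"])),
            gender=row["gender"],
            cigarettes_per_day=float(row["cigarettes_per_day"]),
            years_smoking=float(row["years_smoking"]),
            onset_age=float(row["onset_age"]),
            tobacco_index=float(row["tobacco_index"]),
        )
        for _, row in df.iterrows()
    ]


def load_genotypes(
    path: str | Path,
    panel: Sequence[SnpDef],
    subjects: Sequence[SubjectRecord],
    format: str = "tsv",
) -> GenotypeMatrix:
    """Load a genotype file against a panel, strand-normalizing calls.

    TSV dialect: one subject per row (``subject_id`` column), one rsID
    column per SNP, cells two-character allele pairs or ``"./."``.
    VCF dialect: VCF 4.2 with GT fields; sample IDs must match
    ``subjects``.  Calls that fit neither panel strand become missing
    (counted and logged).
    """
    if format == "tsv":
        raw = _read_genotype_tsv(path)
    elif format == "vcf":
        raw = _read_genotype_vcf(path, panel)
    else:
        raise PanelError(f"unknown genotype format {format!r}")

    by_id = {s.subject_id: s for s in subjects}
    unknown_subjects = [sid for sid in raw.index if sid not in by_id]
    if unknown_subjects:
        raise PanelError(
            f"subjects in genotype file absent from demographics: {unknown_subjects}"
        )
    panel_by_rsid = {s.rsid: s for s in panel}
    unknown_snps = [c for c in raw.columns if c not in panel_by_rsid]
    if unknown_snps:
        raise PanelError(f"SNP columns not in panel: {unknown_snps}")

    n_unrecognized = 0
    norm = {}
    for rsid in raw.columns:
        snp = panel_by_rsid[rsid]
        col = []
        for cell in raw[rsid]:
            call = normalize_call(cell, snp)
            if call == MISSING_CALL and cell != MISSING_CALL:
                n_unrecognized += 1
            col.append(call)
        norm[rsid] = col
    if n_unrecognized:
        logger.warning("%d genotype calls did not match either panel strand; set missing",
                       n_unrecognized)

    matrix_subjects = [by_id[sid] for sid in raw.index]
    matrix_snps = [panel_by_rsid[c] for c in raw.columns]
    calls = pd.DataFrame(norm, index=raw.index)[list(raw.columns)]
    return GenotypeMatrix(matrix_subjects, matrix_snps, calls)


def _read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise PanelError("genotype TSV must have a subject_id column")
    return df.set_index("subject_id").fillna(MISSING_CALL)


def _read_genotype_vcf(path: str | Path, panel: Sequence[SnpDef]) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency, TSV is the primary dialect

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict = {}
    for variant in vcf:
        rsid = variant.ID
        alleles = [variant.REF] + list(variant.ALT)
        col = []
        for gt in variant.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col.append(MISSING_CALL)
            else:
                col.append(alleles[a] + alleles[b])
        data[rsid] = col
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = matrix.calls.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (e.g. star-allele names)."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise PanelError(f"duplicate key {key!r} in allele definition config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def load_allele_definitions(path: str | Path) -> list:
    """Load the star-allele definition config (YAML).

    Layout::

        alleles:
          "*1": {function: normal, snps: {}}
          "*9": {function: decreased, snps: {rs28399433: C}}

    Each panel SNP may appear in at most one allele definition (the
    panel was designed so each SNP set discriminates a single allele).
    """
    with open(path) as fh:
        config = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(config, dict) or "alleles" not in config:
        raise PanelError("allele definition config must have an 'alleles' mapping")
    defs = []
    snp_owner: dict = {}
    for name, body in config["alleles"].items():
        snps = dict(body.get("snps") or {})
        for rsid, allele in snps.items():
            if allele not in NUCLEOTIDES:
                raise PanelError(f"star allele {name}: bad required allele {allele!r} for {rsid}")
            if rsid in snp_owner:
                raise PanelError(
                    f"SNP {rsid} claimed by both {snp_owner[rsid]} and {name}"
                )
            snp_owner[rsid] = name
        defs.append(StarAlleleDef(name=name, defining_snps=snps,
                                  function_class=body["function"]))
    return defs


def load_default_allele_definitions() -> list:
    return load_allele_definitions(default_allele_definitions_path())
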