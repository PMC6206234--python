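"""Domain types and I/O for individual-level case-control cohorts.

A cohort is a panel of biallelic SNPs plus a list of subjects with
case/control status, age (months), sex, tumor site of origin (cases only)
and unphased genotypes.  Genotypes are stored as variant-allele *dose*
(0, 1 or 2 copies of the variant allele); the "X>Y" orientation of each
SNP fixes which allele is counted, so additive coding and
protective-genotype membership are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

MISSING_GENOTYPE = "./."

GENOTYPE_CATEGORIES = ("hom_common", "het", "hom_variant")
CATEGORY_BY_DOSE = {0: "hom_common", 1: "het", 2: "hom_variant"}

VALID_SITES = ("adrenal", "retroperitoneal", "mediastinum", "other", "NA")


class CohortError(ValueError):
    """Raised for malformed cohort files or inconsistent records."""


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP with a fixed common>variant allele orientation.

    ``protective_genotypes`` names the genotype categories (``het``,
    ``hom_variant``, ``hom_common``) treated as protective when scoring
    subjects across the panel.
    """

    rsid: str
    common_allele: str
    variant_allele: str
    protective_genotypes: frozenset = frozenset()

    def __post_init__(self):
        if len(self.common_allele) != 1 or len(self.variant_allele) != 1:
            raise CohortError(f"{self.rsid}: alleles must be single characters")
        if self.common_allele == self.variant_allele:
            raise CohortError(f"{self.rsid}: common and variant alleles must differ")
        bad = set(self.protective_genotypes) - set(GENOTYPE_CATEGORIES)
        if bad:
            raise CohortError(f"{self.rsid}: unknown genotype categories {sorted(bad)}")

    def dose_from_string(self, genotype: str) -> Optional[int]:
        """Convert a two-letter genotype string to a variant-allele dose.

        Allele order is ignored ("AG" == "GA"); ``"./."`` maps to None.
        """
        if genotype == MISSING_GENOTYPE:
            return None
        if len(genotype) != 2:
            raise CohortError(f"{self.rsid}: malformed genotype {genotype!r}")
        dose = 0
        for allele in genotype:
            if allele == self.variant_allele:
                dose += 1
            elif allele != self.common_allele:
                raise CohortError(
                    f"{self.rsid}: unknown allele {allele!r} in genotype {genotype!r}"
                )
        return dose

    def genotype_string(self, dose: Optional[int]) -> str:
        """Canonical genotype string for a dose (common allele first)."""
        if dose is None:
            return MISSING_GENOTYPE
        if dose == 0:
            return self.common_allele * 2
        if dose == 1:
            return self.common_allele + self.variant_allele
        if dose == 2:
            return self.variant_allele * 2
        raise CohortError(f"{self.rsid}: invalid dose {dose}")

    @property
    def protective_doses(self) -> frozenset:
        inv = {v: k for k, v in CATEGORY_BY_DOSE.items()}
        return frozenset(inv[c] for c in self.protective_genotypes)


#: The five LMO1 SNPs of the eastern-Chinese neuroblastoma case-control
#: study, in study order.  Orientation follows the common>variant notation
#: (rs110419 A>G, rs4758051 G>A, rs10840002 A>G, rs204938 A>G,
#: rs2168101 G>T); for every SNP the variant-carrying genotypes
#: (het / hom_variant) are the protective ones.
STUDY_PANEL: tuple = tuple(
    SnpDef(rsid, common, variant, frozenset({"het", "hom_variant"}))
    for rsid, common, variant in [
        ("rs110419", "A", "G"),
        ("rs4758051", "G", "A"),
        ("rs10840002", "A", "G"),
        ("rs204938", "A", "G"),
        ("rs2168101", "G", "T"),
    ]
)


@dataclass
class Subject:
    subject_id: str
    status: str  # "case" | "control"
    age_months: float
    sex: str  # "F" | "M"
    site: str  # "adrenal" | "retroperitoneal" | "mediastinum" | "other" | "NA"
    genotypes: dict = field(default_factory=dict)  # rsid -> dose (0/1/2) or None

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise CohortError(f"{self.subject_id}: invalid status {self.status!r}")
        if self.sex not in ("F", "M"):
            raise CohortError(f"{self.subject_id}: invalid sex {self.sex!r}")
        if self.site not in VALID_SITES:
            raise CohortError(f"{self.subject_id}: invalid site {self.site!r}")
        if self.status == "control" and self.site != "NA":
            raise CohortError(f"{self.subject_id}: controls must have site NA")
        if not (self.age_months >= 0):
            raise CohortError(f"{self.subject_id}: invalid age {self.age_months!r}")
        for rsid, dose in self.genotypes.items():
            if dose is not None and dose not in (0, 1, 2):
                raise CohortError(f"{self.subject_id}: invalid dose {dose!r} at {rsid}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class Cohort:
    panel: Sequence[SnpDef]
    subjects: list

    def __post_init__(self):
        rsids = {s.rsid for s in self.panel}
        seen = set()
        for subj in self.subjects:
            if subj.subject_id in seen:
                raise CohortError(f"duplicate subject_id {subj.subject_id!r}")
            seen.add(subj.subject_id)
            extra = set(subj.genotypes) - rsids
            if extra:
                raise CohortError(
                    f"{subj.subject_id}: genotypes at SNPs not in panel: {sorted(extra)}"
                )

    @property
    def rsids(self):
        return [s.rsid for s in self.panel]

    @property
    def cases(self):
        return [s for s in self.subjects if s.is_case]

    @property
    def controls(self):
        return [s for s in self.subjects if not s.is_case]

    def snp(self, rsid: str) -> SnpDef:
        for s in self.panel:
            if s.rsid == rsid:
                return s
        raise CohortError(f"{rsid!r} not in panel")


@dataclass(frozen=True)
class GenotypeCounts:
    """3x2 genotype-by-status count table for one SNP (doses 0/1/2)."""

    rsid: str
    case_counts: tuple  # (n0, n1, n2)
    control_counts: tuple  # (m0, m1, m2)
    missing_cases: int = 0
    missing_controls: int = 0

    def __post_init__(self):
        for triple in (self.case_counts, self.control_counts):
            if len(triple) != 3 or any(c < 0 for c in triple):
                raise CohortError(f"{self.rsid}: invalid count triple {triple}")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["subject_id", "status", "age_months", "sex", "site"]


def read_cohort(path, panel: Sequence[SnpDef] = STUDY_PANEL) -> Cohort:
    """Read a cohort TSV (one subject per row, genotypes as allele strings).

    Expected header: ``subject_id status age_months sex site <rsid...>``.
    Genotype strings are unordered ("AG" == "GA"); missing is "./.".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    expected = COHORT_COLUMNS + [s.rsid for s in panel]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise CohortError(f"{path}: missing columns {missing_cols}")
    subjects = []
    for i, row in df.iterrows():
        try:
            age = float(row["age_months"])
        except (TypeError, ValueError):
            raise CohortError(f"{path} row {i}: malformed age {row['age_months']!r}")
        genotypes = {}
        for snp in panel:
            try:
                genotypes[snp.rsid] = snp.dose_from_string(str(row[snp.rsid]))
            except CohortError as exc:
                raise CohortError(f"{path} row {i}, column {snp.rsid}: {exc}")
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                status=str(row["status"]),
                age_months=age,
                sex=str(row["sex"]),
                site=str(row["site"]),
                genotypes=genotypes,
            )
        )
    return Cohort(panel=list(panel), subjects=subjects)


def write_cohort(cohort: Cohort, path, header_comment: str = "") -> None:
    """Write a cohort TSV with canonical (common-allele-first) genotypes."""
    rows = []
    for subj in cohort.subjects:
        row = {
            "subject_id": subj.subject_id,
            "status": subj.status,
            "age_months": repr(subj.age_months),
            "sex": subj.sex,
            "site": subj.site,
        }
        for snp in cohort.panel:
            row[snp.rsid] = snp.genotype_string(subj.genotypes.get(snp.rsid))
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS + cohort.rsids)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def tabulate_genotypes(cohort: Cohort, rsid: str) -> GenotypeCounts:
    """Count doses 0/1/2 by case/control status for one SNP.

    Subjects with a missing genotype at the SNP are excluded from the
    triples and reported in the missing tallies.
    """
    cohort.snp(rsid)  # raises if absent
    case = [0, 0, 0]
    ctrl = [0, 0, 0]
    miss_case = miss_ctrl = 0
    for subj in cohort.subjects:
        dose = subj.genotypes.get(rsid)
        if dose is None:
            if subj.is_case:
                miss_case += 1
            else:
                miss_ctrl += 1
        elif subj.is_case:
            case[dose] += 1
        else:
            ctrl[dose] += 1
    return GenotypeCounts(
        rsid=rsid,
        case_counts=tuple(case),
        control_counts=tuple(ctrl),
        missing_cases=miss_case,
        missing_controls=miss_ctrl,
    )


@dataclass(frozen=True)
class Finding:
    level: str  # "warning" | "error"
    code: str
    message: str


def validate_cohort(cohort: Cohort) -> list:
    """Structural checks; returns findings, never raises."""
    findings = []
    n_cases, n_controls = len(cohort.cases), len(cohort.controls)
    if n_cases == 0:
        findings.append(Finding("error", "empty_group", "cohort has zero cases"))
    if n_controls == 0:
        findings.append(Finding("error", "empty_group", "cohort has zero controls"))
    for snp in cohort.panel:
        doses = [
            s.genotypes.get(snp.rsid)
            for s in cohort.subjects
            if s.genotypes.get(snp.rsid) is not None
        ]
        if not doses:
            findings.append(
                Finding("error", "all_missing", f"{snp.rsid}: all genotypes missing")
            )
        elif len(set(doses)) == 1 and doses[0] in (0, 2):
            findings.append(
                Finding("warning", "monomorphic", f"{snp.rsid}: monomorphic ({doses[0]})")
            )
    return findings


# ---------------------------------------------------------------------------
# Aggregate count tables (dose-coded TSV: rsid genotype n_case n_control)
# ---------------------------------------------------------------------------

def read_count_table(path) -> dict:
    """Read a per-SNP genotype count TSV into {rsid: GenotypeCounts}."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"rsid", "genotype", "n_case", "n_control"}
    if not required.issubset(df.columns):
        raise CohortError(f"{path}: need columns {sorted(required)}")
    out = {}
    for rsid, grp in df.groupby("rsid", sort=False):
        case = [0, 0, 0]
        ctrl = [0, 0, 0]
        for _, row in grp.iterrows():
            dose = int(row["genotype"])
            if dose not in (0, 1, 2):
                raise CohortError(f"{path}: invalid genotype dose {dose} for {rsid}")
            case[dose] = int(row["n_case"])
            ctrl[dose] = int(row["n_control"])
        out[str(rsid)] = GenotypeCounts(str(rsid), tuple(case), tuple(ctrl))
    return out


def write_count_table(counts: Iterable[GenotypeCounts], path, header_comment: str = "") -> None:
    rows = [
        {"rsid": c.rsid, "genotype": d, "n_case": c.case_counts[d], "n_control": c.control_counts[d]}
        for c in counts
        for d in (0, 1, 2)
    ]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
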