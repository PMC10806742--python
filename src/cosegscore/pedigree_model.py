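"""Pedigree data model and co-segregation counting.

Families are read from a standard 6-column PED file (FID IID PAT MAT SEX
PHENO) paired with a TSV genotype table (individual_id, variant_id,
genotype).  The counting rules implemented here convert a family's genotype
and affection pattern into the integer co-segregation counts that the
evidence engine prices in points:

* autosomal recessive -- affected relatives sharing the proband's biallelic
  genotype count heavily; unaffected relatives lacking it count lightly and
  only when the disease is fully penetrant;
* autosomal dominant -- affected carriers and (if fully penetrant)
  unaffected non-carriers each count once;
* X-linked recessive -- affected hemizygous males, unaffected non-carrier
  males, and carrier (or obligate-carrier) females each count once.

Phase-setting individuals are consumed, never counted, and unaffected
parents are never counted under autosomal inheritance because they are the
individuals that establish phase.  Inconsistent genotype/affection pairs are
reported as non-segregation events rather than errors: they are evidence
(against pathogenicity), not noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

__all__ = [
    "Sex",
    "Affection",
    "Genotype",
    "Individual",
    "Pedigree",
    "InheritanceMode",
    "PhaseResult",
    "NonsegregationEvent",
    "SegregationSummary",
    "PedigreeError",
    "parse_ped",
    "establish_phase",
    "count_cosegregations",
    "detect_nonsegregations",
    "lod_from_meioses",
]


class PedigreeError(ValueError):
    """Malformed pedigree or genotype input."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(str, Enum):
    ABSENT = "absent"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    UNTYPED = "untyped"


#: Genotype tokens accepted in the TSV table.  "1" denotes a hemizygous
#: carrier (X-linked male); "0" a hemizygous non-carrier; "." untyped.
GENOTYPE_TOKENS: dict[str, Genotype] = {
    "0/0": Genotype.ABSENT,
    "0/1": Genotype.HETEROZYGOUS,
    "1/0": Genotype.HETEROZYGOUS,
    "1/1": Genotype.HOMOZYGOUS,
    "1": Genotype.HEMIZYGOUS,
    "0": Genotype.ABSENT,
    ".": Genotype.UNTYPED,
}

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}

_CARRIER_STATES = (Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS, Genotype.HEMIZYGOUS)


@dataclass
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    #: variant ids for which this individual is asserted (as input data) to
    #: be an obligate carrier despite being untyped.
    obligate_variants: set[str] = field(default_factory=set)

    def genotype(self, variant_id: str) -> Genotype:
        return self.genotypes.get(variant_id, Genotype.UNTYPED)

    def carries(self, variant_id: str) -> bool:
        return self.genotype(variant_id) in _CARRIER_STATES

    def typed_for(self, variant_id: str) -> bool:
        return self.genotype(variant_id) is not Genotype.UNTYPED

    @property
    def is_affected(self) -> bool:
        return self.affection is Affection.AFFECTED

    @property
    def is_unaffected(self) -> bool:
        return self.affection is Affection.UNAFFECTED


@dataclass
class Pedigree:
    family_id: str
    individuals: dict[str, Individual]
    proband_id: str

    def __post_init__(self) -> None:
        if self.proband_id not in self.individuals:
            raise PedigreeError(f"proband {self.proband_id!r} not in pedigree")
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.id!r} references missing parent {pid!r}"
                    )
        self._check_acyclic()
        proband = self.proband
        if proband.affection is Affection.UNAFFECTED:
            raise PedigreeError(f"proband {self.proband_id!r} must be affected or unknown")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"parent links form a cycle at {iid!r}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for iid in self.individuals:
            visit(iid)

    @property
    def proband(self) -> Individual:
        return self.individuals[self.proband_id]

    def members(self) -> Iterable[Individual]:
        return self.individuals.values()

    def parents(self, ind: Individual) -> list[Individual]:
        out = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                out.append(self.individuals[pid])
        return out

    def children(self, iid: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals.values()
            if iid in (ind.father_id, ind.mother_id)
        ]

    def siblings(self, ind: Individual) -> list[Individual]:
        if ind.father_id is None and ind.mother_id is None:
            return []
        return [
            other
            for other in self.individuals.values()
            if other.id != ind.id
            and (other.father_id, other.mother_id) == (ind.father_id, ind.mother_id)
        ]

    def co_parent(self, parent: Individual, child: Individual) -> Individual | None:
        """The other parent of ``child``, if present."""
        for pid in (child.father_id, child.mother_id):
            if pid is not None and pid != parent.id:
                return self.individuals[pid]
        return None

    def is_parent_of_affected(self, ind: Individual) -> bool:
        return any(c.is_affected for c in self.children(ind.id))


@dataclass(frozen=True)
class InheritanceMode:
    """Inheritance model under which segregations are counted.

    ``fully_penetrant=False`` triggers an affected-only analysis: unaffected
    relatives are never counted in any category and unaffected carriers are
    not treated as non-segregations (reduced penetrance explains them).
    ``phenocopy_negligible=False`` marks traits for which this heuristic is
    not valid (formal segregation analysis required).
    """

    mode: str  # "AR", "AD" or "XLR"
    fully_penetrant: bool = True
    phenocopy_negligible: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("AR", "AD", "XLR"):
            raise ValueError(f"unknown inheritance mode {self.mode!r}")


@dataclass(frozen=True)
class PhaseResult:
    ok: bool
    consumed: tuple[str, ...] = ()
    #: candidate variants remaining after phase was set (AD: the variant the
    #: phase-setting meiosis implicates; otherwise the input set).
    selected_variants: tuple[str, ...] = ()
    reason: str = ""


@dataclass(frozen=True)
class NonsegregationEvent:
    individual_id: str
    variant_ids: tuple[str, ...]
    reason: str


@dataclass
class SegregationSummary:
    ar_affected: int = 0
    ar_unaffected: int = 0
    ad_individuals: int = 0
    xl_males: int = 0
    xl_obligate_females: int = 0
    phase_setting_individuals: list[str] = field(default_factory=list)
    counted_individuals: list[str] = field(default_factory=list)
    nonsegregations: list[NonsegregationEvent] = field(default_factory=list)
    uninformative_individuals: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return (
            self.ar_affected
            + self.ar_unaffected
            + self.ad_individuals
            + self.xl_males
            + self.xl_obligate_females
        )


# ---------------------------------------------------------------------------
# parsing


def _open_lines(source: Union[str, Path, IO[str]]) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()  # type: ignore[union-attr]
    path = Path(source)
    return path.read_text().splitlines()


def parse_ped(
    ped_stream: Union[str, Path, IO[str]],
    genotype_table_stream: Union[str, Path, IO[str], None] = None,
    *,
    proband_id: str | None = None,
    obligate_carriers: Mapping[str, Sequence[str]] | None = None,
) -> Pedigree:
    """Build a validated :class:`Pedigree` from a 6-column PED file and an
    optional genotype TSV.

    PED columns are FID IID PAT MAT SEX PHENO (tab- or space-separated;
    PHENO 2=affected, 1=unaffected, 0/-9=unknown; PAT/MAT 0=founder).  The
    genotype table has columns individual_id, variant_id, genotype with
    genotype in {0/0, 0/1, 1/1, 1, 0, .}.  Individuals without genotype rows
    are untyped.  The proband defaults to the first affected individual in
    file order.
    """
    individuals: dict[str, Individual] = {}
    family_id: str | None = None
    for lineno, raw in enumerate(_open_lines(ped_stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise PedigreeError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
        fid, iid, pat, mat, sex_code, pheno_code = fields
        if family_id is None:
            family_id = fid
        elif fid != family_id:
            raise PedigreeError(f"PED line {lineno}: multiple family ids ({family_id!r}, {fid!r})")
        if iid in individuals:
            raise PedigreeError(f"PED line {lineno}: duplicate individual id {iid!r}")
        if sex_code not in _SEX_CODES:
            raise PedigreeError(f"PED line {lineno}: bad sex code {sex_code!r}")
        if pheno_code not in _PHENO_CODES:
            raise PedigreeError(f"PED line {lineno}: bad phenotype code {pheno_code!r}")
        individuals[iid] = Individual(
            id=iid,
            father_id=None if pat == "0" else pat,
            mother_id=None if mat == "0" else mat,
            sex=_SEX_CODES[sex_code],
            affection=_PHENO_CODES[pheno_code],
        )
    if not individuals:
        raise PedigreeError("PED file contains no individuals")
    for ind in individuals.values():
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid not in individuals:
                raise PedigreeError(
                    f"individual {ind.id!r} references parent {pid!r} not present in PED file"
                )

    if genotype_table_stream is not None:
        for lineno, raw in enumerate(_open_lines(genotype_table_stream), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and fields[0].lower() in ("individual_id", "iid"):
                continue
            if len(fields) != 3:
                raise PedigreeError(
                    f"genotype table line {lineno}: expected 3 columns, got {len(fields)}"
                )
            iid, variant_id, token = fields
            if iid not in individuals:
                raise PedigreeError(
                    f"genotype table line {lineno}: unknown individual {iid!r}"
                )
            if token not in GENOTYPE_TOKENS:
                raise PedigreeError(
                    f"genotype table line {lineno}: malformed genotype token {token!r}"
                )
            geno = GENOTYPE_TOKENS[token]
            if geno is Genotype.HEMIZYGOUS and individuals[iid].sex is Sex.FEMALE:
                raise PedigreeError(
                    f"genotype table line {lineno}: hemizygous genotype for female {iid!r}"
                )
            individuals[iid].genotypes[variant_id] = geno

    if obligate_carriers:
        for iid, variant_ids in obligate_carriers.items():
            if iid not in individuals:
                raise PedigreeError(f"obligate carrier {iid!r} not in pedigree")
            individuals[iid].obligate_variants.update(variant_ids)

    if proband_id is None:
        proband_id = next(
            (iid for iid, ind in individuals.items() if ind.is_affected), None
        )
        if proband_id is None:
            raise PedigreeError("no affected individual to serve as proband; pass proband_id")

    return Pedigree(family_id=family_id or "FAM", individuals=individuals, proband_id=proband_id)


def validate_x_linked_genotypes(ped: Pedigree, variant_ids: Iterable[str]) -> None:
    """Reject sex-inconsistent genotypes at an X-linked locus (diploid male
    genotypes).  Called by the engine once the inheritance mode is known."""
    for ind in ped.members():
        if ind.sex is not Sex.MALE:
            continue
        for vid in variant_ids:
            if ind.genotype(vid) in (Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS):
                raise PedigreeError(
                    f"male {ind.id!r} has diploid genotype for X-linked variant {vid!r}"
                )


# ---------------------------------------------------------------------------
# phase


def establish_phase(
    ped: Pedigree,
    allele_variants: Sequence[str],
    mode: InheritanceMode,
) -> PhaseResult:
    """Determine whether phase between candidate variants and the phenotype
    can be set, and which individuals (meioses) are consumed doing so.

    * A single candidate variant needs no phase.
    * X-linked: an affected hemizygous male sets phase with zero meioses.
    * Autosomal recessive: a homozygous proband needs no meiosis; a compound
      heterozygous proband is itself the phase-setting individual.
    * Autosomal dominant with several candidate variants: the first affected
      non-proband relative typed positive for exactly one candidate sets
      phase (one meiosis consumed) and selects that variant.
    """
    variants = tuple(allele_variants)
    if not variants:
        raise ValueError("allele_variants must be non-empty")
    proband = ped.proband

    if len(variants) == 1:
        return PhaseResult(True, (), variants, "single candidate variant; no phase needed")

    if mode.mode == "XLR":
        for ind in ped.members():
            if ind.is_affected and ind.sex is Sex.MALE:
                carried = tuple(v for v in variants if ind.genotype(v) is Genotype.HEMIZYGOUS)
                if carried:
                    return PhaseResult(
                        True, (), carried,
                        f"phase set in affected male {ind.id} without consuming a meiosis",
                    )
        return PhaseResult(False, (), variants, "no affected hemizygous male to set phase")

    if mode.mode == "AR":
        hom = tuple(v for v in variants if proband.genotype(v) is Genotype.HOMOZYGOUS)
        if hom:
            return PhaseResult(True, (), hom, "homozygous proband; no meiosis consumed")
        het = tuple(v for v in variants if proband.genotype(v) is Genotype.HETEROZYGOUS)
        if len(het) >= 2:
            return PhaseResult(
                True, (proband.id,), het,
                f"compound heterozygous proband {proband.id} sets phase",
            )
        return PhaseResult(False, (), variants, "proband genotype cannot set phase")

    # autosomal dominant with >1 candidate variant: one affected meiosis
    for ind in ped.members():
        if ind.id == proband.id or not ind.is_affected:
            continue
        typed = [v for v in variants if ind.typed_for(v)]
        carried = [v for v in variants if ind.carries(v)]
        if typed and len(carried) == 1:
            return PhaseResult(
                True, (ind.id,), tuple(carried),
                f"phase set by affected relative {ind.id} carrying {carried[0]}",
            )
    return PhaseResult(False, (), variants, "no informative affected meiosis to set phase")


# ---------------------------------------------------------------------------
# causal genotype patterns


def _causal_pattern(
    proband: Individual, variants: Sequence[str], mode: InheritanceMode
) -> dict[str, Genotype]:
    """Genotype pattern (per candidate variant) that tracks the disease
    allele(s), derived from the proband."""
    pattern: dict[str, Genotype] = {}
    if mode.mode == "AR":
        for v in variants:
            g = proband.genotype(v)
            if g in (Genotype.HOMOZYGOUS, Genotype.HETEROZYGOUS):
                pattern[v] = g
    elif mode.mode == "XLR":
        for v in variants:
            if proband.genotype(v) in (Genotype.HEMIZYGOUS, Genotype.HETEROZYGOUS):
                pattern[v] = Genotype.HEMIZYGOUS
    else:  # AD: carrier status of each candidate
        for v in variants:
            if proband.carries(v):
                pattern[v] = Genotype.HETEROZYGOUS
    return pattern


def _has_full_genotype(ind: Individual, pattern: Mapping[str, Genotype], mode: InheritanceMode) -> bool:
    """Does this individual carry the complete causal genotype?"""
    if not pattern:
        return False
    for v, required in pattern.items():
        g = ind.genotype(v)
        if mode.mode == "AD":
            if g not in _CARRIER_STATES:
                return False
        elif mode.mode == "XLR":
            ok = g is Genotype.HEMIZYGOUS if ind.sex is Sex.MALE else g in (
                Genotype.HETEROZYGOUS,
                Genotype.HOMOZYGOUS,
            )
            if not ok:
                return False
        else:  # AR
            if required is Genotype.HOMOZYGOUS:
                if g is not Genotype.HOMOZYGOUS:
                    return False
            else:  # compound-het component: het or hom acceptable
                if g not in (Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS):
                    return False
    return True


def _demonstrably_lacks_genotype(
    ind: Individual, pattern: Mapping[str, Genotype], mode: InheritanceMode
) -> bool:
    """Typed evidence that this individual does NOT carry the full causal
    genotype (at least one required component positively excluded)."""
    if not pattern:
        return False
    for v, required in pattern.items():
        g = ind.genotype(v)
        if g is Genotype.UNTYPED:
            continue
        if mode.mode in ("AD", "XLR"):
            if g is Genotype.ABSENT:
                return True
        else:  # AR
            if required is Genotype.HOMOZYGOUS and g in (Genotype.ABSENT, Genotype.HETEROZYGOUS):
                return True
            if required is Genotype.HETEROZYGOUS and g is Genotype.ABSENT:
                return True
    return False


def _has_possible_carrier_parent(
    ped: Pedigree, ind: Individual, variants: Sequence[str], mode: InheritanceMode
) -> bool:
    """Could this individual have inherited a candidate variant from a parent
    in the pedigree?  Married-in founders cannot, and their negative
    genotypes are therefore uninformative."""
    parents = ped.parents(ind)
    if mode.mode == "XLR":
        parents = [p for p in parents if p.sex is not Sex.MALE]
    if not parents:
        return False
    for p in parents:
        for v in variants:
            if p.genotype(v) is not Genotype.ABSENT:
                return True
    return False


# ---------------------------------------------------------------------------
# inference of untyped genotypes


def _inferred_autosomal_carrier(
    ped: Pedigree, ind: Individual, variants: Sequence[str]
) -> str | None:
    """An untyped individual is an inferred carrier of a variant if a child
    is a typed carrier while the child's other parent is typed negative."""
    for child in ped.children(ind.id):
        other = ped.co_parent(ind, child)
        for v in variants:
            if child.genotype(v) in _CARRIER_STATES:
                if other is not None and other.genotype(v) is Genotype.ABSENT:
                    return v
    return None


def _obligate_xl_female(ped: Pedigree, ind: Individual, variants: Sequence[str]) -> bool:
    """Obligate-carrier inference for an untyped female under X-linked
    recessive inheritance: her carrier status is affirmed by having an
    affected brother and an affected (or typed hemizygous-carrier) son."""
    has_affected_brother = any(
        sib.sex is Sex.MALE and sib.is_affected for sib in ped.siblings(ind)
    )
    if not has_affected_brother:
        return False
    for child in ped.children(ind.id):
        if child.sex is Sex.MALE and (
            child.is_affected
            or any(child.genotype(v) is Genotype.HEMIZYGOUS for v in variants)
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# counting


def count_cosegregations(
    ped: Pedigree,
    allele_variants: Sequence[str],
    mode: InheritanceMode,
    *,
    consumed: Sequence[str] = (),
    count_inferred_genotypes: bool = True,
) -> SegregationSummary:
    """Count informative co-segregations at one locus.

    ``allele_variants`` are the candidate variant ids at the locus after any
    phase resolution.  The proband and phase-consumed individuals are never
    counted; unaffected parents are never counted under autosomal
    inheritance; unknown affection status is never counted.  Individuals
    whose typed genotype contradicts their affection status are recorded in
    ``nonsegregations`` (they are the input to BS4/locus exclusion, and are
    never simultaneously counted as co-segregations).
    """
    variants = tuple(allele_variants)
    proband = ped.proband
    pattern = _causal_pattern(proband, variants, mode)
    summary = SegregationSummary(phase_setting_individuals=list(consumed))
    skip = {proband.id, *consumed}

    for ind in ped.members():
        if ind.id in skip:
            continue
        if ind.affection is Affection.UNKNOWN:
            summary.uninformative_individuals.append(ind.id)
            continue

        if mode.mode == "AR":
            _count_ar(ped, ind, pattern, mode, summary)
        elif mode.mode == "AD":
            _count_ad(ped, ind, pattern, variants, mode, summary, count_inferred_genotypes)
        else:
            _count_xlr(ped, ind, pattern, variants, mode, summary, count_inferred_genotypes)
    return summary


def _count_ar(
    ped: Pedigree,
    ind: Individual,
    pattern: Mapping[str, Genotype],
    mode: InheritanceMode,
    summary: SegregationSummary,
) -> None:
    causal_vars = tuple(pattern)
    if ind.is_affected:
        if _has_full_genotype(ind, pattern, mode):
            summary.ar_affected += 1
            summary.counted_individuals.append(ind.id)
        elif _demonstrably_lacks_genotype(ind, pattern, mode):
            summary.nonsegregations.append(
                NonsegregationEvent(ind.id, causal_vars, "affected_lacks_causal_genotype")
            )
        else:
            summary.uninformative_individuals.append(ind.id)
        return
    # unaffected
    if not mode.fully_penetrant or ped.is_parent_of_affected(ind):
        summary.uninformative_individuals.append(ind.id)
        return
    if _has_full_genotype(ind, pattern, mode):
        summary.nonsegregations.append(
            NonsegregationEvent(ind.id, causal_vars, "unaffected_carries_causal_genotype")
        )
    elif _demonstrably_lacks_genotype(ind, pattern, mode) and _has_possible_carrier_parent(
        ped, ind, causal_vars, mode
    ):
        summary.ar_unaffected += 1
        summary.counted_individuals.append(ind.id)
    else:
        summary.uninformative_individuals.append(ind.id)


def _count_ad(
    ped: Pedigree,
    ind: Individual,
    pattern: Mapping[str, Genotype],
    variants: Sequence[str],
    mode: InheritanceMode,
    summary: SegregationSummary,
    infer: bool,
) -> None:
    causal_vars = tuple(pattern) or variants
    if ind.is_affected:
        if _has_full_genotype(ind, pattern, mode):
            summary.ad_individuals += 1
            summary.counted_individuals.append(ind.id)
            return
        if _demonstrably_lacks_genotype(ind, pattern, mode):
            summary.nonsegregations.append(
                NonsegregationEvent(ind.id, causal_vars, "affected_lacks_causal_genotype")
            )
            return
        # untyped: explicit obligate assertion or inferred genotype
        if any(v in ind.obligate_variants for v in causal_vars):
            summary.ad_individuals += 1
            summary.counted_individuals.append(ind.id)
            return
        if infer and _inferred_autosomal_carrier(ped, ind, causal_vars):
            summary.ad_individuals += 1
            summary.counted_individuals.append(ind.id)
            return
        summary.uninformative_individuals.append(ind.id)
        return
    # unaffected
    if not mode.fully_penetrant or ped.is_parent_of_affected(ind):
        summary.uninformative_individuals.append(ind.id)
        return
    if _has_full_genotype(ind, pattern, mode):
        summary.nonsegregations.append(
            NonsegregationEvent(ind.id, causal_vars, "unaffected_carries_causal_genotype")
        )
    elif _demonstrably_lacks_genotype(ind, pattern, mode) and _has_possible_carrier_parent(
        ped, ind, causal_vars, mode
    ):
        summary.ad_individuals += 1
        summary.counted_individuals.append(ind.id)
    else:
        summary.uninformative_individuals.append(ind.id)


def _count_xlr(
    ped: Pedigree,
    ind: Individual,
    pattern: Mapping[str, Genotype],
    variants: Sequence[str],
    mode: InheritanceMode,
    summary: SegregationSummary,
    infer: bool,
) -> None:
    causal_vars = tuple(pattern) or variants
    if ind.sex is Sex.MALE:
        if ind.is_affected:
            if any(ind.genotype(v) is Genotype.HEMIZYGOUS for v in causal_vars):
                summary.xl_males += 1
                summary.counted_individuals.append(ind.id)
            elif _demonstrably_lacks_genotype(ind, pattern, mode):
                summary.nonsegregations.append(
                    NonsegregationEvent(ind.id, causal_vars, "affected_lacks_causal_genotype")
                )
            elif any(v in ind.obligate_variants for v in causal_vars):
                summary.xl_males += 1
                summary.counted_individuals.append(ind.id)
            else:
                summary.uninformative_individuals.append(ind.id)
            return
        # unaffected male
        if not mode.fully_penetrant:
            summary.uninformative_individuals.append(ind.id)
            return
        if any(ind.genotype(v) is Genotype.HEMIZYGOUS for v in causal_vars):
            summary.nonsegregations.append(
                NonsegregationEvent(ind.id, causal_vars, "unaffected_carries_causal_genotype")
            )
        elif _demonstrably_lacks_genotype(ind, pattern, mode) and _has_possible_carrier_parent(
            ped, ind, causal_vars, mode
        ):
            summary.xl_males += 1
            summary.counted_individuals.append(ind.id)
        else:
            summary.uninformative_individuals.append(ind.id)
        return

    # females: carrier (typed het), asserted obligate, or inferred obligate
    if any(ind.genotype(v) in (Genotype.HETEROZYGOUS, Genotype.HOMOZYGOUS) for v in causal_vars):
        summary.xl_obligate_females += 1
        summary.counted_individuals.append(ind.id)
        return
    if any(v in ind.obligate_variants for v in causal_vars):
        summary.xl_obligate_females += 1
        summary.counted_individuals.append(ind.id)
        return
    if (
        infer
        and not ind.is_affected
        and all(not ind.typed_for(v) for v in causal_vars)
        and _obligate_xl_female(ped, ind, causal_vars)
    ):
        summary.xl_obligate_females += 1
        summary.counted_individuals.append(ind.id)
        return
    summary.uninformative_individuals.append(ind.id)


# ---------------------------------------------------------------------------
# non-segregation detection


def detect_nonsegregations(
    ped: Pedigree,
    locus_variants: Mapping[str, Sequence[str]],
    mode: InheritanceMode,
) -> dict[str, list[NonsegregationEvent]]:
    """Flag genotype/affection contradictions per gene.

    Under a fully penetrant model an unaffected relative carrying the full
    causal genotype is a non-segregation; under a negligible-phenocopy model
    an affected relative demonstrably lacking the candidate genotype is one.
    For dominant and X-linked loci, events are reported per candidate
    variant (an unaffected carrier of one candidate indicts that variant
    only); for recessive loci the biallelic genotype is the unit.  Genes
    with no contradictions are omitted from the result.
    """
    proband = ped.proband
    out: dict[str, list[NonsegregationEvent]] = {}
    for gene, variants in locus_variants.items():
        events: list[NonsegregationEvent] = []
        if mode.mode == "AR":
            pattern = _causal_pattern(proband, variants, mode)
            if pattern:
                for ind in ped.members():
                    if ind.id == proband.id:
                        continue
                    if (
                        mode.fully_penetrant
                        and ind.is_unaffected
                        and _has_full_genotype(ind, pattern, mode)
                    ):
                        events.append(
                            NonsegregationEvent(
                                ind.id, tuple(pattern), "unaffected_carries_causal_genotype"
                            )
                        )
                    elif (
                        mode.phenocopy_negligible
                        and ind.is_affected
                        and _demonstrably_lacks_genotype(ind, pattern, mode)
                    ):
                        events.append(
                            NonsegregationEvent(
                                ind.id, tuple(pattern), "affected_lacks_causal_genotype"
                            )
                        )
        else:
            for v in variants:
                if not proband.carries(v):
                    continue
                for ind in ped.members():
                    if ind.id == proband.id:
                        continue
                    g = ind.genotype(v)
                    carrier = (
                        g is Genotype.HEMIZYGOUS
                        if (mode.mode == "XLR" and ind.sex is Sex.MALE)
                        else g in _CARRIER_STATES
                    )
                    # X-linked carrier females are consistent, not events
                    if mode.mode == "XLR" and ind.sex is not Sex.MALE:
                        continue
                    if mode.fully_penetrant and ind.is_unaffected and carrier:
                        events.append(
                            NonsegregationEvent(ind.id, (v,), "unaffected_carries_causal_genotype")
                        )
                    elif (
                        mode.phenocopy_negligible
                        and ind.is_affected
                        and g is Genotype.ABSENT
                    ):
                        events.append(
                            NonsegregationEvent(ind.id, (v,), "affected_lacks_causal_genotype")
                        )
        if events:
            out[gene] = events
    return out


# ---------------------------------------------------------------------------
# LOD arithmetic


def lod_from_meioses(informative_meioses: int) -> tuple[float, float]:
    """Likelihood ratio and LOD score for fully informative, recombination-
    free meioses: LR = 2**m, LOD = log10(LR).  Two informative meioses give
    4:1 odds (LOD ~= 0.6)."""
    m = int(informative_meioses)
    if m < 0:
        raise ValueError("meiosis count must be non-negative")
    lr = 2.0 ** m
    return lr, m * math.log10(2.0)
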