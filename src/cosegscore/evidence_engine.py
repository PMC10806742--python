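"""Orchestration of phenotype-specificity (PP4), co-segregation (PP1) and
non-segregation (BS4) evidence into per-variant points and classifications.

The decision flow:

1. Architecture check.  A phenotype attributable to a single gene with
   diagnostic yield above 90% is a locus-homogeneity scenario: the phenotype
   already implicates the locus nearly perfectly, so co-segregation cannot
   add evidence -- PP4 alone is scored and PP1 is suppressed.
2. Under locus heterogeneity, PP4 points come from the gene's diagnostic
   yield (with a 20% floor) and PP1 points from counted co-segregations
   (current family plus any supplied literature families).
3. Non-segregations assign BS4 (-4.0 points) to the offending variants and
   can exclude a locus outright, in which case the remaining genes' yields
   are renormalized (capped at a practical ceiling of 99%) and PP4 is
   reassessed -- benign evidence at one locus is pathogenic evidence for the
   others.
4. Locus-level evidence (PP1+PP4) is capped at +5.0 points per variant
   because a typed variant may merely be in linkage disequilibrium with the
   true causal variant.  Alleles carrying several variants in cis have their
   *posterior* (not their points) divided equally across the variants, or
   redistributed wholesale to one variant when independent evidence
   separates the candidates by at least the 6-point span between the likely
   benign and likely pathogenic thresholds.
5. Independent per-variant evidence points are added and the total is
   classified on the standard five-tier scale.

Every rule firing is recorded in an ordered audit log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .bayes_core import (
    BayesConfig,
    DEFAULT_CONFIG,
    classify_points,
    odds_from_points,
    posterior_from_points,
    strength_label,
    yield_to_points,
)
from .pedigree_model import (
    InheritanceMode,
    NonsegregationEvent,
    Pedigree,
    PhaseResult,
    count_cosegregations,
    detect_nonsegregations,
    establish_phase,
    validate_x_linked_genotypes,
)

__all__ = [
    "GenePhenotypeDyad",
    "AlleleCandidate",
    "EngineConfig",
    "VariantEvidence",
    "EvidenceResult",
    "AuditEntry",
    "pp4_assign",
    "apply_locus_exclusion",
    "pp1_assign",
    "bs4_assign",
    "divide_allele_evidence",
    "redistribute_allele_evidence",
    "combine_and_cap",
    "floor_to_half_point",
    "evaluate_case",
]

BS4_POINTS = -4.0
PHANTOM_LOCUS = "__unexplained__"


@dataclass(frozen=True)
class GenePhenotypeDyad:
    """A gene considered causal for the phenotype under evaluation.

    ``diagnostic_yield`` is the fraction of phenotype-matched probands in
    whom causative variants are found in this gene with a comparable assay
    (None when unknown -- PP4 is then never awarded).  ``validity`` is the
    gene-disease validity tier; PP4 requires definitive or strong validity.
    ``phenotype_specific`` records whether the proband's phenotyping was
    adequate for phenotype-specificity evidence.
    """

    gene: str
    diagnostic_yield: float | None
    inheritance: InheritanceMode
    validity: str = "definitive"  # definitive | strong | lower
    phenotype_specific: bool = True
    linked_group: str | None = None

    def __post_init__(self) -> None:
        if self.diagnostic_yield is not None and not (0.0 <= self.diagnostic_yield <= 1.0):
            raise ValueError(f"diagnostic yield must lie in [0, 1], got {self.diagnostic_yield!r}")
        if self.validity not in ("definitive", "strong", "lower"):
            raise ValueError(f"unknown validity tier {self.validity!r}")


@dataclass(frozen=True)
class AlleleCandidate:
    """One allele: an ordered set of variants asserted in cis, each with any
    independent (non-PP1/PP4/BS4) evidence points already assigned."""

    gene: str
    variant_ids: tuple[str, ...]
    independent_points: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise ValueError("an allele must carry at least one variant")
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "independent_points", dict(self.independent_points))

    def points_for(self, variant_id: str) -> float:
        return float(self.independent_points.get(variant_id, 0.0))


@dataclass(frozen=True)
class EngineConfig:
    """Tunable rules of the heuristic.  Defaults are the recommended values."""

    bayes: BayesConfig = DEFAULT_CONFIG
    cap: float = 5.0
    #: the cap may be lifted for disorders whose pathogenic mechanism must be
    #: coding (e.g. gain of function) with complete coding coverage.
    cap_lifted: bool = False
    min_pp4_yield: float = 0.20
    homogeneity_yield_threshold: float = 0.90
    redistribution_threshold: float = 6.0
    post_exclusion_ceiling: float = 0.99
    #: user-asserted post-exclusion yields per gene, overriding arithmetic
    #: renormalization (e.g. an externally sourced ">95%" estimate).
    post_exclusion_yield: Mapping[str, float] = field(default_factory=dict)
    count_inferred_genotypes: bool = True
    #: points per autosomal-recessive affected co-segregation beyond the
    #: fifth (2.0 continues the table row; 0.4 is the alternative reading).
    ar_affected_increment_above_five: float = 2.0
    #: genes excluded by evidence outside this engine (e.g. complete coding
    #: coverage with no variant found under a coding-only mechanism).
    excluded_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "post_exclusion_yield", dict(self.post_exclusion_yield))
        object.__setattr__(self, "excluded_genes", frozenset(self.excluded_genes))


@dataclass
class AuditEntry:
    rule: str
    detail: str
    data: dict = field(default_factory=dict)


@dataclass
class VariantEvidence:
    variant_id: str
    gene: str
    pp4_points: float = 0.0
    pp1_points: float = 0.0
    bs4_points: float = 0.0
    #: capped PP1+PP4 evidence at full internal (0.1-point) precision.
    combined_locus_points: float = 0.0
    #: combined locus evidence floored to the half-point reporting grid.
    reported_locus_points: float = 0.0
    other_points: float = 0.0
    total_points: float = 0.0
    strength: str = "not applicable"
    classification: str = "Uncertain significance"
    #: pp4/pp1/combined before locus exclusion reassessed PP4 (present only
    #: when exclusion fired).
    pre_exclusion: dict | None = None


@dataclass
class EvidenceResult:
    variants: dict[str, VariantEvidence]
    excluded_loci: list[str] = field(default_factory=list)
    nonsegregations: dict[str, list[NonsegregationEvent]] = field(default_factory=dict)
    requires_formal_linkage: bool = False
    audit_log: list[AuditEntry] = field(default_factory=list)

    def variant(self, variant_id: str) -> VariantEvidence:
        return self.variants[variant_id]


# ---------------------------------------------------------------------------
# individual rules


def pp4_assign(
    dyads: Sequence[GenePhenotypeDyad],
    target_gene: str,
    cfg: BayesConfig = DEFAULT_CONFIG,
    min_yield: float = 0.20,
) -> float:
    """Phenotype-specificity points for one gene from its diagnostic yield.

    Returns 0 when the yield is unknown or below the 20% floor, when the
    phenotyping was inadequate, or when gene-disease validity is below
    strong.
    """
    dyad = next((d for d in dyads if d.gene == target_gene), None)
    if dyad is None:
        raise ValueError(f"gene {target_gene!r} not among the configured dyads")
    if not dyad.phenotype_specific:
        return 0.0
    if dyad.validity not in ("definitive", "strong"):
        raise ValueError(
            f"PP4 requires definitive or strong gene-disease validity; "
            f"{dyad.gene} is {dyad.validity!r}"
        )
    if dyad.diagnostic_yield is None:
        return 0.0
    return yield_to_points(dyad.diagnostic_yield, cfg, min_yield=min_yield)


def apply_locus_exclusion(
    dyads: Sequence[GenePhenotypeDyad],
    excluded_genes: set[str] | frozenset[str],
    ceiling: float = 0.99,
    post_exclusion_yield: Mapping[str, float] | None = None,
) -> list[GenePhenotypeDyad]:
    """Renormalize diagnostic yields after excluding loci.

    Each surviving yield becomes ``yield / (1 - sum(excluded yields))``,
    truncated at the practical ceiling of 99%.  The unexplained fraction of
    the phenotype behaves as a phantom locus that is implicitly retained (it
    is part of the denominator and can never be excluded).  Per-gene
    ``post_exclusion_yield`` overrides replace the arithmetic value.
    """
    unknown = excluded_genes - {d.gene for d in dyads}
    if unknown:
        raise ValueError(f"cannot exclude genes not among the dyads: {sorted(unknown)}")
    remaining = [d for d in dyads if d.gene not in excluded_genes]
    if not remaining:
        raise ValueError("cannot exclude every locus: at least one candidate gene must remain")
    if not excluded_genes:
        return list(dyads)
    excluded_yield = sum(
        d.diagnostic_yield or 0.0 for d in dyads if d.gene in excluded_genes
    )
    denom = 1.0 - excluded_yield
    if denom <= 0.0:
        raise ValueError("excluded yields sum to >= 1; inputs are contradictory")
    overrides = post_exclusion_yield or {}
    out = []
    for d in remaining:
        if d.gene in overrides:
            out.append(replace(d, diagnostic_yield=min(overrides[d.gene], ceiling)))
        elif d.diagnostic_yield is None:
            out.append(d)
        else:
            out.append(replace(d, diagnostic_yield=min(d.diagnostic_yield / denom, ceiling)))
    return out


def pp1_assign(
    summary,
    mode: InheritanceMode,
    *,
    ar_affected_increment_above_five: float = 2.0,
) -> float:
    """Price a co-segregation count in points.

    Per co-segregating individual: +2.0 for an affected relative sharing the
    biallelic recessive genotype, +0.4 for an unaffected relative lacking it,
    +1.0 under dominant inheritance, +1.0 per X-linked male or obligate
    carrier female.  Beyond five recessive affected co-segregations the
    per-meiosis increment is configurable (the published table's footnote is
    ambiguous); all other rows continue linearly.
    """
    counts = (
        summary.ar_affected,
        summary.ar_unaffected,
        summary.ad_individuals,
        summary.xl_males,
        summary.xl_obligate_females,
    )
    if any(c < 0 for c in counts):
        raise ValueError("co-segregation counts must be non-negative")
    n_ar = summary.ar_affected
    ar_affected_pts = 2.0 * min(n_ar, 5) + ar_affected_increment_above_five * max(0, n_ar - 5)
    return (
        ar_affected_pts
        + 0.4 * summary.ar_unaffected
        + 1.0 * summary.ad_individuals
        + 1.0 * summary.xl_males
        + 1.0 * summary.xl_obligate_females
    )


def bs4_assign(
    events: Sequence[NonsegregationEvent],
    mode: InheritanceMode,
    zygosity: str,
) -> float:
    """Non-segregation points: -4.0 for one or more events, except for
    compound-heterozygous recessive cases where a non-segregation cannot
    identify which of the two alleles is benign (0.0)."""
    if zygosity not in ("homozygous", "compound_het", "heterozygous", "hemizygous"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if not events:
        return 0.0
    if zygosity == "compound_het":
        return 0.0
    return BS4_POINTS


def divide_allele_evidence(
    allele_posterior: float,
    n_variants: int,
    cfg: BayesConfig = DEFAULT_CONFIG,
) -> float:
    """Per-variant points when an allele's evidence is shared by ``n``
    candidate variants in cis.

    The allele's *posterior probability* is divided equally and each share
    converted back to points with the round-down rule.  Dividing the points
    arithmetically would be wrong: points are log-odds, so halving a
    posterior of ~96% gives +2.5 points per variant, not +3.5.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0.0 < allele_posterior <= 1.0):
        raise ValueError(f"allele posterior must lie in (0, 1], got {allele_posterior!r}")
    return yield_to_points(allele_posterior / n_variants, cfg, min_yield=0.0)


def redistribute_allele_evidence(
    allele: AlleleCandidate,
    allele_points: float,
    allele_posterior: float,
    threshold_points: float = 6.0,
    cap: float = 5.0,
    cfg: BayesConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Apportion an allele's locus evidence across its in-cis variants.

    Locus evidence shared by several variants is fungible: if independent
    evidence separates the best-supported variant from the worst by at least
    ``threshold_points`` (the 6-point span between the likely benign and
    likely pathogenic thresholds, odds 81:1), the allele is treated as a
    single-variant allele -- the favored variant receives the full allele
    points (capped) and the rest none.  Otherwise the allele posterior is
    divided equally.
    """
    variants = allele.variant_ids
    if len(variants) == 1:
        return {variants[0]: min(allele_points, cap)}
    indep = {v: allele.points_for(v) for v in variants}
    spread = max(indep.values()) - min(indep.values())
    if spread >= threshold_points:
        top = max(indep.values())
        favored = [v for v in variants if indep[v] == top]
        if len(favored) == 1:
            out = {v: 0.0 for v in variants}
            out[favored[0]] = min(allele_points, cap)
            return out
        # several equally favored variants: divide among them only
        share = divide_allele_evidence(allele_posterior, len(favored), cfg)
        return {v: (min(share, cap) if v in favored else 0.0) for v in variants}
    per = min(divide_allele_evidence(allele_posterior, len(variants), cfg), cap)
    return {v: per for v in variants}


def combine_and_cap(pp4: float, pp1: float, cap: float | None = 5.0) -> float:
    """Combined locus evidence, capped (default +5.0).  ``cap=None`` lifts
    the cap (coding-only mechanism with complete coding coverage)."""
    if pp4 < 0 or pp1 < 0:
        raise ValueError("PP4 and PP1 points must be non-negative")
    total = pp4 + pp1
    return total if cap is None else min(total, cap)


def floor_to_half_point(points: float) -> float:
    """Round locus evidence down to the half-point reporting grid."""
    return math.floor(points / 0.5 + 1e-9) * 0.5


# ---------------------------------------------------------------------------
# case-level orchestration


def _allele_posterior(
    gene_yield: float | None, pp1_points: float, cfg: BayesConfig
) -> float:
    """Posterior probability that the allele is causal: the diagnostic yield
    (a hypothetical posterior) updated by the co-segregation odds."""
    if gene_yield is None or gene_yield <= 0.0:
        return posterior_from_points(pp1_points, cfg)
    if gene_yield >= 1.0:
        return 1.0
    odds = gene_yield / (1.0 - gene_yield) * odds_from_points(pp1_points, cfg)
    return odds / (1.0 + odds)


def _zygosity(
    ped: Pedigree, alleles: Sequence[AlleleCandidate], gene: str, mode: InheritanceMode
) -> str:
    from .pedigree_model import Genotype

    gene_alleles = [a for a in alleles if a.gene == gene]
    proband = ped.proband
    if mode.mode == "XLR":
        return "hemizygous"
    if mode.mode == "AR":
        for a in gene_alleles:
            for v in a.variant_ids:
                if proband.genotype(v) is Genotype.HOMOZYGOUS:
                    return "homozygous"
        return "compound_het" if len(gene_alleles) >= 2 else "homozygous"
    return "heterozygous"


@dataclass(frozen=True)
class _GenePhase:
    """Phase outcome restricted to one gene's candidate variants."""

    countable_vids: tuple[str, ...]  # variants whose co-segregations may be counted
    live_vids: tuple[str, ...]       # variants retaining locus evidence
    consumed: tuple[str, ...]
    unresolved: bool
    note: str = ""


def _phase_for_gene(
    fam: Pedigree,
    gene_vids: Sequence[str],
    all_vids: Sequence[str],
    mode: InheritanceMode,
) -> _GenePhase:
    """Resolve phase as it affects one gene.

    Dominant inheritance phases the whole candidate set at once (a single
    affected meiosis picks the co-segregating variant among all candidates,
    across genes); recessive and X-linked phase within the gene.
    """
    gene_vids = tuple(gene_vids)
    if mode.mode == "AD" and len(all_vids) > 1:
        ph = establish_phase(fam, all_vids, mode)
        if not ph.ok:
            return _GenePhase((), gene_vids, (), True, ph.reason)
        sel_in_gene = tuple(v for v in ph.selected_variants if v in gene_vids)
        if sel_in_gene:
            return _GenePhase(sel_in_gene, sel_in_gene, ph.consumed, False, ph.reason)
        # the co-segregating variant lies in another gene: this gene's
        # variants keep PP4 (until excluded) but cannot accrue PP1
        return _GenePhase((), gene_vids, ph.consumed, False, ph.reason)
    ph = establish_phase(fam, gene_vids, mode)
    if not ph.ok:
        return _GenePhase((), gene_vids, (), True, ph.reason)
    return _GenePhase(
        ph.selected_variants, ph.selected_variants, ph.consumed, False, ph.reason
    )


def evaluate_case(
    ped: Pedigree,
    alleles: Sequence[AlleleCandidate],
    dyads: Sequence[GenePhenotypeDyad],
    config: EngineConfig = EngineConfig(),
    literature_families: Sequence[Pedigree] = (),
) -> EvidenceResult:
    """Run the full decision flow for one case and return per-variant
    evidence with an audit trail.

    ``literature_families`` are additional pedigrees segregating the same
    variants; phase is re-established and co-segregations counted within
    each family independently, then summed.
    """
    if not alleles:
        raise ValueError("at least one allele candidate is required")
    mode = dyads[0].inheritance if dyads else InheritanceMode("AD")
    audit: list[AuditEntry] = []
    result = EvidenceResult(variants={}, audit_log=audit)

    all_vids = [v for a in alleles for v in a.variant_ids]
    if len(set(all_vids)) != len(all_vids):
        raise ValueError("a variant may appear on only one allele candidate")
    if mode.mode == "XLR":
        validate_x_linked_genotypes(ped, all_vids)

    for a in alleles:
        for v in a.variant_ids:
            result.variants[v] = VariantEvidence(variant_id=v, gene=a.gene)

    # applicability gate: phenocopies make the heuristic invalid
    if not mode.phenocopy_negligible:
        result.requires_formal_linkage = True
        audit.append(
            AuditEntry(
                "requires_formal_linkage",
                "non-negligible phenocopy rate: co-segregation heuristic not valid, "
                "formal linkage analysis required; no PP1/PP4 emitted",
            )
        )
        _finalize(result, alleles)
        return result

    dyad_by_gene = {d.gene: d for d in dyads}
    candidate_genes = sorted({a.gene for a in alleles})
    locus_variants = {
        g: [v for a in alleles if a.gene == g for v in a.variant_ids]
        for g in candidate_genes
    }

    # tightly linked dyad genes share segregation evidence; warn
    by_group: dict[str, list[str]] = {}
    for d in dyads:
        if d.linked_group:
            by_group.setdefault(d.linked_group, []).append(d.gene)
    for group, genes in by_group.items():
        if len(genes) >= 2:
            audit.append(
                AuditEntry(
                    "linked_loci_warning",
                    f"genes {sorted(genes)} share linked group {group!r}: segregation "
                    "evidence implicates the linked locus pair jointly and must be "
                    "apportioned between them",
                )
            )

    # step 1: non-segregations
    nonsegs = detect_nonsegregations(ped, locus_variants, mode)
    result.nonsegregations = nonsegs
    for gene, events in nonsegs.items():
        audit.append(
            AuditEntry(
                "nonsegregation_detected",
                f"{len(events)} non-segregation event(s) at {gene}",
                {"gene": gene, "events": [(e.individual_id, e.reason) for e in events]},
            )
        )

    # conflicting co-segregation (support and contradiction at one locus)
    # cannot be priced by this heuristic
    for gene, events in nonsegs.items():
        probe = count_cosegregations(
            ped,
            locus_variants[gene],
            mode,
            count_inferred_genotypes=config.count_inferred_genotypes,
        )
        if probe.total_count > 0:
            result.requires_formal_linkage = True
            audit.append(
                AuditEntry(
                    "requires_formal_linkage",
                    f"conflicting co-segregation at {gene}: both supporting "
                    "co-segregations and non-segregations observed; formal linkage "
                    "analysis required, no PP1/PP4 emitted",
                    {"gene": gene},
                )
            )
            _finalize(result, alleles)
            return result

    # step 2: locus exclusion
    excluded = set(config.excluded_genes)
    for gene, events in nonsegs.items():
        if gene not in dyad_by_gene:
            continue
        vids_hit = {v for e in events for v in e.variant_ids}
        if mode.mode == "AR" or vids_hit >= set(locus_variants[gene]):
            excluded.add(gene)
    excluded &= set(dyad_by_gene)
    if excluded and excluded >= {d.gene for d in dyads}:
        raise ValueError("non-segregation evidence excludes every candidate locus")
    result.excluded_loci = sorted(excluded)

    effective_dyads = list(dyads)
    if excluded:
        effective_dyads = apply_locus_exclusion(
            dyads, excluded, config.post_exclusion_ceiling, config.post_exclusion_yield
        )
        denom = 1.0 - sum(dyad_by_gene[g].diagnostic_yield or 0.0 for g in excluded)
        for d in effective_dyads:
            old = dyad_by_gene[d.gene].diagnostic_yield
            audit.append(
                AuditEntry(
                    "locus_exclusion_renormalization",
                    f"{d.gene}: diagnostic yield {old} -> {d.diagnostic_yield} "
                    f"after excluding {sorted(excluded)}",
                    {"gene": d.gene, "yield_before": old, "yield_after": d.diagnostic_yield},
                )
            )
            if d.gene in config.post_exclusion_yield and old is not None:
                arithmetic = min(old / denom, config.post_exclusion_ceiling)
                if abs(config.post_exclusion_yield[d.gene] - arithmetic) > 1e-9:
                    audit.append(
                        AuditEntry(
                            "post_exclusion_yield_override",
                            f"{d.gene}: asserted post-exclusion yield "
                            f"{config.post_exclusion_yield[d.gene]} diverges from "
                            f"arithmetic renormalization {arithmetic:.4f}",
                        )
                    )

    # step 3: architecture check on the *configured* architecture (exclusion
    # converts a case to effective homogeneity but does not silence PP1)
    homogeneous = (
        len(dyads) == 1
        and dyads[0].diagnostic_yield is not None
        and dyads[0].diagnostic_yield > config.homogeneity_yield_threshold
    )
    if homogeneous:
        audit.append(
            AuditEntry(
                "locus_homogeneity",
                f"single-locus phenotype with diagnostic yield "
                f"{dyads[0].diagnostic_yield:.3f} > {config.homogeneity_yield_threshold}: "
                "co-segregation is already implied by the phenotype, PP1 suppressed",
            )
        )

    cap = None if config.cap_lifted else config.cap
    min_yield = config.min_pp4_yield

    # step 4: per-gene scoring
    for gene in candidate_genes:
        gene_alleles = [a for a in alleles if a.gene == gene]
        gene_vids = locus_variants[gene]
        dyad = dyad_by_gene.get(gene)
        zygosity = _zygosity(ped, alleles, gene, mode)

        gene_events = nonsegs.get(gene, [])
        bs4_by_variant: dict[str, float] = {}
        for v in gene_vids:
            v_events = [e for e in gene_events if v in e.variant_ids]
            bs4_by_variant[v] = bs4_assign(v_events, mode, zygosity)
            if bs4_by_variant[v] != 0.0:
                audit.append(
                    AuditEntry(
                        "bs4_assigned",
                        f"{v}: {bs4_by_variant[v]:+.1f} points for non-segregation",
                        {"variant": v, "events": [(e.individual_id, e.reason) for e in v_events]},
                    )
                )
            elif v_events and zygosity == "compound_het":
                audit.append(
                    AuditEntry(
                        "bs4_exempt_compound_het",
                        f"{v}: non-segregation observed but the compound-heterozygous "
                        "configuration cannot identify which allele is benign; BS4 not applied",
                    )
                )

        if gene in excluded:
            for v in gene_vids:
                ev = result.variants[v]
                ev.bs4_points = bs4_by_variant[v]
            audit.append(
                AuditEntry(
                    "locus_excluded",
                    f"{gene} excluded by non-segregation: PP4/PP1 withdrawn for its variants",
                    {"gene": gene},
                )
            )
            continue

        # PP4 (pre- and post-exclusion)
        pp4 = pp4_pre = 0.0
        if dyad is not None:
            pp4_pre = pp4_assign(dyads, gene, config.bayes, min_yield)
            pp4 = pp4_assign(effective_dyads, gene, config.bayes, min_yield)
            eff = next(d for d in effective_dyads if d.gene == gene)
            if not dyad.phenotype_specific:
                audit.append(
                    AuditEntry("pp4_skipped", f"{gene}: phenotyping inadequate for PP4")
                )
            elif dyad.diagnostic_yield is None:
                audit.append(
                    AuditEntry("pp4_skipped", f"{gene}: diagnostic yield unknown, PP4 not awarded")
                )
            elif pp4 == 0.0:
                audit.append(
                    AuditEntry(
                        "pp4_below_floor",
                        f"{gene}: diagnostic yield {eff.diagnostic_yield:.3f} below the "
                        f"{min_yield:.0%} floor, PP4 not applied",
                    )
                )
            else:
                audit.append(
                    AuditEntry(
                        "pp4_assigned",
                        f"{gene}: diagnostic yield {eff.diagnostic_yield:.3f} -> {pp4:+.1f} points",
                        {"gene": gene, "yield": eff.diagnostic_yield, "points": pp4},
                    )
                )

        # phase, then PP1 (summed across families)
        gp = _phase_for_gene(ped, gene_vids, all_vids, mode)
        if set(gp.live_vids) != set(gene_vids):
            audit.append(
                AuditEntry(
                    "phase_established",
                    f"{gene}: {gp.note}; remaining candidate(s) {list(gp.live_vids)}",
                    {"gene": gene, "consumed": list(gp.consumed)},
                )
            )
        pp1 = 0.0
        if homogeneous:
            if gp.countable_vids:
                audit.append(
                    AuditEntry(
                        "pp1_suppressed",
                        f"{gene}: co-segregation evidence not applicable under locus homogeneity",
                    )
                )
        elif gp.countable_vids:
            for fam in (ped, *literature_families):
                fam_gp = gp if fam is ped else _phase_for_gene(fam, gene_vids, all_vids, mode)
                if not fam_gp.countable_vids:
                    if fam_gp.unresolved:
                        audit.append(
                            AuditEntry(
                                "phase_unresolved",
                                f"{gene} ({fam.family_id}): {fam_gp.note}; "
                                "co-segregation not counted for this family",
                            )
                        )
                    continue
                summary = count_cosegregations(
                    fam,
                    fam_gp.countable_vids,
                    mode,
                    consumed=fam_gp.consumed,
                    count_inferred_genotypes=config.count_inferred_genotypes,
                )
                fam_pp1 = pp1_assign(
                    summary,
                    mode,
                    ar_affected_increment_above_five=config.ar_affected_increment_above_five,
                )
                pp1 += fam_pp1
                if fam_pp1 or summary.counted_individuals:
                    audit.append(
                        AuditEntry(
                            "pp1_counted",
                            f"{gene} ({fam.family_id}): co-segregations "
                            f"{summary.counted_individuals} -> {fam_pp1:+.1f} points",
                            {
                                "gene": gene,
                                "family": fam.family_id,
                                "counted": list(summary.counted_individuals),
                                "points": fam_pp1,
                            },
                        )
                    )
        elif gp.unresolved:
            audit.append(
                AuditEntry(
                    "phase_unresolved",
                    f"{gene}: {gp.note}; co-segregation not counted",
                )
            )

        gene_yield = None
        if dyad is not None:
            gene_yield = next(d for d in effective_dyads if d.gene == gene).diagnostic_yield

        # unresolved phase with several candidates: the locus posterior is
        # shared equally by every candidate variant at the locus
        if gp.unresolved and len(gene_vids) > 1:
            post = _allele_posterior(gene_yield, pp1, config.bayes)
            per = divide_allele_evidence(post, len(gene_vids), config.bayes)
            if cap is not None:
                per = min(per, cap)
            audit.append(
                AuditEntry(
                    "unphased_division",
                    f"{gene}: posterior {post:.3f} divided over {len(gene_vids)} "
                    f"unphased candidate variants -> {per:+.1f} points each",
                    {"gene": gene, "posterior": post, "n": len(gene_vids), "per_variant": per},
                )
            )
            for v in gene_vids:
                ev = result.variants[v]
                ev.pp4_points = pp4
                ev.pp1_points = pp1
                ev.bs4_points = bs4_by_variant[v]
                ev.combined_locus_points = per
            continue

        combined = combine_and_cap(pp4, pp1, cap)
        if combined != pp4 + pp1:
            audit.append(
                AuditEntry(
                    "evidence_capped",
                    f"{gene}: PP4 {pp4:+.1f} + PP1 {pp1:+.1f} = {pp4 + pp1:+.1f} "
                    f"capped at {combined:+.1f}",
                    {"gene": gene, "uncapped": pp4 + pp1, "capped": combined},
                )
            )

        for allele in gene_alleles:
            in_play = [v for v in allele.variant_ids if v in gp.live_vids]
            if not in_play:
                # allele eliminated by phase: no locus evidence
                for v in allele.variant_ids:
                    result.variants[v].bs4_points = bs4_by_variant[v]
                continue
            if len(in_play) == 1:
                shares = {in_play[0]: combined}
            else:
                post = _allele_posterior(gene_yield, pp1, config.bayes)
                sub = AlleleCandidate(
                    gene, tuple(in_play), {v: allele.points_for(v) for v in in_play}
                )
                shares = redistribute_allele_evidence(
                    sub,
                    pp4 + pp1,
                    post,
                    config.redistribution_threshold,
                    cap if cap is not None else math.inf,
                    config.bayes,
                )
                if any(shares[v] == 0.0 for v in in_play):
                    audit.append(
                        AuditEntry(
                            "evidence_redistributed",
                            f"{gene}: independent evidence separates in-cis variants by "
                            f">= {config.redistribution_threshold} points; locus evidence "
                            "redistributed to the favored variant",
                            {"shares": dict(shares)},
                        )
                    )
                else:
                    audit.append(
                        AuditEntry(
                            "allele_evidence_divided",
                            f"{gene}: allele posterior {post:.3f} divided over "
                            f"{len(in_play)} in-cis variants",
                            {"shares": dict(shares)},
                        )
                    )
            for v in allele.variant_ids:
                ev = result.variants[v]
                ev.bs4_points = bs4_by_variant[v]
                if v not in shares:
                    continue
                ev.pp4_points = pp4
                ev.pp1_points = pp1
                ev.combined_locus_points = shares[v]
                if excluded:
                    ev.pre_exclusion = {
                        "pp4_points": pp4_pre,
                        "pp1_points": pp1,
                        "combined_locus_points": combine_and_cap(pp4_pre, pp1, cap),
                    }

    _finalize(result, alleles)
    if not audit:
        audit.append(AuditEntry("no_rules_fired", "trivial case: no evidence rules applied"))
    return result


def _finalize(result: EvidenceResult, alleles: Sequence[AlleleCandidate]) -> None:
    points_by_variant = {v: a.points_for(v) for a in alleles for v in a.variant_ids}
    for v, ev in result.variants.items():
        ev.reported_locus_points = floor_to_half_point(ev.combined_locus_points)
        ev.other_points = points_by_variant.get(v, 0.0)
        ev.total_points = ev.reported_locus_points + ev.bs4_points + ev.other_points
        ev.strength = strength_label(ev.reported_locus_points).combined_code
        ev.classification = classify_points(ev.total_points)
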