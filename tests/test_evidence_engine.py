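"""Rule-level and case-level tests of the evidence engine."""

from io import StringIO

import pytest
from hypothesis import given, settings, strategies as st

from cosegscore.bayes_core import classify_points, yield_to_points
from cosegscore.evidence_engine import (
    AlleleCandidate,
    EngineConfig,
    GenePhenotypeDyad,
    apply_locus_exclusion,
    bs4_assign,
    combine_and_cap,
    divide_allele_evidence,
    evaluate_case,
    floor_to_half_point,
    pp1_assign,
    pp4_assign,
    redistribute_allele_evidence,
)
from cosegscore.fixtures import build_example
from cosegscore.pedigree_model import (
    InheritanceMode,
    NonsegregationEvent,
    SegregationSummary,
    parse_ped,
)

AR = InheritanceMode("AR")
AD = InheritanceMode("AD")


def dyad(gene, y, mode=AR, **kw):
    return GenePhenotypeDyad(gene=gene, diagnostic_yield=y, inheritance=mode, **kw)


class TestPP4Assign:
    def test_high_yield_homogeneous_gene(self):
        assert pp4_assign([dyad("CTNS", 0.958)], "CTNS") == 7.0

    def test_yield_below_floor_scores_nothing(self):
        assert pp4_assign([dyad("MYH7", 0.13, AD)], "MYH7") == 0.0

    def test_two_locus_dominant_yields(self):
        dyads = [dyad("TSC1", 0.26, AD), dyad("TSC2", 0.69, AD)]
        assert pp4_assign(dyads, "TSC1") == 1.5
        assert pp4_assign(dyads, "TSC2") == 4.0

    def test_inadequate_phenotyping_scores_nothing(self):
        assert pp4_assign([dyad("CTNS", 0.958, phenotype_specific=False)], "CTNS") == 0.0

    def test_low_validity_gene_is_refused(self):
        with pytest.raises(ValueError, match="validity"):
            pp4_assign([dyad("NEW1", 0.80, validity="lower")], "NEW1")

    def test_unknown_gene_is_an_error(self):
        with pytest.raises(ValueError, match="not among"):
            pp4_assign([dyad("CTNS", 0.958)], "NOPE")


class TestApplyLocusExclusion:
    def test_two_locus_recessive_exclusion_hits_the_ceiling(self):
        dyads = [dyad("ERCC6", 0.70), dyad("ERCC8", 0.30)]
        updated = apply_locus_exclusion(dyads, {"ERCC8"})
        (ercc6,) = updated
        assert ercc6.diagnostic_yield == pytest.approx(0.99)
        assert yield_to_points(ercc6.diagnostic_yield) == 9.0

    def test_excluding_nothing_leaves_dyads_unchanged(self):
        dyads = [dyad("ERCC6", 0.70), dyad("ERCC8", 0.30)]
        assert apply_locus_exclusion(dyads, set()) == dyads

    def test_unexplained_fraction_acts_as_phantom_locus(self):
        # 26% + 69% leave 5% unexplained; excluding the 69% gene renormalizes
        # to 0.26/0.31, not to 1.0
        dyads = [dyad("TSC1", 0.26, AD), dyad("TSC2", 0.69, AD)]
        (tsc1,) = apply_locus_exclusion(dyads, {"TSC2"})
        assert tsc1.diagnostic_yield == pytest.approx(0.26 / 0.31)
        assert yield_to_points(tsc1.diagnostic_yield) == 5.0

    def test_post_exclusion_override_is_honored(self):
        dyads = [dyad("TSC1", 0.26, AD), dyad("TSC2", 0.69, AD)]
        (tsc1,) = apply_locus_exclusion(dyads, {"TSC2"}, post_exclusion_yield={"TSC1": 0.95})
        assert tsc1.diagnostic_yield == pytest.approx(0.95)

    def test_excluding_every_locus_is_a_contradiction(self):
        with pytest.raises(ValueError, match="at least one"):
            apply_locus_exclusion([dyad("A", 0.5), dyad("B", 0.4)], {"A", "B"})

    @given(
        st.lists(st.floats(min_value=0.05, max_value=0.45), min_size=2, max_size=4),
    )
    @settings(derandomize=True)
    def test_exclusion_never_decreases_surviving_pp4(self, yields):
        total = sum(yields)
        if total > 0.98:
            yields = [y * 0.98 / total for y in yields]
        dyads = [dyad(f"G{i}", y) for i, y in enumerate(yields)]
        updated = apply_locus_exclusion(dyads, {"G0"})
        for before, after in zip(dyads[1:], updated):
            assert after.diagnostic_yield >= before.diagnostic_yield
            assert yield_to_points(after.diagnostic_yield, min_yield=0.0) >= yield_to_points(
                before.diagnostic_yield, min_yield=0.0
            )


class TestPP1Assign:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            ({"ar_affected": 1}, 2.0),
            ({"ar_unaffected": 5}, 2.0),
            ({}, 0.0),
            ({"xl_males": 3, "xl_obligate_females": 1}, 4.0),
            ({"ad_individuals": 2}, 2.0),
            ({"ar_affected": 2, "ar_unaffected": 1}, 4.4),
        ],
    )
    def test_points_per_category(self, kwargs, expected):
        assert pp1_assign(SegregationSummary(**kwargs), AR) == pytest.approx(expected)

    def test_recessive_affected_beyond_five_is_configurable(self):
        summary = SegregationSummary(ar_affected=7)
        assert pp1_assign(summary, AR) == pytest.approx(14.0)
        assert pp1_assign(summary, AR, ar_affected_increment_above_five=0.4) == pytest.approx(10.8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pp1_assign(SegregationSummary(ar_affected=-1), AR)


class TestBS4Assign:
    EVENT = NonsegregationEvent("II-2", ("V",), "affected_lacks_causal_genotype")

    def test_dominant_nonsegregation_scores_minus_four(self):
        assert bs4_assign([self.EVENT, self.EVENT], AD, "heterozygous") == -4.0

    def test_no_events_scores_zero(self):
        assert bs4_assign([], AD, "heterozygous") == 0.0

    def test_compound_het_is_exempt(self):
        # a non-segregation cannot identify which of the two alleles is benign
        assert bs4_assign([self.EVENT], AR, "compound_het") == 0.0

    def test_homozygous_recessive_is_not_exempt(self):
        assert bs4_assign([self.EVENT], AR, "homozygous") == -4.0


class TestDivideAlleleEvidence:
    @pytest.mark.parametrize(
        "posterior,n,expected",
        [
            (0.958, 2, 2.5),   # ~96% allele split two ways -> 48% -> +2.5 each
            (0.91, 2, 2.5),    # 45.5% per variant
            (0.958, 1, 7.0),   # division by one is the undivided conversion
        ],
    )
    def test_posterior_division(self, posterior, n, expected):
        assert divide_allele_evidence(posterior, n) == expected

    def test_dividing_points_arithmetically_would_be_wrong(self):
        # +7.0 allele points halved arithmetically would be +3.5; the correct
        # posterior division gives +2.5
        allele_points = yield_to_points(0.958)
        assert divide_allele_evidence(0.958, 2) != allele_points / 2

    def test_zero_variants_rejected(self):
        with pytest.raises(ValueError):
            divide_allele_evidence(0.9, 0)

    @given(
        st.floats(min_value=0.05, max_value=1.0),
        st.integers(min_value=1, max_value=6),
    )
    @settings(derandomize=True)
    def test_divided_points_never_exceed_undivided(self, posterior, n):
        per_variant = divide_allele_evidence(posterior, n)
        whole = yield_to_points(posterior, min_yield=0.0)
        assert per_variant <= whole
        # shares sum back to the allele posterior by construction
        assert n * (posterior / n) == pytest.approx(posterior)


class TestRedistributeAlleleEvidence:
    def allele(self, points_a, points_b):
        return AlleleCandidate("CTNS", ("VA", "VB"), {"VA": points_a, "VB": points_b})

    def test_wide_independent_spread_redistributes_everything(self):
        # +2.0 vs -6.0: 8-point spread >= the 6-point threshold
        shares = redistribute_allele_evidence(self.allele(2.0, -6.0), 7.0, 0.958)
        assert shares == {"VA": 5.0, "VB": 0.0}

    def test_no_independent_evidence_divides_equally(self):
        shares = redistribute_allele_evidence(self.allele(0.0, 0.0), 7.0, 0.958)
        assert shares == {"VA": 2.5, "VB": 2.5}

    def test_spread_below_threshold_divides(self):
        shares = redistribute_allele_evidence(self.allele(2.0, -2.0), 7.0, 0.958)
        assert shares == {"VA": 2.5, "VB": 2.5}

    def test_favored_variant_total_reaches_likely_pathogenic(self):
        shares = redistribute_allele_evidence(self.allele(2.0, -6.0), 7.0, 0.958)
        total = shares["VA"] + 2.0  # locus evidence plus the independent +2.0
        assert total == 7.0
        assert classify_points(total) == "Likely pathogenic"

    def test_equality_with_threshold_suffices(self):
        shares = redistribute_allele_evidence(self.allele(3.0, -3.0), 7.0, 0.958)
        assert shares == {"VA": 5.0, "VB": 0.0}


class TestCombineAndCap:
    @pytest.mark.parametrize(
        "pp4,pp1,expected",
        [(4.0, 2.0, 5.0), (4.0, 0.4, 4.4), (0.0, 0.0, 0.0), (3.0, 1.5, 4.5)],
    )
    def test_cap_at_five(self, pp4, pp1, expected):
        assert combine_and_cap(pp4, pp1) == pytest.approx(expected)

    def test_cap_can_be_lifted(self):
        assert combine_and_cap(9.0, 2.0, cap=None) == pytest.approx(11.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_and_cap(-1.0, 0.0)

    @given(
        st.floats(min_value=0.0, max_value=12.0),
        st.floats(min_value=0.0, max_value=12.0),
    )
    @settings(derandomize=True)
    def test_cap_invariant(self, pp4, pp1):
        assert combine_and_cap(pp4, pp1) <= 5.0

    def test_reporting_floor(self):
        assert floor_to_half_point(4.4) == 4.0
        assert floor_to_half_point(9.4) == 9.0
        assert floor_to_half_point(0.4) == 0.0
        assert floor_to_half_point(2.5) == 2.5


class TestEvaluateCase:
    def test_trivial_case_is_all_zero_vus(self):
        ped = parse_ped(StringIO("F A 0 0 1 2\n"), None)
        result = evaluate_case(
            ped, [AlleleCandidate("GENE", ("V",))], [], EngineConfig()
        )
        ev = result.variant("V")
        assert ev.total_points == 0.0
        assert ev.classification == "Uncertain significance"
        assert result.audit_log  # audit trail is never empty

    def test_phenocopy_prone_trait_requires_formal_linkage(self):
        ex = build_example("fig5a")
        mode = InheritanceMode("AD", fully_penetrant=False, phenocopy_negligible=False)
        dyads = [GenePhenotypeDyad("MYH7", 0.13, mode)]
        result = evaluate_case(ex.bundle.pedigree, ex.bundle.alleles, dyads)
        assert result.requires_formal_linkage
        ev = result.variant("MYH7:p.Arg1500Trp")
        assert ev.pp1_points == 0.0 and ev.pp4_points == 0.0

    def test_conflicting_cosegregation_requires_formal_linkage(self):
        # two affected siblings, one homozygous (support) and one typed
        # without the genotype (contradiction) at the same locus
        ped = parse_ped(
            StringIO(
                "F I-1 0 0 1 1\nF I-2 0 0 2 1\n"
                "F II-1 I-1 I-2 1 2\nF II-2 I-1 I-2 2 2\nF II-3 I-1 I-2 1 2\n"
            ),
            StringIO(
                "I-1\tV\t0/1\nI-2\tV\t0/1\nII-1\tV\t1/1\nII-2\tV\t1/1\nII-3\tV\t0/0\n"
            ),
            proband_id="II-1",
        )
        result = evaluate_case(
            ped,
            [AlleleCandidate("G", ("V",))],
            [dyad("G", 0.70), dyad("G2", 0.30)],
        )
        assert result.requires_formal_linkage
        assert result.variant("V").total_points == 0.0

    def test_low_validity_gene_with_pp4_is_refused(self):
        ex = build_example("fig3a")
        dyads = [
            GenePhenotypeDyad("ERCC6", 0.70, AR, validity="lower"),
            GenePhenotypeDyad("ERCC8", 0.30, AR),
        ]
        with pytest.raises(ValueError, match="validity"):
            evaluate_case(ex.bundle.pedigree, ex.bundle.alleles, dyads)

    def test_literature_families_sum_across_families(self):
        # the same dominant variant observed in a second family with one more
        # affected carrier parent adds one more co-segregation point
        ex = build_example("fig5a")
        lit = build_example("fig5a").bundle.pedigree
        result = evaluate_case(
            ex.bundle.pedigree,
            ex.bundle.alleles,
            ex.bundle.dyads,
            ex.bundle.config,
            literature_families=[lit],
        )
        assert result.variant("MYH7:p.Arg1500Trp").pp1_points == pytest.approx(2.0)

    def test_linked_gene_pair_triggers_audit_warning(self):
        ex = build_example("fig3a")
        dyads = [
            GenePhenotypeDyad("ERCC6", 0.70, AR, linked_group="pair1"),
            GenePhenotypeDyad("ERCC8", 0.30, AR, linked_group="pair1"),
        ]
        result = evaluate_case(ex.bundle.pedigree, ex.bundle.alleles, dyads)
        assert any(e.rule == "linked_loci_warning" for e in result.audit_log)

    def test_unphased_dominant_candidates_divide_the_posterior(self):
        # two candidate variants, no relatives typed: each takes points from
        # half the 91% locus posterior
        ped = parse_ped(
            StringIO("F A 0 0 1 2\n"),
            StringIO("A\tV1\t0/1\nA\tV2\t0/1\n"),
        )
        result = evaluate_case(
            ped,
            [AlleleCandidate("FBN1", ("V1",)), AlleleCandidate("FBN1", ("V2",))],
            [dyad("FBN1", 0.91, AD)],
        )
        assert result.variant("V1").combined_locus_points == 2.5
        assert result.variant("V2").combined_locus_points == 2.5

    def test_duplicate_variant_on_two_alleles_rejected(self):
        ped = parse_ped(StringIO("F A 0 0 1 2\n"), None)
        with pytest.raises(ValueError, match="only one allele"):
            evaluate_case(
                ped,
                [AlleleCandidate("G", ("V",)), AlleleCandidate("G", ("V",))],
                [],
            )

    def test_cap_invariant_on_all_worked_examples(self, worked_example):
        result = worked_example.bundle.evaluate()
        for ev in result.variants.values():
            assert ev.combined_locus_points <= 5.0 + 1e-9

    def test_lifting_the_cap_for_coding_only_disorders(self):
        from dataclasses import replace

        ex = build_example("fig3a")
        cfg = replace(ex.bundle.config, cap_lifted=True)
        result = evaluate_case(ex.bundle.pedigree, ex.bundle.alleles, ex.bundle.dyads, cfg)
        assert result.variant("ERCC6:p.Trp588Cys").combined_locus_points == pytest.approx(6.0)
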