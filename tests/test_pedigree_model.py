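"""Pedigree parsing, phase, counting and non-segregation detection."""

from io import StringIO

import pytest
from hypothesis import given, settings, strategies as st

from cosegscore.fixtures import build_example
from cosegscore.pedigree_model import (
    Affection,
    Genotype,
    InheritanceMode,
    Pedigree,
    PedigreeError,
    count_cosegregations,
    detect_nonsegregations,
    establish_phase,
    lod_from_meioses,
    parse_ped,
)

AR = InheritanceMode("AR")
AD = InheritanceMode("AD")
AD_REDUCED = InheritanceMode("AD", fully_penetrant=False)
XLR = InheritanceMode("XLR")


def ped_of(example_id):
    return build_example(example_id).bundle.pedigree


class TestParsePed:
    def test_recessive_family_structure(self):
        ped = ped_of("fig3a")
        assert len(ped.individuals) == 4
        hom = [
            i.id
            for i in ped.members()
            if i.is_affected and i.genotype("ERCC6:p.Trp588Cys") is Genotype.HOMOZYGOUS
        ]
        assert sorted(hom) == ["II-1", "II-2"]

    def test_no_genotype_table_means_untyped(self):
        ped = parse_ped(StringIO("F A 0 0 1 2\n"), None)
        assert ped.proband.genotype("anything") is Genotype.UNTYPED

    def test_dangling_parent_names_the_row(self):
        with pytest.raises(PedigreeError, match="GHOST"):
            parse_ped(StringIO("F A GHOST 0 1 2\n"), None)

    def test_duplicate_individual_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            parse_ped(StringIO("F A 0 0 1 2\nF A 0 0 1 2\n"), None)

    def test_malformed_genotype_token_reports_line(self):
        with pytest.raises(PedigreeError, match="line 2"):
            parse_ped(
                StringIO("F A 0 0 1 2\n"),
                StringIO("individual_id\tvariant_id\tgenotype\nA\tV\t0|1\n"),
            )

    def test_hemizygous_female_is_a_parse_error(self):
        with pytest.raises(PedigreeError, match="hemizygous"):
            parse_ped(StringIO("F A 0 0 2 2\n"), StringIO("A\tV\t1\n"))

    def test_proband_defaults_to_first_affected(self):
        ped = parse_ped(StringIO("F A 0 0 1 1\nF B 0 0 2 2\nF C 0 0 1 2\n"), None)
        assert ped.proband_id == "B"

    def test_unaffected_proband_rejected(self):
        with pytest.raises(PedigreeError, match="affected or unknown"):
            parse_ped(StringIO("F A 0 0 1 1\nF B 0 0 2 2\n"), None, proband_id="A")

    def test_cycle_in_parent_links_rejected(self):
        text = "F A B 0 1 2\nF B A 0 1 1\n"
        with pytest.raises(PedigreeError, match="cycle"):
            parse_ped(StringIO(text), None)


class TestEstablishPhase:
    def test_dominant_phase_set_by_affected_parent(self):
        ped = ped_of("fig4a")
        result = establish_phase(ped, ["FBN1:p.Gly940Val", "FBN1:p.Glu1005Val"], AD)
        assert result.ok
        assert result.consumed == ("I-1",)
        assert result.selected_variants == ("FBN1:p.Gly940Val",)

    def test_xlinked_affected_male_sets_phase_without_meioses(self):
        ped = ped_of("fig6")
        result = establish_phase(ped, ["RBM10:p.Cys219PheX", "RBM10:p.Cys219Phe"], XLR)
        assert result.ok
        assert result.consumed == ()

    def test_dominant_unphased_without_typed_relatives(self):
        ped = parse_ped(
            StringIO("F A 0 0 1 2\n"),
            StringIO("A\tV1\t0/1\nA\tV2\t0/1\n"),
        )
        result = establish_phase(ped, ["V1", "V2"], AD)
        assert not result.ok

    def test_recessive_compound_het_consumes_the_proband(self):
        ped = ped_of("fig3b")
        result = establish_phase(ped, ["ERCC6:p.Trp588Cys", "ERCC6:p.Leu1255Pro"], AR)
        assert result.ok
        assert result.consumed == ("II-1",)

    def test_single_candidate_needs_no_phase(self):
        ped = ped_of("fig5a")
        result = establish_phase(ped, ["MYH7:p.Arg1500Trp"], AD_REDUCED)
        assert result.ok and result.consumed == ()


class TestCountCosegregations:
    def test_recessive_homozygous_sibling_counts_once(self):
        summary = count_cosegregations(ped_of("fig3a"), ["ERCC6:p.Trp588Cys"], AR)
        assert summary.ar_affected == 1
        assert summary.counted_individuals == ["II-2"]

    def test_unaffected_parents_are_never_counted(self):
        summary = count_cosegregations(ped_of("fig3a"), ["ERCC6:p.Trp588Cys"], AR)
        assert "I-1" in summary.uninformative_individuals
        assert "I-2" in summary.uninformative_individuals

    def test_xlinked_family_counts_four_including_obligate_female(self):
        summary = count_cosegregations(ped_of("fig6"), ["RBM10:p.Cys219Phe"], XLR)
        assert summary.xl_males == 3
        assert summary.xl_obligate_females == 1
        assert sorted(summary.counted_individuals) == ["II-1", "II-2", "III-1", "III-2"]

    def test_proband_only_family_counts_nothing(self):
        ped = parse_ped(StringIO("F A 0 0 1 2\n"), StringIO("A\tV\t0/1\n"))
        summary = count_cosegregations(ped, ["V"], AD)
        assert summary.total_count == 0

    def test_inference_flag_controls_grandmother(self):
        ped = ped_of("fig5b")
        with_inf = count_cosegregations(
            ped, ["MYH7:p.Arg1500Trp"], AD_REDUCED, count_inferred_genotypes=True
        )
        without = count_cosegregations(
            ped, ["MYH7:p.Arg1500Trp"], AD_REDUCED, count_inferred_genotypes=False
        )
        assert with_inf.ad_individuals == 3
        assert without.ad_individuals == 2
        assert "I-2" in with_inf.counted_individuals
        assert "I-2" not in without.counted_individuals

    def test_unknown_affection_is_never_counted(self):
        ped = parse_ped(
            StringIO("F A 0 0 1 2\nF B 0 0 1 0\n"),
            StringIO("A\tV\t0/1\nB\tV\t0/1\n"),
        )
        summary = count_cosegregations(ped, ["V"], AD)
        assert summary.total_count == 0
        assert "B" in summary.uninformative_individuals

    def test_affected_only_analysis_skips_unaffected(self):
        # under reduced penetrance, unaffected relatives never count
        ped = ped_of("fig5b")
        summary = count_cosegregations(ped, ["MYH7:p.Arg1500Trp"], AD_REDUCED)
        assert summary.ar_unaffected == 0
        assert "III-2" in summary.uninformative_individuals  # unaffected carrier

    @pytest.mark.parametrize(
        "example_id,mode",
        [("fig3a", AR), ("fig3c", AR), ("fig4b", AD), ("fig5b", AD_REDUCED), ("fig6", XLR)],
    )
    def test_every_non_proband_lands_in_exactly_one_bin(self, example_id, mode):
        ex = build_example(example_id)
        ped = ex.bundle.pedigree
        variants = [v for a in ex.bundle.alleles for v in a.variant_ids]
        summary = count_cosegregations(ped, variants, mode)
        accounted = (
            set(summary.counted_individuals)
            | {e.individual_id for e in summary.nonsegregations}
            | set(summary.uninformative_individuals)
            | (set(summary.phase_setting_individuals) - {ped.proband_id})
        )
        assert accounted == set(ped.individuals) - {ped.proband_id}
        assert len(summary.counted_individuals) == summary.total_count

    def test_counting_is_order_independent(self):
        ex = build_example("fig6")
        ped = ex.bundle.pedigree
        reversed_ped = Pedigree(
            family_id=ped.family_id,
            individuals=dict(reversed(list(ped.individuals.items()))),
            proband_id=ped.proband_id,
        )
        a = count_cosegregations(ped, ["RBM10:p.Cys219Phe"], XLR)
        b = count_cosegregations(reversed_ped, ["RBM10:p.Cys219Phe"], XLR)
        assert sorted(a.counted_individuals) == sorted(b.counted_individuals)
        assert a.total_count == b.total_count


class TestDetectNonsegregations:
    def test_unaffected_sibling_with_full_recessive_genotype(self):
        ex = build_example("fig3d")
        events = detect_nonsegregations(
            ex.bundle.pedigree,
            {"ERCC8": ["ERCC8:p.Tyr100Phe"],
             "ERCC6": ["ERCC6:p.Trp588Cys", "ERCC6:p.Leu1255Pro"]},
            AR,
        )
        assert list(events) == ["ERCC8"]
        assert [e.individual_id for e in events["ERCC8"]] == ["II-2"]
        assert events["ERCC8"][0].reason == "unaffected_carries_causal_genotype"

    def test_affected_relatives_lacking_dominant_variant(self):
        ex = build_example("fig4b")
        events = detect_nonsegregations(
            ex.bundle.pedigree,
            {"TSC1": ["TSC1:p.Leu19Gln"], "TSC2": ["TSC2:p.Lys34Thr"]},
            AD,
        )
        assert list(events) == ["TSC2"]
        assert sorted(e.individual_id for e in events["TSC2"]) == ["II-2", "II-3"]

    def test_consistent_family_returns_empty(self):
        ex = build_example("fig3a")
        events = detect_nonsegregations(
            ex.bundle.pedigree, {"ERCC6": ["ERCC6:p.Trp588Cys"]}, AR
        )
        assert events == {}

    def test_reduced_penetrance_exempts_unaffected_carriers(self):
        ex = build_example("fig5b")
        events = detect_nonsegregations(
            ex.bundle.pedigree, {"MYH7": ["MYH7:p.Arg1500Trp"]}, AD_REDUCED
        )
        assert events == {}

    def test_same_individual_never_counted_and_flagged_for_one_gene(self):
        # fig3d's unaffected sibling: co-segregation for ERCC6, event for ERCC8
        ex = build_example("fig3d")
        ped = ex.bundle.pedigree
        summary = count_cosegregations(
            ped, ["ERCC6:p.Trp588Cys", "ERCC6:p.Leu1255Pro"], AR
        )
        events = detect_nonsegregations(ped, {"ERCC6": ["ERCC6:p.Trp588Cys", "ERCC6:p.Leu1255Pro"]}, AR)
        assert "II-2" in summary.counted_individuals
        assert events == {}


class TestLodFromMeioses:
    @pytest.mark.parametrize(
        "m,lr,lod",
        [(2, 4.0, 0.602), (0, 1.0, 0.0), (10, 1024.0, 3.0103)],
    )
    def test_fully_informative_meioses(self, m, lr, lod):
        got_lr, got_lod = lod_from_meioses(m)
        assert got_lr == lr
        assert got_lod == pytest.approx(lod, abs=5e-4)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            lod_from_meioses(-1)

    @given(st.integers(min_value=0, max_value=60))
    @settings(derandomize=True)
    def test_lod_is_log10_of_likelihood_ratio(self, m):
        import math

        lr, lod = lod_from_meioses(m)
        assert lod == pytest.approx(math.log10(lr))
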