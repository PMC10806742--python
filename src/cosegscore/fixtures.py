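"""Programmatic builders for the worked example families.

Each example is a small clinical-testing scenario -- a pedigree, its
genotypes, the gene-phenotype dyads and allele candidates -- together with
the expected per-variant evidence, forming the package's regression surface:

* ``fig2a``/``fig2b`` -- cystinosis (CTNS): locus homogeneity under
  autosomal-recessive inheritance; evidence capping and in-cis division.
* ``fig3a``-``fig3d`` -- Cockayne syndrome (ERCC6/ERCC8): two-locus
  heterogeneity; affected vs unaffected recessive co-segregations; benign
  evidence at one locus becoming pathogenic evidence at the other.
* ``fig4a`` -- Marfan syndrome (FBN1): dominant locus homogeneity and
  phase-setting with a single affected meiosis.
* ``fig4b`` -- tuberous sclerosis (TSC1/TSC2): dominant heterogeneity,
  non-segregation, locus exclusion and PP4 reassessment.
* ``fig5a``/``fig5b`` -- dilated cardiomyopathy (MYH7): diagnostic yield
  below the PP4 floor, reduced penetrance (affected-only counting), and
  obligate/inferred genotypes.
* ``fig6`` -- TARP syndrome (RBM10): X-linked recessive counting with an
  obligate-carrier female.

Pedigree details not fixed by the scenario descriptions (founder genotypes,
sibling order, the identity of the proband in multi-affected families) are
chosen deterministically and documented in each builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

from .evidence_engine import AlleleCandidate, EngineConfig, GenePhenotypeDyad
from .io import CaseBundle, parse_case_yaml, write_bundle_files
from .pedigree_model import parse_ped

__all__ = ["WorkedExample", "EXAMPLE_IDS", "build_example", "write_bundle"]

# Table of variants used across the examples (gene, protein change).
CTNS_MET1ARG = "CTNS:p.Met1Arg"
CTNS_VAL32GLY = "CTNS:p.Val32Gly"
CTNS_GLY37ALA = "CTNS:p.Gly37Ala"
ERCC6_TRP588CYS = "ERCC6:p.Trp588Cys"
ERCC6_LEU1255PRO = "ERCC6:p.Leu1255Pro"
ERCC8_TYR100PHE = "ERCC8:p.Tyr100Phe"
FBN1_GLY940VAL = "FBN1:p.Gly940Val"
FBN1_GLU1005VAL = "FBN1:p.Glu1005Val"
TSC1_LEU19GLN = "TSC1:p.Leu19Gln"
TSC2_LYS34THR = "TSC2:p.Lys34Thr"
MYH7_ARG1500TRP = "MYH7:p.Arg1500Trp"
RBM10_CYS219PHE = "RBM10:p.Cys219Phe"

# Diagnostic yields used by the scenarios.
CYSTINOSIS_CTNS_YIELD = 0.958
COCKAYNE_ERCC6_YIELD = 0.70
COCKAYNE_ERCC8_YIELD = 0.30
MARFAN_FBN1_YIELD = 0.91
TS_TSC1_YIELD = 0.26
TS_TSC2_YIELD = 0.69
#: dilated cardiomyopathy: MYH7 accounts for well under the 20% PP4 floor.
DCM_MYH7_YIELD = 0.13


@dataclass
class WorkedExample:
    example_id: str
    ped_text: str
    genotypes_text: str
    case_data: dict[str, Any]
    #: expected per-variant evidence, keys matching VariantEvidence fields.
    expected: dict[str, dict[str, Any]]
    expected_excluded_loci: list[str] = field(default_factory=list)

    @property
    def bundle(self) -> CaseBundle:
        parsed = parse_case_yaml(self.case_data)
        from io import StringIO

        ped = parse_ped(
            StringIO(self.ped_text),
            StringIO(self.genotypes_text),
            proband_id=parsed["proband"],
            obligate_carriers=parsed["obligate_carriers"],
        )
        return CaseBundle(
            pedigree=ped,
            alleles=parsed["alleles"],
            dyads=parsed["dyads"],
            config=parsed["config"],
            literature_families=[],
        )


def _ped(rows: list[tuple[str, str, str, int, int]], fam: str) -> str:
    """rows: (iid, pat, mat, sex, pheno)."""
    return "\n".join(f"{fam}\t{i}\t{p}\t{m}\t{s}\t{a}" for i, p, m, s, a in rows) + "\n"


def _gt(rows: list[tuple[str, str, str]]) -> str:
    lines = ["individual_id\tvariant_id\tgenotype"]
    lines += [f"{i}\t{v}\t{g}" for i, v, g in rows]
    return "\n".join(lines) + "\n"


def _vus(pp4: float, pp1: float, combined: float, reported: float | None = None) -> dict:
    reported = combined if reported is None else reported
    return {
        "pp4_points": pp4,
        "pp1_points": pp1,
        "bs4_points": 0.0,
        "combined_locus_points": combined,
        "reported_locus_points": reported,
        "total_points": reported,
        "classification": "Uncertain significance",
    }


_EXCLUDED_VARIANT = {
    "pp4_points": 0.0,
    "pp1_points": 0.0,
    "bs4_points": -4.0,
    "combined_locus_points": 0.0,
    "reported_locus_points": 0.0,
    "total_points": -4.0,
    "classification": "Likely benign",
}


def _fig2a() -> WorkedExample:
    """Cystinosis simplex family: proband compound heterozygous, one variant
    per parental allele.  Locus homogeneity: the 95.8% yield gives +7.0
    points per allele, capped at +5.0; co-segregation is inapplicable."""
    ped = _ped(
        [("I-1", "0", "0", 1, 1), ("I-2", "0", "0", 2, 1), ("II-1", "I-1", "I-2", 1, 2)],
        "FAM2A",
    )
    gt = _gt(
        [
            ("I-1", CTNS_MET1ARG, "0/1"),
            ("I-1", CTNS_VAL32GLY, "0/0"),
            ("I-2", CTNS_MET1ARG, "0/0"),
            ("I-2", CTNS_VAL32GLY, "0/1"),
            ("II-1", CTNS_MET1ARG, "0/1"),
            ("II-1", CTNS_VAL32GLY, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": [{"gene": "CTNS", "diagnostic_yield": CYSTINOSIS_CTNS_YIELD}],
        "alleles": [
            {"gene": "CTNS", "variants": [CTNS_MET1ARG]},
            {"gene": "CTNS", "variants": [CTNS_VAL32GLY]},
        ],
    }
    expected = {
        CTNS_MET1ARG: _vus(7.0, 0.0, 5.0),
        CTNS_VAL32GLY: _vus(7.0, 0.0, 5.0),
    }
    return WorkedExample("fig2a", ped, gt, case, expected)


def _fig2b() -> WorkedExample:
    """As fig2a but the paternal allele carries two variants in cis: the
    allele's ~96% posterior is split to 48% per variant, +2.5 points each;
    the single-variant maternal allele keeps the capped +5.0."""
    ped = _ped(
        [("I-1", "0", "0", 1, 1), ("I-2", "0", "0", 2, 1), ("II-1", "I-1", "I-2", 1, 2)],
        "FAM2B",
    )
    gt = _gt(
        [
            ("I-1", CTNS_MET1ARG, "0/1"),
            ("I-1", CTNS_GLY37ALA, "0/1"),
            ("I-1", CTNS_VAL32GLY, "0/0"),
            ("I-2", CTNS_MET1ARG, "0/0"),
            ("I-2", CTNS_GLY37ALA, "0/0"),
            ("I-2", CTNS_VAL32GLY, "0/1"),
            ("II-1", CTNS_MET1ARG, "0/1"),
            ("II-1", CTNS_GLY37ALA, "0/1"),
            ("II-1", CTNS_VAL32GLY, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": [{"gene": "CTNS", "diagnostic_yield": CYSTINOSIS_CTNS_YIELD}],
        "alleles": [
            {"gene": "CTNS", "variants": [CTNS_MET1ARG, CTNS_GLY37ALA]},
            {"gene": "CTNS", "variants": [CTNS_VAL32GLY]},
        ],
    }
    expected = {
        CTNS_MET1ARG: _vus(7.0, 0.0, 2.5),
        CTNS_GLY37ALA: _vus(7.0, 0.0, 2.5),
        CTNS_VAL32GLY: _vus(7.0, 0.0, 5.0),
    }
    return WorkedExample("fig2b", ped, gt, case, expected)


_COCKAYNE_DYADS = [
    {"gene": "ERCC6", "diagnostic_yield": COCKAYNE_ERCC6_YIELD},
    {"gene": "ERCC8", "diagnostic_yield": COCKAYNE_ERCC8_YIELD},
]


def _fig3a() -> WorkedExample:
    """Cockayne syndrome, ERCC6 only sequenced: two affected children
    homozygous for a variant heterozygous in both parents.  PP4 +4.0 (70%
    yield) plus +2.0 for the co-segregating homozygous sibling, capped."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 2),
        ],
        "FAM3A",
    )
    gt = _gt(
        [
            ("I-1", ERCC6_TRP588CYS, "0/1"),
            ("I-2", ERCC6_TRP588CYS, "0/1"),
            ("II-1", ERCC6_TRP588CYS, "1/1"),
            ("II-2", ERCC6_TRP588CYS, "1/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": _COCKAYNE_DYADS,
        "alleles": [{"gene": "ERCC6", "variants": [ERCC6_TRP588CYS]}],
    }
    expected = {ERCC6_TRP588CYS: _vus(4.0, 2.0, 5.0)}
    return WorkedExample("fig3a", ped, gt, case, expected)


def _fig3b() -> WorkedExample:
    """As fig3a but the children are compound heterozygotes; the affected
    sibling garners +2.0 points for each allele (PP1 is gene-based and is
    not divided across in-trans alleles)."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 2),
        ],
        "FAM3B",
    )
    gt = _gt(
        [
            ("I-1", ERCC6_TRP588CYS, "0/1"),
            ("I-1", ERCC6_LEU1255PRO, "0/0"),
            ("I-2", ERCC6_TRP588CYS, "0/0"),
            ("I-2", ERCC6_LEU1255PRO, "0/1"),
            ("II-1", ERCC6_TRP588CYS, "0/1"),
            ("II-1", ERCC6_LEU1255PRO, "0/1"),
            ("II-2", ERCC6_TRP588CYS, "0/1"),
            ("II-2", ERCC6_LEU1255PRO, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": _COCKAYNE_DYADS,
        "alleles": [
            {"gene": "ERCC6", "variants": [ERCC6_TRP588CYS]},
            {"gene": "ERCC6", "variants": [ERCC6_LEU1255PRO]},
        ],
    }
    expected = {
        ERCC6_TRP588CYS: _vus(4.0, 2.0, 5.0),
        ERCC6_LEU1255PRO: _vus(4.0, 2.0, 5.0),
    }
    return WorkedExample("fig3b", ped, gt, case, expected)


def _fig3c() -> WorkedExample:
    """Compound-het proband with one unaffected sibling who inherited
    neither variant: +0.4 co-segregation points per allele, retained
    internally (+4.4 combined) but rounded down to +4.0 for reporting."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 1),
        ],
        "FAM3C",
    )
    gt = _gt(
        [
            ("I-1", ERCC6_TRP588CYS, "0/1"),
            ("I-1", ERCC6_LEU1255PRO, "0/0"),
            ("I-2", ERCC6_TRP588CYS, "0/0"),
            ("I-2", ERCC6_LEU1255PRO, "0/1"),
            ("II-1", ERCC6_TRP588CYS, "0/1"),
            ("II-1", ERCC6_LEU1255PRO, "0/1"),
            ("II-2", ERCC6_TRP588CYS, "0/0"),
            ("II-2", ERCC6_LEU1255PRO, "0/0"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": _COCKAYNE_DYADS,
        "alleles": [
            {"gene": "ERCC6", "variants": [ERCC6_TRP588CYS]},
            {"gene": "ERCC6", "variants": [ERCC6_LEU1255PRO]},
        ],
    }
    expected = {
        ERCC6_TRP588CYS: _vus(4.0, 0.4, 4.4, reported=4.0),
        ERCC6_LEU1255PRO: _vus(4.0, 0.4, 4.4, reported=4.0),
    }
    return WorkedExample("fig3c", ped, gt, case, expected)


def _fig3d() -> WorkedExample:
    """Both Cockayne genes tested.  The unaffected sibling shares the
    proband's homozygous ERCC8 genotype (non-segregation), excluding ERCC8:
    the ERCC6 yield renormalizes from 70% to the practical 99% ceiling
    (+9.0 points, was +4.4 combined pre-exclusion) and is capped at +5.0;
    the ERCC8 variant takes BS4."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 1),
        ],
        "FAM3D",
    )
    gt = _gt(
        [
            ("I-1", ERCC6_TRP588CYS, "0/1"),
            ("I-1", ERCC6_LEU1255PRO, "0/0"),
            ("I-1", ERCC8_TYR100PHE, "0/1"),
            ("I-2", ERCC6_TRP588CYS, "0/0"),
            ("I-2", ERCC6_LEU1255PRO, "0/1"),
            ("I-2", ERCC8_TYR100PHE, "0/1"),
            ("II-1", ERCC6_TRP588CYS, "0/1"),
            ("II-1", ERCC6_LEU1255PRO, "0/1"),
            ("II-1", ERCC8_TYR100PHE, "1/1"),
            ("II-2", ERCC6_TRP588CYS, "0/0"),
            ("II-2", ERCC6_LEU1255PRO, "0/0"),
            ("II-2", ERCC8_TYR100PHE, "1/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AR"},
        "dyads": _COCKAYNE_DYADS,
        "alleles": [
            {"gene": "ERCC6", "variants": [ERCC6_TRP588CYS]},
            {"gene": "ERCC6", "variants": [ERCC6_LEU1255PRO]},
            {"gene": "ERCC8", "variants": [ERCC8_TYR100PHE]},
        ],
    }
    pre = {"pp4_points": 4.0, "pp1_points": 0.4, "combined_locus_points": 4.4}
    expected = {
        ERCC6_TRP588CYS: {**_vus(9.0, 0.4, 5.0), "pre_exclusion": pre},
        ERCC6_LEU1255PRO: {**_vus(9.0, 0.4, 5.0), "pre_exclusion": pre},
        ERCC8_TYR100PHE: dict(_EXCLUDED_VARIANT),
    }
    return WorkedExample("fig3d", ped, gt, case, expected, ["ERCC8"])


def _fig4a() -> WorkedExample:
    """Marfan syndrome: proband with two FBN1 variants, affected father
    carrying only one.  The single affected meiosis sets phase: the
    co-segregating variant takes the full 91% yield (+6.0, capped +5.0); the
    variant from the unaffected mother takes strong benign evidence."""
    ped = _ped(
        [("I-1", "0", "0", 1, 2), ("I-2", "0", "0", 2, 1), ("II-1", "I-1", "I-2", 1, 2)],
        "FAM4A",
    )
    gt = _gt(
        [
            ("I-1", FBN1_GLY940VAL, "0/1"),
            ("I-1", FBN1_GLU1005VAL, "0/0"),
            ("I-2", FBN1_GLY940VAL, "0/0"),
            ("I-2", FBN1_GLU1005VAL, "0/1"),
            ("II-1", FBN1_GLY940VAL, "0/1"),
            ("II-1", FBN1_GLU1005VAL, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AD"},
        "dyads": [{"gene": "FBN1", "diagnostic_yield": MARFAN_FBN1_YIELD}],
        "alleles": [
            {"gene": "FBN1", "variants": [FBN1_GLY940VAL]},
            {"gene": "FBN1", "variants": [FBN1_GLU1005VAL]},
        ],
    }
    expected = {
        FBN1_GLY940VAL: _vus(6.0, 0.0, 5.0),
        FBN1_GLU1005VAL: {
            "pp4_points": 0.0,
            "pp1_points": 0.0,
            "bs4_points": -4.0,
            "combined_locus_points": 0.0,
            "reported_locus_points": 0.0,
            "total_points": -4.0,
            "classification": "Likely benign",
        },
    }
    return WorkedExample("fig4a", ped, gt, case, expected)


def _fig4b() -> WorkedExample:
    """Tuberous sclerosis panel: one variant in each of TSC1 and TSC2.
    Pre-exclusion: TSC1 +1.5 (26% yield) plus +2.0 for two co-segregations;
    TSC2 non-segregates in both affected siblings and is excluded, raising
    the asserted TSC1 post-exclusion yield to 95% (+7.0), capped at +5.0."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 2),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 2),
            ("II-3", "I-1", "I-2", 1, 2),
        ],
        "FAM4B",
    )
    gt = _gt(
        [
            ("I-1", TSC1_LEU19GLN, "0/1"),
            ("II-1", TSC1_LEU19GLN, "0/1"),
            ("II-1", TSC2_LYS34THR, "0/1"),
            ("II-2", TSC1_LEU19GLN, "0/1"),
            ("II-2", TSC2_LYS34THR, "0/0"),
            ("II-3", TSC1_LEU19GLN, "0/1"),
            ("II-3", TSC2_LYS34THR, "0/0"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AD"},
        "dyads": [
            {"gene": "TSC1", "diagnostic_yield": TS_TSC1_YIELD},
            {"gene": "TSC2", "diagnostic_yield": TS_TSC2_YIELD},
        ],
        "alleles": [
            {"gene": "TSC1", "variants": [TSC1_LEU19GLN]},
            {"gene": "TSC2", "variants": [TSC2_LYS34THR]},
        ],
        # the scenario asserts a >95% post-exclusion yield for TSC1 (external
        # estimate) rather than the arithmetic renormalization 0.26/0.31
        "options": {"post_exclusion_yield": {"TSC1": 0.95}},
    }
    expected = {
        TSC1_LEU19GLN: {
            **_vus(7.0, 2.0, 5.0),
            "pre_exclusion": {
                "pp4_points": 1.5,
                "pp1_points": 2.0,
                "combined_locus_points": 3.5,
            },
        },
        TSC2_LYS34THR: dict(_EXCLUDED_VARIANT),
    }
    return WorkedExample("fig4b", ped, gt, case, expected, ["TSC2"])


def _fig5a() -> WorkedExample:
    """Dilated cardiomyopathy (reduced penetrance, affected-only counting):
    MYH7 yield is below the 20% PP4 floor, so only the single co-segregation
    from the affected father scores (+1.0)."""
    ped = _ped(
        [("I-1", "0", "0", 1, 2), ("I-2", "0", "0", 2, 1), ("II-1", "I-1", "I-2", 1, 2)],
        "FAM5A",
    )
    gt = _gt(
        [
            ("I-1", MYH7_ARG1500TRP, "0/1"),
            ("I-2", MYH7_ARG1500TRP, "0/0"),
            ("II-1", MYH7_ARG1500TRP, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AD", "fully_penetrant": False},
        "dyads": [{"gene": "MYH7", "diagnostic_yield": DCM_MYH7_YIELD}],
        "alleles": [{"gene": "MYH7", "variants": [MYH7_ARG1500TRP]}],
    }
    expected = {MYH7_ARG1500TRP: _vus(0.0, 1.0, 1.0)}
    return WorkedExample("fig5a", ped, gt, case, expected)


def _fig5b() -> WorkedExample:
    """Three-generation dilated cardiomyopathy family.  The obligate-carrier
    affected daughter (II-2) and her typed affected son (III-1) give +2.0;
    with genotype inference enabled (default) the affected grandmother I-2
    -- whose carrier status follows from her typed-carrier child and
    typed-negative spouse -- adds a third point.  The unaffected carrier
    III-2 is not counted (reduced penetrance, age-related onset)."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 2),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 2),
            ("II-3", "0", "0", 1, 1),
            ("III-1", "II-3", "II-2", 1, 2),
            ("III-2", "II-3", "II-2", 1, 1),
        ],
        "FAM5B",
    )
    gt = _gt(
        [
            ("I-1", MYH7_ARG1500TRP, "0/0"),
            ("II-1", MYH7_ARG1500TRP, "0/1"),
            ("III-1", MYH7_ARG1500TRP, "0/1"),
            ("III-2", MYH7_ARG1500TRP, "0/1"),
        ]
    )
    case = {
        "proband": "II-1",
        "inheritance": {"mode": "AD", "fully_penetrant": False},
        "dyads": [{"gene": "MYH7", "diagnostic_yield": DCM_MYH7_YIELD}],
        "alleles": [{"gene": "MYH7", "variants": [MYH7_ARG1500TRP]}],
        "obligate_carriers": {"II-2": [MYH7_ARG1500TRP]},
    }
    expected = {MYH7_ARG1500TRP: _vus(0.0, 3.0, 3.0)}
    return WorkedExample("fig5b", ped, gt, case, expected)


def _fig6() -> WorkedExample:
    """TARP syndrome, X-linked recessive, three generations.  Diagnostic
    yield unknown, so no PP4.  Four co-segregations: the affected uncle
    II-1, the obligate-carrier female II-2 (affirmed by affected brother and
    sons), and the proband's affected brothers III-1 and III-2 (+4.0).  The
    proband III-3, an affected hemizygous male, sets phase without consuming
    a meiosis."""
    ped = _ped(
        [
            ("I-1", "0", "0", 1, 1),
            ("I-2", "0", "0", 2, 1),
            ("II-1", "I-1", "I-2", 1, 2),
            ("II-2", "I-1", "I-2", 2, 1),
            ("II-3", "0", "0", 1, 1),
            ("III-1", "II-3", "II-2", 1, 2),
            ("III-2", "II-3", "II-2", 1, 2),
            ("III-3", "II-3", "II-2", 1, 2),
        ],
        "FAM6",
    )
    gt = _gt(
        [
            ("II-1", RBM10_CYS219PHE, "1"),
            ("III-1", RBM10_CYS219PHE, "1"),
            ("III-2", RBM10_CYS219PHE, "1"),
            ("III-3", RBM10_CYS219PHE, "1"),
        ]
    )
    case = {
        "proband": "III-3",
        "inheritance": {"mode": "XLR"},
        "dyads": [{"gene": "RBM10", "diagnostic_yield": None}],
        "alleles": [{"gene": "RBM10", "variants": [RBM10_CYS219PHE]}],
    }
    expected = {RBM10_CYS219PHE: _vus(0.0, 4.0, 4.0)}
    return WorkedExample("fig6", ped, gt, case, expected)


_BUILDERS: dict[str, Callable[[], WorkedExample]] = {
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig3a": _fig3a,
    "fig3b": _fig3b,
    "fig3c": _fig3c,
    "fig3d": _fig3d,
    "fig4a": _fig4a,
    "fig4b": _fig4b,
    "fig5a": _fig5a,
    "fig5b": _fig5b,
    "fig6": _fig6,
}

EXAMPLE_IDS: tuple[str, ...] = tuple(_BUILDERS)


def build_example(example_id: str) -> WorkedExample:
    """Deterministically build one worked example with its expected result."""
    try:
        builder = _BUILDERS[example_id]
    except KeyError:
        raise ValueError(
            f"unknown example id {example_id!r}; choose from {EXAMPLE_IDS}"
        ) from None
    return builder()


def write_bundle(example: WorkedExample, directory: str | Path) -> list[Path]:
    """Write the example's case bundle (family.ped, genotypes.tsv, case.yaml)
    to a directory; loading it back yields an equivalent bundle."""
    return write_bundle_files(
        directory, example.ped_text, example.genotypes_text, example.case_data
    )
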