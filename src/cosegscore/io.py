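"""Case-bundle input and report output.

A case is a directory with three files:

* ``family.ped`` -- 6-column PED family structure;
* ``genotypes.tsv`` -- individual_id, variant_id, genotype;
* ``case.yaml`` -- gene-phenotype dyads, inheritance mode, allele candidates
  with independent evidence points, and rule options.

Reports are rendered as canonical JSON (sorted keys, no timestamps: a bundle
evaluates to byte-identical output on every run) plus a plain-text audit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .bayes_core import (
    BayesConfig,
    STRENGTH_BANDS,
    generate_table2,
)
from .evidence_engine import (
    AlleleCandidate,
    EngineConfig,
    EvidenceResult,
    GenePhenotypeDyad,
    evaluate_case,
)
from .pedigree_model import InheritanceMode, Pedigree, parse_ped

__all__ = [
    "CaseBundle",
    "ConfigError",
    "load_bundle",
    "write_bundle_files",
    "evaluate_bundle",
    "result_to_dict",
    "render_audit",
    "render_table",
]

SCHEMA_VERSION = 1

PED_FILENAME = "family.ped"
GENOTYPES_FILENAME = "genotypes.tsv"
CASE_FILENAME = "case.yaml"


class ConfigError(ValueError):
    """Invalid case.yaml content."""


@dataclass
class CaseBundle:
    pedigree: Pedigree
    alleles: list[AlleleCandidate]
    dyads: list[GenePhenotypeDyad]
    config: EngineConfig
    literature_families: list[Pedigree]

    def evaluate(self) -> EvidenceResult:
        return evaluate_case(
            self.pedigree,
            self.alleles,
            self.dyads,
            self.config,
            self.literature_families,
        )


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


_CASE_KEYS = {
    "proband",
    "inheritance",
    "dyads",
    "alleles",
    "obligate_carriers",
    "options",
    "bayes",
    "literature_families",
}
_INHERITANCE_KEYS = {"mode", "fully_penetrant", "phenocopy_negligible"}
_DYAD_KEYS = {"gene", "diagnostic_yield", "validity", "phenotype_specific", "linked_group"}
_ALLELE_KEYS = {"gene", "variants", "independent_points"}
_OPTION_KEYS = {
    "cap",
    "cap_lifted",
    "min_pp4_yield",
    "homogeneity_yield_threshold",
    "redistribution_threshold",
    "post_exclusion_ceiling",
    "post_exclusion_yield",
    "count_inferred_genotypes",
    "ar_affected_increment_above_five",
    "excluded_genes",
}
_BAYES_KEYS = {"prior_probability", "odds_per_point_base", "points_per_exponent_unit"}
_LITFAM_KEYS = {"ped", "genotypes", "source"}


def parse_case_yaml(data: Mapping[str, Any]) -> dict[str, Any]:
    """Validate a case.yaml mapping; returns the pieces needed to assemble a
    :class:`CaseBundle` (pedigree files are parsed separately)."""
    if not isinstance(data, Mapping):
        raise ConfigError("case.yaml must contain a mapping")
    _check_keys(data, _CASE_KEYS, "case.yaml")

    inh = data.get("inheritance")
    if not isinstance(inh, Mapping) or "mode" not in inh:
        raise ConfigError("case.yaml requires an 'inheritance' mapping with a 'mode'")
    _check_keys(inh, _INHERITANCE_KEYS, "inheritance")
    mode = InheritanceMode(
        mode=str(inh["mode"]),
        fully_penetrant=bool(inh.get("fully_penetrant", True)),
        phenocopy_negligible=bool(inh.get("phenocopy_negligible", True)),
    )

    dyads = []
    for i, d in enumerate(data.get("dyads", []) or []):
        _check_keys(d, _DYAD_KEYS, f"dyads[{i}]")
        if "gene" not in d:
            raise ConfigError(f"dyads[{i}] requires a 'gene'")
        dy = d.get("diagnostic_yield")
        dyads.append(
            GenePhenotypeDyad(
                gene=str(d["gene"]),
                diagnostic_yield=None if dy is None else float(dy),
                inheritance=mode,
                validity=str(d.get("validity", "definitive")),
                phenotype_specific=bool(d.get("phenotype_specific", True)),
                linked_group=d.get("linked_group"),
            )
        )
    known = sum(d.diagnostic_yield or 0.0 for d in dyads)
    if known > 1.0 + 0.02:
        raise ConfigError(
            f"diagnostic yields of the dyads sum to {known:.3f} > 1 "
            "(plus the unexplained fraction they must total at most 1)"
        )

    alleles = []
    for i, a in enumerate(data.get("alleles", []) or []):
        _check_keys(a, _ALLELE_KEYS, f"alleles[{i}]")
        if "gene" not in a or not a.get("variants"):
            raise ConfigError(f"alleles[{i}] requires 'gene' and non-empty 'variants'")
        alleles.append(
            AlleleCandidate(
                gene=str(a["gene"]),
                variant_ids=tuple(str(v) for v in a["variants"]),
                independent_points={
                    str(k): float(v) for k, v in (a.get("independent_points") or {}).items()
                },
            )
        )
    if not alleles:
        raise ConfigError("case.yaml requires at least one allele candidate")

    bayes_raw = data.get("bayes") or {}
    _check_keys(bayes_raw, _BAYES_KEYS, "bayes")
    bayes = BayesConfig(
        prior_probability=float(bayes_raw.get("prior_probability", 0.102)),
        odds_per_point_base=float(bayes_raw.get("odds_per_point_base", 81.0)),
        points_per_exponent_unit=float(bayes_raw.get("points_per_exponent_unit", 6.0)),
    )

    opts = data.get("options") or {}
    _check_keys(opts, _OPTION_KEYS, "options")
    config = EngineConfig(
        bayes=bayes,
        cap=float(opts.get("cap", 5.0)),
        cap_lifted=bool(opts.get("cap_lifted", False)),
        min_pp4_yield=float(opts.get("min_pp4_yield", 0.20)),
        homogeneity_yield_threshold=float(opts.get("homogeneity_yield_threshold", 0.90)),
        redistribution_threshold=float(opts.get("redistribution_threshold", 6.0)),
        post_exclusion_ceiling=float(opts.get("post_exclusion_ceiling", 0.99)),
        post_exclusion_yield={
            str(k): float(v) for k, v in (opts.get("post_exclusion_yield") or {}).items()
        },
        count_inferred_genotypes=bool(opts.get("count_inferred_genotypes", True)),
        ar_affected_increment_above_five=float(
            opts.get("ar_affected_increment_above_five", 2.0)
        ),
        excluded_genes=frozenset(opts.get("excluded_genes") or ()),
    )

    obligate = {
        str(k): [str(v) for v in vs]
        for k, vs in (data.get("obligate_carriers") or {}).items()
    }

    return {
        "proband": data.get("proband"),
        "mode": mode,
        "dyads": dyads,
        "alleles": alleles,
        "config": config,
        "obligate_carriers": obligate,
        "literature_families": list(data.get("literature_families") or []),
    }


def load_bundle(directory: str | Path) -> CaseBundle:
    """Read family.ped + genotypes.tsv + case.yaml from a case directory."""
    directory = Path(directory)
    case_path = directory / CASE_FILENAME
    if not case_path.exists():
        raise ConfigError(f"missing {CASE_FILENAME} in {directory}")
    parsed = parse_case_yaml(yaml.safe_load(case_path.read_text()))

    genotypes = directory / GENOTYPES_FILENAME
    ped = parse_ped(
        directory / PED_FILENAME,
        genotypes if genotypes.exists() else None,
        proband_id=parsed["proband"],
        obligate_carriers=parsed["obligate_carriers"],
    )

    literature = []
    for i, fam in enumerate(parsed["literature_families"]):
        _check_keys(fam, _LITFAM_KEYS, f"literature_families[{i}]")
        lit_ped = directory / fam["ped"]
        lit_gt = directory / fam["genotypes"] if fam.get("genotypes") else None
        literature.append(parse_ped(lit_ped, lit_gt))

    return CaseBundle(
        pedigree=ped,
        alleles=parsed["alleles"],
        dyads=parsed["dyads"],
        config=parsed["config"],
        literature_families=literature,
    )


def write_bundle_files(
    directory: str | Path,
    ped_text: str,
    genotypes_text: str,
    case_data: Mapping[str, Any],
) -> list[Path]:
    """Write the three bundle files; returns the created paths."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = [
            directory / PED_FILENAME,
            directory / GENOTYPES_FILENAME,
            directory / CASE_FILENAME,
        ]
        paths[0].write_text(ped_text)
        paths[1].write_text(genotypes_text)
        paths[2].write_text(yaml.safe_dump(dict(case_data), sort_keys=False))
    except OSError as exc:
        raise OSError(f"cannot write case bundle under {directory}: {exc}") from exc
    return paths


def evaluate_bundle(directory: str | Path) -> EvidenceResult:
    return load_bundle(directory).evaluate()


# ---------------------------------------------------------------------------
# rendering


def result_to_dict(result: EvidenceResult) -> dict[str, Any]:
    """Canonical, JSON-serializable report (deterministic: sorted variants,
    no timestamps)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "requires_formal_linkage": result.requires_formal_linkage,
        "excluded_loci": list(result.excluded_loci),
        "nonsegregations": {
            gene: [
                {
                    "individual_id": e.individual_id,
                    "variant_ids": list(e.variant_ids),
                    "reason": e.reason,
                }
                for e in events
            ]
            for gene, events in sorted(result.nonsegregations.items())
        },
        "variants": {
            vid: {
                "gene": ev.gene,
                "pp4_points": ev.pp4_points,
                "pp1_points": ev.pp1_points,
                "bs4_points": ev.bs4_points,
                "combined_locus_points": round(ev.combined_locus_points, 4),
                "reported_locus_points": ev.reported_locus_points,
                "other_points": ev.other_points,
                "total_points": ev.total_points,
                "strength": ev.strength,
                "classification": ev.classification,
                "pre_exclusion": ev.pre_exclusion,
            }
            for vid, ev in sorted(result.variants.items())
        },
        "audit": [asdict(entry) for entry in result.audit_log],
    }


def result_to_json(result: EvidenceResult) -> str:
    return json.dumps(result_to_dict(result), indent=2, sort_keys=True) + "\n"


def render_audit(result: EvidenceResult) -> str:
    lines = ["audit trail (ordered rule firings)", "=" * 36]
    for i, entry in enumerate(result.audit_log, 1):
        lines.append(f"{i:2d}. [{entry.rule}] {entry.detail}")
    lines.append("")
    lines.append("per-variant evidence")
    lines.append("=" * 36)
    for vid, ev in sorted(result.variants.items()):
        lines.append(
            f"{vid} ({ev.gene}): PP4 {ev.pp4_points:+.1f}, PP1 {ev.pp1_points:+.1f}, "
            f"BS4 {ev.bs4_points:+.1f}, locus (capped) {ev.combined_locus_points:.1f} "
            f"-> reported {ev.reported_locus_points:.1f}, other {ev.other_points:+.1f}, "
            f"total {ev.total_points:+.1f} => {ev.classification}"
        )
        lines.append(f"    combined-code strength: {ev.strength}")
    return "\n".join(lines) + "\n"


#: co-segregation points per counted individual, by scenario row.
TABLE3_ROWS: tuple[tuple[str, float], ...] = (
    ("Autosomal-recessive affected", 2.0),
    ("Autosomal-recessive unaffected", 0.4),
    ("Autosomal-dominant affected and unaffected", 1.0),
    ("X-linked-recessive male affected and unaffected", 1.0),
)


def render_table(which: int, cfg: BayesConfig = BayesConfig()) -> str:
    """Render one of the three reference tables as plain text: 2 = diagnostic
    yield to points, 3 = co-segregation points, 4 = combined-code strengths."""
    if which == 2:
        lines = ["Diagnostic yield -> Bayesian points", "-" * 35]
        for pct, points in generate_table2(cfg):
            p = f"{points:g}"
            lines.append(f"{pct:5.1f}%   {p:>4}")
        return "\n".join(lines) + "\n"
    if which == 3:
        lines = ["Points per co-segregating individual (1..5 individuals)", "-" * 55]
        for name, per in TABLE3_ROWS:
            row = "  ".join(f"{per * n:4.1f}" for n in range(1, 6))
            lines.append(f"{name:<48} {row}")
        lines.append("Only count unaffected individuals if the disease is fully penetrant.")
        lines.append("Do not count unaffected parents; they establish phase.")
        return "\n".join(lines) + "\n"
    if which == 4:
        lines = ["Combined PP1/PP4 points -> maximum allowable combined code strength", "-" * 67]
        for lo, hi, code in STRENGTH_BANDS:
            band = f">={lo:g}" if hi == float("inf") else f"{lo:g}-{hi - 0.1:g}"
            lines.append(f"{band:>7}   {code}")
        return "\n".join(lines) + "\n"
    raise ValueError("table must be 2, 3 or 4")
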