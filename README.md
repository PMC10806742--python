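# cosegscore

Points-based scoring of co-segregation (PP1/BS4) and phenotype-specificity
(PP4) evidence for Mendelian sequence-variant classification.

Clinical laboratories classifying variants under the ACMG/AMP framework must
weigh how a variant travels with disease through a family (PP1 when it
co-segregates, BS4 when it does not) and how specifically the proband's
phenotype points to a single gene (PP4). `cosegscore` implements a practical
heuristic that turns these observations into Bayesian evidence points, for
variant analysts and rare-disease researchers working on genes with
definitive or strong gene–disease validity.

## The model

Evidence is expressed on the Tavtigian points scale: a piece of evidence
worth *p* points carries conditional odds of pathogenicity

```
Odds_path(p) = 81^(p/6)
```

(+1 supporting, +2 moderate, +4 strong, +8 very strong), combined with a
prior probability of pathogenicity of 0.102 in a naive Bayesian classifier:

```
posterior(p) = prior_odds · 81^(p/6) / (1 + prior_odds · 81^(p/6)),
prior_odds = 0.102 / 0.898
```

On top of this arithmetic the engine applies the heuristic's rules:

- **PP4 from diagnostic yield.** A gene's diagnostic yield is a hypothetical
  posterior; it converts to points on a 0.5-point grid, rounding down, with
  a 20% floor (minimum +1.0 points). A phenotype attributable to a single
  gene with yield > 90% is a locus-homogeneity scenario: PP4 alone applies
  and co-segregation is suppressed (it is already implied by the phenotype).
- **PP1 from counted co-segregations.** Per co-segregating individual:
  +2.0 (recessive affected), +0.4 (recessive unaffected), +1.0 (dominant,
  or X-linked male / obligate-carrier female). Phase-setting meioses are
  consumed, never counted; unaffected individuals count only under full
  penetrance; unaffected parents never count.
- **BS4 = −4.0** per variant with observed non-segregation, except recessive
  compound heterozygotes (a single family cannot tell which allele is benign).
- **Locus exclusion.** Non-segregation at one locus excludes it and
  renormalizes the surviving yields (`yield/(1−excluded)`, ceiling 99%):
  benign evidence at one locus is pathogenic evidence for the others.
- **The +5.0 cap.** Locus-level evidence (PP1+PP4) is capped at +5.0 points
  per variant (odds 38.9:1) because the typed variant may be in linkage
  disequilibrium with an undetected causal variant; +6.0 points (81:1)
  reaches likely pathogenic and +10.0 (1,516:1) pathogenic.
- **Allele division and redistribution.** Several variants in cis share the
  allele's *posterior* (divided equally, then reconverted to points — never
  the points arithmetically); independent evidence separating the candidates
  by ≥ 6 points reassigns the whole allele evidence to the favored variant.

## Worked example

Two children with Cockayne syndrome are homozygous for an ERCC6 variant that
is heterozygous in both parents; ERCC6 accounts for 70% of cases and ERCC8
for 30%:

```python
from cosegscore.fixtures import build_example

result = build_example("fig3a").bundle.evaluate()
ev = result.variant("ERCC6:p.Trp588Cys")
print(ev.pp4_points, ev.pp1_points, ev.combined_locus_points, ev.classification)
```

prints

```
4.0 2.0 5.0 Uncertain significance
```

— +4.0 PP4 points from the 70% yield, +2.0 PP1 points for the co-segregating
homozygous sibling, and a capped total of +5.0: strong locus evidence, but a
variant still needs variant-level evidence (functional, computational, …) to
leave the uncertain band. `examples/` contains narrative scripts for yield
conversion, locus exclusion, and X-linked/inferred-genotype counting.

Case bundles can also be scored from the shell:

```
cosegscore evaluate <dir>     # dir holds family.ped, genotypes.tsv, case.yaml
cosegscore table 2            # regenerate the yield->points table
cosegscore classify 7         # classify a point total
```

writing `report.json` (deterministic, schema-versioned) and a plain-text
audit of every rule fired.

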