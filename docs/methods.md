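# Methods

## Model

`cosegscore` scores three interlocking evidence types for Mendelian variant
classification — phenotype specificity (PP4), co-segregation (PP1) and
non-segregation (BS4) — on the points adaptation of the Bayesian ACMG/AMP
framework. The basis is a naive Bayesian classifier with prior probability
of pathogenicity 0.102 and conditional odds `81^(points/6)`, so that +1
point is supporting evidence (odds ≈ 2.08:1), +2 moderate, +4 strong, +8
very strong; +6 points (81:1) reaches the likely pathogenic posterior (90%)
and +10 (≈1,516:1) the pathogenic posterior (99%). The exponent is exactly
`points/6`: the commonly quoted per-point factor 0.166 is display rounding,
and only the exact sixth reproduces the published conversion table (e.g.
81^(3/6) = 9 → 50.6%). An alternative basis (supporting odds 2.0:1, prior
0.125, i.e. odds `2^points`) is accepted as a `BayesConfig` override.

Model assumptions, inherited from the heuristic being implemented: single-
gene Mendelian disorders of high penetrance and negligible phenocopy rate in
genes of definitive/strong gene–disease validity; fully informative,
recombination-free meioses; diagnostic yields measured with a testing
methodology comparable to the case's. Cases with a material phenocopy rate
or with conflicting co-segregation at one locus are refused
(`requires_formal_linkage`): they need formal likelihood-ratio segregation
analysis with liability classes, which is explicitly out of scope.

## Yield-to-points conversion

Diagnostic yield is treated as a hypothetical posterior and mapped to the
largest grid value (0.5-point steps, 0.5–12.0) whose posterior does not
exceed it — the round-down rule, so evidence strength is never overstated.
The comparison is performed at the table's printed precision (posteriors
rounded to 0.1 percentage point on both sides): users quote yields at that
precision, and a raw floating-point comparison would misplace boundary
values (a 95.0% yield would fall below the 95.003% row and convert to +6.5
instead of the intended +7.0) and would break the exact grid round-trip
`yield_to_points(posterior_from_points(p)) = p`. PP4 additionally has a 20%
yield floor (minimum award +1.0 points), guarding against high-order locus
heterogeneity where per-gene yields are unstable across populations; the
floor and the grid are config-exposed, and posterior shares from allele
division are converted with the floor disabled.

## Decision flow

1. **Applicability.** `phenocopy_negligible=False` on the inheritance mode,
   or a locus showing both supporting co-segregations and non-segregations,
   flags the case for formal linkage analysis and emits no PP1/PP4. The
   conflict probe counts co-segregations against the full causal genotype at
   the locus, so a dominant phase-setting observation (one variant supported,
   its in-trans partner contradicted) is not mistaken for a conflict.
2. **Non-segregation and exclusion.** Under full penetrance, an unaffected
   relative carrying the complete causal genotype is a non-segregation;
   under negligible phenocopies, an affected relative demonstrably lacking
   it is one. BS4 (−4.0) attaches per variant, except in recessive
   compound-het cases. A recessive locus with any event — or a dominant /
   X-linked locus all of whose candidate variants have events — is excluded;
   surviving yields renormalize as `yield/(1−Σ excluded)`, truncated at a
   practical ceiling of 99% (+9.0 points), with the unexplained fraction of
   the phenotype acting as a phantom locus that is never excluded. A
   per-gene `post_exclusion_yield` override lets users assert an externally
   sourced post-exclusion yield; the audit logs any divergence from the
   arithmetic value. (In the two-locus dominant worked example the
   arithmetic renormalization 0.26/0.31 ≈ 0.84 → +5.0 differs from the
   asserted 95% → +7.0; both produce the same +5.0 after capping.)
3. **Architecture.** Locus homogeneity (a single configured gene) with
   yield > 90% suppresses PP1: the phenotype already implicates the locus
   nearly perfectly, so segregation cannot add evidence. The check uses the
   *configured* architecture — exclusion converts a heterogeneous case into
   effective homogeneity but does not retroactively silence the counted
   co-segregations.
4. **Phase.** Dominant inheritance phases the whole candidate set at once:
   the first affected non-proband relative carrying exactly one candidate
   consumes one meiosis and selects that variant (other candidates in the
   same gene lose locus evidence entirely; candidates in other genes keep
   PP4 but accrue no PP1). Recessive homozygous probands and affected
   hemizygous males phase with zero meioses; a recessive compound-het
   proband is itself the phase-setting individual. With no phase-capable
   individual, the locus posterior is divided equally over all candidate
   variants.
5. **Counting.** Performed per family (the tested family plus any literature
   families, each re-phased independently, points summed), excluding the
   proband, phase-consumed individuals, unknown-affection individuals, and
   — under autosomal inheritance — unaffected parents of affected
   individuals. Unaffected non-carriers additionally require a parent in the
   pedigree who could have transmitted the variant (married-in founders are
   uninformative). Reduced penetrance (`fully_penetrant=False`) switches to
   affected-only counting.
6. **Capping, division, redistribution.** Combined PP4+PP1 is capped at
   +5.0 points per variant (odds 38.9:1), guarding against linkage
   disequilibrium with an undetected causal variant; the cap can be lifted
   (`cap_lifted`) for coding-only mechanisms with complete coding coverage.
   An allele with several variants in cis divides its *posterior* equally —
   dividing points would be wrong, since points are log-odds (a ~96%
   posterior halves to 48%, i.e. +2.5 points per variant, not +3.5). The
   posterior divided is the diagnostic yield updated by the co-segregation
   odds (`odds = yield/(1−yield) · 81^(pp1/6)`), reducing to the raw yield
   when no co-segregations were counted. When independent evidence separates
   the in-cis candidates by at least 6 points — the span between the likely
   benign and likely pathogenic thresholds, odds 81:1 — the favored variant
   takes the full allele evidence (capped) and the others none; equality
   with the threshold suffices, and a tie among several favored variants
   falls back to division among them. (One published discussion of this rule
   quotes 81^(8/6) as "530:1"; direct evaluation gives ≈350:1. The engine
   never uses that number — the ≥6-point rule, whose 81:1 anchor verifies,
   governs.)

## Genotype inference

Untyped relatives can be counted from logic rather than assay, controlled by
`count_inferred_genotypes` (default on):

- autosomal: an untyped individual with a typed-carrier child whose other
  parent is typed negative;
- X-linked: an untyped female whose carrier status is affirmed by an
  affected brother *and* an affected (or typed hemizygous) son. The stricter
  brother-and-son conjunction is deliberate: a carrier-son-alone rule would
  also infer the founder grandmother in a three-generation family and
  over-count by one relative.

Individuals may also be asserted as obligate carriers in the input
(`obligate_carriers` in `case.yaml`), which counts regardless of the flag.

## Rounding and reporting

Internal arithmetic is full precision; co-segregation increments come in
0.1-point resolution (the +0.4 recessive-unaffected row). The capped
combined locus evidence is retained internally (e.g. +4.4) but floored to
the half-point grid for reporting, strength labels, and the classification
total — reconciling "+0.4 rounds down to 0.0" with intermediate sums like
+4.4 that matter when exclusion later reassesses PP4. Classification bands:
≥ +10 pathogenic, +6 to +9.9 likely pathogenic, above −1 uncertain, −1 to
−6.9 likely benign, ≤ −7 benign; the negative bands follow the points
framework the engine builds on, since point sums such as −6.0 → likely
benign presuppose them. Odds are reported to one decimal and posteriors to
0.1 percentage point.

## Published-table ambiguities

The co-segregation points table's footnotes are ambiguous in two places; the
interpretation adopted (both config-selectable):

- "+0.4 per meiosis above five" extends the recessive-unaffected row, making
  every row linear in the count; the alternative reading (recessive-affected
  co-segregations beyond the fifth worth +0.4 instead of +2.0) is available
  as `ar_affected_increment_above_five=0.4` and is moot under the +5.0 cap.
- The obligate-female note attaches to the X-linked row, consistent with the
  X-linked worked family.

## Worked-example fixtures

The eleven fixture families (`cosegscore.fixtures`) encode the published
worked scenarios with their expected per-variant points and classifications;
they are the regression surface. Pedigree details the scenarios leave open —
founder genotypes, sibling order, which affected individual is the proband
in multi-affected families — are fixed deterministically and documented per
builder (e.g. the X-linked family's proband is the youngest affected
brother, so the four countable co-segregations are the uncle, the
obligate-carrier mother and the two typed affected brothers; the dilated-
cardiomyopathy gene yield is set to 13%, a realistic value under the 20%
floor the scenario requires). One scenario names a variant inconsistently
between its table and caption; the fixtures follow the variant table. These
fixtures are constructed families, not real patient data: passing them shows
the rules fire exactly as specified on clean, fully ascertained pedigrees;
it does not probe genotyping error, incomplete ascertainment, consanguinity,
or age-dependent penetrance, all of which are out of scope for the
heuristic itself.

## Limitations

No formal linkage or multipoint analysis, no liability classes, no
penetrance estimation, no recombination modelling, no PS4/PM3 case counting
(only the bookkeeping rule that a family is used once across PP4/PS4), no
automatic yield derivation (yields are user-supplied), and no sharing of
segregation evidence across tightly linked gene pairs beyond an audit
warning when two dyads carry the same `linked_group` tag. Variant identity
is symbolic (no VCF ingestion).
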