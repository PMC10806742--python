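"""Benign evidence at one locus is pathogenic evidence for another.

Tuberous sclerosis panel testing finds one variant in each of TSC1 (26% of
cases) and TSC2 (69%).  The TSC2 variant fails to segregate in two affected
siblings: TSC2 is excluded, its variant takes BS4 (-4.0), and the TSC1
post-exclusion yield (asserted at 95%) raises that variant's PP4 from +1.5
to +7.0 -- capped, with the +2.0 of co-segregation, at +5.0.
"""

from cosegscore.fixtures import build_example

result = build_example("fig4b").bundle.evaluate()

print("excluded loci:", result.excluded_loci)
for vid, ev in sorted(result.variants.items()):
    line = (
        f"{vid}: PP4 {ev.pp4_points:+.1f}, PP1 {ev.pp1_points:+.1f}, "
        f"BS4 {ev.bs4_points:+.1f}, capped locus {ev.combined_locus_points:+.1f} "
        f"=> {ev.classification}"
    )
    if ev.pre_exclusion:
        line += (
            f"  (pre-exclusion: PP4 {ev.pre_exclusion['pp4_points']:+.1f}, "
            f"combined {ev.pre_exclusion['combined_locus_points']:+.1f})"
        )
    print(line)
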