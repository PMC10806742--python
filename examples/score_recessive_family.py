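"""Score a recessive two-affected-children family end to end.

The family: both children homozygous for an ERCC6 variant that is
heterozygous in both parents, phenotype consistent with Cockayne syndrome
(70% of cases attributable to ERCC6, 30% to ERCC8).  PP4 contributes +4.0
points (70% yield), the co-segregating affected sibling +2.0, and the +6.0
total is capped at +5.0 because locus-level evidence alone cannot exclude
linkage disequilibrium with an undetected causal variant.
"""

from cosegscore.fixtures import build_example
from cosegscore.io import render_audit

example = build_example("fig3a")
result = example.bundle.evaluate()

print(render_audit(result))
ev = result.variant("ERCC6:p.Trp588Cys")
print(
    f"PP4 {ev.pp4_points:+.1f} + PP1 {ev.pp1_points:+.1f} "
    f"-> capped locus evidence {ev.combined_locus_points:+.1f} points "
    f"({ev.classification}); on code-based platforms: {ev.strength}"
)
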