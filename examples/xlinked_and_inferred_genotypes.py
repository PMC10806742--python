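"""Counting co-segregations when genotypes must be inferred.

Two scenarios:

* An X-linked recessive three-generation family (TARP syndrome/RBM10): the
  diagnostic yield is unknown so PP4 is not awarded, but four relatives
  co-segregate -- three hemizygous affected males and an obligate-carrier
  female whose status is affirmed by an affected brother and affected sons.

* A reduced-penetrance dominant family (dilated cardiomyopathy/MYH7) where
  one counted relative is an asserted obligate carrier and another's carrier
  genotype is inferred from a typed-carrier child and a typed-negative
  spouse; disabling inference drops the count from 3 to 2.
"""

from dataclasses import replace

from cosegscore.fixtures import build_example

xl = build_example("fig6").bundle.evaluate()
ev = xl.variant("RBM10:p.Cys219Phe")
print(f"X-linked family: PP4 {ev.pp4_points:+.1f} (yield unknown), "
      f"PP1 {ev.pp1_points:+.1f} from four co-segregations => {ev.classification}")

dcm = build_example("fig5b")
with_inference = dcm.bundle.evaluate().variant("MYH7:p.Arg1500Trp").pp1_points
bundle = dcm.bundle
bundle.config = replace(bundle.config, count_inferred_genotypes=False)
without_inference = bundle.evaluate().variant("MYH7:p.Arg1500Trp").pp1_points
print(f"dominant family: PP1 {with_inference:+.1f} with genotype inference, "
      f"{without_inference:+.1f} without")
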