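"""Convert diagnostic yields to Bayesian evidence points.

A gene's diagnostic yield -- the fraction of phenotype-matched probands in
whom a causative variant is found in that gene -- acts as a hypothetical
posterior probability of pathogenicity, and converts to evidence points on
a half-point grid, always rounding down.
"""

from cosegscore import generate_table2, posterior_from_points, yield_to_points

print("full conversion table (yield percent -> points):")
for pct, points in generate_table2():
    print(f"  {pct:5.1f}%  ->  {points:+.1f}")

print()
for y, label in [
    (0.958, "cystinosis/CTNS"),
    (0.70, "Cockayne/ERCC6"),
    (0.26, "tuberous sclerosis/TSC1"),
    (0.13, "dilated cardiomyopathy/MYH7"),
]:
    pts = yield_to_points(y)
    note = "below the 20% floor, PP4 not applicable" if pts == 0 else f"PP4 {pts:+.1f} points"
    print(f"yield {y:.1%} ({label}): {note}")

# points are log-odds: +6 points is odds 81:1, i.e. posterior 90.2% from the
# 0.102 prior
print(f"\nposterior after +6.0 points: {posterior_from_points(6.0):.1%}")
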