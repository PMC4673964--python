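"""Concentration curve and index for a small grouped population.

Ten people, two per SES class, with access scores that improve with
class — a pro-rich pattern the index should flag as positive.
"""

from pharmequity import SESClass, build_grouped_distribution, concentration_curve, index_area_oracle

access_by_class = {
    SESClass.EXTREMELY_POOR: (1, 10),    # black market / nothing
    SESClass.POOR: (30, 50),
    SESClass.MODERATE: (60, 70),
    SESClass.GOOD: (80, 90),
    SESClass.WEALTHY: (100, 100),        # everything in any pharmacy
}
pairs = [(cls, a) for cls, scores in access_by_class.items() for a in scores]

dist = build_grouped_distribution(pairs, grouping="five_classes")
result = concentration_curve(dist)

print("group            P      L")
for (p, l), group in zip(result.curve_points[1:], dist.groups):
    print(f"{group:<14} {p:5.2f}  {l:5.3f}")
print(f"\nconcentration index C = {result.index:+.4f}")
print(f"area-identity cross-check: {index_area_oracle(dist):+.4f}")
print()
print("Each curve point is (cumulative population share, cumulative access")
print("share), poorest classes first. L < P everywhere and C > 0: access is")
print("concentrated among the wealthier classes (pro-rich inequity).")
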