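"""Islet irregularity index from insulin/glucagon masks.

A healthy rodent islet keeps alpha-cells (glucagon) in a thin mantle
around the beta-cell (insulin) core, so glucagon pixels sit near the
convex hull of the insulin region and the trimmed mean of their signed
distances to the rim is near zero.  When alpha-cells infiltrate the core
the index grows toward R/3 (the mean depth of a uniformly mixed disk).
"""

import dualeigen as de

print("infiltration -> irregularity index (radius 80 px)")
indices = {}
for level in (0.0, 0.25, 0.5, 0.75, 1.0):
    ins, glu = de.simulate_islet_masks(
        radius_px=80, infiltration=level, n_glucagon=1500, seed=5
    )
    m = de.analyze_islet(ins, glu)
    indices[level] = m.index
    print(f"  {level:4.2f} -> {m.index:6.2f} px   "
          f"(hull area {m.hull_area:.0f} px^2, {m.n_glucagon} glucagon px)")

# paired cohort comparison: five healthy vs five progressively infiltrated
healthy, diseased = [], []
for i, lv in enumerate((0.2, 0.4, 0.6, 0.8, 1.0)):
    im, gm = de.simulate_islet_masks(80, 0.0, 1200, seed=100 + i)
    healthy.append(de.analyze_islet(im, gm).index)
    im, gm = de.simulate_islet_masks(80, lv, 1200, seed=200 + i)
    diseased.append(de.analyze_islet(im, gm).index)
p = de.paired_signed_rank(diseased, healthy, sided="greater")
print(f"\npaired one-sided signed-rank p (diseased > healthy): {p:.3f}")
# five concordant pairs give the exact minimum p = 1/2^5 = 0.03125
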