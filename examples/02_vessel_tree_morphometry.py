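"""Grow a vessel tree with a planted junction exponent and measure it back.

The generator solves the bifurcation diameter law D_p^X = D_a^X + D_b^X
exactly at every branch point. Feeding the true diameters to the
junction-exponent solver must return the planted X; the cube-ratio R_B
equals 1 only when X = 3 (Murray's minimum-work law).
"""

import ringpact as rp

tree = rp.generate_vessel_tree(
    seed=7, n_levels=3, root_diameter=1.8, junction_exponent=2.63,
    asymmetry=0.8,
)
print(f"tree: {len(tree.segments)} segments, "
      f"{len(tree.bifurcations)} bifurcations, planted X = 2.63\n")
print("  D_parent  D_a     D_b     X_B     R_B")
for dp, da, db in tree.bifurcation_diameters()[:5]:
    b = rp.junction_metrics(dp, da, db)
    print(f"  {dp:.3f}    {da:.3f}   {db:.3f}   {b.x_b:.3f}   {b.r_b:.3f}")
print("\nX_B equals the planted exponent at every branch; R_B > 1 because"
      "\nthe planted X < 3 (daughter cubes fall short of the parent cube).")
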