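"""Phylogenetic ANCOVA: published arithmetic and a synthetic clade test.

First reproduces the F column of the published ANCOVA table from its
residual sums of squares (n = 2,176 species; full model with clade-specific
intercept and slope has 4 parameters, the shared reduced model 2).  Then
runs the same test end-to-end on synthetic data with a genuine shift.
"""
import oushift as ou

print("published residual sums of squares -> F statistics")
reduced = 4017.494
for name, rss_full in [("Southeast Asian ranids", 4003.601),
                       ("Ranid frogs", 3967.213),
                       ("Fitzinger tree frogs", 3995.990),
                       ("Poison frogs", 3993.421)]:
    r = ou.f_ratio(rss_full, 4, reduced, 2, 2176)
    print(f"  {name:26s} F = {r.f:7.3f}  Pr(>F) = {r.p_value:.3f}  "
          f"MSS_full = {r.mss_full:.3f}")

print()
print("synthetic check: clade with a displaced intercept should reject")
tree, table, config, params, delta = ou.simulate.planted_shift_dataset(
    n_tips=80, target_tips=20, seed=5)
clade = [tree.tip_labels[i]
         for i in tree.subtree_tips(config.shifts[0].branch)]
r = ou.pancova(tree, table, clade)
print(f"  planted clade ({len(clade)} species): F = {r.f:.2f}, "
      f"p = {r.p_value:.2g}  (small p corroborates the shift)")
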