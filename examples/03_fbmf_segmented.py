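"""Segmented regression of the foliage+branch mass fraction on biomass.

Small shrubs put ~half their mass into foliage and branches; as total
biomass grows the fraction declines and bends onto a plateau near 0.3.
The hinge fit locates that bend and Davies' test asks whether a slope
change exists at all.
"""

from shrubvol import GeneratorConfig, fit_segmented, generate_trees

trees = generate_trees(GeneratorConfig(seed=42, n_trees=300))
fbmf = (trees.fb_dry / trees.total_dry).to_numpy()

fit = fit_segmented(trees.total_dry.to_numpy(), fbmf)
print("breakpoint at %.1f kg total biomass" % fit.psi)
print("FBMF level at the breakpoint: %.3f" % fit.y_at_breakpoint)
print("slopes: %.4f (left) -> %.5f (right) per kg" % (fit.slope_left, fit.slope_right))
print("Davies p-value for a slope change: %.2g" % fit.davies_p)
# The level at the breakpoint (~0.3) is the foliage+branch share a harvest
# of large individuals should expect; the near-zero right slope says the
# share barely moves beyond the break.
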