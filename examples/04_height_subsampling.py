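"""How many height measurements per 100 m^2 are enough to predict biomass?

Runs the Monte-Carlo subsampling experiment on a synthetic 11-plot
campaign: for each sample size n, heights are drawn from every plot's
canopy height model, per-plot means are correlated with harvested biomass,
and the mean Pearson r over repetitions traces a rising, saturating curve.
The hinge breakpoint of that curve is the practical minimum sampling
effort. (Uses 500 repetitions; the CLI default is 10,000.)
"""

from shrubvol import GeneratorConfig, generate_stands, min_observations, r_curve

stands, grids = generate_stands(GeneratorConfig(seed=42))
clouds = {pid: g.heights() for pid, g in grids.items()}

curve = r_curve(clouds, stands.total_dry.to_numpy(), n_max=400, reps=500, seed=1)
for n in (1, 5, 10, 20, 50, 100, 400):
    print("n=%3d per plot  (%4.0f /100m2):  mean r = %.3f" % (n, n * 4, curve.mean_r[n - 1]))
print("full-cloud r (upper bound): %.3f" % curve.full_cloud_r)

result = min_observations(curve)
print("minimum observations per 100 m^2: %s" % result.n_per_100m2)
# Beyond the breakpoint, extra height measurements no longer improve the
# biomass correlation -- a crew can stop measuring there.
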