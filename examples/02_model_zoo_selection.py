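"""Fit the allometric model zoo and select best / most parsimonious models.

Enumerates all 42 candidate equations for total single-tree biomass
(3 families x predictor subsets of {V, A, H, D}), ranks them by BIC and
prints the two selections. Lower BIC is better; the parsimonious model is
the cheapest-to-measure equation still within 10 BIC of the global best.
"""

from shrubvol import (
    GeneratorConfig,
    enumerate_models,
    fit_model,
    format_equation,
    generate_trees,
    select_models,
)
from shrubvol.errors import DomainError

trees = generate_trees(GeneratorConfig(seed=42, n_trees=300))

fits = []
for spec in enumerate_models("trees", "total"):
    try:
        fit = fit_model(spec, trees)
    except DomainError:
        continue
    if fit.converged:
        fits.append(fit)

best, parsimonious = select_models(fits, delta_bic=10.0)
print("candidates fitted:", len(fits))
print("best          :", format_equation(best), " RMSE %.2f kg, BIC %.1f" % (best.rmse, best.bic))
print("parsimonious  :", format_equation(parsimonious),
      " RMSE %.2f kg, BIC %.1f" % (parsimonious.rmse, parsimonious.bic))
# A manager can use the parsimonious equation with fewer field measurements
# at a small accuracy cost relative to the best model.
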