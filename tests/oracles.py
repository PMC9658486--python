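"""Independent brute-force oracles, deliberately naive.

These re-implement the ranking/fitting primitives with nothing but
``math``/``numpy.linalg.lstsq`` so the package's optimised paths can be
checked against exhaustive computation.
"""

import math

import numpy as np


def bic_naive(n: int, rss: float, k: int) -> float:
    """Gaussian BIC computed from first principles."""
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + k * math.log(n)


def rank_fits_naive(fits):
    """Exhaustive re-ranking of fitted models by independently computed BIC."""
    scored = []
    for f in fits:
        k = f.spec.n_mean_params + 1
        scored.append((bic_naive(f.n, f.rss, k), f.spec.n_mean_params, f.spec.family, f))
    family_order = {"linear": 0, "ln_linear": 1, "power_sum": 2}
    scored.sort(key=lambda t: (t[0], t[1], family_order[t[2]]))
    return [t[3] for t in scored]


def power_fit_gridsearch(x, y, c_grid=None):
    """Single-predictor shifted power fit y = a + b*x**c by exhaustive search.

    For each candidate exponent c the conditionally linear (a, b) are solved
    by least squares; returns (a, b, c, rss) at the best grid point.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if c_grid is None:
        c_grid = np.arange(0.1, 5.0 + 1e-9, 0.001)
    best = None
    for c in c_grid:
        design = np.column_stack([np.ones_like(x), x**c])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((y - design @ coef) ** 2).sum())
        if best is None or rss < best[3]:
            best = (float(coef[0]), float(coef[1]), float(c), rss)
    return best


def hinge_fit_dense(x, y, n_grid=10_000, lo=None, hi=None):
    """Segmented (hinge) fit by a dense breakpoint grid; returns (psi, rss)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if lo is None:
        lo, hi = np.quantile(x, [0.05, 0.95])
    grid = np.linspace(lo, hi, n_grid)
    best = None
    for psi in grid:
        design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0, None)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((y - design @ coef) ** 2).sum())
        if best is None or rss < best[1]:
            best = (float(psi), rss)
    return best
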