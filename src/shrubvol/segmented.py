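"""Segmented (breakpoint) regression with a Davies-type slope-change test.

The model is the continuous two-segment ("hinge") line

    y = b0 + b1 * x + b2 * (x - psi)_+ ,

linear in (b0, b1, b2) once the breakpoint ``psi`` is fixed. ``psi`` is
estimated by profiling the residual sum of squares: a grid search over
interior x-quantiles followed by golden-section refinement around the grid
minimum. Because the breakpoint vanishes from the model under the null of
no slope change, its significance is assessed with Davies' bound over the
maximum Wald statistic at a set of candidate breakpoints.

Used twice in the pipeline: for the decline-then-plateau of the
foliage+branch mass fraction against total biomass, and for the
number-of-height-observations curve of the Monte-Carlo subsampling stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["SegmentedFit", "fit_segmented", "davies_test", "fitted_curve_csv"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SegmentedFit:
    """A fitted hinge regression.

    ``slope_left``/``slope_right`` are the slopes before and after ``psi``
    (so ``slope_right - slope_left`` is the slope change b2); the fitted
    curve is continuous at the breakpoint. ``davies_p`` tests the existence
    of any slope change; ``wald_p`` is the secondary Wald test of b2 at the
    fitted breakpoint (anti-conservative, since psi was estimated).
    ``degenerate`` flags fits whose breakpoint ran into the search boundary,
    i.e. no interior hinge is supported by the data.
    """

    psi: float
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    davies_p: float
    wald_p: float
    n: int
    degenerate: bool

    @property
    def slope_change(self) -> float:
        return self.slope_right - self.slope_left

    def value_at(self, x) -> np.ndarray:
        """Fitted values of the hinge curve."""
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slope_left * x + self.slope_change * np.clip(x - self.psi, 0, None)
        return out.item() if out.ndim == 0 else out

    @property
    def y_at_breakpoint(self) -> float:
        """Fitted response at the breakpoint (the level where the hinge bends)."""
        return float(self.value_at(self.psi))


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float):
    design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    rss = float(((y - fitted) ** 2).sum())
    return rss, coef, design


def _check_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 6:
        raise DomainError("need at least 6 observations")
    if np.unique(x).size < 4:
        raise DomainError("need at least 4 distinct x values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values in x or y")
    return x, y


def fit_segmented(
    x,
    y,
    n_grid: int = 200,
    quantile_range: tuple[float, float] = (0.05, 0.95),
    davies_m: int = 10,
) -> SegmentedFit:
    """Fit the hinge model by profiled RSS over the breakpoint.

    The breakpoint is searched on ``n_grid`` points between the interior
    x-quantiles given by ``quantile_range`` and refined by golden section
    between the neighbours of the grid minimum. A fit whose refined
    breakpoint sits at the search boundary is flagged degenerate.
    """
    x, y = _check_xy(x, y)
    lo, hi = np.quantile(x, quantile_range)
    if not lo < hi:
        raise DomainError("degenerate x distribution: empty interior quantile range")
    grid = np.linspace(lo, hi, n_grid)
    rss_grid = np.array([_hinge_rss(x, y, p)[0] for p in grid])
    i = int(np.argmin(rss_grid))

    # golden-section refinement between the grid neighbours of the minimum
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = _hinge_rss(x, y, c)[0], _hinge_rss(x, y, d)[0]
    for _ in range(60):
        if b - a < 1e-9 * max(1.0, hi - lo):
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = _hinge_rss(x, y, c)[0]
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = _hinge_rss(x, y, d)[0]
    psi = float((a + b) / 2)
    rss, coef, design = _hinge_rss(x, y, psi)

    boundary_tol = (hi - lo) / (n_grid - 1)
    degenerate = psi <= lo + boundary_tol or psi >= hi - boundary_tol
    # a hinge that does not improve on the plain line is no hinge at all
    line_design = np.column_stack([np.ones_like(x), x])
    line_coef, *_ = np.linalg.lstsq(line_design, y, rcond=None)
    line_rss = float(((y - line_design @ line_coef) ** 2).sum())
    scale = float(((y - y.mean()) ** 2).sum()) + float(np.abs(y).max()) ** 2
    if line_rss - rss <= 1e-12 * max(scale, 1e-30):
        degenerate = True

    wald_p = _wald_p_at(x, y, psi)
    davies_p = davies_test(x, y, m=davies_m)

    return SegmentedFit(
        psi=psi,
        intercept=float(coef[0]),
        slope_left=float(coef[1]),
        slope_right=float(coef[1] + coef[2]),
        rss=rss,
        davies_p=davies_p,
        wald_p=wald_p,
        n=x.size,
        degenerate=degenerate,
    )


def _hinge_t_stat(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    """Wald t statistic for the slope-change coefficient at a fixed breakpoint."""
    design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = x.size - 3
    if dof <= 0:
        return 0.0
    s2 = float(resid @ resid) / dof
    scale = float(np.var(y)) + 1e-30
    if s2 <= 1e-14 * scale:  # perfect fit: either no hinge at all or an exact one
        return 0.0 if abs(coef[2]) <= 1e-10 * np.sqrt(scale) else 1e6
    try:
        cov = np.linalg.inv(design.T @ design) * s2
    except np.linalg.LinAlgError:
        return 0.0
    se = np.sqrt(max(cov[2, 2], 1e-300))
    return float(coef[2] / se)


def _wald_p_at(x, y, psi) -> float:
    t = _hinge_t_stat(x, y, psi)
    dof = max(x.size - 3, 1)
    return float(2 * stats.t.sf(abs(t), dof))


def fitted_curve_csv(fit: SegmentedFit, x, path, n_points: int = 200) -> None:
    """Plotting hook: write (x, fitted y) points of the hinge curve as CSV.

    Evaluates the fitted curve on ``n_points`` spanning the data range, with
    the breakpoint itself inserted so plots show the kink exactly.
    """
    x = np.asarray(x, dtype=float)
    grid = np.unique(np.append(np.linspace(x.min(), x.max(), n_points), fit.psi))
    values = fit.value_at(grid)
    with open(path, "w") as fh:
        fh.write("x,fitted\n")
        for xi, yi in zip(grid, values):
            fh.write(f"{xi:.10g},{yi:.10g}\n")


def davies_test(x, y, m: int = 10, quantile_range: tuple[float, float] = (0.1, 0.9)) -> float:
    """Davies' upper-bound p-value for a change in slope at an unknown breakpoint.

    Computes the Wald statistic for the hinge coefficient at ``m`` equally
    spaced candidate breakpoints inside the interior x-range and bounds the
    two-sided p-value of the maximum by

        p <= 2*(1 - Phi(M)) + V * exp(-M**2 / 2) / sqrt(8*pi),

    where M is the largest absolute statistic and V the total variation of
    the statistic sequence over the candidates. Conservative by design: the
    realised type-I error sits at or below the nominal level.
    """
    x, y = _check_xy(x, y)
    if m < 2:
        raise DomainError("need at least 2 evaluation points")
    lo, hi = np.quantile(x, quantile_range)
    if not lo < hi:
        raise DomainError("degenerate x distribution")
    psis = np.linspace(lo, hi, m)
    t_stats = np.array([_hinge_t_stat(x, y, p) for p in psis])
    big_m = float(np.abs(t_stats).max())
    total_variation = float(np.abs(np.diff(t_stats)).sum())
    dof = max(x.size - 3, 1)
    # correction term for a t-process (reduces to exp(-M^2/2) as dof -> inf)
    correction = total_variation * (1 + big_m**2 / dof) ** (-(dof - 1) / 2) / np.sqrt(8 * np.pi)
    p = 2 * stats.t.sf(big_m, dof) + correction
    return float(np.clip(p, 0.0, 1.0))
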