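"""Monte-Carlo estimation of the minimum number of height observations.

A stand's biomass can be predicted from its mean canopy height (volume =
mean height x area), but a practitioner without a high-resolution terrain
model can only afford a handful of manual height measurements. This module
reproduces the subsampling experiment that answers "how many are enough":
for each sample size n, draw n heights per plot without replacement from
the plot's height observations, correlate the resulting per-plot mean
heights with the harvested biomass across plots, and average Pearson's r
over many repetitions. The r-vs-n curve rises and plateaus; a segmented
regression of mean r on n locates the breakpoint after which extra
measurements no longer improve the correlation. Sample sizes are reported
per 100 m^2 (n * 100 / plot area).

Implementation note: for every repetition one vector of uniform random keys
is drawn per plot; the n_max smallest keys, ordered by key, form a sample
whose every prefix of size n is itself a uniform without-replacement sample.
Prefix cumulative means therefore yield the entire n = 1..n_max curve from
a single draw per repetition, with unbiased mean r at each n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError
from .segmented import SegmentedFit, fit_segmented

__all__ = ["SubsamplingCurve", "MinObsResult", "r_curve", "min_observations"]

_CHUNK_REPS = 250  # keeps the random-key matrix ~125 MB at 62,500-point clouds


@dataclass
class SubsamplingCurve:
    """Mean Pearson r between per-plot mean height and biomass, per sample size."""

    n_values: np.ndarray          # raw heights sampled per plot
    n_per_100m2: np.ndarray       # the same, scaled to a 100 m^2 reference area
    mean_r: np.ndarray
    reps: int
    seed: int
    plot_area_m2: float
    full_cloud_r: float           # r using every available height observation
    sd_r: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MinObsResult:
    """Breakpoint of the r-vs-n curve, in observations per 100 m^2."""

    n_per_100m2: int | None
    degenerate: bool
    fit: SegmentedFit


def _prefix_means(cloud: np.ndarray, n_max: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """(reps, n_max) matrix of without-replacement prefix sample means."""
    big_n = cloud.size
    out = np.empty((reps, n_max))
    done = 0
    while done < reps:
        chunk = min(_CHUNK_REPS, reps - done)
        keys = rng.random((chunk, big_n))
        idx = np.argpartition(keys, n_max - 1, axis=1)[:, :n_max]
        order = np.take_along_axis(keys, idx, axis=1).argsort(axis=1)
        idx = np.take_along_axis(idx, order, axis=1)
        values = cloud[idx]
        out[done : done + chunk] = values.cumsum(axis=1) / np.arange(1, n_max + 1)
        done += chunk
    return out


def _pearson_rows(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of each row of x with the fixed vector b."""
    xc = x - x.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    num = xc @ bc
    den = np.sqrt((xc**2).sum(axis=1) * (bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, 0.0)


def r_curve(
    clouds: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    biomass: Sequence[float],
    n_max: int = 400,
    reps: int = 10_000,
    seed: int = 0,
    plot_area_m2: float = 25.0,
) -> SubsamplingCurve:
    """Mean-r curve over sample sizes n = 1..n_max.

    ``clouds`` maps plot ids to 1-D arrays of canopy heights (or is a
    sequence of such arrays, ordered like ``biomass``). If a cloud is
    smaller than ``n_max``, sample sizes beyond the smallest cloud are
    skipped with a warning.
    """
    if isinstance(clouds, Mapping):
        arrays = [np.asarray(clouds[k], dtype=float).ravel() for k in clouds]
    else:
        arrays = [np.asarray(c, dtype=float).ravel() for c in clouds]
    arrays = [a[np.isfinite(a)] for a in arrays]
    b = np.asarray(biomass, dtype=float)
    if len(arrays) < 3:
        raise DomainError("need at least 3 plots")
    if b.size != len(arrays):
        raise DomainError("biomass vector must align with the clouds")
    if reps < 1 or n_max < 1:
        raise DomainError("reps and n_max must be positive")

    smallest = min(a.size for a in arrays)
    if smallest < n_max:
        warnings.warn(
            f"smallest cloud has {smallest} points; sample sizes above that are skipped",
            stacklevel=2,
        )
        n_max = smallest

    rng = np.random.default_rng(seed)
    # (reps, n_max, n_plots) stack of prefix means
    means = np.stack([_prefix_means(a, n_max, reps, rng) for a in arrays], axis=2)

    mean_r = np.empty(n_max)
    sd_r = np.empty(n_max)
    for j in range(n_max):
        r = _pearson_rows(means[:, j, :], b)
        mean_r[j] = r.mean()
        sd_r[j] = r.std(ddof=1) if reps > 1 else 0.0

    full_means = np.array([a.mean() for a in arrays])
    full_r = float(_pearson_rows(full_means[None, :], b)[0])

    n_values = np.arange(1, n_max + 1)
    return SubsamplingCurve(
        n_values=n_values,
        n_per_100m2=n_values * (100.0 / plot_area_m2),
        mean_r=mean_r,
        reps=reps,
        seed=seed,
        plot_area_m2=plot_area_m2,
        full_cloud_r=full_r,
        sd_r=sd_r,
    )


def min_observations(curve: SubsamplingCurve, thin: str = "geometric") -> MinObsResult:
    """Breakpoint of the mean-r curve: observations per 100 m^2 beyond which
    additional height measurements no longer improve the correlation.

    Fits the hinge regression of mean r on the per-100 m^2 sample size
    (``thin="geometric"`` fits on a geometrically spaced subset of the
    curve, ``"none"`` on every point); a degenerate fit (no interior
    breakpoint) propagates a flag instead of an integer.
    """
    if curve.mean_r.size < 10:
        raise DomainError("need at least 10 curve points")
    x, y = curve.n_per_100m2, curve.mean_r
    if thin == "geometric" and x.size > 60:
        # a saturating curve sampled on a uniform grid is all plateau by
        # count; a geometric grid weights each scale decade equally so the
        # hinge locks onto the elbow instead of the tail
        idx = np.unique(np.round(np.geomspace(1, x.size, 60)).astype(int) - 1)
        x, y = x[idx], y[idx]
    elif thin not in ("geometric", "none"):
        raise DomainError(f"unknown thinning {thin!r}")
    # the abscissa is a dense deterministic grid, so the hinge may sit
    # anywhere in it — no interior-quantile guard on the low end, where the
    # elbow of a saturating curve lives
    fit = fit_segmented(x, y, quantile_range=(0.0, 0.95))
    if fit.degenerate:
        return MinObsResult(n_per_100m2=None, degenerate=True, fit=fit)
    return MinObsResult(n_per_100m2=int(round(fit.psi)), degenerate=False, fit=fit)
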