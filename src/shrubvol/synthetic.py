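"""Synthetic harvest-campaign data with the statistical structure of the study.

The generator produces the four dataset kinds the pipeline consumes —
single-tree tables, stand-plot tables with canopy height grids, and tissue
chemistry — so every downstream stage is testable without field data.

What it emulates
----------------
* Tree dimensions (H, basal D, canopy diameters C1/C2) are correlated
  lognormals calibrated so the marginals sit inside the published min-max
  envelopes of the harvest campaign (see :mod:`shrubvol.reference`); canopy
  area and cone volume are then *computed* through :mod:`shrubvol.geometry`,
  never drawn.
* Total dry mass follows a power law in crown volume,
  ``BM = k * V**b * eps`` with ``b = scaling_exponent`` (default 0.75, the
  allometric partitioning expectation) and multiplicative lognormal noise
  ``eps`` of coefficient of variation ``noise_cv``.
* The foliage+branch mass fraction (FBMF) declines steeply (linearly) with
  total biomass down to a level of 0.3 at the break, then much more slowly
  (a shallow power law, i.e. the F+B *mass* nearly saturates while the
  trunk keeps growing) — the hinge shape the segmented regression stage is
  designed to recover, and a partitioning curve whose emergent shifted-power
  exponent sits near the theoretical 0.75. Foliage vs. branch mass within
  the F+B pool splits near the published 4.1:3.3 ratio of means with a small
  Beta jitter.
* Stand plots place cone-shaped stem crowns uniformly in a square plot and
  rasterise the per-cell maximum crown height plus Gaussian sensor noise;
  plot masses derive from the summed stem cone volumes with a
  density/size-dependent FBMF decline. SOM and litter are drawn from a
  bivariate Gaussian so that their squared correlation targets the published
  r^2 (default 0.72).
* Chemistry rows are Normal(mean, SE) draws around the published tissue
  table; concentration draws are resampled until positive.

Everything is a pure function of ``(config, config.seed)``: the same
configuration yields bit-identical tables.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.special import ndtri

from . import reference
from .errors import ConfigurationError
from .geometry import HeightGrid, canopy_area, cone_volume, cover_area, mean_height, surface_volume

__all__ = ["GeneratorConfig", "generate_trees", "generate_stands", "generate_chemistry"]

# Independent deterministic substreams per dataset kind.
_TREE_STREAM, _STAND_STREAM, _CHEM_STREAM = 11, 22, 33

# Lognormal calibration: the printed min-max envelope spans +-_RANGE_SIGMAS
# standard deviations on the log scale (~99.4% of draws inside per variable).
_RANGE_SIGMAS = 2.75

# Log-scale correlations: height vs. crown diameter, basal diameter vs. volume.
_RHO_H_CROWN = 0.5
_RHO_D_VOLUME = 0.85

# Foliage share of the F+B pool: Beta around the published ratio of means
# 4.1 / (4.1 + 3.3), concentration 80 (sd ~ 0.055).
_FOLIAGE_SHARE_MEAN = 4.1 / 7.4
_FOLIAGE_SHARE_CONC = 80.0

# Stand-level calibration (see docs/methods.md). The plot canopy volume is
# drawn directly (the DTM surface volume is what the published envelope
# describes) with a wide spread mirroring the campaign's mix of young
# regrowth and tall stands (mean plot heights spanning roughly 0.4-7 m);
# crown heights are then rescaled so the noiseless surface volume hits the
# drawn target exactly. The stand mass-volume power is shallower than the
# single-tree one because the printed stand mass envelope is much narrower
# (in log range) than the volume envelope.
_STAND_LN_VOL_MU = 3.65              # ln m^3 of plot canopy volume
_STAND_LN_VOL_SD = 0.55
_STAND_MASS_COEF = 2.25              # BM = coef * V**exp * eps
_STAND_MASS_EXP = 0.8
_STAND_FBMF_INTERCEPT = 0.55
_STAND_FBMF_SLOPE = 0.0017           # per kg of plot biomass
_STAND_FBMF_NOISE_SD = 0.02
_STAND_LN_NRS_MU = math.log(12.0)
_STAND_LN_NRS_SD = 0.4
_STAND_STEM_H_MEDIAN = 3.0           # m, before volume-budget rescaling
_STAND_STEM_H_SD = 0.25              # log scale
_STAND_CROWN_COEF = 0.8              # crown radius = coef * h**0.8
_STAND_SOM_MEAN, _STAND_SOM_SD = 0.8, 0.15       # %
_STAND_LITTER_MEAN, _STAND_LITTER_SD = 0.8, 0.25  # kg/m^2


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic harvest-campaign generator.

    Defaults reproduce the study conditions: 37 single trees, 11 stand
    plots of 5 x 5 m rasterised at 2 cm, mass-volume scaling exponent 0.75,
    FBMF plateau 0.3, 15% multiplicative noise and a litter~SOM squared
    correlation of 0.72.
    """

    model_config = ConfigDict(frozen=True)

    n_trees: int = 37
    n_stands: int = 11
    seed: int = 0

    height_range_m: tuple[float, float] = (2.1, 10.6)
    diameter_range_cm: tuple[float, float] = (1.9, 25.5)
    area_range_m2: tuple[float, float] = (1.2, 24.6)

    scaling_exponent: float = 0.75
    mass_coefficient: float = 3.0        # kg per m^3**scaling_exponent
    noise_cv: float = 0.15

    fbmf_plateau: float = 0.3
    fbmf_decline_slope: float = 0.014    # FBMF increase per kg below the break
    fbmf_breakpoint_kg: float = 25.0
    fbmf_postbreak_exponent: float = -0.175  # FBMF ~ BM**e beyond the break
    fbmf_noise_sd: float = 0.03

    stems_range: tuple[int, int] = (3, 45)
    plot_side_m: float = 5.0
    grid_resolution_m: float = 0.02
    sensor_noise_sd_m: float = 0.05
    dmean_range_cm: tuple[float, float] = (7.2, 34.1)
    litter_som_r2: float = 0.72

    chemistry_means_ses: Optional[dict] = None  # None -> published tissue table

    @field_validator("n_trees", "n_stands")
    @classmethod
    def _counts(cls, v):
        if v < 0:
            raise ConfigurationError("counts must be non-negative")
        return v

    @field_validator("height_range_m", "diameter_range_cm", "area_range_m2", "dmean_range_cm")
    @classmethod
    def _ranges(cls, v):
        lo, hi = v
        if not (0 < lo < hi):
            raise ConfigurationError(f"range must satisfy 0 < min < max, got {v}")
        return v

    @field_validator("noise_cv", "sensor_noise_sd_m", "fbmf_noise_sd")
    @classmethod
    def _nonneg_noise(cls, v, info):
        if info.field_name == "noise_cv" and not v > 0:
            raise ConfigurationError("noise_cv must be positive")
        if v < 0:
            raise ConfigurationError("noise levels cannot be negative")
        return v

    @field_validator("fbmf_plateau")
    @classmethod
    def _plateau(cls, v):
        if not (0 < v < 1):
            raise ConfigurationError("fbmf_plateau must lie in (0, 1)")
        return v

    @model_validator(mode="after")
    def _plot_vs_cell(self):
        lo, hi = self.stems_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("stems_range must satisfy 1 <= min <= max")
        if self.plot_side_m < self.grid_resolution_m:
            raise ConfigurationError("plot smaller than one grid cell")
        return self

    def chemistry(self) -> dict:
        return self.chemistry_means_ses or reference.DEFAULT_CHEMISTRY


def _ln_params(lo: float, hi: float, mean: float | None = None) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose min-max envelope spans +-_RANGE_SIGMAS sd.

    The median is placed so the distribution mean matches ``mean`` when
    given (and safe), else at the geometric midpoint of the envelope.
    """
    sigma = (math.log(hi) - math.log(lo)) / (2 * _RANGE_SIGMAS)
    if mean is not None:
        mu = math.log(mean) - sigma**2 / 2
    else:
        mu = 0.5 * (math.log(lo) + math.log(hi))
    return mu, sigma


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    s = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(s * rng.standard_normal(size) - s**2 / 2)


TREE_COLUMNS = [
    "tree_id", "H", "D", "C1", "C2", "A", "V",
    "trunk_dry", "branch_dry", "foliage_dry", "fb_dry", "total_dry",
]


def generate_trees(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a single-tree destructive-harvest table.

    Columns: tree_id, H (m), D (cm), C1/C2 (m), A (m^2), V (m^3) and the
    dry-mass compartments (kg). Mass conservation is exact by construction:
    ``fb_dry = branch_dry + foliage_dry`` and
    ``total_dry = trunk_dry + fb_dry``.
    """
    n = config.n_trees
    rng = np.random.default_rng([config.seed, _TREE_STREAM])

    mu_h, s_h = _ln_params(*config.height_range_m, mean=reference.TREE_SUMMARY["H"].mean)
    mu_a, s_a = _ln_params(*config.area_range_m2, mean=reference.TREE_SUMMARY["A"].mean)
    mu_d, s_d = _ln_params(*config.diameter_range_cm, mean=reference.TREE_SUMMARY["D"].mean)
    # crown mean diameter Cm: A = pi * (Cm / 2)**2
    mu_c = (mu_a + math.log(4 / math.pi)) / 2
    s_c = s_a / 2

    z_h, z_c, z_d = rng.standard_normal((3, n))
    height = np.exp(mu_h + s_h * z_h)
    crown_mean = np.exp(mu_c + s_c * (_RHO_H_CROWN * z_h + math.sqrt(1 - _RHO_H_CROWN**2) * z_c))
    asym = rng.uniform(0.05, 0.35, n)
    c1 = crown_mean * (1 + asym)
    c2 = crown_mean * (1 - asym)

    if n > 0:
        area = np.atleast_1d(canopy_area(c1, c2))
        volume = np.atleast_1d(cone_volume(area, height))
    else:
        area = np.empty(0)
        volume = np.empty(0)

    # basal diameter correlated with log-volume (theoretical moments)
    mu_v = mu_a + mu_h - math.log(3.0)
    sd_v = math.sqrt(s_a**2 + s_h**2 + 2 * _RHO_H_CROWN * s_a * s_h)
    z_v = (np.log(volume) - mu_v) / sd_v if n > 0 else np.empty(0)
    diameter = np.exp(mu_d + s_d * (_RHO_D_VOLUME * z_v + math.sqrt(1 - _RHO_D_VOLUME**2) * z_d))

    total = (
        config.mass_coefficient
        * volume**config.scaling_exponent
        * _lognormal_noise(rng, config.noise_cv, n)
    )
    # Foliage+branch mass fraction: steep linear decline down to the plateau
    # level at the break, then a much shallower power-law decline (the F+B
    # *mass* saturates while trunk growth continues).
    with np.errstate(invalid="ignore"):
        fbmf_mean = np.where(
            total < config.fbmf_breakpoint_kg,
            config.fbmf_plateau
            + config.fbmf_decline_slope * (config.fbmf_breakpoint_kg - total),
            config.fbmf_plateau
            * (total / config.fbmf_breakpoint_kg) ** config.fbmf_postbreak_exponent,
        )
    fbmf = np.clip(fbmf_mean + rng.normal(0.0, config.fbmf_noise_sd, n), 0.05, 0.95)
    fb = fbmf * total
    trunk = total - fb
    share = rng.beta(
        _FOLIAGE_SHARE_MEAN * _FOLIAGE_SHARE_CONC,
        (1 - _FOLIAGE_SHARE_MEAN) * _FOLIAGE_SHARE_CONC,
        n,
    )
    foliage = share * fb
    branch = fb - foliage

    return pd.DataFrame(
        {
            "tree_id": [f"T{i + 1:03d}" for i in range(n)],
            "H": height,
            "D": diameter,
            "C1": c1,
            "C2": c2,
            "A": area,
            "V": volume,
            "trunk_dry": trunk,
            "branch_dry": branch,
            "foliage_dry": foliage,
            "fb_dry": fb,
            "total_dry": trunk + fb,
        },
        columns=TREE_COLUMNS,
    )


def _rasterise_cones(side, res, xs, ys, hs, rs, noise_sd, rng):
    """Per-cell maximum crown height of cone-shaped crowns, plus sensor noise."""
    ncell = int(round(side / res))
    centres = (np.arange(ncell) + 0.5) * res
    xx, yy = np.meshgrid(centres, centres)
    z = np.zeros((ncell, ncell))
    for x0, y0, h, r in zip(xs, ys, hs, rs):
        dist = np.hypot(xx - x0, yy - y0)
        np.maximum(z, h * np.clip(1.0 - dist / r, 0.0, None), out=z)
    if noise_sd > 0:
        z += rng.normal(0.0, noise_sd, z.shape)
    return z


STAND_COLUMNS = [
    "plot_id", "V", "A", "NrS", "D_mean", "H_mean",
    "trunk_dry", "fb_dry", "total_dry", "SOM", "litter", "V_true",
]


def generate_stands(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, HeightGrid]]:
    """Generate stand-plot records and their canopy height grids.

    Per plot, stems are placed uniformly in the square plot (crowns kept
    inside it); each stem carries a cone-shaped crown, and all crown heights
    are rescaled so the noiseless canopy surface volume equals a lognormally
    drawn plot volume (column ``V_true``). The grid is the per-cell maximum
    crown height plus Gaussian sensor noise; V (surface volume), A (cover
    above 30 cm) and H_mean (mean over all cells) in the returned table are
    *measured from the noisy grid* with the geometry module, while masses
    derive from the noiseless volume truth.
    """
    rng = np.random.default_rng([config.seed, _STAND_STREAM])
    side, res = config.plot_side_m, config.grid_resolution_m
    lo_s, hi_s = config.stems_range

    mu_dm, s_dm = _ln_params(*config.dmean_range_cm)
    rho_sl = math.sqrt(config.litter_som_r2)

    rows = []
    grids: dict[str, HeightGrid] = {}
    n_p = config.n_stands
    for p in range(config.n_stands):
        plot_id = f"S{p + 1:02d}"
        # plot volumes are stratified over the lognormal quantiles (with
        # jitter): field campaigns place quadrats deliberately across the
        # stand-development gradient, not at random
        u = (p + 0.5) / n_p + rng.uniform(-0.5, 0.5) / n_p
        z_vol = float(ndtri(u))
        v_target = math.exp(_STAND_LN_VOL_MU + _STAND_LN_VOL_SD * z_vol)

        nrs = int(np.clip(round(math.exp(rng.normal(_STAND_LN_NRS_MU, _STAND_LN_NRS_SD))), lo_s, hi_s))
        # pre-size crowns toward the volume target (taller stands get taller,
        # wider crowns — radii capped by the plot) so the exact height
        # rescaling below stays a modest correction and tall plots keep a
        # plausible closed-canopy morphology instead of needle-thin spikes
        size_factor = (v_target / 30.0) ** (1.0 / 3.0)
        h_shape = size_factor * np.exp(
            rng.normal(math.log(_STAND_STEM_H_MEDIAN), _STAND_STEM_H_SD, nrs)
        )
        r_shape = np.minimum(_STAND_CROWN_COEF * h_shape**0.8, 0.96 * side / 2)
        # crowns stay inside the quadrat (clear-cut plots are sampled whole)
        margin = np.minimum(r_shape, side / 2)
        xs = rng.uniform(margin, side - margin)
        ys = rng.uniform(margin, side - margin)

        z_unit = _rasterise_cones(side, res, xs, ys, h_shape, r_shape, 0.0, rng)
        unit_volume = float(z_unit.sum()) * res**2
        # scale all crown heights so the noiseless surface volume equals the
        # drawn plot volume (max-composition commutes with positive scaling)
        z = z_unit * (v_target / unit_volume)
        if config.sensor_noise_sd_m > 0:
            z = z + rng.normal(0.0, config.sensor_noise_sd_m, z.shape)
        grid = HeightGrid(plot_id=plot_id, origin=(0.0, 0.0), cell_size=res, z=z, z0=0.0)
        grids[plot_id] = grid

        total = (
            _STAND_MASS_COEF
            * v_target**_STAND_MASS_EXP
            * float(_lognormal_noise(rng, config.noise_cv, 1)[0])
        )
        fbmf = float(
            np.clip(
                _STAND_FBMF_INTERCEPT
                - _STAND_FBMF_SLOPE * total
                + rng.normal(0.0, _STAND_FBMF_NOISE_SD),
                0.20,
                0.62,
            )
        )
        fb = fbmf * total
        trunk = total - fb
        z_d = rng.standard_normal()
        d_mean = math.exp(
            mu_dm + s_dm * (0.7 * z_vol + math.sqrt(1 - 0.7**2) * z_d)
        )
        z1, z2 = rng.standard_normal(2)
        som = float(np.clip(_STAND_SOM_MEAN + _STAND_SOM_SD * z1, 0.05, None))
        litter = float(
            np.clip(
                _STAND_LITTER_MEAN
                + _STAND_LITTER_SD * (rho_sl * z1 + math.sqrt(1 - rho_sl**2) * z2),
                0.005,
                None,
            )
        )

        rows.append(
            {
                "plot_id": plot_id,
                "V": surface_volume(grid),
                "A": cover_area(grid),
                "NrS": nrs,
                "D_mean": d_mean,
                "H_mean": mean_height(grid),
                "trunk_dry": trunk,
                "fb_dry": fb,
                "total_dry": trunk + fb,  # conservation exact in floats
                "SOM": som,
                "litter": litter,
                "V_true": v_target,  # noiseless canopy surface volume (truth)
            }
        )

    return pd.DataFrame(rows, columns=STAND_COLUMNS), grids


CHEMISTRY_COLUMNS = [
    "unit", "tissue", "C_pct", "N_pct", "P_permil", "d13C", "d15N", "CN_ratio", "NP_ratio",
]


def generate_chemistry(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one tissue-chemistry row per (unit, tissue) around the published table.

    Values are Normal(mean, SE); concentration draws (C, N, P) are resampled
    until positive so no impossible chemistry is ever emitted. C/N is the
    mass ratio C%/N%; N/P converts N to permil first (N% * 10 / P permil).
    """
    rng = np.random.default_rng([config.seed, _CHEM_STREAM])
    rows = []
    for (unit, tissue), analytes in config.chemistry().items():
        row = {"unit": unit, "tissue": tissue}
        for name, ms in analytes.items():
            if ms is None:
                row[name] = np.nan
                continue
            mean, se = ms
            value = rng.normal(mean, se)
            if name in ("C_pct", "N_pct", "P_permil"):
                while value <= 0:  # truncated-positive resampling
                    value = rng.normal(mean, se)
            row[name] = value
        row["CN_ratio"] = row["C_pct"] / row["N_pct"]
        row["NP_ratio"] = (
            row["N_pct"] * 10.0 / row["P_permil"] if np.isfinite(row.get("P_permil", np.nan)) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=CHEMISTRY_COLUMNS)
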