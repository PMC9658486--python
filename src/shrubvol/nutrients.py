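"""Nutrient-pool extrapolation and biomass partitioning.

Elemental totals (C, N, P) of a tree or stand are the mass-weighted sums of
compartment dry masses and tissue concentrations; the foliage+branch mass
fraction FBMF = FB / (FB + trunk) and its complement, the trunk mass
fraction TMF, summarise partitioning. The allometric partitioning fit
FB ~ a + b * BM**c (theory expects c near 0.75) delegates to the power
machinery of :mod:`shrubvol.allometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .allometry import FittedModel, ModelSpec, fit_model
from .errors import DomainError

__all__ = ["PoolTotals", "pool_totals", "fit_partitioning", "dry_mass", "chemistry_lookup"]

#: Compartments counted into the foliage+branch pool.
_FB_COMPARTMENTS = {"branch", "foliage", "fb"}


@dataclass
class PoolTotals:
    """Elemental totals (kg) and mass fractions for one tree or plot."""

    C_tot: float
    N_tot: float
    P_tot: float | None
    CN_total: float
    FBMF: float
    TMF: float


def chemistry_lookup(chemistry: pd.DataFrame, unit: str) -> dict[str, dict[str, float]]:
    """Index a chemistry table (as produced by the generator) by tissue for one unit."""
    sub = chemistry[chemistry["unit"] == unit]
    return {
        row["tissue"]: {k: row[k] for k in ("C_pct", "N_pct", "P_permil")}
        for _, row in sub.iterrows()
    }


def pool_totals(
    masses: Mapping[str, float],
    chem: Mapping[str, Mapping[str, float]],
    allow_partial_P: bool = False,
) -> PoolTotals:
    """Extrapolate elemental totals from compartment masses and tissue chemistry.

    ``masses`` maps compartment names (trunk plus any of branch / foliage /
    fb) to dry masses in kg; ``chem`` maps the same names to concentrations
    (``C_pct``, ``N_pct`` in %, ``P_permil`` in permil, NaN/absent when not
    measured). Every mass compartment must have C and N chemistry — there
    is no silent default. Phosphorus was not measured for every tissue; by
    default a compartment without P raises, while ``allow_partial_P=True``
    sums P over the compartments that report it (None if none do).
    """
    if not masses:
        raise DomainError("no mass compartments given")
    fb_mass = trunk_mass = 0.0
    c_tot = n_tot = 0.0
    p_tot = 0.0
    p_seen = False
    for comp, mass in masses.items():
        if mass < 0:
            raise DomainError(f"negative mass for compartment {comp!r}")
        if comp not in chem:
            raise DomainError(f"missing chemistry for compartment {comp!r}")
        row = chem[comp]
        for key in ("C_pct", "N_pct"):
            if key not in row or not np.isfinite(row[key]):
                raise DomainError(f"missing {key} for compartment {comp!r}")
        c_tot += mass * row["C_pct"] / 100.0
        n_tot += mass * row["N_pct"] / 100.0
        p_conc = row.get("P_permil", np.nan)
        if p_conc is not None and np.isfinite(p_conc):
            p_tot += mass * p_conc / 1000.0
            p_seen = True
        elif not allow_partial_P:
            raise DomainError(
                f"no P concentration for compartment {comp!r} "
                "(pass allow_partial_P=True to sum over measured compartments)"
            )
        if comp in _FB_COMPARTMENTS:
            fb_mass += mass
        elif comp == "trunk":
            trunk_mass += mass
        else:
            raise DomainError(f"unknown compartment {comp!r}")
    total = fb_mass + trunk_mass
    if total <= 0:
        raise DomainError("total mass is zero: mass fractions undefined")
    if n_tot <= 0:
        raise DomainError("total N is zero: C/N undefined")
    fbmf = fb_mass / total
    return PoolTotals(
        C_tot=c_tot,
        N_tot=n_tot,
        P_tot=p_tot if p_seen else None,
        CN_total=c_tot / n_tot,
        FBMF=fbmf,
        TMF=1.0 - fbmf,
    )


def fit_partitioning(total_biomass, fb_mass) -> FittedModel:
    """Allometric partitioning fit FB ~ a + b * BM**c (shifted power form).

    ``param_se`` on the result provides a Wald-type interval for the
    exponent c (``c_BM`` entry) to compare against the theoretical 0.75.
    """
    bm = np.asarray(total_biomass, dtype=float)
    fb = np.asarray(fb_mass, dtype=float)
    if bm.size < 4:
        raise DomainError("need at least 4 observations")
    if np.any(bm <= 0):
        raise DomainError("total biomass must be positive")
    data = pd.DataFrame({"BM": bm, "FB": fb})
    return fit_model(ModelSpec(response="FB", predictors=("BM",), family="power_sum"), data)


def dry_mass(fresh_kg: float, dry_fraction: float) -> float:
    """Dry mass from fresh mass and the subsample dry-matter fraction."""
    if not 0 < dry_fraction < 1:
        raise DomainError("dry_fraction must lie strictly between 0 and 1")
    if fresh_kg < 0:
        raise DomainError("fresh mass cannot be negative")
    return fresh_kg * dry_fraction
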