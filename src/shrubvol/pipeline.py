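"""End-to-end orchestration: generate/load -> geometry -> fit -> select ->
segment -> height curve -> nutrient pools, with a reproducibility manifest.

Every stage failure is re-raised as a :class:`PipelineStageError` carrying
the stage name. A run is a pure function of its :class:`RunConfig`; running
the same configuration twice writes bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__ as _version
from . import reference
from .allometry import (
    FittedModel,
    enumerate_models,
    fit_combined_volume_model,
    fit_model,
    format_equation,
    select_models,
)
from .errors import ConfigurationError, DomainError, PipelineStageError, SelectionError
from .nutrients import chemistry_lookup, dry_mass, pool_totals
from .segmented import fit_segmented
from .subsampling import min_observations, r_curve
from .synthetic import GeneratorConfig, generate_chemistry, generate_stands, generate_trees

__all__ = ["RunConfig", "RunReport", "run_all", "validate_worked_example", "WorkedExampleResult"]

TREE_RESPONSES = ("total", "trunk", "foliage", "branches", "fb", "C_tot", "N_tot", "P_tot")
STAND_RESPONSES = ("total", "trunk", "fb", "litter", "SOM", "C_tot", "N_tot")


class RunConfig(BaseModel):
    """Configuration of a full pipeline run.

    Exactly one data source per run: a generator configuration, or paths to
    tree/stand CSV tables (with an optional chemistry CSV and a directory
    of per-plot xyz point clouds for the height-curve stage).
    """

    model_config = ConfigDict(frozen=True)

    generator: Optional[GeneratorConfig] = None
    trees_csv: Optional[str] = None
    stands_csv: Optional[str] = None
    chemistry_csv: Optional[str] = None
    clouds_dir: Optional[str] = None

    out_dir: str = "shrubvol_run"
    delta_bic: float = 10.0
    subsample_n_max: int = 400
    subsample_reps: int = 10_000
    run_nutrients: bool = True
    run_heightcurve: bool = True

    @model_validator(mode="after")
    def _one_source(self):
        from_files = self.trees_csv is not None or self.stands_csv is not None
        if (self.generator is None) == (not from_files):
            raise ConfigurationError(
                "exactly one data source: a generator config or input CSV paths"
            )
        return self


@dataclass
class RunReport:
    """Objects and file paths produced by :func:`run_all`."""

    trees: pd.DataFrame
    stands: pd.DataFrame
    chemistry: pd.DataFrame | None
    selection_trees: pd.DataFrame
    selection_stands: pd.DataFrame
    combined_model: FittedModel
    fbmf_segmented: object
    height_curve: object | None
    min_obs: object | None
    pool_table: pd.DataFrame | None
    out_dir: Path
    files: list[str] = field(default_factory=list)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _zoo_table(data: pd.DataFrame, kind: str, responses, delta_bic: float) -> pd.DataFrame:
    """Fit the full candidate zoo per response and tabulate both selections."""
    rows = []
    for response in responses:
        fits = []
        for spec in enumerate_models(kind, response):
            if spec.response_column() not in data.columns:
                continue
            try:
                fits.append(fit_model(spec, data))
            except DomainError:
                continue
        if not fits:
            continue
        try:
            best, pars = select_models(fits, delta_bic=delta_bic)
        except SelectionError:
            continue
        for label, fit in (("parsimonious", pars), ("best", best)):
            rows.append(
                {
                    "response": response,
                    "selection": label,
                    "equation": format_equation(fit),
                    "family": fit.spec.family,
                    "predictors": "+".join(fit.spec.predictors),
                    "n": fit.n,
                    "RMSE": fit.rmse,
                    "BIC": fit.bic,
                }
            )
    return pd.DataFrame(rows)


def _add_nutrient_totals(table: pd.DataFrame, chem: dict, unit: str) -> pd.DataFrame:
    """Append C_tot / N_tot (and P_tot where measurable) columns per row."""
    if unit == "tree":
        comps = ("trunk", "branch", "foliage")
        cols = {"trunk": "trunk_dry", "branch": "branch_dry", "foliage": "foliage_dry"}
    else:
        comps = ("trunk", "fb")
        cols = {"trunk": "trunk_dry", "fb": "fb_dry"}
    c_tot, n_tot, p_tot = [], [], []
    for _, row in table.iterrows():
        masses = {c: float(row[cols[c]]) for c in comps}
        totals = pool_totals(masses, chem, allow_partial_P=True)
        c_tot.append(totals.C_tot)
        n_tot.append(totals.N_tot)
        p_tot.append(totals.P_tot if totals.P_tot is not None else np.nan)
    out = table.copy()
    out["C_tot"] = c_tot
    out["N_tot"] = n_tot
    if np.isfinite(p_tot).any():
        out["P_tot"] = p_tot
    return out


def run_all(config: RunConfig) -> RunReport:
    """Execute the whole pipeline and write the report bundle to ``out_dir``.

    Outputs: the input tables (CSV), selected-model tables for trees and
    stands (CSV), the combined volumetric model (JSON), the FBMF segmented
    fit (JSON), the height-subsampling curve (CSV) with its breakpoint
    (JSON), per-unit nutrient pool totals (CSV) and a manifest (JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def save_csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        files.append(name)

    def save_json(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
        files.append(name)

    with _stage("data"):
        if config.generator is not None:
            trees = generate_trees(config.generator)
            stands, grids = generate_stands(config.generator)
        else:
            if config.trees_csv is None or config.stands_csv is None:
                raise ConfigurationError("both trees_csv and stands_csv are required")
            trees = pd.read_csv(config.trees_csv)
            stands = pd.read_csv(config.stands_csv)
            grids = None
        save_csv(trees, "trees.csv")
        save_csv(stands, "stands.csv")

    chemistry = None
    pool_table = None
    if config.run_nutrients:
        with _stage("chemistry"):
            if config.generator is not None:
                chemistry = generate_chemistry(config.generator)
            elif config.chemistry_csv is not None:
                chemistry = pd.read_csv(config.chemistry_csv)
            else:
                raise ConfigurationError("nutrient stage requested but no chemistry source")
            save_csv(chemistry, "chemistry.csv")
        with _stage("nutrients"):
            tree_chem = chemistry_lookup(chemistry, "tree")
            stand_chem = chemistry_lookup(chemistry, "stand")
            trees = _add_nutrient_totals(trees, tree_chem, "tree")
            stands = _add_nutrient_totals(stands, stand_chem, "stand")
            pools = []
            for _, row in trees.iterrows():
                pools.append(
                    {
                        "unit_id": row["tree_id"],
                        "kind": "tree",
                        "C_tot": row["C_tot"],
                        "N_tot": row["N_tot"],
                        "P_tot": row.get("P_tot", np.nan),
                        "FBMF": row["fb_dry"] / row["total_dry"],
                    }
                )
            for _, row in stands.iterrows():
                pools.append(
                    {
                        "unit_id": row["plot_id"],
                        "kind": "stand",
                        "C_tot": row["C_tot"],
                        "N_tot": row["N_tot"],
                        "P_tot": np.nan,
                        "FBMF": row["fb_dry"] / row["total_dry"],
                    }
                )
            pool_table = pd.DataFrame(pools)
            save_csv(pool_table, "pool_totals.csv")

    with _stage("model_zoo"):
        tree_resp = [r for r in TREE_RESPONSES if r == "total" or _response_available(trees, r)]
        stand_resp = [r for r in STAND_RESPONSES if r == "total" or _response_available(stands, r)]
        selection_trees = _zoo_table(trees, "trees", tree_resp, config.delta_bic)
        selection_stands = _zoo_table(stands, "stands", stand_resp, config.delta_bic)
        save_csv(selection_trees, "model_selection_trees.csv")
        save_csv(selection_stands, "model_selection_stands.csv")

    with _stage("combined_model"):
        combined = fit_combined_volume_model(trees, stands)
        save_json(
            {
                "equation": format_equation(combined),
                "params": combined.params,
                "n": combined.n,
                "RMSE": combined.rmse,
                "BIC": combined.bic,
            },
            "combined_model.json",
        )

    with _stage("segmented"):
        fbmf = trees["fb_dry"] / trees["total_dry"]
        seg = fit_segmented(trees["total_dry"].to_numpy(), fbmf.to_numpy())
        save_json(
            {
                "psi_kg": seg.psi,
                "fbmf_at_breakpoint": seg.y_at_breakpoint,
                "slope_left": seg.slope_left,
                "slope_right": seg.slope_right,
                "davies_p": seg.davies_p,
                "wald_p": seg.wald_p,
                "degenerate": seg.degenerate,
                "n": seg.n,
            },
            "fbmf_segmented.json",
        )

    curve = minobs = None
    if config.run_heightcurve:
        with _stage("height_curve"):
            clouds = _load_clouds(config, stands, grids)
            if clouds is not None:
                plot_area = (
                    config.generator.plot_side_m**2 if config.generator is not None else 25.0
                )
                seed = config.generator.seed if config.generator is not None else 0
                curve = r_curve(
                    clouds,
                    stands["total_dry"].to_numpy(),
                    n_max=config.subsample_n_max,
                    reps=config.subsample_reps,
                    seed=seed,
                    plot_area_m2=plot_area,
                )
                save_csv(
                    pd.DataFrame(
                        {
                            "n": curve.n_values,
                            "n_per_100m2": curve.n_per_100m2,
                            "mean_r": curve.mean_r,
                        }
                    ),
                    "height_curve.csv",
                )
                minobs = min_observations(curve)
                save_json(
                    {
                        "min_obs_per_100m2": minobs.n_per_100m2,
                        "degenerate": minobs.degenerate,
                        "full_cloud_r": curve.full_cloud_r,
                        "reps": curve.reps,
                        "seed": curve.seed,
                    },
                    "min_observations.json",
                )

    with _stage("manifest"):
        manifest = {
            "shrubvol_version": _version,
            "config": json.loads(config.model_dump_json()),
            "files": sorted(files + ["manifest.json"]),
        }
        save_json(manifest, "manifest.json")

    return RunReport(
        trees=trees,
        stands=stands,
        chemistry=chemistry,
        selection_trees=selection_trees,
        selection_stands=selection_stands,
        combined_model=combined,
        fbmf_segmented=seg,
        height_curve=curve,
        min_obs=minobs,
        pool_table=pool_table,
        out_dir=out,
        files=sorted(files),
    )


def _response_available(table: pd.DataFrame, response: str) -> bool:
    from .allometry import RESPONSE_COLUMNS

    col = RESPONSE_COLUMNS.get(response, response)
    return col in table.columns and np.isfinite(np.asarray(table[col], dtype=float)).all()


def _load_clouds(config: RunConfig, stands: pd.DataFrame, grids):
    if grids is not None:
        return {pid: grids[pid].heights() for pid in stands["plot_id"]}
    if config.clouds_dir is not None:
        from .gridio import read_xyz

        clouds = {}
        for pid in stands["plot_id"]:
            path = Path(config.clouds_dir) / f"{pid}.xyz"
            if not path.exists():
                raise ConfigurationError(f"missing point cloud for plot {pid}: {path}")
            clouds[pid] = read_xyz(path)[:, 2]
        return clouds
    return None


@dataclass
class WorkedExampleResult:
    """Whole-plot validation of the simplified volumetric model."""

    predicted_kg: float
    measured_dry_kg: float
    deviation_kg: float
    deviation_pct: float


def validate_worked_example(
    volume_m3: float | None = None,
    intercept: float | None = None,
    slope: float | None = None,
    fresh_kg: float | None = None,
    dry_fraction: float | None = None,
    measured_dry_kg: float | None = None,
) -> WorkedExampleResult:
    """Re-run the whole-plot validation of the combined volumetric model.

    Applies the published model coefficients to the DTM-derived plot volume
    of the final clear-cut, converts the lorry-scale fresh biomass to dry
    mass with the subsample dry-matter fraction, and reports the percent
    deviation of prediction from measurement. All defaults are the printed
    campaign values (:data:`shrubvol.reference.WORKED_EXAMPLE`); pass
    ``measured_dry_kg`` to use a printed dry mass instead of the computed
    one.
    """
    ref = reference.WORKED_EXAMPLE
    volume_m3 = ref["plot_volume_m3"] if volume_m3 is None else volume_m3
    intercept = ref["intercept_kg"] if intercept is None else intercept
    slope = ref["slope_kg_per_m3"] if slope is None else slope
    fresh_kg = ref["fresh_biomass_kg"] if fresh_kg is None else fresh_kg
    dry_fraction = ref["dry_matter_fraction"] if dry_fraction is None else dry_fraction

    predicted = intercept + slope * volume_m3
    measured = (
        dry_mass(fresh_kg, dry_fraction) if measured_dry_kg is None else float(measured_dry_kg)
    )
    deviation = measured - predicted
    return WorkedExampleResult(
        predicted_kg=predicted,
        measured_dry_kg=measured,
        deviation_kg=deviation,
        deviation_pct=100.0 * deviation / measured,
    )
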