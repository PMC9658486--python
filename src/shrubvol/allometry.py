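"""Allometric model zoo: three equation families, BIC ranking and selection.

The candidate equations predict a biomass (or nutrient-total) response from
subsets of the dimensional predictors — {V, A, H, D} for single trees,
{V, A, H_mean, D_mean, NrS} for stand plots — in one of three families:

* ``linear``     Y = a + sum_i b_i * X_i                    (OLS)
* ``ln_linear``  Y = a + sum_i b_i * ln(X_i)                (OLS)
* ``power_sum``  Y = a + sum_i b_i * X_i**c_i               (Levenberg-Marquardt)

The response is never transformed, so fits are comparable across families
and no back-transformation bias correction is needed. Candidates are ranked
by BIC computed from the Gaussian log-likelihood,

    BIC = n * ln(RSS / n) + k * ln(n),

with k counting the mean-function parameters plus one for the error
variance — the identical formula across families. The *best* model is the
global BIC minimum; the *most parsimonious* model is the BIC minimum among
models using the smallest predictor count whose best BIC comes within
``delta_bic`` (default 10, the strong-evidence threshold) of the global
minimum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import DomainError, SelectionError, UnsupportedModelError

__all__ = [
    "ModelSpec",
    "FittedModel",
    "bic",
    "fit_model",
    "enumerate_models",
    "select_models",
    "fit_combined_volume_model",
    "predict",
    "prediction_interval",
    "format_equation",
]

FAMILIES = ("linear", "ln_linear", "power_sum")
TREE_PREDICTORS = ("V", "A", "H", "D")
STAND_PREDICTORS = ("V", "A", "H_mean", "D_mean", "NrS")

#: Response name -> table column (responses not listed map to themselves).
RESPONSE_COLUMNS = {
    "total": "total_dry",
    "trunk": "trunk_dry",
    "foliage": "foliage_dry",
    "branches": "branch_dry",
    "fb": "fb_dry",
}

# power_sum safeguards: shared-exponent restart grid against local minima
_RESTART_EXPONENTS = (0.5, 1.0, 1.5, 2.0, 3.0)
_MAX_ITER = 200
_RSS_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """One candidate equation: response, ordered predictor names, family."""

    response: str
    predictors: tuple[str, ...]
    family: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise DomainError(f"unknown family {self.family!r}")
        if not (1 <= len(self.predictors) <= 4):
            raise DomainError("1 to 4 predictors required")
        if len(set(self.predictors)) != len(self.predictors):
            raise DomainError("duplicate predictors")

    @property
    def n_mean_params(self) -> int:
        per = 2 if self.family == "power_sum" else 1
        return 1 + per * len(self.predictors)

    def response_column(self) -> str:
        return RESPONSE_COLUMNS.get(self.response, self.response)


@dataclass
class FittedModel:
    """A fitted candidate: coefficients, goodness of fit and BIC.

    ``params`` holds the intercept ``a``, per-predictor slopes ``b_<name>``
    and, for the power family, exponents ``c_<name>``. ``param_se`` carries
    large-sample standard errors where available (OLS always; power fits via
    the Jacobian at the solution).
    """

    spec: ModelSpec
    params: dict[str, float]
    n: int
    rss: float
    rmse: float
    bic: float
    converged: bool
    param_se: dict[str, float] | None = None
    _sm_result: object | None = field(default=None, repr=False, compare=False)

    @property
    def n_predictors(self) -> int:
        return len(self.spec.predictors)


def bic(n: int, rss: float, k: int) -> float:
    """Gaussian BIC: ``n*ln(RSS/n) + k*ln(n)`` with k the total parameter count.

    A perfect fit (RSS = 0) returns ``-inf`` so it ranks strictly best.
    """
    if n <= 0:
        raise DomainError("n must be positive")
    if rss < 0:
        raise DomainError("RSS cannot be negative")
    if rss == 0.0:
        return -np.inf
    return n * np.log(rss / n) + k * np.log(n)


def bic_of(fit: FittedModel) -> float:
    """BIC of a fitted model (mean-function parameters + 1 for the variance)."""
    if not fit.converged:
        raise DomainError("BIC undefined for non-converged fits")
    return bic(fit.n, fit.rss, fit.spec.n_mean_params + 1)


def _design(data: Mapping | pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    cols = [np.asarray(data[p], dtype=float) for p in predictors]
    return np.column_stack(cols)


def _finish(spec, params, n, rss, converged, param_se=None, sm_result=None) -> FittedModel:
    rmse = float(np.sqrt(rss / n))
    value = bic(n, rss, spec.n_mean_params + 1) if converged else np.nan
    return FittedModel(
        spec=spec, params=params, n=n, rss=float(rss), rmse=rmse,
        bic=value, converged=converged, param_se=param_se, _sm_result=sm_result,
    )


def _snap_rss(rss: float, y: np.ndarray) -> float:
    """Snap a numerically-zero residual sum to exactly 0 (perfect fit)."""
    return 0.0 if rss <= 1e-12 * max(float(y @ y), 1e-300) else rss


def _fit_ols(spec: ModelSpec, x: np.ndarray, y: np.ndarray) -> FittedModel:
    if spec.family == "ln_linear":
        if np.any(x <= 0):
            raise DomainError("ln_linear requires strictly positive predictors")
        x = np.log(x)
    res = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    names = ["a"] + [f"b_{p}" for p in spec.predictors]
    params = dict(zip(names, map(float, res.params)))
    ses = dict(zip(names, map(float, res.bse)))
    return _finish(spec, params, len(y), _snap_rss(float(res.ssr), y), True, ses, res)


def _power_model(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c = theta[0], theta[1::2], theta[2::2]
    return a + (b * x**c).sum(axis=1)


def _power_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Initial parameter vectors: per-predictor log-log OLS plus a shared-exponent grid."""
    n, p = x.shape
    starts = []
    # log-log initialisation on the shifted response
    shifted = np.log(y - y.min() + 1e-6)
    theta = [float(y.min())]
    for j in range(p):
        slope, inter = np.polyfit(np.log(x[:, j]), shifted, 1)
        theta += [float(np.exp(inter)), float(np.clip(slope, 0.05, 5.0))]
    starts.append(np.array(theta))
    # shared exponents with exact conditional OLS for (a, b)
    for expo in _RESTART_EXPONENTS:
        design = np.column_stack([np.ones(n), x**expo])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        theta = [coef[0]]
        for j in range(p):
            theta += [float(coef[1 + j]), expo]
        starts.append(np.array(theta))
    return starts


def _fit_power(spec: ModelSpec, x: np.ndarray, y: np.ndarray) -> FittedModel:
    if np.any(x <= 0):
        raise DomainError("power_sum requires strictly positive predictors")
    n = len(y)

    log_x = np.log(x)

    def residuals(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            r = _power_model(theta, x) - y
        return np.where(np.isfinite(r), r, 1e12)

    def jacobian(theta):
        b, c = theta[1::2], theta[2::2]
        with np.errstate(over="ignore", invalid="ignore"):
            powers = x**c
            cols = [np.ones(n)]
            for j in range(x.shape[1]):
                cols.append(powers[:, j])
                cols.append(b[j] * powers[:, j] * log_x[:, j])
            jac = np.column_stack(cols)
        return np.where(np.isfinite(jac), jac, 0.0)

    best = None
    for start in _power_starts(x, y):
        try:
            sol = least_squares(
                residuals, start, jac=jacobian, method="lm",
                ftol=_RSS_TOL, xtol=_RSS_TOL, gtol=_RSS_TOL,
                max_nfev=_MAX_ITER * len(start),
            )
        except Exception:  # noqa: BLE001 - a failed restart is just skipped
            continue
        rss = float(2 * sol.cost)
        if np.isfinite(rss) and (best is None or rss < best[0] - _RSS_TOL):
            best = (rss, sol)
    if best is None:
        names = ["a"] + [n for p in spec.predictors for n in (f"b_{p}", f"c_{p}")]
        return _finish(spec, dict.fromkeys(names, np.nan), n, np.inf, False)

    rss, sol = best
    rss = _snap_rss(rss, y)
    names = ["a"] + [nm for p in spec.predictors for nm in (f"b_{p}", f"c_{p}")]
    params = dict(zip(names, map(float, sol.x)))
    ses = None
    dof = n - len(sol.x) - 1
    if dof > 0 and rss > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
            ses = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
        except np.linalg.LinAlgError:
            ses = None
    converged = bool(sol.success and np.isfinite(sol.x).all())
    return _finish(spec, params, n, rss, converged, ses)


def fit_model(spec: ModelSpec, data) -> FittedModel:
    """Fit one candidate equation to a table of observations.

    Requires ``n`` strictly greater than the number of mean-function
    parameters, and strictly positive predictors for the log and power
    families. Non-convergence of the power optimiser is flagged on the
    result (``converged=False``), not raised, so zoo runs can skip it.
    """
    y = np.asarray(data[spec.response_column()], dtype=float)
    x = _design(data, spec.predictors)
    if len(y) <= spec.n_mean_params:
        raise DomainError(
            f"n={len(y)} too small for {spec.n_mean_params} parameters ({spec.family})"
        )
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise DomainError("non-finite values in response or predictors")
    if spec.family in ("linear", "ln_linear"):
        return _fit_ols(spec, x, y)
    return _fit_power(spec, x, y)


def enumerate_models(dataset_kind: str, response: str) -> list[ModelSpec]:
    """All candidate specs for a response: predictor subsets x families.

    Trees: non-empty subsets of {V, A, H, D} up to size 3; stands: subsets
    of {V, A, H_mean, D_mean, NrS} up to size 4. Every subset is crossed
    with the three families (42 tree specs, 90 stand specs per response).
    """
    if dataset_kind == "trees":
        pool, max_size = TREE_PREDICTORS, 3
    elif dataset_kind == "stands":
        pool, max_size = STAND_PREDICTORS, 4
    else:
        raise DomainError(f"unknown dataset kind {dataset_kind!r}")
    specs = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(pool, size):
            for family in FAMILIES:
                specs.append(ModelSpec(response=response, predictors=combo, family=family))
    return specs


def _rank_key(fit: FittedModel):
    return (fit.bic, fit.spec.n_mean_params, FAMILIES.index(fit.spec.family))


def select_models(
    fits: Iterable[FittedModel], delta_bic: float = 10.0
) -> tuple[FittedModel, FittedModel]:
    """Pick the best (global BIC minimum) and most parsimonious models.

    The parsimonious choice uses the smallest predictor count whose best
    BIC is within ``delta_bic`` of the global minimum; ties break by fewer
    parameters, then by family order linear < ln_linear < power_sum.
    """
    usable = [f for f in fits if f.converged and not np.isnan(f.bic)]
    if not usable:
        raise SelectionError("no converged fits to select from")
    best = min(usable, key=_rank_key)
    counts = sorted({f.n_predictors for f in usable})
    for v in counts:
        group = [f for f in usable if f.n_predictors == v]
        group_best = min(group, key=_rank_key)
        if group_best.bic <= best.bic + delta_bic:
            return best, group_best
    return best, best  # unreachable: the best model's own count always qualifies


def fit_combined_volume_model(trees: pd.DataFrame, stands: pd.DataFrame) -> FittedModel:
    """Pooled simplified volumetric model: total dry biomass ~ a + b * V.

    Single trees and stand plots are concatenated into one sample — the
    user-friendly equation that scales to remote-sensing volume estimates.
    """
    parts = []
    for tbl in (trees, stands):
        if tbl is None or len(tbl) == 0:
            raise DomainError("both tree and stand tables must be non-empty")
        parts.append(tbl[["V", "total_dry"]])
    pooled = pd.concat(parts, ignore_index=True)
    if len(pooled) < 3:
        raise DomainError("fewer than 3 pooled observations")
    spec = ModelSpec(response="total", predictors=("V",), family="linear")
    return fit_model(spec, pooled)


def predict(fit: FittedModel, newdata) -> np.ndarray:
    """Point predictions of a fitted model at new predictor values."""
    x = _design(newdata, fit.spec.predictors)
    a = fit.params["a"]
    if fit.spec.family == "power_sum":
        b = np.array([fit.params[f"b_{p}"] for p in fit.spec.predictors])
        c = np.array([fit.params[f"c_{p}"] for p in fit.spec.predictors])
        return a + (b * x**c).sum(axis=1)
    if fit.spec.family == "ln_linear":
        x = np.log(x)
    b = np.array([fit.params[f"b_{p}"] for p in fit.spec.predictors])
    return a + x @ b


def prediction_interval(fit: FittedModel, newdata, level: float = 0.95) -> np.ndarray:
    """Normal-theory confidence interval for the mean response (OLS families).

    Returns an (n, 2) array of lower/upper bounds. Not defined for the
    nonlinear power family.
    """
    if fit.spec.family == "power_sum" or fit._sm_result is None:
        raise UnsupportedModelError("intervals are only available for OLS-family fits")
    x = _design(newdata, fit.spec.predictors)
    if fit.spec.family == "ln_linear":
        x = np.log(x)
    exog = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = fit._sm_result.get_prediction(exog)
    return np.asarray(pred.conf_int(alpha=1 - level))


def format_equation(fit: FittedModel, digits: int = 3) -> str:
    """Human-readable equation string, e.g. ``Y ~ 0.25 + 1.46*V``."""

    def num(v):
        return f"{v:.{digits}g}"

    a = fit.params["a"]
    terms = [num(a)]
    for p in fit.spec.predictors:
        b = fit.params[f"b_{p}"]
        sign = " + " if b >= 0 else " - "
        mag = num(abs(b))
        if fit.spec.family == "linear":
            terms.append(f"{sign}{mag}*{p}")
        elif fit.spec.family == "ln_linear":
            terms.append(f"{sign}{mag}*ln({p})")
        else:
            terms.append(f"{sign}{mag}*{p}^{num(fit.params[f'c_{p}'])}")
    return "Y ~ " + "".join(terms)
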