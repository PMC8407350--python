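"""Maintenance-energy calibration from chemostat data.

NGAM comes from the y-intercept of nitrite uptake regressed on growth
rate, multiplied by the model's net ATP yield.  GAM is then fitted by
bisection so that the model's uptake-vs-growth slope (minimum nitrite
uptake at a series of fixed growth rates) matches the experimentally
implied slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .core import MaintenanceParams, MetabolicModel
from .fba import BoundOverride, FBAError, solve_fba


@dataclass(frozen=True)
class RatePair:
    """One chemostat observation: nitrite uptake (mmol gDW-1 h-1) at a
    set growth (dilution) rate (h-1)."""

    uptake: float
    growth: float

    def __post_init__(self) -> None:
        if self.uptake < 0 or self.growth < 0:
            raise ValueError("uptake and growth must be non-negative")


@dataclass
class CalibrationResult:
    ngam: float                 # mmol ATP gDW-1 h-1
    gam: float                  # mmol ATP gDW-1
    intercept_uptake: float     # mmol NO2- gDW-1 h-1
    slope: float                # mmol NO2- gDW-1
    r_squared: float
    residual_sd: float


class CalibrationError(ValueError):
    pass


def fit_ngam(
    pairs: Sequence[RatePair], atp_yield: float
) -> Tuple[float, float, float]:
    """OLS fit uptake = slope * growth + intercept; NGAM = intercept * yield.

    Returns (ngam, intercept, slope).  Growth is the regressor.
    """
    if len(pairs) < 2:
        raise CalibrationError("need at least two rate pairs")
    x = np.array([p.growth for p in pairs])
    y = np.array([p.uptake for p in pairs])
    if np.allclose(x, x[0]):
        raise CalibrationError("all growth rates identical: singular fit")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(intercept * atp_yield), float(intercept), float(slope)


def fit_diagnostics(
    pairs: Sequence[RatePair], slope: float, intercept: float
) -> Tuple[float, float]:
    x = np.array([p.growth for p in pairs])
    y = np.array([p.uptake for p in pairs])
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(pairs) - 2, 1)
    return r2, float(np.sqrt(ss_res / dof))


def set_maintenance(
    model: MetabolicModel, gam: float = None, ngam: float = None
) -> MetabolicModel:
    """Copy of the model with new maintenance parameters.

    GAM is the ATP coefficient of the biomass reaction (the ADP product
    coefficient tracks it); NGAM is the lower bound of the ATP
    maintenance reaction.
    """
    out = model.copy()
    if gam is not None:
        if gam < 0:
            raise CalibrationError("GAM must be non-negative")
        bm = out.get_reaction("biomass")
        for sid, sign in (
            ("atp_c", -1.0),
            ("h2o_c", -1.0),
            ("adp_c", 1.0),
            ("pi_c", 1.0),
            ("h_c", 1.0),
        ):
            bm.stoichiometry[sid] = sign * gam
    if ngam is not None:
        if ngam < 0:
            raise CalibrationError("NGAM must be non-negative")
        out.get_reaction("ATPM_c0").lower_bound = ngam
    return out


DEFAULT_GROWTH_RATES = (0.002, 0.006, 0.010)


def model_uptake_slope(
    model: MetabolicModel,
    growth_rates: Sequence[float] = DEFAULT_GROWTH_RATES,
) -> float:
    """Slope of minimum nitrite uptake vs fixed growth rate (OLS over
    the given rates), mmol NO2- per gDW."""
    ups = []
    for mu in growth_rates:
        sol = solve_fba(
            model,
            [
                BoundOverride("biomass", mu, mu),
                BoundOverride("EX_no2_e", -1000.0, 0.0),
            ],
            objective="EX_no2_e",
            sense="max",  # max of EX (negative = uptake) minimizes uptake
            parsimonious=False,
        )
        if not sol.optimal:
            raise CalibrationError(
                f"model infeasible at fixed growth {mu}: {sol.status}"
            )
        ups.append(-sol.objective_value)
    x = np.asarray(growth_rates, dtype=float)
    y = np.asarray(ups)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, _), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope)


def fit_gam(
    model: MetabolicModel,
    target_slope: float,
    ngam: float,
    growth_rates: Sequence[float] = DEFAULT_GROWTH_RATES,
    bracket: Tuple[float, float] = (0.0, 5000.0),
    rel_tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Bisection on GAM until the model slope matches ``target_slope``.

    Raises if the target slope is below the zero-GAM model slope (the
    biosynthetic demand alone already exceeds it).
    """
    if target_slope <= 0:
        raise CalibrationError("target slope must be positive")
    base = set_maintenance(model, gam=bracket[0], ngam=ngam)
    s_lo = model_uptake_slope(base, growth_rates)
    if target_slope < s_lo * (1 - rel_tol):
        raise CalibrationError(
            f"slope unattainable: zero-GAM model slope {s_lo:.1f} exceeds "
            f"target {target_slope:.1f}"
        )
    lo, hi = bracket
    s_hi = model_uptake_slope(set_maintenance(model, gam=hi, ngam=ngam), growth_rates)
    if target_slope > s_hi:
        raise CalibrationError(
            f"target slope {target_slope:.1f} above bracket maximum {s_hi:.1f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s_mid = model_uptake_slope(
            set_maintenance(model, gam=mid, ngam=ngam), growth_rates
        )
        if abs(s_mid - target_slope) / target_slope <= rel_tol:
            return mid
        if s_mid < target_slope:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate(
    model: MetabolicModel,
    pairs: Sequence[RatePair],
    atp_yield: float,
    operating_point: Tuple[float, float] = (8.5, 0.006),
    growth_rates: Sequence[float] = DEFAULT_GROWTH_RATES,
) -> Tuple[MetabolicModel, CalibrationResult]:
    """Full maintenance calibration.

    NGAM from the regression intercept; the target slope from the
    chemostat operating point (uptake, growth) and that intercept; GAM
    by slope-matching bisection.  Returns the calibrated model and the
    result record.
    """
    ngam, intercept, slope_exp = fit_ngam(pairs, atp_yield)
    uptake_op, growth_op = operating_point
    target_slope = (uptake_op - intercept) / growth_op
    gam = fit_gam(model, target_slope, ngam, growth_rates)
    r2, rsd = fit_diagnostics(pairs, slope_exp, intercept)
    calibrated = set_maintenance(model, gam=gam, ngam=ngam)
    return calibrated, CalibrationResult(
        ngam=ngam,
        gam=gam,
        intercept_uptake=intercept,
        slope=slope_exp,
        r_squared=r2,
        residual_sd=rsd,
    )
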