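"""Simultaneous least-squares fitting of gradient models to timer data.

A model is fitted jointly to the green (sfGFP) intensity profile and the
red/green ratio profile along the axis.  The objective is

    r^2 = r^2_green + r^2_ratio,
    r^2_O = (1/N_O) * sum_i ((E_i - O_i) / <O>)^2,

with <O> the mean observed value of that observable -- the normalization
balances the two contributions and makes each component dimensionless
(a constant offset of one <O> per point gives r^2_O = 1).

Minimization uses a derivative-free Nelder-Mead simplex with multiple
restarts; fluorophore maturation half-times are drawn from their Gaussian
priors per restart.  Two parameters enter the prediction linearly -- the
green amplitude A and the red/green intensity scaling eps -- so they are
profiled out exactly by linear least squares inside every objective
evaluation (variable projection); the simplex explores only the model's
nonlinear parameters (e.g. D and the protein half-life for SDD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_models import (
    ModelParams, ModelSpec, make_model, default_params, MIN, LN2,
)
from .pde_engine import Grid, SolverError, simulate
from .timer_model import MaturationParams, TFTProfile, intensities_from_state

T_OBSERVE = 2.5 * 3600.0            # observation time (early n.c. 14)
FIT_WINDOW = (60.0, 450.0)          # um; excludes source cell and far boundary
FIT_GRID = Grid(500.0, 100)         # forward-model grid used inside fits

#: nonlinear fit parameters per model and their (log-uniform) bounds
FREE_PARAMS = {
    "SDD": {"D_protein": (0.1, 10.0), "protein_half_life": (10.0, 120.0)},
    "NucSh": {"D_protein": (0.1, 10.0), "k_on0": (2e-5, 2e-3)},
    "RNA-grad": {"rna_gradient_length": (20.0, 200.0),
                 "protein_half_life": (10.0, 120.0)},
    "RNA-diff": {"D_rna": (0.1, 10.0), "rna_half_life": (10.0, 120.0)},
}


class ObjectiveError(ValueError):
    pass


def objective(E: Dict[str, np.ndarray], O: Dict[str, np.ndarray]) -> dict:
    """Normalized squared residuals per observable plus their total.

    ``E`` and ``O`` map observable name -> values on identical grids.
    """
    comps = {}
    for name, obs in O.items():
        pred = np.asarray(E[name], dtype=float)
        obs = np.asarray(obs, dtype=float)
        if pred.shape != obs.shape:
            raise ObjectiveError(
                f"{name}: prediction grid {pred.shape} != observation grid "
                f"{obs.shape}")
        mean_obs = obs.mean()
        if mean_obs == 0:
            raise ObjectiveError(f"{name}: mean observed value is zero")
        comps[name] = float(np.mean(((pred - obs) / mean_obs) ** 2))
    comps["total"] = sum(v for k, v in comps.items() if k != "total")
    return comps


@dataclass
class FitResult:
    model: str
    params: dict                 # all parameter values at the optimum
    free: tuple                  # names of the simplex (nonlinear) parameters
    r2: float
    r2_green: float
    r2_ratio: float
    n_green: int
    n_ratio: int
    n_evaluations: int
    converged: bool
    maturation: MaturationParams
    amplitude: float = 1.0
    eps: float = 1.0
    restarts: list = field(default_factory=list)   # (r2, params) per restart

    def to_dict(self) -> dict:
        return {
            "model": self.model, "params": self.params,
            "free": list(self.free), "r2": self.r2,
            "r2_green": self.r2_green, "r2_ratio": self.r2_ratio,
            "n_green": self.n_green, "n_ratio": self.n_ratio,
            "n_evaluations": self.n_evaluations, "converged": self.converged,
            "amplitude": self.amplitude, "eps": self.eps,
            "maturation_half_times": [self.maturation.green_half_time,
                                      self.maturation.red_half_time_1,
                                      self.maturation.red_half_time_2],
        }


def _params_for(model: str, values: dict) -> ModelParams:
    base = default_params(model)
    for key, val in values.items():
        setattr(base, key, float(val))
    return base


def _mask(data: TFTProfile, window) -> tuple:
    lo, hi = window
    in_win = (data.positions >= lo) & (data.positions <= hi)
    green_ok = in_win & np.isfinite(data.green)
    ratio_ok = in_win & np.isfinite(data.ratio)
    return green_ok, ratio_ok


def predict_observables(model: str, values: dict,
                        maturation: MaturationParams,
                        data_positions: np.ndarray,
                        grid: Grid = FIT_GRID,
                        t: float = T_OBSERVE) -> tuple:
    """Unit-amplitude green shape and unit-eps ratio shape on data positions."""
    spec = make_model(model, _params_for(model, values))
    state = simulate(spec, grid, t_end=t, dt_out=t, maturation=maturation)[-1]
    prof = intensities_from_state(state, eps=1.0)
    green = np.interp(data_positions, prof.positions, prof.green)
    ratio = np.interp(data_positions, prof.positions, prof.ratio)
    return green, ratio


def _profiled_objective(model: str, values: dict,
                        maturation: MaturationParams, data: TFTProfile,
                        window, grid: Grid, t: float,
                        eps_fixed=None) -> tuple:
    """Objective with A (and eps, unless pinned) solved exactly."""
    green_ok, ratio_ok = _mask(data, window)
    g_shape_all, r_shape_all = predict_observables(
        model, values, maturation, data.positions, grid, t)
    g_shape = g_shape_all[green_ok]
    r_shape = r_shape_all[ratio_ok]
    o_green = data.green[green_ok]
    o_ratio = data.ratio[ratio_ok]
    denom_g = float(np.dot(g_shape, g_shape))
    denom_r = float(np.dot(r_shape, r_shape))
    if denom_g == 0 or denom_r == 0 or not (np.isfinite(denom_g) and
                                            np.isfinite(denom_r)):
        return math.inf, math.nan, math.nan, math.nan, math.nan
    A = float(np.dot(g_shape, o_green)) / denom_g
    eps = (float(np.dot(r_shape, o_ratio)) / denom_r
           if eps_fixed is None else float(eps_fixed))
    comps = objective({"green": A * g_shape, "ratio": eps * r_shape},
                      {"green": o_green, "ratio": o_ratio})
    return comps["total"], comps["green"], comps["ratio"], A, eps


def fit_model(model: str, data: TFTProfile,
              maturation_prior: Optional[MaturationParams] = None,
              n_restarts: int = 16, seed: int = 0,
              free_params: Optional[dict] = None,
              x0: Optional[dict] = None, eps_fixed: Optional[float] = None,
              window=FIT_WINDOW, grid: Grid = FIT_GRID,
              t: float = T_OBSERVE,
              fatol: float = 1e-8, xatol: float = 1e-6,
              maxfev: int = 120) -> FitResult:
    """Fit a model simultaneously to the green profile and red/green ratio.

    Per restart the maturation half-times are drawn from their Gaussian
    priors (restart 0 uses the prior means) and a Nelder-Mead simplex runs
    over the model's nonlinear parameters, starting from ``x0`` (restart 0,
    if given) or a log-uniform draw within the physiological bounds.  The
    green amplitude and the red/green scaling eps are free parameters fitted
    exactly at every evaluation; ``eps_fixed`` pins eps to a known value
    instead (when the channel scaling has been calibrated, the absolute
    ratio level directly constrains the degradation rate).  Deterministic
    for fixed seed and restarts.
    """
    if model not in FREE_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    bounds = free_params or FREE_PARAMS[model]
    names = tuple(bounds)
    maturation_prior = maturation_prior or MaturationParams.preset("sfGFP-mCherry")
    green_ok, ratio_ok = _mask(data, window)
    if green_ok.sum() < len(names) + 2 or ratio_ok.sum() < len(names) + 2:
        raise ValueError("too few usable data points in the fitting window")

    rng = np.random.default_rng(seed)
    nfev_total = 0
    best = None
    restart_log = []
    for restart in range(n_restarts):
        mat = (maturation_prior if restart == 0
               else maturation_prior.draw(rng))
        if restart == 0 and x0 is not None:
            start = np.array([math.log(x0[n]) for n in names])
        else:
            start = np.array([rng.uniform(math.log(lo), math.log(hi))
                              for lo, hi in bounds.values()])

        def fun(logv):
            values = {n: math.exp(v) for n, v in zip(names, logv)}
            # physiological bounds are hard constraints
            for (lo, hi), v in zip(bounds.values(), values.values()):
                if not (lo <= v <= hi):
                    return 1e6
            try:
                total, *_ = _profiled_objective(
                    model, values, mat, data, window, grid, t,
                    eps_fixed=eps_fixed)
            except (SolverError, ValueError):
                return 1e6
            return total if math.isfinite(total) else 1e6

        res = minimize(fun, start, method="Nelder-Mead",
                       options={"fatol": fatol, "xatol": xatol,
                                "maxfev": maxfev})
        nfev_total += res.nfev
        values = {n: math.exp(v) for n, v in zip(names, res.x)}
        total, r2g, r2r, A, eps = _profiled_objective(
            model, values, mat, data, window, grid, t, eps_fixed=eps_fixed)
        restart_log.append((total, values))
        if best is None or total < best[0]:
            best = (total, r2g, r2r, A, eps, values, mat, bool(res.success))

    total, r2g, r2r, A, eps, values, mat, conv = best
    if not math.isfinite(total):
        raise RuntimeError(
            f"all {n_restarts} restarts failed for model {model}; "
            f"restart objectives: {[r[0] for r in restart_log]}")
    all_params = _params_for(model, values).to_dict()
    return FitResult(
        model=model, params=all_params, free=names, r2=total,
        r2_green=r2g, r2_ratio=r2r,
        n_green=int(green_ok.sum()), n_ratio=int(ratio_ok.sum()),
        n_evaluations=nfev_total, converged=conv, maturation=mat,
        amplitude=A, eps=eps, restarts=restart_log)


# ---------------------------------------------------------------------------
# (D, half-life) grid scans and envelope interval estimates
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    D_grid: np.ndarray            # um^2/s
    half_life_grid: np.ndarray    # min
    score: np.ndarray             # r^2 per (D, t_half) cell; NaN on cell failure
    lam: np.ndarray               # implied steady-state decay length (um)
    contours: dict                # lambda -> (D array, t_half array)
    errors: dict                  # (i, j) -> message for failed cells


def decay_length(D: float, half_life_min: float) -> float:
    """Steady-state SDD decay length sqrt(D * t_half / ln2), t_half in min."""
    return math.sqrt(D * half_life_min * MIN / LN2)


def iso_lambda_contour(lam: float, D_grid: np.ndarray) -> np.ndarray:
    """Half-life (min) along the curve D * t_half / ln2 = lambda^2."""
    return lam ** 2 * LN2 / (np.asarray(D_grid, dtype=float) * MIN)


def grid_scan(data: TFTProfile, D_grid: Sequence[float],
              half_life_grid: Sequence[float],
              maturation: Optional[MaturationParams] = None,
              model: str = "SDD", window=FIT_WINDOW,
              grid: Grid = FIT_GRID, t: float = T_OBSERVE,
              contour_lambdas=(75.0, 95.0)) -> ScanResult:
    """Fit quality over a (D, half-life) grid with A and eps free per cell."""
    D_grid = np.asarray(D_grid, dtype=float)
    half_life_grid = np.asarray(half_life_grid, dtype=float)
    maturation = maturation or MaturationParams.preset("sfGFP-mCherry")
    score = np.full((D_grid.size, half_life_grid.size), np.nan)
    errors = {}
    for i, D in enumerate(D_grid):
        for j, th in enumerate(half_life_grid):
            try:
                total, *_ = _profiled_objective(
                    model, {"D_protein": D, "protein_half_life": th},
                    maturation, data, window, grid, t)
                score[i, j] = total
            except (SolverError, ValueError) as e:
                errors[(i, j)] = str(e)
    lam = np.sqrt(np.outer(D_grid, half_life_grid) * MIN / LN2)
    contours = {l: (D_grid.copy(), iso_lambda_contour(l, D_grid))
                for l in contour_lambdas}
    return ScanResult(D_grid, half_life_grid, score, lam, contours, errors)


def interval_estimates(scan: ScanResult, tolerance: float = 0.1) -> dict:
    """Parameter envelopes over cells scoring within (1+tolerance) of the best.

    Returns D, half-life and implied decay-length ranges plus the argmin cell.
    The argmin cell is always included, so the envelope is never empty.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    score = scan.score
    if np.all(np.isnan(score)):
        raise ValueError("scan contains no successful cells")
    best = np.nanmin(score)
    keep = score <= (1.0 + tolerance) * best
    ii, jj = np.nonzero(keep)
    D_sel = scan.D_grid[ii]
    th_sel = scan.half_life_grid[jj]
    lam_sel = scan.lam[keep]
    i0, j0 = np.unravel_index(np.nanargmin(score), score.shape)
    return {
        "D_range": (float(D_sel.min()), float(D_sel.max())),
        "half_life_range": (float(th_sel.min()), float(th_sel.max())),
        "lambda_range": (float(lam_sel.min()), float(lam_sel.max())),
        "best": {"D": float(scan.D_grid[i0]),
                 "half_life": float(scan.half_life_grid[j0]),
                 "score": float(best)},
        "n_cells": int(keep.sum()),
    }
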