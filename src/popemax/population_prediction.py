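"""Monte Carlo calibration of the population-steepness formula.

The population-averaged concentration-effect curve cannot be derived in
closed form when C50 and gamma vary log-normally between individuals.  This
module generates large simulated populations, averages their individual
sigmoid Emax curves, fits a single Emax (or cumulative log-normal) curve to
the average, and calibrates the constants of the variance-summation formula
for ``sigma*^2`` against a full factorial grid of (gamma, omega_c50,
omega_gamma) combinations.

The factorial calibration grid reproduces the study conditions: 9 gamma
values x 6 omega_c50 values x 6 omega_gamma values = 324 cells, 10,000
simulated individuals per cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit, ndtr

from .pd_models import (
    LOGISTIC_A,
    GridSpec,
    IIVSpec,
    PDParams,
    PiConstants,
    concentration_grid,
    gamma_star,
    prob_emax,
)

__all__ = [
    "MCConfig",
    "IndividualParams",
    "PopulationCurve",
    "CurveFit",
    "simulate_individuals",
    "population_curve",
    "fit_population_curve",
    "run_grid",
    "fit_pi_constants",
    "rmse_report",
]

GAMMA_GRID_DEFAULT = (0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 30.0, 50.0)
OMEGA_GRID_DEFAULT = (0.0, 0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass(frozen=True)
class MCConfig:
    """Configuration of the factorial Monte Carlo calibration run."""

    n_individuals: int = 10_000
    gamma_grid: tuple = GAMMA_GRID_DEFAULT
    omega_c50_grid: tuple = OMEGA_GRID_DEFAULT
    omega_gamma_grid: tuple = OMEGA_GRID_DEFAULT
    c50: float = 1.0
    dichotomize: bool = False
    seed: int = 0
    grid_spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")

    @property
    def n_cells(self) -> int:
        return (
            len(self.gamma_grid)
            * len(self.omega_c50_grid)
            * len(self.omega_gamma_grid)
        )

    def cells(self):
        """Yield (index, gamma, omega_c50, omega_gamma) in factorial order."""
        idx = 0
        for g in self.gamma_grid:
            for w1 in self.omega_c50_grid:
                for w2 in self.omega_gamma_grid:
                    yield idx, g, w1, w2
                    idx += 1


@dataclass(frozen=True)
class IndividualParams:
    """Per-individual (c50_i, gamma_i) drawn from the log-normal IIV model."""

    c50_i: np.ndarray
    gamma_i: np.ndarray

    def __len__(self) -> int:
        return len(self.c50_i)


@dataclass(frozen=True)
class PopulationCurve:
    """Concentration grid plus probability averaged over individuals."""

    concentrations: np.ndarray
    mean_p: np.ndarray


@dataclass(frozen=True)
class CurveFit:
    """Least-squares fit of a single curve to a population average."""

    c50_hat: float
    steepness_hat: float  # gamma for "emax", sigma for "lognormal"
    sse: float
    model_tag: str
    converged: bool = True


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_individuals(
    params: PDParams, iiv: IIVSpec, n: int, seed
) -> IndividualParams:
    """Draw n individuals with multiplicative log-normal random effects.

    ``c50_i = C50 * exp(eta1)``, ``gamma_i = gamma * exp(eta2)`` with
    ``eta1 ~ N(0, omega_c50)`` and ``eta2 ~ N(0, omega_gamma)`` (omegas are
    variances).  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eta1 = rng.standard_normal(n) * math.sqrt(iiv.omega_c50)
    eta2 = rng.standard_normal(n) * math.sqrt(iiv.omega_gamma)
    return IndividualParams(
        c50_i=params.c50 * np.exp(eta1), gamma_i=params.gamma * np.exp(eta2)
    )


def population_curve(
    individuals: IndividualParams,
    grid: np.ndarray,
    dichotomize: bool = False,
    seed=None,
) -> PopulationCurve:
    """Average the individual Emax curves over the population.

    ``mean_p[k]`` is the mean over individuals of their sigmoid Emax
    probability at ``grid[k]``.  With ``dichotomize`` each individual
    probability is first converted to a Bernoulli draw (presence/absence of
    effect); averaging the draws estimates the same curve with extra
    binomial noise, so dichotomization is off by default.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or len(individuals) == 0:
        raise ValueError("grid and individuals must be nonempty")
    log_ratio = np.log(grid)[None, :] - np.log(individuals.c50_i)[:, None]
    p = expit(individuals.gamma_i[:, None] * log_ratio)
    if dichotomize:
        rng = np.random.default_rng(seed)
        p = (rng.random(p.shape) < p).astype(float)
    return PopulationCurve(concentrations=grid, mean_p=p.mean(axis=0))


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def _model_p(log_c: np.ndarray, ln_c50: float, ln_steep: float, tag: str):
    if tag == "emax":
        return expit(math.exp(ln_steep) * (log_c - ln_c50))
    if tag == "lognormal":
        return ndtr((log_c - ln_c50) / math.exp(ln_steep))
    raise ValueError(f"unknown model_tag {tag!r}")


def fit_population_curve(curve: PopulationCurve, model_tag: str = "emax") -> CurveFit:
    """Least-squares (C50, steepness) fit to a population-averaged curve.

    Minimizes the unweighted sum of squared differences between the model
    and ``mean_p`` over all grid points, parameterized in (ln C50,
    ln steepness) for positivity, with a small multistart over the initial
    steepness to avoid local minima at high gamma.
    """
    log_c = np.log(curve.concentrations)
    y = np.asarray(curve.mean_p, dtype=float)
    if y.size < 3 or y.min() > 0.5 or y.max() < 0.5:
        raise ValueError("curve must have >= 3 points spanning P = 0.5")

    # grid-implied initials: C50 where the curve crosses 0.5, steepness from
    # the logit (or probit) slope against ln C
    ln_c50_0 = float(np.interp(0.5, y, log_c))
    yc = np.clip(y, 1e-6, 1 - 1e-6)
    z = np.log(yc / (1 - yc))
    slope = float(np.polyfit(log_c, z, 1)[0])
    steep0 = slope if model_tag == "emax" else LOGISTIC_A / max(slope, 1e-6)
    steep0 = min(max(steep0, 1e-3), 1e3)

    best = None
    for mult in (1.0, 0.5, 2.0):
        try:
            res = least_squares(
                lambda x: _model_p(log_c, x[0], x[1], model_tag) - y,
                x0=[ln_c50_0, math.log(steep0 * mult)],
                method="lm",
            )
        except Exception:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return CurveFit(math.nan, math.nan, math.inf, model_tag, converged=False)
    sse, res = best
    return CurveFit(
        c50_hat=float(math.exp(res.x[0])),
        steepness_hat=float(math.exp(res.x[1])),
        sse=sse,
        model_tag=model_tag,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Factorial grid
# ---------------------------------------------------------------------------

def run_grid(config: MCConfig, constants: PiConstants = PiConstants()) -> pd.DataFrame:
    """Run the factorial Monte Carlo grid and fit each population curve.

    For each (gamma, omega_c50, omega_gamma) cell: predict (gamma*, sigma*)
    from the current formula constants, build the log-spaced concentration
    grid from gamma*, simulate ``n_individuals`` parameter sets, average
    their curves, and fit both the Emax and the log-normal model.  Each cell
    uses an independent, reproducible random substream derived from
    ``(seed, cell index)``.

    Returns a table with one row per cell: gamma, omega_c50, omega_gamma,
    gamma_mc, sigma_mc, gamma_star, sigma_star, pct_diff_gamma,
    pct_diff_sigma (percent difference of formula vs Monte Carlo fit).
    """
    rows = []
    for idx, g, w1, w2 in config.cells():
        iiv = IIVSpec(omega_c50=w1, omega_gamma=w2)
        star = gamma_star(g, iiv, constants)
        grid = concentration_grid(config.c50, star.gamma_star, config.grid_spec)
        cell_seed = np.random.SeedSequence(config.seed, spawn_key=(idx,))
        ind = simulate_individuals(
            PDParams(config.c50, g), iiv, config.n_individuals, cell_seed
        )
        curve = population_curve(
            ind,
            grid,
            dichotomize=config.dichotomize,
            seed=np.random.SeedSequence(config.seed, spawn_key=(idx, 1)),
        )
        fit_e = fit_population_curve(curve, "emax")
        fit_l = fit_population_curve(curve, "lognormal")
        rows.append(
            {
                "gamma": g,
                "omega_c50": w1,
                "omega_gamma": w2,
                "gamma_mc": fit_e.steepness_hat,
                "sigma_mc": fit_l.steepness_hat,
                "c50_mc": fit_e.c50_hat,
                "gamma_star": star.gamma_star,
                "sigma_star": star.sigma_star,
                "pct_diff_gamma": 100.0
                * (star.gamma_star - fit_e.steepness_hat)
                / fit_e.steepness_hat,
                "pct_diff_sigma": 100.0
                * (star.sigma_star - fit_l.steepness_hat)
                / fit_l.steepness_hat,
                "converged": fit_e.converged and fit_l.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibrating the formula constants
# ---------------------------------------------------------------------------

def _sigma_star_sq_formula(p: np.ndarray, g, w1, w2):
    s2 = (LOGISTIC_A / g) ** 2
    return (
        p[0] * s2 / g ** p[4]
        + p[1] * w1 / g ** p[5]
        + p[2] * w2 / g ** p[6]
        + p[3] * w1 * w2 / g ** p[7]
    )


def _loglinear(y: np.ndarray, ln_g: np.ndarray):
    """Fit ln y = ln coeff - power * ln gamma; returns (coeff, power >= 0)."""
    keep = y > 0
    if keep.sum() < 2 or np.ptp(ln_g[keep]) == 0:
        return float(np.exp(np.mean(np.log(y[keep])))) if keep.any() else 0.0, 0.0
    power, intercept = np.polyfit(-ln_g[keep], np.log(y[keep]), 1)
    return float(np.exp(intercept)), float(max(power, 0.0))


def _stepwise_init(table: pd.DataFrame) -> np.ndarray:
    """Stepwise initial values for the formula constants.

    Each step isolates one variance term by restricting to grid cells where
    the other terms vanish, then solves the coefficient and gamma power by
    log-linear regression of the Monte Carlo residual variance on ln gamma:
    (1) p1, p5 from the no-IIV cells; (2) p2, p6 adding omega_c50; (3) p3, p7
    adding omega_gamma; (4) p4, p8 from the cells with both omegas nonzero.
    """
    g = table["gamma"].to_numpy()
    w1 = table["omega_c50"].to_numpy()
    w2 = table["omega_gamma"].to_numpy()
    s2_mc = (LOGISTIC_A / table["gamma_mc"].to_numpy()) ** 2
    ln_g = np.log(g)
    s2_ind = (LOGISTIC_A / g) ** 2
    p = np.zeros(8)

    m = (w1 == 0) & (w2 == 0)
    p[0], p[4] = _loglinear(s2_mc[m] / s2_ind[m], ln_g[m])

    m = (w1 > 0) & (w2 == 0)
    if m.any():
        resid = s2_mc[m] - p[0] * s2_ind[m] / g[m] ** p[4]
        p[1], p[5] = _loglinear(np.maximum(resid, 0) / w1[m], ln_g[m])

    m = (w1 == 0) & (w2 > 0)
    if m.any():
        resid = s2_mc[m] - p[0] * s2_ind[m] / g[m] ** p[4]
        p[2], p[6] = _loglinear(np.maximum(resid, 0) / w2[m], ln_g[m])

    m = (w1 > 0) & (w2 > 0)
    if m.any():
        resid = (
            s2_mc[m]
            - p[0] * s2_ind[m] / g[m] ** p[4]
            - p[1] * w1[m] / g[m] ** p[5]
            - p[2] * w2[m] / g[m] ** p[6]
        )
        p[3], p[7] = _loglinear(np.maximum(resid, 0) / (w1[m] * w2[m]), ln_g[m])
    return p


def _joint_refit(table: pd.DataFrame, p0: np.ndarray) -> np.ndarray:
    """Minimize sum of squared log differences between formula and MC gamma*."""
    g = table["gamma"].to_numpy()
    w1 = table["omega_c50"].to_numpy()
    w2 = table["omega_gamma"].to_numpy()
    ln_gmc = np.log(table["gamma_mc"].to_numpy())

    def objective(p):
        s2 = _sigma_star_sq_formula(p, g, w1, w2)
        ln_gs = math.log(LOGISTIC_A) - 0.5 * np.log(s2)
        return float(np.sum((ln_gs - ln_gmc) ** 2))

    res = minimize(
        objective,
        x0=np.clip(p0, 0.0, None),
        method="L-BFGS-B",
        bounds=[(0.0, None)] * 8,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return res.x


def fit_pi_constants(
    grid_results: pd.DataFrame,
    config: MCConfig | None = None,
    rel_tol: float = 1e-3,
    max_outer: int = 6,
) -> PiConstants:
    """Estimate the variance-summation constants from a calibration grid.

    A stepwise pass provides initial values, followed by a joint fit of all
    eight constants minimizing the sum of squared differences between the
    logarithms of the formula gamma* and the fitted Monte Carlo gamma.  The
    concentration grids used in the simulation themselves depend on gamma*
    (hence on the constants), so when ``config`` is given the grid is
    regenerated with the updated constants and the fit repeated until every
    constant changes by less than ``rel_tol`` relative (outer iteration);
    without ``config`` a single fit on the supplied table is returned.
    """
    w_varies = (grid_results["omega_c50"] > 0).any() or (
        grid_results["omega_gamma"] > 0
    ).any()
    if not w_varies:
        warnings.warn(
            "grid has no IIV variation: only p1 and p5 are identifiable; "
            "p2..p4 and p6..p8 fixed at 0",
            stacklevel=2,
        )
        p = _stepwise_init(grid_results)
        return PiConstants.from_array(p)

    table = grid_results
    p = _joint_refit(table, _stepwise_init(table))
    if config is None:
        return PiConstants.from_array(p)

    for _ in range(max_outer):
        constants = PiConstants.from_array(p)
        table = run_grid(config, constants)
        p_new = _joint_refit(table, p)
        scale = np.maximum(np.abs(p), 1e-3)
        if np.max(np.abs(p_new - p) / scale) < rel_tol:
            p = p_new
            break
        p = p_new
    return PiConstants.from_array(p)


def rmse_report(grid_results: pd.DataFrame, column: str = "pct_diff_gamma") -> dict:
    """RMSE and range of the percent-difference column of a grid run."""
    if grid_results.empty:
        raise ValueError("grid_results is empty")
    d = grid_results[column].to_numpy(dtype=float)
    return {
        "rmse_pct": float(np.sqrt(np.mean(d**2))),
        "min_pct": float(d.min()),
        "max_pct": float(d.max()),
    }
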