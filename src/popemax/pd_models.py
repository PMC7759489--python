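"""Closed-form pharmacodynamic probability models and population steepness.

The sigmoid Emax (Hill) model ``P = C^g / (C50^g + C^g)`` and the cumulative
log-normal model ``P = Phi((ln C - ln C50)/sigma)`` are nearly identical
curves; the logistic approximation of the normal CDF with constant
``a = 1.7`` links their steepness parameters via ``gamma = 1.7 / sigma``.

When the individual parameters C50 and gamma carry log-normal
inter-individual variability (IIV) with variances ``omega_c50`` and
``omega_gamma``, the population-averaged concentration-effect curve is
shallower than any individual's.  Its steepness ``gamma*`` is predicted by an
empirical variance-summation formula

    sigma*^2 = sigma^2 + omega_c50 + 1.25 * omega_gamma / gamma^2
               + 2.5 * omega_c50 * omega_gamma / gamma
    gamma*   = 1.7 / sigma*

whose constants are calibrated by Monte Carlo simulation (see
:mod:`popemax.population_prediction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, ndtr

#: Logistic approximation constant for the standard normal CDF.  The minimax
#: optimum is 1.702 (see :func:`calibrate_logistic_constant`); 1.7 is accurate
#: enough for all conversions and is used throughout.
LOGISTIC_A = 1.7

__all__ = [
    "LOGISTIC_A",
    "PDParams",
    "IIVSpec",
    "PiConstants",
    "PopulationSteepness",
    "GridSpec",
    "prob_emax",
    "prob_lognormal",
    "prob_logistic",
    "sigma_from_gamma",
    "gamma_from_sigma",
    "calibrate_logistic_constant",
    "sigma_star_sq",
    "gamma_star",
    "concentration_grid",
    "max_delta_p",
]


@dataclass(frozen=True)
class PDParams:
    """Typical-individual model parameters.

    Parameters
    ----------
    c50
        Effect-site concentration giving P = 0.5 (arbitrary units, > 0).
    gamma
        Dimensionless steepness (Hill coefficient, > 0).
    """

    c50: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.c50 > 0:
            raise ValueError(f"c50 must be positive, got {self.c50}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @property
    def sigma(self) -> float:
        """Equivalent log-normal SD, ``1.7 / gamma``."""
        return sigma_from_gamma(self.gamma)

    @classmethod
    def from_sigma(cls, c50: float, sigma: float) -> "PDParams":
        return cls(c50=c50, gamma=gamma_from_sigma(sigma))


@dataclass(frozen=True)
class IIVSpec:
    """Inter-individual variances of the log-scale random effects.

    ``omega_c50`` and ``omega_gamma`` are variances (the NONMEM "omega"
    convention), not standard deviations.
    """

    omega_c50: float = 0.0
    omega_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_c50 < 0 or self.omega_gamma < 0:
            raise ValueError("omega variances must be nonnegative")


@dataclass(frozen=True)
class PiConstants:
    """Constants of the variance-summation formula for ``sigma*^2``.

    Defaults are the calibrated, rounded values (1, 1, 1.25, 2.5, 0, 0, 2, 1):
    p1..p4 are coefficients of the four variance terms, p5..p8 the powers of
    gamma dividing each term.
    """

    p1: float = 1.0
    p2: float = 1.0
    p3: float = 1.25
    p4: float = 2.5
    p5: float = 0.0
    p6: float = 0.0
    p7: float = 2.0
    p8: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p1, self.p2, self.p3, self.p4, self.p5, self.p6, self.p7, self.p8]
        )

    @classmethod
    def from_array(cls, p: np.ndarray) -> "PiConstants":
        return cls(*(float(v) for v in p))


@dataclass(frozen=True)
class PopulationSteepness:
    """Steepness of the population-averaged curve, both parameterizations."""

    gamma_star: float
    sigma_star: float


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced concentration grid covering P from p_edge to 1 - p_edge.

    The grid has ``2 * n_half + 1`` points, symmetric about C50 on the log
    scale; under the population curve (c50, gamma*) the outermost points sit
    exactly at probabilities ``p_edge`` and ``1 - p_edge``.
    """

    p_edge: float = 0.01
    n_half: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.p_edge < 0.5:
            raise ValueError("p_edge must be in (0, 0.5)")
        if self.n_half < 1:
            raise ValueError("n_half must be a positive integer")


# ---------------------------------------------------------------------------
# Probability models
# ---------------------------------------------------------------------------

def prob_emax(c, c50: float, gamma: float):
    """Sigmoid Emax probability ``C^g / (C50^g + C^g)``.

    Evaluated as ``expit(gamma * (ln C - ln C50))`` for numerical stability
    at large gamma.  ``c = 0`` returns exactly 0 (the limit).
    """
    if not c50 > 0:
        raise ValueError("c50 must be positive")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    with np.errstate(divide="ignore"):
        p = expit(gamma * (np.log(c) - math.log(c50)))
    p = np.where(c == 0, 0.0, p)
    return p if p.ndim else float(p)


def prob_lognormal(c, c50: float, sigma: float):
    """Cumulative log-normal probability ``Phi((ln C - ln C50)/sigma)``."""
    if not c50 > 0:
        raise ValueError("c50 must be positive")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    with np.errstate(divide="ignore"):
        p = ndtr((np.log(c) - math.log(c50)) / sigma)
    p = np.where(c == 0, 0.0, p)
    return p if p.ndim else float(p)


def prob_logistic(z, a: float = LOGISTIC_A):
    """Logistic approximation ``1 / (1 + exp(-a z))`` of the normal CDF."""
    if not a > 0:
        raise ValueError("a must be positive")
    p = expit(a * np.asarray(z, dtype=float))
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# Steepness conversions
# ---------------------------------------------------------------------------

def sigma_from_gamma(gamma: float) -> float:
    """Convert Hill steepness to log-normal SD: ``sigma = 1.7 / gamma``."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return LOGISTIC_A / gamma


def gamma_from_sigma(sigma: float) -> float:
    """Convert log-normal SD to Hill steepness: ``gamma = 1.7 / sigma``."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return LOGISTIC_A / sigma


def calibrate_logistic_constant(
    z_max: float = 10.0, n_z: int = 20001
) -> float:
    """Best logistic constant ``a`` for approximating the normal CDF.

    Minimizes the maximum absolute deviation ``|expit(a z) - Phi(z)|`` over
    ``z in [-z_max, z_max]`` (minimax criterion): coarse grid over
    ``a in [1.5, 1.9]`` followed by bounded scalar refinement.  Returns
    approximately 1.702.
    """
    # both curves are antisymmetric about z = 0, so z >= 0 suffices
    z = np.linspace(0.0, z_max, n_z)
    phi = ndtr(z)

    def max_dev(a: float) -> float:
        return float(np.max(np.abs(expit(a * z) - phi)))

    a_grid = np.linspace(1.5, 1.9, 81)
    a0 = a_grid[int(np.argmin([max_dev(a) for a in a_grid]))]
    res = minimize_scalar(
        max_dev, bounds=(a0 - 0.01, a0 + 0.01), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Population steepness formula
# ---------------------------------------------------------------------------

def sigma_star_sq(
    params: PDParams, iiv: IIVSpec, constants: PiConstants = PiConstants()
) -> float:
    """Population variance ``sigma*^2`` from the variance-summation formula.

    General form::

        sigma*^2 = p1 * sigma^2 / gamma^p5 + p2 * omega_c50 / gamma^p6
                   + p3 * omega_gamma / gamma^p7
                   + p4 * omega_c50 * omega_gamma / gamma^p8

    With the default constants this is
    ``sigma^2 + omega_c50 + 1.25 omega_gamma / gamma^2
    + 2.5 omega_c50 omega_gamma / gamma``.
    """
    g = params.gamma
    s2 = params.sigma**2
    k = constants
    return (
        k.p1 * s2 / g**k.p5
        + k.p2 * iiv.omega_c50 / g**k.p6
        + k.p3 * iiv.omega_gamma / g**k.p7
        + k.p4 * iiv.omega_c50 * iiv.omega_gamma / g**k.p8
    )


def gamma_star(
    gamma: float,
    iiv: IIVSpec,
    constants: PiConstants = PiConstants(),
    c50: float = 1.0,
) -> PopulationSteepness:
    """Population steepness ``gamma* = 1.7 / sigma*`` for a typical gamma.

    Equals ``gamma`` exactly when both omegas are zero; strictly smaller as
    soon as any IIV is present.
    """
    s2 = sigma_star_sq(PDParams(c50=c50, gamma=gamma), iiv, constants)
    sigma_s = math.sqrt(s2)
    return PopulationSteepness(
        gamma_star=LOGISTIC_A / sigma_s, sigma_star=sigma_s
    )


# ---------------------------------------------------------------------------
# Concentration grid
# ---------------------------------------------------------------------------

def concentration_grid(
    c50: float, gamma_star_value: float, spec: GridSpec = GridSpec()
) -> np.ndarray:
    """Log-spaced concentrations ``C_i = C50 exp(i ln(1/p - 1) / (n g*))``.

    ``i`` runs from ``-n_half`` to ``+n_half``; by construction the
    population-curve probability at the first and last point is ``p_edge``
    and ``1 - p_edge``.
    """
    if not c50 > 0 or not gamma_star_value > 0:
        raise ValueError("c50 and gamma_star must be positive")
    spec = spec if isinstance(spec, GridSpec) else GridSpec(*spec)
    i = np.arange(-spec.n_half, spec.n_half + 1)
    step = math.log(1.0 / spec.p_edge - 1.0) / (spec.n_half * gamma_star_value)
    return c50 * np.exp(i * step)


def max_delta_p(
    gamma_star_value: float,
    sigma_star_value: float,
    c50: float = 1.0,
    n_points: int = 2001,
    return_profile: bool = False,
):
    """Maximum absolute difference between the Emax and log-normal curves.

    Evaluates both curves with the given population steepness on a dense
    log-spaced concentration grid spanning Emax probabilities 0.001 to 0.999
    and returns ``max |P_emax - P_lognormal|`` (optionally with the signed
    difference profile for inspecting its zero crossings).
    """
    if not gamma_star_value > 0 or not sigma_star_value > 0:
        raise ValueError("steepness values must be positive")
    lo = c50 * (0.001 / 0.999) ** (1.0 / gamma_star_value)
    hi = c50 * (0.999 / 0.001) ** (1.0 / gamma_star_value)
    c = np.geomspace(lo, hi, n_points)
    delta = prob_emax(c, c50, gamma_star_value) - prob_lognormal(
        c, c50, sigma_star_value
    )
    if return_profile:
        return float(np.max(np.abs(delta))), c, delta
    return float(np.max(np.abs(delta)))
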