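"""Maximum-likelihood estimation of the sigmoid Emax model from trial data.

Two estimators are provided:

* **Naive pooling** — all observations are treated as coming from one
  individual.  For binary data this is the Bernoulli likelihood of the Emax
  probability, algebraically identical to logistic regression on ln C
  (slope gamma, intercept -gamma ln C50); for continuous data it is a
  Gaussian likelihood with the residual SD profiled out (least squares).

* **Mixed effects** — log-normal random effects on C50 and/or gamma with
  variances omega; the marginal likelihood integrates each subject's random
  effects out via the Laplace approximation (second-order expansion of the
  joint log-density around the subject's empirical-Bayes mode, found by a
  safeguarded Newton iteration with analytic derivatives).  This mirrors
  conditional Laplace estimation for categorical likelihoods in standard
  nonlinear mixed-effects software.

Estimates are reported with NONMEM-style diagnostics: a convergence flag, a
"covariance step" analog (positive-definite, well-conditioned Hessian of
the objective at the optimum) and near-boundary flags for gamma and the
omega variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .pd_models import IIVSpec
from .trial_simulation import TrialDataset

__all__ = [
    "FitSpec",
    "FitResult",
    "negloglik_pooled",
    "fit_naive_pooled",
    "marginal_negloglik_laplace",
    "fit_mixed",
]

_P_CLAMP = 1e-12  # keeps separated binary data finite without moving interior optima
_OMEGA_FLOOR = 1e-10  # active variance floor; below this Laplace == pooled
_OMEGA_ZERO_TOL = 1e-6  # "near lower boundary" threshold for omega estimates


@dataclass(frozen=True)
class FitSpec:
    """Estimation settings: which IIV terms are active, bounds, tolerances."""

    iiv_c50: bool = False
    iiv_gamma: bool = False
    gamma_upper: float = 50.0
    gamma_lower: float = 0.01
    boundary_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.gamma_lower < self.gamma_upper:
            raise ValueError("gamma bounds must satisfy 0 < lower < upper")
        if not 0 < self.boundary_tolerance < 0.1:
            raise ValueError("boundary_tolerance must be in (0, 0.1)")


@dataclass(frozen=True)
class FitResult:
    """Point estimates with convergence and boundary diagnostics."""

    c50_hat: float
    gamma_hat: float
    omega_c50_hat: float | None
    omega_gamma_hat: float | None
    neg_loglik: float
    minimized: bool
    covariance_ok: bool
    boundary_flags: frozenset = frozenset()
    n_subjects: int = 0
    mode: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "c50_hat": self.c50_hat,
            "gamma_hat": self.gamma_hat,
            "omega_c50_hat": self.omega_c50_hat,
            "omega_gamma_hat": self.omega_gamma_hat,
            "neg_loglik": self.neg_loglik,
            "minimized": self.minimized,
            "covariance_ok": self.covariance_ok,
            "boundary_flags": sorted(self.boundary_flags),
            "n_subjects": self.n_subjects,
            "mode": self.mode,
        }


# ---------------------------------------------------------------------------
# Data access helpers
# ---------------------------------------------------------------------------

def _arrays(dataset: TrialDataset):
    df = dataset.data
    if len(df) == 0:
        raise ValueError("dataset is empty")
    conc = df["CONC"].to_numpy(dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    y = df["DV"].to_numpy(dtype=float)
    if dataset.kind == "binary" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary responses must be 0 or 1")
    return np.log(conc), y


def _subject_matrices(dataset: TrialDataset):
    """Per-subject (log conc, response) matrices; requires a rectangular design."""
    df = dataset.data
    counts = df.groupby("ID").size()
    if counts.nunique() != 1:
        raise ValueError("mixed-effects estimation requires equal observations per subject")
    k = int(counts.iloc[0])
    d = df.sort_values(["ID"], kind="stable")
    logc = np.log(d["CONC"].to_numpy(dtype=float)).reshape(-1, k)
    y = d["DV"].to_numpy(dtype=float).reshape(-1, k)
    return logc, y


# ---------------------------------------------------------------------------
# Naive pooling
# ---------------------------------------------------------------------------

def negloglik_pooled(c50: float, gamma: float, dataset: TrialDataset) -> float:
    """Negative log-likelihood ignoring inter-individual variability.

    Binary: Bernoulli with P from the Emax model, P clamped to
    [1e-12, 1 - 1e-12].  Continuous: Gaussian with the residual variance
    profiled out, ``n/2 (ln(2 pi sse/n) + 1)``.
    """
    if not c50 > 0 or not gamma > 0:
        raise ValueError("c50 and gamma must be positive")
    logc, y = _arrays(dataset)
    p = expit(gamma * (logc - math.log(c50)))
    if dataset.kind == "binary":
        p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
        return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    sse = float(np.sum((y - p) ** 2))
    n = len(y)
    return 0.5 * n * (math.log(2.0 * math.pi * max(sse, 1e-30) / n) + 1.0)


def _pooled_objective(theta, logc, y, binary: bool):
    """Objective and gradient in (ln c50, ln gamma)."""
    ln_c50, ln_g = theta
    g = math.exp(ln_g)
    x = g * (logc - ln_c50)
    p = expit(x)
    if binary:
        pc = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
        f = -np.sum(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
        r = p - y
        return float(f), np.array([-g * r.sum(), float(r @ x)])
    resid = p - y
    f = float(resid @ resid)
    w = resid * p * (1.0 - p)
    return f, np.array([-2.0 * g * w.sum(), 2.0 * float(w @ x)])


def fit_naive_pooled(
    dataset: TrialDataset, spec: FitSpec = FitSpec(), compute_covariance: bool = True
) -> FitResult:
    """Maximum-likelihood Emax fit treating all data as one individual.

    Optimizes over (ln C50, ln gamma) with bound-constrained quasi-Newton
    and a small multistart over the initial gamma.  Perfectly separated
    binary data drives gamma to the upper bound; the estimate is still
    reported with the boundary flag set.
    """
    logc, y = _arrays(dataset)
    binary = dataset.kind == "binary"
    if binary and (y.min() == y.max()):
        raise ValueError("binary dataset must contain both responses")

    # initial C50: where the mean response per concentration level crosses 0.5
    uniq, inv = np.unique(logc, return_inverse=True)
    level_mean = np.bincount(inv, weights=y) / np.bincount(inv)
    ln_c50_0 = float(np.interp(0.5, np.maximum.accumulate(level_mean), uniq))
    if not np.isfinite(ln_c50_0):
        ln_c50_0 = float(np.median(logc))
    bounds = [(None, None), (math.log(spec.gamma_lower), math.log(spec.gamma_upper))]

    best = None
    for g0 in (1.0, 5.0, 25.0):
        res = minimize(
            _pooled_objective,
            x0=[ln_c50_0, math.log(g0)],
            args=(logc, y, binary),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best

    c50_hat = math.exp(res.x[0])
    gamma_hat = math.exp(res.x[1])
    flags = _gamma_flags(gamma_hat, spec)
    nll = negloglik_pooled(c50_hat, gamma_hat, dataset)
    cov_ok = False
    if compute_covariance and res.success:
        hess = _numeric_hessian(
            lambda t: _pooled_objective(t, logc, y, binary)[0], res.x
        )
        cov_ok = _hessian_ok(hess) and not flags
    return FitResult(
        c50_hat=c50_hat,
        gamma_hat=gamma_hat,
        omega_c50_hat=None,
        omega_gamma_hat=None,
        neg_loglik=nll,
        minimized=bool(res.success),
        covariance_ok=cov_ok,
        boundary_flags=frozenset(flags),
        n_subjects=int(dataset.data["ID"].nunique()),
        mode="pooled",
    )


def _gamma_flags(gamma_hat: float, spec: FitSpec) -> set:
    flags = set()
    if gamma_hat >= spec.gamma_upper * (1.0 - spec.boundary_tolerance):
        flags.add("gamma_upper")
    if gamma_hat <= spec.gamma_lower * (1.0 + spec.boundary_tolerance):
        flags.add("gamma_lower")
    return flags


def _numeric_hessian(fn, x, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((n, n))
    f0 = fn(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                fp = fn(x + _e(n, i, h[i]))
                fm = fn(x - _e(n, i, h[i]))
                hess[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
            else:
                fpp = fn(x + _e(n, i, h[i]) + _e(n, j, h[j]))
                fpm = fn(x + _e(n, i, h[i]) - _e(n, j, h[j]))
                fmp = fn(x - _e(n, i, h[i]) + _e(n, j, h[j]))
                fmm = fn(x - _e(n, i, h[i]) - _e(n, j, h[j]))
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4.0 * h[i] * h[j]
                )
    return hess


def _e(n, i, v):
    out = np.zeros(n)
    out[i] = v
    return out


def _hessian_ok(hess: np.ndarray, cond_max: float = 1e10) -> bool:
    try:
        eig = np.linalg.eigvalsh(hess)
    except np.linalg.LinAlgError:
        return False
    if eig.min() <= 0:
        return False
    return bool(eig.max() / eig.min() < cond_max)


# ---------------------------------------------------------------------------
# Laplace marginal likelihood (binary data)
# ---------------------------------------------------------------------------

def _joint_ll_terms(eta1, eta2, ln_c50, gamma, logc, y):
    """Per-subject Bernoulli log-likelihood and intermediates.

    eta1/eta2 are (S,) arrays of random effects on ln C50 and ln gamma;
    logc, y are (S, K) matrices.
    """
    g_i = gamma * np.exp(eta2)
    u = logc - ln_c50 - eta1[:, None]
    x = g_i[:, None] * u
    p = expit(x)
    pc = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
    ll = np.sum(y * np.log(pc) + (1.0 - y) * np.log1p(-pc), axis=1)
    return ll, p, x, g_i


def _laplace_subjects(ln_c50, gamma, omega1, omega2, logc, y,
                      max_iter: int = 60, gtol: float = 1e-8):
    """Laplace-approximate marginal log-likelihood, summed over subjects.

    Both random effects are always carried; an inactive/zero effect is given
    a variance at the numerical floor, which pins its mode at zero and makes
    the prior and curvature contributions cancel exactly, so the result
    reduces to the pooled likelihood in that coordinate.
    """
    s = logc.shape[0]
    w1 = max(omega1, _OMEGA_FLOOR)
    w2 = max(omega2, _OMEGA_FLOOR)
    eta1 = np.zeros(s)
    eta2 = np.zeros(s)

    def penalized_ll(e1, e2):
        ll, p, x, g_i = _joint_ll_terms(e1, e2, ln_c50, gamma, logc, y)
        pen = ll - e1**2 / (2.0 * w1) - e2**2 / (2.0 * w2)
        return pen, p, x, g_i

    f, p, x, g_i = penalized_ll(eta1, eta2)
    converged = True
    for _ in range(max_iter):
        r = y - p
        w = p * (1.0 - p)
        sum_r = r.sum(axis=1)
        g1 = -g_i * sum_r - eta1 / w1
        g2 = np.sum(r * x, axis=1) - eta2 / w2
        if max(np.abs(g1).max(), np.abs(g2).max()) < gtol:
            break
        # expected-information (Fisher) Hessian: negative definite by
        # construction, which keeps the Newton direction an ascent direction
        h11 = -(g_i**2 * w.sum(axis=1) + 1.0 / w1)
        h22 = -(np.sum(w * x**2, axis=1) + 1.0 / w2)
        h12 = g_i * np.sum(w * x, axis=1)
        det = h11 * h22 - h12**2
        d1 = -(h22 * g1 - h12 * g2) / det
        d2 = -(-h12 * g1 + h11 * g2) / det
        # trust region: random-effect modes live within a few prior SDs, so
        # clip oversized Newton steps (also prevents exp overflow)
        norm = np.hypot(d1, d2)
        shrink = np.minimum(1.0, 3.0 / np.maximum(norm, 1e-300))
        d1 = d1 * shrink
        d2 = d2 * shrink
        # backtracking on the penalized log-likelihood
        step = np.ones(s)
        for _ in range(30):
            f_new, p_new, x_new, gi_new = penalized_ll(
                eta1 + step * d1, eta2 + step * d2
            )
            worse = f_new < f - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        eta1 = eta1 + step * d1
        eta2 = eta2 + step * d2
        f, p, x, g_i = f_new, p_new, x_new, gi_new
    else:
        r = y - p
        g1 = -g_i * r.sum(axis=1) - eta1 / w1
        g2 = np.sum(r * x, axis=1) - eta2 / w2
        converged = bool(max(np.abs(g1).max(), np.abs(g2).max()) < 1e-4)

    # observed curvature at the mode for the Laplace determinant
    r = y - p
    w = p * (1.0 - p)
    h11 = -(g_i**2 * w.sum(axis=1)) - 1.0 / w1
    h22 = np.sum(r * x, axis=1) - np.sum(w * x**2, axis=1) - 1.0 / w2
    h12 = g_i * np.sum(w * x, axis=1) - g_i * r.sum(axis=1)
    det = h11 * h22 - h12**2
    bad = (det <= 0) | (h11 >= 0)
    if bad.any():  # fall back to the always-ND expected information
        h11f = -(g_i**2 * w.sum(axis=1) + 1.0 / w1)
        h22f = -(np.sum(w * x**2, axis=1) + 1.0 / w2)
        h12f = g_i * np.sum(w * x, axis=1)
        detf = h11f * h22f - h12f**2
        det = np.where(bad, detf, det)

    # log marginal = joint at mode + (d/2) ln 2pi - 1/2 ln det(-H),
    # with the joint including the N(0, omega) prior density
    prior_const = -0.5 * (math.log(2.0 * math.pi * w1) + math.log(2.0 * math.pi * w2))
    log_marg = f + prior_const + math.log(2.0 * math.pi) - 0.5 * np.log(det)
    return float(np.sum(log_marg)), converged


def marginal_negloglik_laplace(
    c50: float,
    gamma: float,
    omegas,
    dataset: TrialDataset,
    spec: FitSpec = FitSpec(iiv_c50=True),
) -> float:
    """Laplace-approximated marginal negative log-likelihood (binary data).

    ``omegas`` is an :class:`IIVSpec` or an ``(omega_c50, omega_gamma)``
    pair; only the effects activated in ``spec`` contribute (inactive ones
    are treated as zero-variance, i.e. integrated out trivially).  In the
    limit of vanishing variances this equals :func:`negloglik_pooled`.
    """
    if dataset.kind != "binary":
        raise ValueError("Laplace marginal likelihood is implemented for binary data")
    if not (spec.iiv_c50 or spec.iiv_gamma):
        raise ValueError("at least one IIV term must be active")
    if isinstance(omegas, IIVSpec):
        w1, w2 = omegas.omega_c50, omegas.omega_gamma
    else:
        w1, w2 = omegas
    if w1 < 0 or w2 < 0:
        raise ValueError("omegas must be nonnegative")
    w1 = w1 if spec.iiv_c50 else 0.0
    w2 = w2 if spec.iiv_gamma else 0.0
    logc, y = _subject_matrices(dataset)
    ll, _ = _laplace_subjects(math.log(c50), gamma, w1, w2, logc, y)
    return -ll


def fit_mixed(
    dataset: TrialDataset,
    spec: FitSpec = FitSpec(iiv_c50=True),
    compute_covariance: bool = True,
) -> FitResult:
    """Mixed-effects maximum-likelihood fit via the Laplace approximation.

    Outer optimization over (ln C50, ln gamma bounded, sqrt-omega for each
    active IIV term); the sqrt parameterization keeps variances nonnegative
    without hard constraints.  Variance estimates below 1e-6 are flagged as
    near the lower boundary; the covariance diagnostic requires a
    positive-definite, well-conditioned Hessian of the objective and no
    active boundary flag.
    """
    if dataset.kind != "binary":
        raise ValueError("mixed-effects estimation is implemented for binary data")
    if not (spec.iiv_c50 or spec.iiv_gamma):
        raise ValueError("activate at least one IIV term (or use fit_naive_pooled)")
    logc, y = _subject_matrices(dataset)
    pooled = fit_naive_pooled(dataset, spec, compute_covariance=False)

    active = [name for name, on in (("c50", spec.iiv_c50), ("gamma", spec.iiv_gamma)) if on]

    def unpack(theta):
        w1 = theta[2] ** 2 if spec.iiv_c50 else 0.0
        w2 = theta[2 + spec.iiv_c50] ** 2 if spec.iiv_gamma else 0.0
        return theta[0], math.exp(theta[1]), w1, w2

    inner_failed = [False]

    def objective(theta):
        ln_c50, gamma, w1, w2 = unpack(theta)
        ll, ok = _laplace_subjects(ln_c50, gamma, w1, w2, logc, y)
        if not ok:
            inner_failed[0] = True
        return -ll

    bounds = [(None, None), (math.log(spec.gamma_lower), math.log(spec.gamma_upper))]
    bounds += [(0.0, None)] * len(active)
    g0 = min(max(pooled.gamma_hat, spec.gamma_lower * 1.01), spec.gamma_upper * 0.99)

    best = None
    for s0 in (math.sqrt(0.1), math.sqrt(0.4)):
        x0 = [math.log(pooled.c50_hat), math.log(g0)] + [s0] * len(active)
        inner_failed[0] = False
        res = minimize(objective, x0=x0, method="L-BFGS-B", bounds=bounds)
        res.inner_failed = inner_failed[0]
        if best is None or res.fun < best.fun:
            best = res
    res = best

    ln_c50, gamma_hat, w1, w2 = unpack(res.x)
    flags = _gamma_flags(gamma_hat, spec)
    if spec.iiv_c50 and w1 < _OMEGA_ZERO_TOL:
        flags.add("omega_c50_zero")
    if spec.iiv_gamma and w2 < _OMEGA_ZERO_TOL:
        flags.add("omega_gamma_zero")

    minimized = bool(res.success) and not res.inner_failed
    cov_ok = False
    if compute_covariance and minimized:
        hess = _numeric_hessian(objective, res.x)
        cov_ok = _hessian_ok(hess) and not flags
    return FitResult(
        c50_hat=float(math.exp(ln_c50)),
        gamma_hat=float(gamma_hat),
        omega_c50_hat=float(w1) if spec.iiv_c50 else None,
        omega_gamma_hat=float(w2) if spec.iiv_gamma else None,
        neg_loglik=float(res.fun),
        minimized=minimized,
        covariance_ok=cov_ok,
        boundary_flags=frozenset(flags),
        n_subjects=logc.shape[0],
        mode="mixed_" + "_".join(active),
    )
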