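"""Naive-pooled and Laplace mixed-effects maximum-likelihood estimation."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar
from scipy.special import expit

from popemax import (
    FitSpec,
    IIVSpec,
    PDParams,
    TrialDataset,
    TrialDesign,
    fit_mixed,
    fit_naive_pooled,
    marginal_negloglik_laplace,
    negloglik_pooled,
    simulate_binary_dataset,
    simulate_continuous_dataset,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def glm_logistic_fit(dataset):
    """Logistic regression of DV on ln(CONC): the exact reparameterization of
    the pooled binary Emax likelihood (slope gamma, intercept -gamma ln C50)."""
    x = sm.add_constant(np.log(dataset.data["CONC"].to_numpy()))
    fit = sm.GLM(dataset.data["DV"].to_numpy(), x, family=sm.families.Binomial()).fit()
    intercept, slope = fit.params
    return math.exp(-intercept / slope), slope, -fit.llf


def gh_marginal_negloglik(c50, gamma, omega1, dataset, nodes=61):
    """Adaptive Gauss-Hermite marginal likelihood over the C50 random effect:
    nodes are centered at each subject's conditional mode and scaled by the
    local curvature, then the prior-weighted likelihood is summed exactly."""
    xs, ws = hermgauss(nodes)
    total = 0.0
    for _, sub in dataset.data.groupby("ID"):
        lc = np.log(sub["CONC"].to_numpy())
        y = sub["DV"].to_numpy()

        def neg_joint(eta):
            p = expit(gamma * (lc - math.log(c50) - eta))
            p = np.clip(p, 1e-300, 1 - 1e-16)
            ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
            return -(ll - eta**2 / (2 * omega1))

        mode = minimize_scalar(neg_joint, bounds=(-10, 10), method="bounded",
                               options={"xatol": 1e-10}).x
        h = 1e-4
        curv = (neg_joint(mode + h) - 2 * neg_joint(mode) + neg_joint(mode - h)) / h**2
        scale = 1.0 / math.sqrt(max(curv, 1e-8))
        eta = mode + math.sqrt(2.0) * scale * xs
        # joint log-density already includes the prior exponent; the
        # substitution eta = mode + sqrt(2) scale x absorbs exp(-x^2)
        log_terms = np.array([-neg_joint(e) for e in eta])
        vals = np.exp(log_terms + xs**2)
        integral = math.sqrt(2.0) * scale * np.sum(ws * vals) / math.sqrt(
            2 * math.pi * omega1
        )
        total += math.log(integral)
    return -total


def brute_force_laplace(c50, gamma, omega1, dataset):
    """Independent Laplace evaluation: scalar mode by bounded search, curvature
    by central differences — no shared code with the implementation."""
    total = 0.0
    for _, sub in dataset.data.groupby("ID"):
        lc = np.log(sub["CONC"].to_numpy())
        y = sub["DV"].to_numpy()

        def neg_joint(eta):
            p = np.clip(expit(gamma * (lc - math.log(c50) - eta)), 1e-300, 1 - 1e-16)
            ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
            prior = -(eta**2) / (2 * omega1) - 0.5 * math.log(2 * math.pi * omega1)
            return -(ll + prior)

        mode = minimize_scalar(neg_joint, bounds=(-8, 8), method="bounded",
                               options={"xatol": 1e-12}).x
        h = 1e-5
        curv = (neg_joint(mode + h) - 2 * neg_joint(mode) + neg_joint(mode - h)) / h**2
        total += -neg_joint(mode) + 0.5 * math.log(2 * math.pi) - 0.5 * math.log(curv)
    return -total


# ---------------------------------------------------------------------------
# Pooled likelihood
# ---------------------------------------------------------------------------

class TestNegloglikPooled:
    def test_hand_value_at_half_probability(self):
        df = pd.DataFrame({"ID": [1, 1, 1, 1], "CONC": [1.0] * 4, "DV": [1.0] * 4})
        ds = TrialDataset(data=df, kind="binary")
        assert negloglik_pooled(1.0, 3.0, ds) == pytest.approx(4 * math.log(2))

    def test_equals_logistic_regression_loglik(self, binary_dataset_no_iiv):
        c50_glm, gamma_glm, nll_glm = glm_logistic_fit(binary_dataset_no_iiv)
        ours = negloglik_pooled(c50_glm, gamma_glm, binary_dataset_no_iiv)
        assert ours == pytest.approx(nll_glm, abs=1e-6)

    def test_invalid_inputs(self, binary_dataset_no_iiv):
        with pytest.raises(ValueError):
            negloglik_pooled(-1.0, 2.0, binary_dataset_no_iiv)
        bad = TrialDataset(
            data=pd.DataFrame({"ID": [1], "CONC": [1.0], "DV": [0.4]}),
            kind="binary",
        )
        with pytest.raises(ValueError):
            negloglik_pooled(1.0, 2.0, bad)

    def test_gamma_profile_unimodal(self, binary_dataset_no_iiv):
        gammas = np.geomspace(0.2, 30, 80)
        nll = np.array(
            [negloglik_pooled(1.0, g, binary_dataset_no_iiv) for g in gammas]
        )
        sign = np.sign(np.diff(nll))
        # one descent run followed by one ascent run
        assert np.sum(np.diff(sign) != 0) == 1


class TestFitNaivePooled:
    def test_matches_glm_reparameterization(self, binary_dataset_no_iiv):
        fit = fit_naive_pooled(binary_dataset_no_iiv)
        c50_glm, gamma_glm, _ = glm_logistic_fit(binary_dataset_no_iiv)
        assert fit.gamma_hat == pytest.approx(gamma_glm, abs=1e-5)
        assert fit.c50_hat == pytest.approx(c50_glm, abs=1e-5)
        assert fit.minimized and fit.covariance_ok

    def test_consistency_large_sample(self):
        ds = simulate_binary_dataset(
            PDParams(1.0, 2.0), IIVSpec(), TrialDesign(10_000), seed=12
        )
        fit = fit_naive_pooled(ds)
        assert fit.gamma_hat == pytest.approx(2.0, rel=0.05)
        assert fit.c50_hat == pytest.approx(1.0, rel=0.03)

    def test_exact_recovery_noiseless_continuous(self):
        ds = simulate_continuous_dataset(
            PDParams(1.3, 4.0), IIVSpec(), TrialDesign(10), noise_sd=0.0, seed=0
        )
        fit = fit_naive_pooled(ds)
        assert fit.c50_hat == pytest.approx(1.3, rel=1e-5)
        assert fit.gamma_hat == pytest.approx(4.0, rel=1e-5)

    def test_separation_hits_upper_bound_with_flag(self):
        df = pd.DataFrame(
            {
                "ID": np.arange(1, 9),
                "CONC": [0.5, 0.6, 0.7, 0.8, 1.2, 1.3, 1.4, 1.5],
                "DV": [0.0] * 4 + [1.0] * 4,
            }
        )
        fit = fit_naive_pooled(TrialDataset(data=df, kind="binary"))
        assert "gamma_upper" in fit.boundary_flags
        assert fit.gamma_hat == pytest.approx(50.0, rel=0.01)

    def test_unit_invariance(self, binary_dataset_gamma5):
        fit = fit_naive_pooled(binary_dataset_gamma5)
        scaled = TrialDataset(
            data=binary_dataset_gamma5.data.assign(
                CONC=binary_dataset_gamma5.data.CONC * 100.0
            ),
            kind="binary",
        )
        fit_s = fit_naive_pooled(scaled)
        assert fit_s.gamma_hat == pytest.approx(fit.gamma_hat, rel=1e-4)
        assert fit_s.c50_hat == pytest.approx(100.0 * fit.c50_hat, rel=1e-4)


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

class TestLaplaceMarginal:
    def test_zero_omega_limit_equals_pooled(self, binary_dataset_gamma5):
        pooled = negloglik_pooled(1.1, 4.0, binary_dataset_gamma5)
        for spec in (FitSpec(iiv_c50=True), FitSpec(iiv_c50=True, iiv_gamma=True)):
            lap = marginal_negloglik_laplace(
                1.1, 4.0, (0.0, 0.0), binary_dataset_gamma5, spec
            )
            assert lap == pytest.approx(pooled, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_gauss_hermite_oracle(self, seed):
        # shallow curves: the Laplace approximation is accurate to < 1e-3
        ds = simulate_binary_dataset(
            PDParams(1.0, 1.0), IIVSpec(omega_c50=0.1), TrialDesign(3), seed=seed
        )
        oracle = gh_marginal_negloglik(1.0, 1.0, 0.1, ds)
        ours = marginal_negloglik_laplace(1.0, 1.0, (0.1, 0.0), ds, FitSpec(iiv_c50=True))
        assert ours == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("gamma", [1.0, 5.0, 20.0])
    def test_matches_brute_force_laplace(self, gamma):
        # implementation check at steep gammas where the approximation error
        # itself is larger: both routes must compute the same Laplace value
        ds = simulate_binary_dataset(
            PDParams(1.0, gamma), IIVSpec(omega_c50=0.2), TrialDesign(5), seed=3
        )
        oracle = brute_force_laplace(1.05, gamma * 0.9, 0.2, ds)
        ours = marginal_negloglik_laplace(
            1.05, gamma * 0.9, (0.2, 0.0), ds, FitSpec(iiv_c50=True)
        )
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_invariant_under_subject_relabeling(self, binary_dataset_gamma5):
        base = marginal_negloglik_laplace(
            1.0, 5.0, (0.1, 0.0), binary_dataset_gamma5, FitSpec(iiv_c50=True)
        )
        df = binary_dataset_gamma5.data.copy()
        ids = df["ID"].unique()
        relabel = dict(zip(ids, np.roll(ids, 7)))
        shuffled = TrialDataset(
            data=df.assign(ID=df["ID"].map(relabel)).sort_values("ID"),
            kind="binary",
        )
        assert marginal_negloglik_laplace(
            1.0, 5.0, (0.1, 0.0), shuffled, FitSpec(iiv_c50=True)
        ) == pytest.approx(base, abs=1e-9)

    def test_continuous_data_rejected(self):
        ds = simulate_continuous_dataset(
            PDParams(1, 5), IIVSpec(0.1, 0), TrialDesign(5), seed=0
        )
        with pytest.raises(ValueError, match="binary"):
            marginal_negloglik_laplace(1, 5, (0.1, 0), ds, FitSpec(iiv_c50=True))


class TestFitMixed:
    def test_no_iiv_data_drives_omega_to_lower_boundary(self):
        # a single dataset can support a small positive variance by chance;
        # the typical (median) estimate across replicated no-IIV trials is 0
        fits = [
            fit_mixed(
                simulate_binary_dataset(
                    PDParams(1.0, 5.0), IIVSpec(), TrialDesign(40), seed=s
                ),
                FitSpec(iiv_c50=True),
            )
            for s in range(9)
        ]
        omegas = np.array([f.omega_c50_hat for f in fits])
        assert np.median(omegas) < 0.01
        at_zero = [f for f in fits if f.omega_c50_hat < 1e-6]
        assert at_zero, "no run reached the lower boundary"
        for f in at_zero:
            assert "omega_c50_zero" in f.boundary_flags
            assert not f.covariance_ok  # boundary blocks the covariance analog

    def test_recovers_omega_c50(self):
        ds = simulate_binary_dataset(
            PDParams(1.0, 5.0), IIVSpec(omega_c50=0.1), TrialDesign(40), seed=4
        )
        fit = fit_mixed(ds, FitSpec(iiv_c50=True))
        assert fit.minimized
        assert fit.omega_c50_hat == pytest.approx(0.1, abs=0.08)

    def test_both_iiv_mode_runs(self, binary_dataset_gamma5):
        fit = fit_mixed(
            binary_dataset_gamma5, FitSpec(iiv_c50=True, iiv_gamma=True),
            compute_covariance=False,
        )
        assert fit.omega_gamma_hat is not None
        assert fit.mode == "mixed_c50_gamma"

    def test_unit_invariance(self, binary_dataset_gamma5):
        fit = fit_mixed(binary_dataset_gamma5, FitSpec(iiv_c50=True),
                        compute_covariance=False)
        scaled = TrialDataset(
            data=binary_dataset_gamma5.data.assign(
                CONC=binary_dataset_gamma5.data.CONC * 10.0
            ),
            kind="binary",
        )
        fit_s = fit_mixed(scaled, FitSpec(iiv_c50=True), compute_covariance=False)
        assert fit_s.gamma_hat == pytest.approx(fit.gamma_hat, rel=1e-3)
        assert fit_s.c50_hat == pytest.approx(10.0 * fit.c50_hat, rel=1e-3)
        assert fit_s.omega_c50_hat == pytest.approx(fit.omega_c50_hat, abs=1e-3)

    def test_requires_active_iiv_term(self, binary_dataset_gamma5):
        with pytest.raises(ValueError, match="IIV"):
            fit_mixed(binary_dataset_gamma5, FitSpec())
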