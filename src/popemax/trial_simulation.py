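"""Simulated clinical trials: design concentrations and per-subject responses.

Emulates the study design of steep anesthetic concentration-response
trials: each subject is observed at a fixed set of drug levels chosen so
that the *population-predicted* probability of effect (from the gamma*
formula, i.e. accounting for IIV) hits prescribed targets, by default 0.10,
0.25, 0.75 and 0.90.  Responses are binary (Bernoulli at the individual's
own Emax probability) or continuous (individual probability plus additive
Gaussian error, SD 0.1 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pd_models import IIVSpec, PDParams, PiConstants, gamma_star, prob_emax

__all__ = [
    "TrialDesign",
    "TrialDataset",
    "design_concentrations",
    "simulate_binary_dataset",
    "simulate_continuous_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]

P_TARGETS_DEFAULT = (0.10, 0.25, 0.75, 0.90)


@dataclass(frozen=True)
class TrialDesign:
    """Fixed sampling design: number of subjects and target probabilities."""

    n_subjects: int = 40
    p_targets: tuple = P_TARGETS_DEFAULT

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        t = np.asarray(self.p_targets, dtype=float)
        if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("p_targets must be strictly increasing in (0, 1)")

    @property
    def n_obs_per_subject(self) -> int:
        return len(self.p_targets)


@dataclass(frozen=True)
class TrialDataset:
    """Long-format trial records with generating metadata."""

    data: pd.DataFrame  # columns ID, CONC, DV
    kind: str  # "binary" | "continuous"
    params: PDParams | None = None
    iiv: IIVSpec | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def design_concentrations(
    c50: float, gamma_star_value: float, p_targets=P_TARGETS_DEFAULT
) -> np.ndarray:
    """Concentrations at which the population curve hits the targets.

    Inverts the sigmoid Emax model at the population steepness:
    ``C = C50 * (P / (1 - P))**(1 / gamma*)``.
    """
    if not c50 > 0 or not gamma_star_value > 0:
        raise ValueError("c50 and gamma_star must be positive")
    t = np.asarray(p_targets, dtype=float)
    if np.any(t <= 0) or np.any(t >= 1):
        raise ValueError("targets must be strictly inside (0, 1)")
    return c50 * (t / (1.0 - t)) ** (1.0 / gamma_star_value)


def _simulate(
    params: PDParams,
    iiv: IIVSpec,
    design: TrialDesign,
    seed,
    kind: str,
    noise_sd: float = 0.1,
    constants: PiConstants = PiConstants(),
) -> TrialDataset:
    star = gamma_star(params.gamma, iiv, constants)
    conc = design_concentrations(params.c50, star.gamma_star, design.p_targets)
    ln_conc = np.log(conc)

    # one substream per subject so datasets are stable under re-ordering
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records = []
    for sid in range(design.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=root.entropy, spawn_key=root.spawn_key + (sid,)
            )
        )
        eta1 = rng.standard_normal() * math.sqrt(iiv.omega_c50)
        eta2 = rng.standard_normal() * math.sqrt(iiv.omega_gamma)
        c50_i = params.c50 * math.exp(eta1)
        gamma_i = params.gamma * math.exp(eta2)
        p_i = prob_emax(conc, c50_i, gamma_i)
        if kind == "binary":
            dv = (rng.random(len(conc)) < p_i).astype(float)
        else:
            dv = p_i + noise_sd * rng.standard_normal(len(conc))
        for c, ln_c, y in zip(conc, ln_conc, dv):
            records.append((sid + 1, c, y))

    df = pd.DataFrame(records, columns=["ID", "CONC", "DV"])
    return TrialDataset(
        data=df,
        kind=kind,
        params=params,
        iiv=iiv,
        seed=seed,
        meta={
            "gamma_star": star.gamma_star,
            "sigma_star": star.sigma_star,
            "design_concentrations": conc.tolist(),
            "p_targets": list(design.p_targets),
            "noise_sd": noise_sd if kind == "continuous" else None,
        },
    )


def simulate_binary_dataset(
    params: PDParams,
    iiv: IIVSpec,
    design: TrialDesign = TrialDesign(),
    seed=0,
    constants: PiConstants = PiConstants(),
) -> TrialDataset:
    """Simulate one binary trial.

    Each subject's (C50, gamma) is drawn once from the log-normal IIV model
    and shared across that subject's observations; at each design
    concentration the probability of effect follows the individual's own
    Emax curve and the observed response is a Bernoulli draw (effect present
    if a uniform random number falls below P).
    """
    return _simulate(params, iiv, design, seed, "binary", constants=constants)


def simulate_continuous_dataset(
    params: PDParams,
    iiv: IIVSpec,
    design: TrialDesign = TrialDesign(),
    noise_sd: float = 0.1,
    seed=0,
    constants: PiConstants = PiConstants(),
) -> TrialDataset:
    """Simulate one continuous trial: individual P plus Gaussian error.

    The residual SD defaults to 0.1 (10% of the 0-1 effect scale).
    Responses are deliberately not truncated to [0, 1] so the error model
    stays exactly Gaussian for the least-squares estimator.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    return _simulate(
        params, iiv, design, seed, "continuous", noise_sd=noise_sd,
        constants=constants,
    )


# ---------------------------------------------------------------------------
# Flat-file I/O (NONMEM-like long format)
# ---------------------------------------------------------------------------

def write_dataset_csv(dataset: TrialDataset, path) -> None:
    """Write a dataset as a long-format CSV with header ID, CONC, DV, KIND."""
    out = dataset.data.copy()
    out["KIND"] = dataset.kind
    out.to_csv(path, index=False)


def read_dataset_csv(path) -> TrialDataset:
    """Read a long-format CSV (ID, CONC, DV, KIND) back into a TrialDataset."""
    df = pd.read_csv(path)
    required = {"ID", "CONC", "DV"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset CSV must have columns {sorted(required)}")
    kind = str(df["KIND"].iloc[0]) if "KIND" in df.columns else "binary"
    if kind == "binary" and not df["DV"].isin([0, 1]).all():
        raise ValueError("binary dataset has responses outside {0, 1}")
    return TrialDataset(data=df[["ID", "CONC", "DV"]].copy(), kind=kind)
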