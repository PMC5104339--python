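"""Population layer: covariates, random effects, residual error, baselines.

Individual parameters are built as
``param_i = (typical + covariate shift) * exp(eta)`` with independent
``eta ~ Normal(0, omega^2)`` per parameter (lognormal interindividual
variability, so the population median equals the typical value).

Residual error is applied per observation stream: exponential
(``y = f*exp(eps)``, used for plasma drug and dNTP levels) or proportional
(``y = f*(1+eps)``, used for the intracellular anabolites); proportional
draws that fall below zero are clipped to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ChainConfig, ChainParams, CovariateEffect, ParameterError, VariabilitySpec


@dataclass
class CovariateVector:
    """Binary subject covariates: sex (male=1, female=0), hiv (positive=1)."""

    sex: int = 0
    hiv: int = 0

    def __post_init__(self) -> None:
        if self.sex not in (0, 1) or self.hiv not in (0, 1):
            raise ParameterError("covariates must be 0 or 1")

    def get(self, name: str) -> int:
        return {"sex": self.sex, "hiv": self.hiv}[name]


@dataclass
class VirtualSubject:
    """Covariates plus sampled random effects, resolved per chain."""

    id: str
    covariates: CovariateVector
    etas: dict[str, dict[str, float]] = field(default_factory=dict)       # analyte -> path -> eta
    params: dict[str, ChainParams] = field(default_factory=dict)          # analyte -> resolved bundle


def apply_covariates(typical: ChainParams, cov: CovariateVector,
                     effects: list[CovariateEffect]) -> ChainParams:
    """Additive covariate shifts on typical values; result must stay valid."""
    out = typical.copy()
    for e in effects:
        value = out.get(e.param) + e.coeff * cov.get(e.covariate)
        if value <= 0:
            raise ParameterError(
                f"covariate model drives {e.param} to {value:g} (must stay > 0)")
        out.set(e.param, value)
    out.validate()
    return out


def sample_etas(var: VariabilitySpec, rng: np.random.Generator) -> dict[str, float]:
    """Independent eta ~ N(0, omega^2) per parameter path, in sorted key order
    so draws are reproducible for a given seed regardless of dict insertion."""
    return {path: float(rng.normal(0.0, np.sqrt(w2))) if w2 > 0 else 0.0
            for path, w2 in sorted(var.omega2.items())}


def individualize(typical: ChainParams, etas: dict[str, float]) -> ChainParams:
    out = typical.copy()
    for path, eta in etas.items():
        out.set(path, out.get(path) * float(np.exp(eta)))
    out.validate()
    return out


def sample_individual(cfg: ChainConfig, cov: CovariateVector,
                      rng: np.random.Generator, subject_id: str = "1") -> VirtualSubject:
    """One virtual subject for a single chain (see sample_population for both)."""
    etas = sample_etas(cfg.variability, rng)
    tv = apply_covariates(cfg.params, cov, cfg.covariate_effects)
    subject = VirtualSubject(id=subject_id, covariates=cov)
    subject.etas[cfg.params.analyte] = etas
    subject.params[cfg.params.analyte] = individualize(tv, etas)
    return subject


def apply_residual_error(prediction: float, stream: str, var: VariabilitySpec,
                         rng: np.random.Generator) -> tuple[float, bool]:
    """Observed value and a flag marking a proportional draw clipped at zero."""
    model = var.error_model.get(stream)
    if model is None:
        raise KeyError(f"no error model declared for stream {stream!r}")
    sigma = float(np.sqrt(var.sigma2.get(stream, 0.0)))
    eps = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    if model == "exponential":
        if prediction <= 0:
            raise ValueError(
                f"exponential error for stream {stream!r} needs prediction > 0")
        return prediction * float(np.exp(eps)), False
    y = prediction * (1.0 + eps)
    if y < 0.0:
        return 0.0, True
    return y, False


def baseline_r0(pop_mean: float, observed: float | None, omega2: float,
                sigma2: float, eta_rv: float = 0.0) -> float:
    """Shrinkage estimator of an individual dNTP baseline from one measurement.

    Weights the population mean by sigma^2/(omega^2+sigma^2) and the observed
    baseline by omega^2/(omega^2+sigma^2), then applies the residual random
    effect with its exponent scaled by the same observed-value weight:

        R0_i = (R0_pop*s2/(w2+s2) + R0_obs*w2/(w2+s2)) * exp(eta_rv*w2/(w2+s2))

    With no observed baseline the estimator degrades to the population value
    times exp(eta_rv) (deviation-from-population-mean behaviour).
    """
    if omega2 + sigma2 <= 0:
        raise ValueError("omega2 + sigma2 must be > 0")
    if observed is None:
        return pop_mean * float(np.exp(eta_rv))
    if observed <= 0:
        raise ValueError("observed baseline must be > 0")
    w = omega2 / (omega2 + sigma2)
    return (pop_mean * (1.0 - w) + observed * w) * float(np.exp(eta_rv * w))


def sample_population(n: int, chain_cfgs: list[ChainConfig], seed,
                      p_male: float = 0.675, hiv: int = 0) -> list[VirtualSubject]:
    """n independent virtual subjects across one or more chains.

    Covariate defaults mirror the study demographics (27/40 male); the HIV
    status is fixed per call (prevention-use simulations are HIV-negative).
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        cov = CovariateVector(sex=int(rng.random() < p_male), hiv=hiv)
        subj = VirtualSubject(id=str(i + 1), covariates=cov)
        for cfg in chain_cfgs:
            etas = sample_etas(cfg.variability, rng)
            tv = apply_covariates(cfg.params, cov, cfg.covariate_effects)
            subj.etas[cfg.params.analyte] = etas
            subj.params[cfg.params.analyte] = individualize(tv, etas)
        subjects.append(subj)
    return subjects
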