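"""Sequential-link estimation at desk scale.

The three stages mirror the sequential-link development of the model:
``plasma`` (absorption + two-compartment disposition), ``intracellular``
(formation/saturation/recycle, plasma fixed), and ``dntp`` (indirect
response, anabolite kinetics fixed).  Typical values are estimated by
pooled nonlinear least squares on the residual-error scale — log residuals
for exponential-error streams, relative residuals for proportional ones —
with positive parameters fitted on the log scale and the recycling fraction
on the logit scale.  BLQ rows are excluded (treated as missing).  A
per-subject empirical-Bayes (MAP) step conditional on the population values
and omega^2 is available for the sequential link.  The objective reported
is the least-squares surrogate n*log(RSS/n), used only for likelihood-ratio
threshold arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .design import regimen_from_dataset
from .model import integrate
from .params import ChainConfig, ChainParams
from .population import CovariateVector, apply_covariates, individualize

STAGES = {
    "plasma": ["plasma.Ka", "plasma.Vc_F", "plasma.CL_F", "plasma.Vp_F", "plasma.Q_F"],
    "intracellular": ["ic.Kf", "ic.SC50", "ic.Kel", "ic.R"],
    "dntp": [],  # filled per dNTP stream: dntp.<name>.R0, dntp.<name>.EC50
}


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    estimates: ChainParams
    objective: float
    converged: bool
    stage: str
    n_obs: int
    n_params: int
    message: str = ""
    covariate_coeffs: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] | None = None

    def get(self, path: str) -> float:
        return self.estimates.get(path)


def _to_internal(chain: ChainParams, paths: list[str]) -> np.ndarray:
    x = []
    for p in paths:
        v = chain.get(p)
        if p == "ic.R":
            v = min(max(v, 1e-6), 1 - 1e-6)
            x.append(np.log(v / (1.0 - v)))
        else:
            x.append(np.log(v))
    return np.array(x)


def _from_internal(chain: ChainParams, paths: list[str], x: np.ndarray) -> ChainParams:
    out = chain.copy()
    for p, xi in zip(paths, x):
        out.set(p, float(1.0 / (1.0 + np.exp(-xi)) if p == "ic.R" else np.exp(xi)))
    return out


def _stage_streams(stage: str, chain: ChainParams, dntp_name: str | None) -> list[str]:
    if stage == "plasma":
        return [chain.analyte]
    if stage == "intracellular":
        return [chain.ic_stream]
    if stage == "dntp":
        if dntp_name is None:
            raise ValueError("stage='dntp' requires dntp_name")
        return [dntp_name]
    raise ValueError(f"unknown stage {stage!r}")


def _residual_scale(obs: np.ndarray, pred: np.ndarray, model: str) -> np.ndarray:
    if model == "exponential":
        pred = np.maximum(pred, 1e-12)
        return np.log(obs) - np.log(pred)
    return (obs - pred) / np.maximum(pred, 1e-12)


def fit_stage(table: pd.DataFrame, stage: str, cfg: ChainConfig,
              init: ChainParams | None = None, dntp_name: str | None = None,
              fixed_upstream: ChainParams | dict[int, ChainParams] | None = None,
              estimate_covariates: bool = False,
              n_starts: int = 5, jitter: float = 0.3, seed: int = 0,
              max_nfev: int = 200) -> FitResult:
    """Fit one stage's typical values to a long-format dataset.

    ``fixed_upstream`` supplies the already-estimated upstream parameters:
    a single bundle (typical-value sequential link) or a per-subject-ID map
    (individual sequential link).  ``estimate_covariates`` additionally
    frees the chain's declared covariate coefficients.  Multi-start (jittered
    initial values, seeded) guards against local minima; the best converged
    start wins.
    """
    if stage != "plasma" and fixed_upstream is None:
        raise FitError(f"stage {stage!r} needs fixed_upstream (sequential link)")
    chain0 = (init or cfg.params).copy()
    if fixed_upstream is not None and not isinstance(fixed_upstream, dict):
        base = fixed_upstream.copy()
        for p in STAGES[stage] or [f"dntp.{dntp_name}.R0", f"dntp.{dntp_name}.EC50"]:
            base.set(p, chain0.get(p))
        chain0 = base
    paths = STAGES[stage] or [f"dntp.{dntp_name}.R0", f"dntp.{dntp_name}.EC50"]
    streams = _stage_streams(stage, cfg.params, dntp_name)
    error_model = {s: cfg.variability.error_model.get(s, "exponential")
                   for s in streams}
    effects = [e for e in cfg.covariate_effects
               if estimate_covariates and e.param.split(".")[0] == paths[0].split(".")[0]]

    obs = table[(table["EVID"] == 0) & table["DVID"].isin(streams) &
                (table["BLQ"] == 0) & table["DV"].notna()].copy()
    if len(obs) == 0:
        raise FitError(f"no quantifiable observations for stage {stage!r}")

    # Pool subjects sharing covariates and regimen; simulate once per group.
    groups = []
    for (sex, hiv), grp in obs.groupby(["SEX", "HIV"]):
        ids = sorted(grp["ID"].unique())
        reg = regimen_from_dataset(table, ids[0], cfg.params.analyte)
        if not reg.events:
            raise FitError("dataset carries no dose rows (EVID=1); "
                           "cannot reconstruct the regimen")
        per_subject = (isinstance(fixed_upstream, dict))
        if per_subject:
            for sid in ids:
                sub = grp[grp["ID"] == sid]
                groups.append((CovariateVector(int(sex), int(hiv)), reg, sub,
                               fixed_upstream[sid]))
        else:
            groups.append((CovariateVector(int(sex), int(hiv)), reg, grp, None))

    prepared = []
    for cov, reg, grp, upstream in groups:
        times = np.sort(grp["TIME"].unique())
        grid = np.unique(np.concatenate([[0.0], times]))
        lookup = {t: i for i, t in enumerate(grid)}
        by_stream = {}
        for s in streams:
            sub = grp[grp["DVID"] == s]
            by_stream[s] = (sub["TIME"].map(lookup).to_numpy(dtype=int),
                            sub["DV"].to_numpy(dtype=float))
        prepared.append((cov, reg, grid, by_stream, upstream))

    def residuals(x: np.ndarray) -> np.ndarray:
        n_cov = len(effects)
        chain = _from_internal(chain0, paths, x[:len(paths)] if n_cov else x)
        res = []
        for cov, reg, grid, by_stream, upstream in prepared:
            c = chain if upstream is None else _merge_stage(upstream, chain, paths)
            eff = effects
            if n_cov:
                eff = [type(e)(e.param, e.covariate, float(co))
                       for e, co in zip(effects, x[len(paths):])]
                c = apply_covariates(c, cov, eff)
            elif cfg.covariate_effects:
                c = apply_covariates(c, cov, cfg.covariate_effects)
            traj = integrate(reg, c, grid)
            for s, (idx, dv) in by_stream.items():
                res.append(_residual_scale(dv, traj.observable(s)[idx],
                                           error_model[s]))
        return np.concatenate(res)

    x0 = _to_internal(chain0, paths)
    if effects:
        x0 = np.append(x0, [e.coeff for e in effects])
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, jitter, size=x0.shape)
        try:
            # diff_step well above the ODE-solver noise floor (rtol 1e-8),
            # otherwise finite-difference jacobians are dominated by it
            sol = least_squares(residuals, xs, method="trf", max_nfev=max_nfev,
                                diff_step=1e-4, ftol=1e-12, xtol=1e-12)
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(f"all {n_starts} starts failed for stage {stage!r}")

    n = best.fun.size
    rss = float(2.0 * best.cost)
    objective = n * float(np.log(max(rss, 1e-300) / n))
    est = _from_internal(chain0, paths, best.x[:len(paths)])
    coeffs = {e.param: float(c) for e, c in zip(effects, best.x[len(paths):])}

    # identifiability: a parameter the residuals do not react to is flagged.
    # The floor sits above the finite-difference noise produced by the ODE
    # solver (relative error RTOL over a diff_step of 1e-4 leaves jacobian
    # noise of order 1e-4 per entry).
    jac_norm = np.linalg.norm(np.atleast_2d(best.jac), axis=0)
    floor = max(1e-6 * float(jac_norm.max()), 2e-3 * float(np.sqrt(n)))
    identifiable = bool(np.all(jac_norm > floor))
    converged = bool(best.status > 0 and identifiable and np.isfinite(objective))
    msg = best.message if identifiable else (
        "parameter(s) unidentifiable from the data (flat residual surface): " +
        ", ".join(p for p, g in zip(paths, jac_norm) if g <= floor))
    return FitResult(estimates=est, objective=objective, converged=converged,
                     stage=stage, n_obs=n, n_params=len(best.x), message=msg,
                     covariate_coeffs=coeffs)


def _merge_stage(upstream: ChainParams, fitted: ChainParams,
                 paths: list[str]) -> ChainParams:
    out = upstream.copy()
    for p in paths:
        out.set(p, fitted.get(p))
    return out


def fit_individual_map(table: pd.DataFrame, stage: str, cfg: ChainConfig,
                       population: ChainParams, subject_id: int,
                       dntp_name: str | None = None,
                       max_nfev: int = 100) -> dict[str, float]:
    """Empirical-Bayes (MAP) etas for one subject, given population values.

    Maximizes the penalized objective sum(res^2/sigma^2) + sum(eta^2/omega^2)
    over the stage parameters that carry interindividual variability; returns
    the eta estimates (empty if the stage has none).
    """
    paths = [p for p in (STAGES[stage] or
                         [f"dntp.{dntp_name}.R0", f"dntp.{dntp_name}.EC50"])
             if cfg.variability.omega2.get(p, 0.0) > 0.0]
    if not paths:
        return {}
    streams = _stage_streams(stage, cfg.params, dntp_name)
    sub = table[(table["ID"] == subject_id) & (table["EVID"] == 0) &
                table["DVID"].isin(streams) & (table["BLQ"] == 0) &
                table["DV"].notna()]
    if len(sub) == 0:
        return {p: 0.0 for p in paths}
    cov = CovariateVector(int(sub["SEX"].iloc[0]), int(sub["HIV"].iloc[0]))
    tv = apply_covariates(population, cov, cfg.covariate_effects)
    reg = regimen_from_dataset(table, subject_id, cfg.params.analyte)
    times = np.sort(sub["TIME"].unique())
    grid = np.unique(np.concatenate([[0.0], times]))
    lookup = {t: i for i, t in enumerate(grid)}
    omega = np.array([np.sqrt(cfg.variability.omega2[p]) for p in paths])
    sigma = {s: np.sqrt(cfg.variability.sigma2.get(s, 1.0)) for s in streams}

    def penalized(eta: np.ndarray) -> np.ndarray:
        chain = individualize(tv, dict(zip(paths, eta)))
        traj = integrate(reg, chain, grid)
        res = []
        for s in streams:
            rows = sub[sub["DVID"] == s]
            idx = rows["TIME"].map(lookup).to_numpy(dtype=int)
            r = _residual_scale(rows["DV"].to_numpy(dtype=float),
                                traj.observable(s)[idx],
                                cfg.variability.error_model.get(s, "exponential"))
            res.append(r / sigma[s])
        res.append(eta / omega)
        return np.concatenate(res)

    sol = least_squares(penalized, np.zeros(len(paths)), method="trf",
                        diff_step=1e-4, max_nfev=max_nfev)
    return {p: float(e) for p, e in zip(paths, sol.x)}


#: Likelihood-ratio thresholds on the NONMEM-style objective (chi-square,
#: 1 df): forward inclusion at alpha = 0.01, backward retention at 0.001.
FORWARD_DELTA = -6.64
BACKWARD_DELTA = 10.8


@dataclass
class LrtDecision:
    delta_ofv: float
    include: bool
    mode: str


def lrt_covariate(fit_without: FitResult, fit_with: FitResult,
                  alpha_mode: str = "forward") -> LrtDecision:
    """Covariate decision from a nested pair of fits differing by one parameter.

    forward: include the covariate iff the objective drops by at least 6.64;
    backward: retain it iff removing it raises the objective by more than 10.8.
    """
    if alpha_mode not in ("forward", "backward"):
        raise ValueError("alpha_mode must be 'forward' or 'backward'")
    if not (fit_without.converged and fit_with.converged):
        raise FitError("both fits must have converged for the LRT")
    if fit_with.n_params - fit_without.n_params != 1:
        raise FitError("fits are not nested with one extra parameter")
    delta = fit_with.objective - fit_without.objective
    if alpha_mode == "forward":
        return LrtDecision(delta_ofv=delta, include=delta <= FORWARD_DELTA,
                           mode=alpha_mode)
    return LrtDecision(delta_ofv=delta, include=-delta > BACKWARD_DELTA,
                       mode=alpha_mode)
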