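"""Synthetic-trial generator, dataset I/O, and a simulation-based
predictive check.

The generator reproduces the structure of an intensive first-dose-to-
steady-state PKPD study: an HIV-negative arm dosed daily for 30 days with
washout visits on days 35/45/60, and an HIV-positive arm dosed daily for 60
days with a day-60 visit.  Rich sampling on days 1 and 30 (1, 2, 4, 8, 24 h
post-dose), sparse sampling on days 3, 7, 20 (pre-dose trough, 2 and 8 h),
and single washout samples.  Observable streams: plasma parent drug (TFV,
FTC), intracellular anabolites (TFVDP, FTCTP), and the four dNTPs (sampled
at baseline, the day-1 rich times, and 8 h post-dose at later visits).
Residual error is applied per stream and values under the assay LLOQ are
flagged BLQ with the numeric value dropped (treated as missing downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import integrate
from .params import ChainConfig
from .population import apply_residual_error, sample_population
from .regimen import Regimen

#: Small backward offset used for "pre-dose" trough samples, days (~0.1 s).
PREDOSE_EPS = 1e-6

HOUR = 1.0 / 24.0


def _visit_times(dosing_days: list[int], rich_days: list[int],
                 sparse_days: list[int], washout_days: list[int]) -> dict:
    """PK and dNTP sampling times (days since first dose) for one arm."""
    pk, dntp = [], [0.0 - PREDOSE_EPS]  # dNTP baseline drawn pre-first-dose
    for d in rich_days:
        t0 = d - 1
        pk += [t0 + h * HOUR for h in (1, 2, 4, 8, 24)]
        if d == 1:
            dntp += [t0 + h * HOUR for h in (1, 2, 4, 8, 24)]
        else:
            dntp.append(t0 + 8 * HOUR)
    for d in sparse_days:
        t0 = d - 1
        pk += [t0 - PREDOSE_EPS, t0 + 2 * HOUR, t0 + 8 * HOUR]
        dntp.append(t0 + 8 * HOUR)
    for d in washout_days:
        pk.append(float(d - 1))
        dntp.append(float(d - 1))
    return {"dosing_days": dosing_days, "pk": sorted(pk), "dntp": sorted(dntp)}


@dataclass
class DesignSchedule:
    """Per-arm dosing and sampling map of the emulated study design."""

    arms: dict[str, dict] = field(default_factory=lambda: {
        "neg": _visit_times(list(range(30)), rich_days=[1, 30],
                            sparse_days=[3, 7, 20], washout_days=[35, 45, 60]),
        "pos": _visit_times(list(range(60)), rich_days=[1, 30],
                            sparse_days=[3, 7, 20], washout_days=[60]),
    })

    def regimen(self, arm: str, analyte: str, dose_ug: float | None = None) -> Regimen:
        days = self.arms[arm]["dosing_days"]
        reg = Regimen.daily(analyte, len(days), dose_ug)
        return reg if days == list(range(len(days))) else Regimen(
            [replace(e, time=float(d)) for e, d in zip(reg.events, days)], analyte)


@dataclass
class LloqSpec:
    """Assay lower limits of quantification.

    Plasma is quantified directly in ng/mL; cellular analytes are quantified
    per sample and converted to fmol/10^6 cells through the number of PBMC
    actually recovered, so the effective per-10^6-cells threshold varies
    sample to sample.  Cells per sample are drawn lognormal with the given
    median and CV.
    """

    plasma_ng_ml: float = 10.0
    tfvdp_fmol_per_sample: float = 2.5
    ftctp_fmol_per_sample: float = 100.0       # 0.1 pmol/sample
    dntp_fmol_per_sample: float = 50.0
    cells_per_sample_median: float = 5e6
    cells_per_sample_cv: float = 0.5

    def validate(self) -> None:
        for name in ("plasma_ng_ml", "tfvdp_fmol_per_sample",
                     "ftctp_fmol_per_sample", "dntp_fmol_per_sample",
                     "cells_per_sample_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LloqSpec.{name} must be > 0")

    @classmethod
    def none(cls) -> "LloqSpec":
        """Censoring disabled (thresholds at the smallest positive float)."""
        tiny = 5e-324
        return cls(plasma_ng_ml=tiny, tfvdp_fmol_per_sample=tiny,
                   ftctp_fmol_per_sample=tiny, dntp_fmol_per_sample=tiny)

    def threshold(self, stream: str, rng: np.random.Generator) -> float:
        """Effective LLOQ for one sample, in observation units."""
        if stream in ("TFV", "FTC"):
            return self.plasma_ng_ml
        per_sample = {"TFVDP": self.tfvdp_fmol_per_sample,
                      "FTCTP": self.ftctp_fmol_per_sample}.get(
                          stream, self.dntp_fmol_per_sample)
        sdlog = float(np.sqrt(np.log(1.0 + self.cells_per_sample_cv ** 2)))
        cells = self.cells_per_sample_median * float(np.exp(rng.normal(0.0, sdlog)))
        return per_sample / (cells / 1e6)


DATASET_COLUMNS = ["ID", "TIME", "DVID", "DV", "BLQ", "EVID", "AMT", "SEX", "HIV"]


def generate_trial(n_neg: int, n_pos: int, chain_cfgs: list[ChainConfig],
                   lloq: LloqSpec | None = None, seed=0,
                   schedule: DesignSchedule | None = None,
                   p_male: float = 0.675, include_doses: bool = True) -> pd.DataFrame:
    """Simulate one synthetic trial and return the long-format dataset.

    Deterministic for a given seed.  Rows are observations (EVID=0) plus,
    optionally, dose events (EVID=1, AMT in ug parent equivalent).
    """
    if n_neg < 0 or n_pos < 0:
        raise ValueError("arm sizes must be >= 0")
    lloq = LloqSpec() if lloq is None else lloq
    lloq.validate()
    schedule = schedule or DesignSchedule()
    rng = np.random.default_rng(seed)

    rows = []
    arm_of = ["neg"] * n_neg + ["pos"] * n_pos
    subjects = []
    if n_neg:
        subjects += sample_population(n_neg, chain_cfgs, rng, p_male=p_male, hiv=0)
    if n_pos:
        subjects += sample_population(n_pos, chain_cfgs, rng, p_male=p_male, hiv=1)
    for i, subj in enumerate(subjects):
        subj.id = str(i + 1)

    for subj, arm in zip(subjects, arm_of):
        times = schedule.arms[arm]
        t_end = max(max(times["pk"]), max(times["dntp"]))
        for cfg in chain_cfgs:
            analyte = cfg.params.analyte
            chain = subj.params[analyte]
            reg = schedule.regimen(arm, analyte, chain.dose_ug)
            grid = np.unique(np.concatenate(
                [[0.0 - PREDOSE_EPS], times["pk"], times["dntp"], [t_end]]))
            grid0 = grid - grid[0]       # integrator grid starts at the baseline draw
            traj = integrate(reg.shifted(-grid[0]), chain, grid0)

            def pred_at(t: float, stream: str) -> float:
                j = int(np.searchsorted(grid, t))
                return float(traj.observable(stream)[j])

            stream_times = {analyte: times["pk"], chain.ic_stream: times["pk"]}
            for d in chain.dntps:
                stream_times[d.name] = times["dntp"]
            for stream, ts in stream_times.items():
                for t in ts:
                    pred = pred_at(t, stream)
                    if pred <= 0 and cfg.variability.error_model.get(stream) == "exponential":
                        # drug-free exponential-error stream: nothing measurable
                        value, clipped = 0.0, False
                    else:
                        value, clipped = apply_residual_error(
                            pred, stream, cfg.variability, rng)
                    thr = lloq.threshold(stream, rng)
                    blq = int(clipped or value < thr)
                    rows.append({
                        "ID": int(subj.id), "TIME": max(t, 0.0), "DVID": stream,
                        "DV": (np.nan if blq else value), "BLQ": blq,
                        "EVID": 0, "AMT": np.nan,
                        "SEX": subj.covariates.sex, "HIV": subj.covariates.hiv})
            if include_doses:
                for e in reg.events:
                    rows.append({
                        "ID": int(subj.id), "TIME": e.time, "DVID": analyte,
                        "DV": np.nan, "BLQ": 0, "EVID": 1, "AMT": e.amount,
                        "SEX": subj.covariates.sex, "HIV": subj.covariates.hiv})

    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID", "DVID"],
                          kind="stable").reset_index(drop=True)


VALID_STREAMS = {"TFV", "FTC", "TFVDP", "FTCTP", "dATP", "dGTP", "dCTP", "TTP"}


def write_dataset(table: pd.DataFrame, path) -> None:
    """CSV writer with a fixed column order (UTF-8, '.' decimal)."""
    table.to_csv(path, index=False, columns=DATASET_COLUMNS)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - {"EVID", "AMT"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset lacks required columns: {sorted(missing)}")
    if "EVID" not in df.columns:
        df["EVID"] = 0
    if "AMT" not in df.columns:
        df["AMT"] = np.nan
    bad = set(df["DVID"].unique()) - VALID_STREAMS
    if bad:
        raise ValueError(f"unknown DVID stream(s): {sorted(bad)}")
    for col in ("TIME", "DV", "AMT"):
        vals = pd.to_numeric(df[col], errors="coerce")
        broken = df.index[vals.isna() & df[col].notna() &
                          (df[col].astype(str).str.strip() != "")]
        if len(broken):
            raise ValueError(f"malformed numeric field {col!r} at row {broken[0]}")
        df[col] = vals
    blq_with_dv = (df["BLQ"] == 1) & df["DV"].notna()
    if blq_with_dv.any():
        import warnings
        warnings.warn(f"{int(blq_with_dv.sum())} BLQ rows carry a DV; "
                      "values ignored", stacklevel=2)
        df.loc[blq_with_dv, "DV"] = np.nan
    return df[DATASET_COLUMNS].copy()


def regimen_from_dataset(table: pd.DataFrame, subject_id: int,
                         analyte: str) -> Regimen:
    """Reconstruct a subject's dosing regimen from EVID=1 rows."""
    rows = table[(table["ID"] == subject_id) & (table["EVID"] == 1) &
                 (table["DVID"] == analyte)].sort_values("TIME")
    from .regimen import DoseEvent
    return Regimen([DoseEvent(float(t), float(a))
                    for t, a in zip(rows["TIME"], rows["AMT"])], analyte)


@dataclass
class PredictiveCheckResult:
    """Per-stream simulation bands and observed coverage."""

    bands: pd.DataFrame          # DVID, TIME, p5, p10, p50, p90, p95
    outside_fraction: dict[str, float]
    n_obs: dict[str, int]

    @property
    def overall_outside_fraction(self) -> float:
        total = sum(self.n_obs.values())
        if total == 0:
            return float("nan")
        return sum(self.outside_fraction[s] * self.n_obs[s]
                   for s in self.n_obs) / total


def predictive_check(table: pd.DataFrame, chain_cfgs: list[ChainConfig],
                     n_rep: int = 200, seed=0,
                     schedule: DesignSchedule | None = None) -> PredictiveCheckResult:
    """Simulation-based coverage check of a model against a dataset.

    Replicate trials are simulated under the design actually present in the
    table (arm sizes and covariates are read from it); per (stream, time)
    the 90% and 80% prediction bands are taken over all replicate
    observations, and the fraction of real (non-BLQ) observations falling
    outside the 90% band is reported per stream.  A well-specified model
    yields about 10%; a fraction below 15% is the conventional acceptance
    rule.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100 for stable outer percentiles")
    obs = table[(table["EVID"] == 0)].copy()
    have = set(obs["DVID"].unique())
    modelled = set()
    for cfg in chain_cfgs:
        modelled.update(cfg.params.streams)
    skipped = sorted(have - modelled)
    if skipped:
        import warnings
        warnings.warn(f"streams not covered by the model skipped: {skipped}",
                      stacklevel=2)
    obs = obs[obs["DVID"].isin(modelled)]

    per_subj = obs.groupby("ID").first()
    n_neg = int((per_subj["HIV"] == 0).sum())
    n_pos = int((per_subj["HIV"] == 1).sum())

    rng = np.random.default_rng(seed)
    sims = []
    for r in range(n_rep):
        rep = generate_trial(n_neg, n_pos, chain_cfgs, lloq=LloqSpec.none(),
                             seed=rng.integers(2 ** 31), schedule=schedule,
                             include_doses=False)
        sims.append(rep[rep["DVID"].isin(have)])
    sim = pd.concat(sims, ignore_index=True)
    sim["TIME_R"] = sim["TIME"].round(6)

    q = sim.groupby(["DVID", "TIME_R"])["DV"].quantile(
        [0.05, 0.10, 0.50, 0.90, 0.95]).unstack()
    q.columns = ["p5", "p10", "p50", "p90", "p95"]
    bands = q.reset_index().rename(columns={"TIME_R": "TIME"})

    outside, counts = {}, {}
    for stream, grp in obs[obs["BLQ"] == 0].groupby("DVID"):
        sub = bands[bands["DVID"] == stream].set_index("TIME")
        lo = sub["p5"].reindex(grp["TIME"].round(6)).to_numpy()
        hi = sub["p95"].reindex(grp["TIME"].round(6)).to_numpy()
        vals = grp["DV"].to_numpy()
        ok = np.isfinite(lo) & np.isfinite(hi)
        outside[stream] = float(np.mean((vals[ok] < lo[ok]) | (vals[ok] > hi[ok])))
        counts[stream] = int(ok.sum())
    return PredictiveCheckResult(bands=bands, outside_fraction=outside,
                                 n_obs=counts)
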