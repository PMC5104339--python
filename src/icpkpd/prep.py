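"""Monte-Carlo simulation of analog:dNTP molar ratios under on-demand PrEP.

The on-demand (event-driven) regimen: a double dose (two tablets taken
together) 2-24 hours before coitus, then single doses 24 h and 48 h after
coitus.  Each virtual HIV-negative subject's TFV-DP:dATP and FTC-TP:dCTP
molar ratios are computed pointwise as A4/A7 — both in fmol/10^6 cells, so
the ratio is dimensionless — with the subject's own (drug-perturbed) dNTP
level in the denominator.  Exceedance of in-vitro viral-suppression ratio
thresholds is summarized across the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import integrate
from .params import ChainConfig
from .population import sample_population
from .regimen import DoseEvent, Regimen

HOUR = 1.0 / 24.0

#: In-vitro viral-suppression thresholds on the analog:dNTP molar ratio.
DEFAULT_THRESHOLDS = {
    "tfvdp_datp_ec50": 0.086,
    "ftctp_dctp_ec50": 0.022,
    "ftctp_dctp_ec90": 0.07,
}


@dataclass
class RatioThresholds:
    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("ratio thresholds must be > 0")

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class PrepRegimenSpec:
    """Event-driven dosing around a coitus event at t = 0.

    pre_coitus_offset_h: hours before coitus of the double dose (2-24)
    double_dose_tablets: tablets taken together pre-coitus (default 2)
    post_dose_times_h:   single-tablet doses after coitus (default +24, +48 h)
    horizon_days:        follow-up after coitus
    """

    pre_coitus_offset_h: float = 24.0
    double_dose_tablets: int = 2
    post_dose_times_h: tuple[float, ...] = (24.0, 48.0)
    horizon_days: float = 7.0

    def __post_init__(self) -> None:
        if not (2.0 <= self.pre_coitus_offset_h <= 24.0):
            raise ValueError("pre-coitus offset must lie in [2, 24] hours")
        if self.horizon_days < 2.0:
            raise ValueError("horizon must be >= 2 days")

    def regimen(self, analyte: str, tablet_ug: float) -> Regimen:
        t0 = -self.pre_coitus_offset_h * HOUR
        events = [DoseEvent(t0, self.double_dose_tablets * tablet_ug)]
        events += [DoseEvent(h * HOUR, tablet_ug) for h in self.post_dose_times_h]
        return Regimen(events, analyte)

    def time_grid(self) -> np.ndarray:
        """Dense grid (days, coitus at 0) including very early post-first-dose
        points to capture the initial anabolite accumulation."""
        t0 = -self.pre_coitus_offset_h * HOUR
        grid = np.arange(t0, self.horizon_days + 1e-9, 0.1)
        early = t0 + np.array([0.0, 1e-4, 1e-3, 1e-2])
        dose_times = np.array([h * HOUR for h in self.post_dose_times_h])
        return np.unique(np.concatenate([grid, early, [0.0], dose_times,
                                         [self.horizon_days]]))


#: ratio label -> (analyte chain, dNTP stream)
RATIOS = {"TFVDP:dATP": ("TFV", "dATP"), "FTCTP:dCTP": ("FTC", "dCTP")}


@dataclass
class PrepSimResult:
    times: np.ndarray                       # days, coitus at 0
    ratios: dict[str, np.ndarray]           # label -> (n_subjects, n_times)
    spec: PrepRegimenSpec

    def at_time(self, label: str, at_time: float) -> np.ndarray:
        """Per-subject ratio at one time, linearly interpolated on the grid."""
        if not (self.times[0] <= at_time <= self.times[-1]):
            raise ValueError("at_time outside the simulated horizon")
        arr = self.ratios[label]
        return np.array([np.interp(at_time, self.times, row) for row in arr])


def simulate_prep(n: int, spec: PrepRegimenSpec, chain_cfgs: list[ChainConfig],
                  seed=0, p_male: float = 0.675) -> PrepSimResult:
    """Simulate n virtual HIV-negative subjects under the on-demand regimen."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfgs = {c.params.analyte: c for c in chain_cfgs}
    subjects = sample_population(n, list(cfgs.values()), seed,
                                 p_male=p_male, hiv=0)
    grid = spec.time_grid()
    out = {}
    for label, (analyte, dntp_name) in RATIOS.items():
        if analyte not in cfgs:
            continue
        tablet = cfgs[analyte].params.dose_ug
        reg = spec.regimen(analyte, tablet)
        rows = np.empty((n, len(grid)))
        for i, subj in enumerate(subjects):
            traj = integrate(reg, subj.params[analyte], grid)
            denom = traj.dntp(dntp_name)
            if np.any(denom <= 0):
                raise RuntimeError(f"dNTP {dntp_name} hit zero for subject "
                                   f"{subj.id}; parameters invalid")
            rows[i] = traj.ic_conc / denom
        out[label] = rows
    return PrepSimResult(times=grid, ratios=out, spec=spec)


def percent_above(result: PrepSimResult, label: str, threshold: float,
                  at_time: float = 0.0) -> float:
    """Percentage of subjects whose ratio exceeds ``threshold`` at ``at_time``."""
    vals = result.at_time(label, at_time)
    if vals.size == 0:
        raise ValueError("empty ratio set")
    return 100.0 * float(np.mean(vals > threshold))


def percentile_bands(result: PrepSimResult, label: str,
                     percentiles=None) -> dict[int, np.ndarray]:
    """Per-time empirical percentiles (default P5..P95 by 5) of one ratio."""
    if percentiles is None:
        percentiles = list(range(5, 100, 5))
    arr = result.ratios[label]
    if min(percentiles) <= 5 or max(percentiles) >= 95:
        if arr.shape[0] < 20:
            raise ValueError("outer percentiles need at least 20 subjects")
    return {int(p): np.percentile(arr, p, axis=0) for p in percentiles}
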