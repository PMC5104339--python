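"""Parameter containers for one analyte chain (plasma -> intracellular -> dNTPs).

Unit conventions
----------------
Time is in days throughout (all rate constants are /day).  Doses are entered
in micrograms of parent-drug equivalent (one standard tablet delivers
136,000 ug tenofovir or 200,000 ug emtricitabine) and volumes in litres, so
the plasma observable ``A2/Vc_F`` is in ug/L == ng/mL, the unit of the plasma
assay.  Intracellular anabolite and dNTP amounts are in fmol per 10^6 PBMC;
no mass moves between plasma and cells, the plasma concentration only drives
the intracellular formation rate (the ng/mL -> fmol/10^6 cells conversion is
folded into ``Kf``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field


class ParameterError(ValueError):
    """A parameter value violates its invariant."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{path}: {msg}")


@dataclass
class PlasmaParams:
    """Two-compartment disposition with first-order absorption.

    Ka    absorption rate constant, 1/day
    Vc_F  apparent central volume, L
    CL_F  apparent clearance, L/day
    Vp_F  apparent peripheral volume, L
    Q_F   apparent intercompartmental clearance, L/day
    """

    Ka: float
    Vc_F: float
    CL_F: float
    Vp_F: float
    Q_F: float

    def validate(self, path: str = "plasma") -> None:
        for name in ("Ka", "Vc_F", "CL_F", "Vp_F", "Q_F"):
            _require(getattr(self, name) > 0, f"{path}.{name}", "must be > 0")


@dataclass
class IntracellularParams:
    """Hybrid first-order-formation / saturation / recycle anabolite model.

    Kf    first-order formation rate constant, 1/day (absorbs the
          ng/mL -> fmol/10^6 cells unit conversion)
    SC50  saturation-compartment level giving 50% formation inhibition
          (same units as plasma concentration, ng/mL)
    Kel   total intracellular elimination rate constant, 1/day
    R     recycling fraction in [0, 1); the recycle exchange rates are
          R*Kel and net central elimination (1-R)*Kel
    """

    Kf: float
    SC50: float
    Kel: float
    R: float

    def validate(self, path: str = "ic") -> None:
        for name in ("Kf", "SC50", "Kel"):
            _require(getattr(self, name) > 0, f"{path}.{name}", "must be > 0")
        _require(0.0 <= self.R < 1.0, f"{path}.R", "must lie in [0, 1)")


@dataclass
class DntpParams:
    """Indirect-response (turnover) model for one endogenous dNTP.

    R0     baseline level, fmol/10^6 cells; the zero-order production rate
           is K0in = R0 * Kout
    EC50   anabolite level giving 50% inhibition of production,
           fmol/10^6 cells
    Emax   maximum inhibition fraction (fixed to 1)
    Kout   turnover rate constant (fixed to 1 /day)
    gamma  optional time-waning exponent; when set, the inhibition term is
           additionally multiplied by 1/(1 + t^gamma), t = days since the
           first dose (used for dGTP, whose response is transient)
    """

    name: str
    R0: float
    EC50: float
    Emax: float = 1.0
    Kout: float = 1.0
    gamma: float | None = None

    def validate(self, path: str = "dntp") -> None:
        p = f"{path}.{self.name}"
        _require(self.R0 > 0, f"{p}.R0", "must be > 0")
        _require(self.EC50 > 0, f"{p}.EC50", "must be > 0")
        _require(self.Emax == 1.0, f"{p}.Emax", "is fixed to 1")
        _require(self.Kout == 1.0, f"{p}.Kout", "is fixed to 1 /day")
        if self.gamma is not None:
            _require(self.gamma > 0, f"{p}.gamma", "must be > 0 when present")


#: Observable stream carried by each chain: the plasma parent drug, the
#: intracellular anabolite, and the two linked dNTPs.
IC_STREAM = {"TFV": "TFVDP", "FTC": "FTCTP"}


@dataclass
class ChainParams:
    """Full parameter bundle for one analyte chain.

    A chain is plasma parent drug (TFV or FTC) -> intracellular anabolite
    (TFV-DP or FTC-TP) -> the two endogenous dNTPs it perturbs
    (deoxypurines dATP/dGTP for TFV, deoxypyrimidines dCTP/TTP for FTC).
    """

    analyte: str
    dose_ug: float
    plasma: PlasmaParams
    ic: IntracellularParams
    dntps: list[DntpParams] = field(default_factory=list)

    def validate(self) -> None:
        _require(self.analyte in IC_STREAM, "analyte", "must be 'TFV' or 'FTC'")
        _require(self.dose_ug > 0, "dose_ug", "must be > 0")
        self.plasma.validate()
        self.ic.validate()
        _require(len(self.dntps) == 2, "dntp", "a chain carries exactly two dNTP streams")
        for d in self.dntps:
            d.validate()

    # -- stream / path helpers -------------------------------------------------

    @property
    def ic_stream(self) -> str:
        return IC_STREAM[self.analyte]

    @property
    def streams(self) -> list[str]:
        return [self.analyte, self.ic_stream] + [d.name for d in self.dntps]

    def dntp(self, name: str) -> DntpParams:
        for d in self.dntps:
            if d.name == name:
                return d
        raise KeyError(f"chain {self.analyte} has no dNTP stream {name!r}")

    def copy(self) -> "ChainParams":
        return copy.deepcopy(self)

    def get(self, path: str) -> float:
        """Read a parameter by dotted path, e.g. 'plasma.CL_F' or 'dntp.dATP.R0'."""
        obj, attr = self._resolve(path)
        return getattr(obj, attr)

    def set(self, path: str, value: float) -> None:
        obj, attr = self._resolve(path)
        setattr(obj, attr, value)

    def _resolve(self, path: str):
        parts = path.split(".")
        obj = None
        if parts[0] == "plasma" and len(parts) == 2:
            obj = self.plasma
        elif parts[0] == "ic" and len(parts) == 2:
            obj = self.ic
        elif parts[0] == "dntp" and len(parts) == 3:
            obj = self.dntp(parts[1])
        if obj is None or not hasattr(obj, parts[-1]):
            raise KeyError(f"unknown parameter path {path!r}")
        return obj, parts[-1]


@dataclass
class CovariateEffect:
    """Additive shift of a typical value by a binary covariate.

    ``param := param + coeff * covariate`` with covariate in {0, 1}
    (sex: male=1, female=0; hiv: positive=1, negative=0).
    """

    param: str
    covariate: str
    coeff: float

    def validate(self) -> None:
        _require(self.covariate in ("sex", "hiv"), f"covariate[{self.param}]",
                 "covariate must be 'sex' or 'hiv'")


@dataclass
class VariabilitySpec:
    """Random-effect structure: lognormal IIV and per-stream residual error.

    omega2       parameter path -> IIV variance on the exponential scale
                 (individual = typical * exp(eta), eta ~ N(0, omega2));
                 the printed %CV convention is 100*sqrt(omega2)
    sigma2       observation stream -> residual variance
    error_model  stream -> 'exponential' (y = f*exp(eps)) or
                 'proportional' (y = f*(1+eps))
    """

    omega2: dict[str, float] = field(default_factory=dict)
    sigma2: dict[str, float] = field(default_factory=dict)
    error_model: dict[str, str] = field(default_factory=dict)

    def validate(self, chain: ChainParams | None = None) -> None:
        for k, v in self.omega2.items():
            _require(v >= 0, f"variability.omega2.{k}", "variance must be >= 0")
            if chain is not None:
                chain.get(k)  # raises KeyError for unknown paths
        for k, v in self.sigma2.items():
            _require(v >= 0, f"variability.sigma2.{k}", "variance must be >= 0")
            _require(k in self.error_model, f"variability.error_model.{k}",
                     "every stream with a sigma2 needs an error model")
        for k, m in self.error_model.items():
            _require(m in ("exponential", "proportional"),
                     f"variability.error_model.{k}",
                     "must be 'exponential' or 'proportional'")


@dataclass
class ChainConfig:
    """One chain's typical values + covariate model + variability."""

    params: ChainParams
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    variability: VariabilitySpec = field(default_factory=VariabilitySpec)

    def validate(self) -> None:
        self.params.validate()
        for e in self.covariate_effects:
            e.validate()
            self.params.get(e.param)
        self.variability.validate(self.params)

    def copy(self) -> "ChainConfig":
        return copy.deepcopy(self)
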