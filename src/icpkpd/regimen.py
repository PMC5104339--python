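"""Dosing regimens: timed oral dose events in parent-equivalent micrograms."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Parent-drug equivalent mass of one standard co-formulated tablet, ug.
#: (TDF 300 mg delivers 136 mg tenofovir; FTC tablets contain 200 mg.)
STANDARD_DOSE_UG = {"TFV": 136_000.0, "FTC": 200_000.0}


@dataclass(frozen=True)
class DoseEvent:
    time: float      # days
    amount: float    # ug parent-drug equivalent


@dataclass
class Regimen:
    """A sorted sequence of bolus-into-depot dose events for one analyte."""

    events: list[DoseEvent] = field(default_factory=list)
    analyte: str = "TFV"

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("dose event times must be nondecreasing")
        if any(e.amount < 0 for e in self.events):
            raise ValueError("dose amounts must be >= 0")

    @property
    def times(self) -> list[float]:
        return [e.time for e in self.events]

    @property
    def first_dose_time(self) -> float | None:
        for e in self.events:
            if e.amount > 0:
                return e.time
        return None

    @classmethod
    def daily(cls, analyte: str, n_doses: int, dose_ug: float | None = None,
              tau: float = 1.0, start: float = 0.0) -> "Regimen":
        """n_doses doses of dose_ug every tau days, first dose at ``start``."""
        amt = STANDARD_DOSE_UG[analyte] if dose_ug is None else dose_ug
        return cls([DoseEvent(start + i * tau, amt) for i in range(n_doses)], analyte)

    @classmethod
    def single(cls, analyte: str, dose_ug: float | None = None,
               time: float = 0.0) -> "Regimen":
        return cls.daily(analyte, 1, dose_ug, start=time)

    def scaled(self, factor: float) -> "Regimen":
        return Regimen([DoseEvent(e.time, e.amount * factor) for e in self.events],
                       self.analyte)

    def shifted(self, dt: float) -> "Regimen":
        return Regimen([DoseEvent(e.time + dt, e.amount) for e in self.events],
                       self.analyte)

    def merged(self, other: "Regimen") -> "Regimen":
        if other.analyte != self.analyte:
            raise ValueError("cannot merge regimens of different analytes")
        ev = sorted(self.events + other.events, key=lambda e: e.time)
        return Regimen(ev, self.analyte)

    # -- CSV round trip (columns: time_days, amount_ug, analyte) ---------------

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_days": [e.time for e in self.events],
            "amount_ug": [e.amount for e in self.events],
            "analyte": self.analyte,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Regimen":
        df = pd.read_csv(path)
        missing = {"time_days", "amount_ug", "analyte"} - set(df.columns)
        if missing:
            raise ValueError(f"regimen file lacks columns: {sorted(missing)}")
        analytes = df["analyte"].unique()
        if len(analytes) != 1:
            raise ValueError("a regimen file must contain a single analyte")
        events = [DoseEvent(float(t), float(a))
                  for t, a in zip(df["time_days"], df["amount_ug"])]
        return cls(events, str(analytes[0]))
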