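"""The gas-exchange curve container shared by fitting and simulation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ricephys.errors import InputDataError

#: PPFD ladder used for the light-response measurements (µmol m⁻² s⁻¹),
#: high to low as driven on the instrument.
PPFD_LADDER = (2000, 1800, 1500, 1200, 1000, 800, 600, 400, 200, 150, 100, 50, 20, 0)

#: CO2 setpoint ladder for the A/Ci measurements (ppm): a descending arm
#: from ambient down to 50, then an ascending arm to 1800.
CI_LADDER = (425, 350, 250, 150, 100, 50, 500, 700, 900, 1100, 1300, 1500, 1800)


@dataclass
class GasExchangeCurve:
    """Ordered (driver, Pn) observations from one leaf gas-exchange run.

    ``driver_kind`` is ``"ppfd"`` for a light-response curve (driver in
    µmol photons m⁻² s⁻¹) or ``"ci"`` for an A/Ci curve (driver in
    µmol mol⁻¹). ``pn`` is net photosynthesis in µmol CO2 m⁻² s⁻¹.
    """

    driver_kind: str
    driver: np.ndarray
    pn: np.ndarray
    cultivar: str = ""
    stage: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        self.driver_kind = str(self.driver_kind).lower()
        if self.driver_kind not in ("ppfd", "ci"):
            raise ValueError(f"driver_kind must be 'ppfd' or 'ci', got {self.driver_kind!r}")
        self.driver = np.asarray(self.driver, dtype=float)
        self.pn = np.asarray(self.pn, dtype=float)
        if self.driver.shape != self.pn.shape or self.driver.ndim != 1:
            raise ValueError("driver and pn must be 1-D arrays of equal length")
        if np.any(self.driver < 0):
            raise ValueError("driver values must be nonnegative")
        rounded = np.round(self.driver, 1)
        if len(np.unique(rounded)) != len(rounded):
            raise InputDataError("driver values must be unique after rounding to 0.1")

    def __len__(self) -> int:
        return len(self.driver)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "driver_kind": self.driver_kind,
                "driver": self.driver,
                "pn": self.pn,
                "cultivar": self.cultivar,
                "stage": self.stage,
                "date": self.date,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GasExchangeCurve":
        kinds = df["driver_kind"].astype(str).str.lower().unique()
        if len(kinds) != 1:
            raise InputDataError(f"mixed driver_kind within one curve: {sorted(kinds)}")

        def _meta(col: str) -> str:
            if col not in df.columns:
                return ""
            vals = df[col].astype(str).unique()
            return vals[0] if len(vals) == 1 else ""

        return cls(
            driver_kind=kinds[0],
            driver=df["driver"].to_numpy(dtype=float),
            pn=df["pn"].to_numpy(dtype=float),
            cultivar=_meta("cultivar"),
            stage=_meta("stage"),
            date=_meta("date"),
        )
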