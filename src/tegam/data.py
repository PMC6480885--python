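"""Daily time-series container and its canonical CSV schema.

The canonical on-disk form is a plain CSV with columns
``date,deaths,pm10,no2,so2,temp,rh,pressure,holiday`` — ISO-8601 dates,
deaths as nonnegative integers, pollutant concentrations in ug/m3 (missing
values as empty fields), temperature in degC, relative humidity in %,
pressure in hPa and holiday as a 0/1 flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POLLUTANTS = ("pm10", "no2", "so2")
COLUMNS = ("date", "deaths", "pm10", "no2", "so2", "temp", "rh", "pressure", "holiday")


@dataclass
class DailyDataset:
    """Aligned daily series of counts, exposures, weather and calendar flags.

    Wraps a validated :class:`pandas.DataFrame` with the canonical columns.
    ``true_mu`` optionally carries the simulated per-day expected count for
    oracle use in parameter-recovery studies; it is never written to CSV.
    """

    frame: pd.DataFrame
    true_mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dates = pd.to_datetime(df["date"])
        deltas = dates.diff().dropna()
        if len(df) and not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("dates must be consecutive calendar days")
        if (df["deaths"].dropna() < 0).any():
            raise ValueError("death counts must be nonnegative")
        rh = df["rh"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("relative humidity must lie in [0, 100]")
        for col in POLLUTANTS:
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} concentrations must be nonnegative")
        if self.true_mu is not None and len(self.true_mu) != len(df):
            raise ValueError("true_mu length mismatch")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dow(self) -> pd.Series:
        """Day-of-week category (Monday=0 .. Sunday=6)."""
        return pd.to_datetime(self.frame["date"]).dt.dayofweek

    def to_csv(self, path) -> None:
        out = self.frame.loc[:, list(COLUMNS)].copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out["deaths"] = out["deaths"].astype("Int64")
        out["holiday"] = out["holiday"].astype(int)
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "DailyDataset":
        df = pd.read_csv(path)
        df["date"] = pd.to_datetime(df["date"])
        return cls(frame=df)
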