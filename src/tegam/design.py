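"""Lagged exposures, confounder bases and model matrices for Models I-IV.

The four competing specifications share one confounder block — natural cubic
splines of the 14-day moving-average temperature, same-day humidity and
pressure (df 3 each), a natural cubic spline of calendar time (default
7 df per year), day-of-week dummies (reference Monday) and a holiday flag —
and differ only in how the 3-day moving-average pollutant concentrations
enter:

* Model I   — one pollutant at a time, linearly;
* Model II  — all three pollutants, linearly, no interactions;
* Model III — Model II plus the three pairwise products;
* Model IV  — a sum-to-zero-centered tensor-product smooth of the three
  pollutants with one roughness penalty per margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DailyDataset, POLLUTANTS
from .gam import PenalizedDesign
from .splines import (
    NaturalSplineBasis,
    TensorSmooth,
    apply_centering,
    cubic_marginal,
    expand_penalties,
    natural_cubic_basis,
    tensor_design_matrix,
)

__all__ = ["ModelSpec", "BuiltDesign", "moving_average", "build_confounders", "build_model"]

_DOW_LABELS = ("tue", "wed", "thu", "fri", "sat", "sun")  # Monday is the reference
_PAIRS = (("pm10", "no2"), ("pm10", "so2"), ("no2", "so2"))


@dataclass(frozen=True)
class ModelSpec:
    """Which model to build and with what lags / basis dimensions.

    ``pollutant_lag`` and ``temperature_lag`` are trailing moving-average
    window lengths in days (3 = lag 0-2, 14 = lag 0-13).  ``df_time_per_year``
    follows the daily-mortality convention of spline df per year of data;
    set ``df_time_total`` to pin an absolute total instead.
    """

    model: str = "IV"
    pollutant: str | None = None  # Model I only
    pollutant_lag: int = 3
    temperature_lag: int = 14
    df_time_per_year: float = 7.0
    df_time_total: int | None = None
    df_met: int = 3
    tensor_dims: tuple[int, int, int] = (5, 5, 5)

    def __post_init__(self) -> None:
        if self.model not in {"I", "II", "III", "IV"}:
            raise ValueError("model must be one of I, II, III, IV")
        if self.model == "I" and self.pollutant not in POLLUTANTS:
            raise ValueError("Model I requires pollutant in " + str(POLLUTANTS))
        if self.pollutant_lag < 1 or self.temperature_lag < 1:
            raise ValueError("lag windows must be >= 1 day")
        if self.df_met < 1:
            raise ValueError("df_met must be >= 1")

    def df_time(self, n_days: int) -> int:
        if self.df_time_total is not None:
            return int(self.df_time_total)
        return max(1, int(round(self.df_time_per_year * n_days / 365.25)))


@dataclass
class BuiltDesign:
    """A ready-to-fit penalized design plus the effect-contrast metadata."""

    design: PenalizedDesign
    spec: ModelSpec
    dropped_days: list
    increments: dict[str, float]        # IQR of the lagged exposure in the model
    reference_levels: dict[str, float]  # 25th percentile of the lagged exposure
    lagged: pd.DataFrame                # lagged exposures on the retained days
    smooth: TensorSmooth | None = None
    warnings: list[str] = field(default_factory=list)
    confounder_bases: dict[str, NaturalSplineBasis] = field(default_factory=dict)

    @property
    def n_used(self) -> int:
        return self.design.n

    def quantile(self, pollutant: str, q: float) -> float:
        return float(np.quantile(self.lagged[pollutant].to_numpy(), q))

    def to_csv(self, path) -> None:
        """Export the labeled model matrix for external cross-validation."""
        labels: list[str] = []
        for name, (start, stop) in sorted(self.design.column_map.items(), key=lambda kv: kv[1]):
            width = stop - start
            labels.extend([name] if width == 1 else [f"{name}[{j}]" for j in range(width)])
        out = pd.DataFrame(self.design.X, columns=labels)
        out.insert(0, "deaths", self.design.y)
        out.to_csv(path, index=False)


def moving_average(x, window: int) -> pd.Series:
    """Trailing moving average over days t-window+1 .. t.

    The result is missing whenever ANY constituent day is missing, and for
    the first ``window - 1`` warm-up days.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window, min_periods=window).mean()


def build_confounders(
    data: DailyDataset, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, NaturalSplineBasis]]:
    """Confounder columns shared by all four models.

    Returns the column frame (missing on temperature warm-up days) and the
    fitted natural-spline basis records for reuse at prediction time.
    """
    df = data.frame
    n = len(df)
    temp_ma = moving_average(df["temp"], spec.temperature_lag)
    cols: dict[str, np.ndarray] = {}
    bases: dict[str, NaturalSplineBasis] = {}

    def add_ns(name: str, values: pd.Series, df_spline: int) -> None:
        valid = values.dropna()
        if valid.empty:
            raise ValueError(f"all days dropped: no complete values for {name}")
        mat, basis = natural_cubic_basis(valid.to_numpy(), df_spline)
        full = np.full((n, mat.shape[1]), np.nan)
        full[values.notna().to_numpy()] = mat
        for j in range(mat.shape[1]):
            cols[f"ns({name})[{j}]"] = full[:, j]
        bases[name] = basis

    add_ns("temp_ma", temp_ma, spec.df_met)
    add_ns("rh", df["rh"], spec.df_met)
    add_ns("pressure", df["pressure"], spec.df_met)
    add_ns("time", pd.Series(np.arange(n, dtype=float)), spec.df_time(n))

    dow = data.dow.to_numpy()
    for j, label in enumerate(_DOW_LABELS, start=1):
        cols[f"dow_{label}"] = (dow == j).astype(float)
    cols["holiday"] = df["holiday"].to_numpy().astype(float)

    return pd.DataFrame(cols, index=df.index), bases


def build_model(data: DailyDataset, spec: ModelSpec) -> BuiltDesign:
    """Assemble the model matrix, penalties and contrast metadata.

    Days with any missing required value (count, confounder, lagged
    exposure) are dropped and recorded; IQR increments and 25th-percentile
    reference levels are computed from the lagged exposures actually
    retained in the model.
    """
    df = data.frame
    n = len(df)
    confounders, bases = build_confounders(data, spec)

    lagged = pd.DataFrame(
        {p: moving_average(df[p], spec.pollutant_lag) for p in POLLUTANTS},
        index=df.index,
    )
    needed = list(POLLUTANTS) if spec.model != "I" else [spec.pollutant]

    ok = (
        df["deaths"].notna().to_numpy()
        & confounders.notna().all(axis=1).to_numpy()
        & lagged[needed].notna().all(axis=1).to_numpy()
    )
    dropped = pd.to_datetime(df.loc[~ok, "date"]).tolist()
    warnings_list: list[str] = []
    if not ok.any():
        raise ValueError("all days dropped: no complete rows to fit")
    if len(dropped) > 0.10 * n:
        warnings_list.append(
            f"warning: {len(dropped)} of {n} days dropped for missingness/warm-up"
        )

    y = df.loc[ok, "deaths"].to_numpy(dtype=float)
    blocks: list[np.ndarray] = [np.ones((int(ok.sum()), 1))]
    column_map: dict[str, tuple[int, int]] = {"intercept": (0, 1)}
    pos = 1

    def add_block(name: str, mat: np.ndarray) -> None:
        nonlocal pos
        mat = np.atleast_2d(mat)
        if mat.shape[0] == 1 and mat.shape[1] != 1:
            mat = mat.T
        blocks.append(mat)
        column_map[name] = (pos, pos + mat.shape[1])
        pos += mat.shape[1]

    conf_frame = confounders.loc[ok]
    # indicator columns with no occurrences in the retained days (e.g. a
    # holiday-free sample) would be all-zero; drop them
    nonzero = (conf_frame != 0).any()
    dropped_cols = [c for c in conf_frame.columns if not nonzero[c]]
    if dropped_cols:
        warnings_list.append(f"dropped empty indicator columns: {dropped_cols}")
    add_block("confounders", conf_frame.loc[:, nonzero].to_numpy())

    lag_ok = lagged.loc[ok]
    increments = {
        p: float(lag_ok[p].quantile(0.75) - lag_ok[p].quantile(0.25))
        for p in POLLUTANTS
        if lag_ok[p].notna().all()
    }
    reference_levels = {
        p: float(lag_ok[p].quantile(0.25)) for p in POLLUTANTS if lag_ok[p].notna().all()
    }

    penalties: list[tuple[np.ndarray, str]] = []
    smooth: TensorSmooth | None = None

    if spec.model == "I":
        add_block(spec.pollutant, lag_ok[spec.pollutant].to_numpy().reshape(-1, 1))
    elif spec.model in ("II", "III"):
        for p in POLLUTANTS:
            add_block(p, lag_ok[p].to_numpy().reshape(-1, 1))
        if spec.model == "III":
            for a, b in _PAIRS:
                add_block(
                    f"{a}:{b}",
                    (lag_ok[a].to_numpy() * lag_ok[b].to_numpy()).reshape(-1, 1),
                )
    else:  # Model IV
        dims = spec.tensor_dims
        margins = (
            cubic_marginal(lag_ok["pm10"].to_numpy(), dims[0], name="pm10"),
            cubic_marginal(lag_ok["no2"].to_numpy(), dims[1], name="no2"),
            cubic_marginal(lag_ok["so2"].to_numpy(), dims[2], name="so2"),
        )
        smooth = TensorSmooth(margins=margins)
        T = tensor_design_matrix(
            margins,
            lag_ok["pm10"].to_numpy(),
            lag_ok["no2"].to_numpy(),
            lag_ok["so2"].to_numpy(),
        )
        TZ, Z = apply_centering(smooth, T)
        add_block("te", TZ)
        raw_penalties = expand_penalties(margins)
        for S_raw, label in zip(raw_penalties, ("lambda_pm10", "lambda_no2", "lambda_so2")):
            penalties.append((Z.T @ S_raw @ Z, label))

    X = np.hstack(blocks)
    p_total = X.shape[1]
    embedded: list[tuple[np.ndarray, str]] = []
    for S_small, label in penalties:
        S_full = np.zeros((p_total, p_total))
        start, stop = column_map["te"]
        S_full[start:stop, start:stop] = S_small
        embedded.append((S_full, label))

    design = PenalizedDesign(X=X, y=y, penalties=embedded, column_map=column_map)
    if smooth is not None and not lagged.loc[ok].notna().all().all():
        raise AssertionError("tensor model requires complete lagged exposures")

    return BuiltDesign(
        design=design,
        spec=spec,
        dropped_days=dropped,
        increments=increments,
        reference_levels=reference_levels,
        lagged=lag_ok,
        smooth=smooth,
        warnings=warnings_list,
        confounder_bases=bases,
    )
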