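"""Rate ratios, excess risks and delta-method confidence intervals.

A contrast moves the three lagged pollutant exposures from one profile to
another (default: each pollutant's 25th to 75th percentile, an IQR
increase).  For every model the log rate ratio is a linear functional
c' beta of the fitted coefficients, so

    RR  = exp(c' beta),    se(log RR) = sqrt(c' Sigma c),
    CI  = exp(c' beta +/- z_{0.975} * se),    ER = (RR - 1) * 100%.

For the linear models c collects the exposure increments (plus interaction
difference terms for the interaction model); for the tensor-product model c
is the difference of tensor basis rows at the two profiles, restricted to
the smooth's columns — confounder columns cancel in any pure pollutant
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import POLLUTANTS
from .design import BuiltDesign
from .gam import FitResult
from .splines import TensorSmooth

__all__ = [
    "EffectEstimate",
    "RRSurface",
    "er_from_rr",
    "combined_rr_linear",
    "combined_rr_single_sum",
    "combined_rr_interaction",
    "rr_tensor",
    "profile_contrast",
    "rr_surface",
    "exposure_response_curve",
]

_Z = norm.ppf(0.975)
_PAIRS = (("pm10", "no2"), ("pm10", "so2"), ("no2", "so2"))


def er_from_rr(rr: float) -> float:
    """Excess risk in percent: (RR - 1) * 100."""
    if rr <= 0:
        raise ValueError("rate ratio must be positive")
    return (rr - 1.0) * 100.0


@dataclass(frozen=True)
class EffectEstimate:
    """A rate-ratio contrast with its delta-method uncertainty."""

    rr: float
    se_log_rr: float
    ci_low: float
    ci_high: float
    contrast: tuple[dict, dict]  # (from_levels, to_levels) in ug/m3
    model: str
    label: str = "combined"

    @property
    def log_rr(self) -> float:
        return float(np.log(self.rr))

    @property
    def er_percent(self) -> float:
        return er_from_rr(self.rr)

    @property
    def er_ci(self) -> tuple[float, float]:
        return ((self.ci_low - 1.0) * 100.0, (self.ci_high - 1.0) * 100.0)

    def covers(self, true_rr: float) -> bool:
        return self.ci_low <= true_rr <= self.ci_high


def _estimate(log_rr: float, var: float, contrast, model: str, label: str) -> EffectEstimate:
    se = float(np.sqrt(max(var, 0.0)))
    return EffectEstimate(
        rr=float(np.exp(log_rr)),
        se_log_rr=se,
        ci_low=float(np.exp(log_rr - _Z * se)),
        ci_high=float(np.exp(log_rr + _Z * se)),
        contrast=contrast,
        model=model,
        label=label,
    )


def _single_column(fit: FitResult, name: str) -> int:
    if name not in fit.column_map:
        raise KeyError(f"term {name!r} absent from the fitted model")
    start, stop = fit.column_map[name]
    if stop - start != 1:
        raise ValueError(f"term {name!r} is not a single column")
    return start


def combined_rr_linear(
    fit: FitResult,
    increments: Mapping[str, float],
    *,
    model: str = "II",
    label: str = "combined",
) -> EffectEstimate:
    """Exponentiated sum of coefficient x increment over the named pollutants."""
    idx = np.array([_single_column(fit, p) for p in increments])
    delta = np.array([increments[p] for p in increments], dtype=float)
    beta = fit.coefficients[idx]
    log_rr = float(beta @ delta)
    var = float(delta @ fit.covariance[np.ix_(idx, idx)] @ delta)
    contrast = ({p: 0.0 for p in increments}, dict(increments))
    return _estimate(log_rr, var, contrast, model, label)


def combined_rr_single_sum(
    fits: Mapping[str, FitResult], increments: Mapping[str, float]
) -> EffectEstimate:
    """Model I combined effect: sum of the three independent single fits.

    Covariances between the separate fits are zero, so the log rate ratios
    and their variances add.
    """
    log_rr = 0.0
    var = 0.0
    for p, fit in fits.items():
        j = _single_column(fit, p)
        log_rr += fit.coefficients[j] * increments[p]
        var += fit.covariance[j, j] * increments[p] ** 2
    contrast = ({p: 0.0 for p in fits}, dict(increments))
    return _estimate(log_rr, var, contrast, "I", "combined")


def combined_rr_interaction(
    fit: FitResult,
    from_levels: Mapping[str, float],
    to_levels: Mapping[str, float],
    *,
    label: str = "combined",
) -> EffectEstimate:
    """Interaction-model contrast: main-effect increments plus the
    differences of the pairwise products between the two profiles."""
    p = len(fit.coefficients)
    c = np.zeros(p)
    for pol in POLLUTANTS:
        c[_single_column(fit, pol)] = to_levels[pol] - from_levels[pol]
    for a, b in _PAIRS:
        name = f"{a}:{b}"
        if name in fit.column_map:
            c[_single_column(fit, name)] = (
                to_levels[a] * to_levels[b] - from_levels[a] * from_levels[b]
            )
    log_rr = float(c @ fit.coefficients)
    var = float(c @ fit.covariance @ c)
    return _estimate(log_rr, var, (dict(from_levels), dict(to_levels)), "III", label)


def _check_range(smooth: TensorSmooth, levels: Sequence[float]) -> None:
    for margin, level in zip(smooth.margins, levels):
        lo, hi = margin.knots[0], margin.knots[-1]
        pad = 0.10 * (hi - lo)
        if level < lo - pad or level > hi + pad:
            raise ValueError(
                f"{margin.variable_name} level {level:.3g} is beyond 10% outside "
                f"the training range [{lo:.3g}, {hi:.3g}]"
            )


def rr_tensor(
    fit: FitResult,
    smooth: TensorSmooth,
    from_levels: Sequence[float] | Mapping[str, float],
    to_levels: Sequence[float] | Mapping[str, float],
    *,
    label: str = "combined",
) -> EffectEstimate:
    """Tensor-product contrast RR = exp(te' v), se = sqrt(te' Sigma te).

    ``te`` is the difference of (centered) tensor basis rows at the two
    (pm10, no2, so2) profiles; Sigma is the coefficient covariance
    restricted to the smooth's columns.
    """
    if isinstance(from_levels, Mapping):
        from_levels = [from_levels[p] for p in POLLUTANTS]
    if isinstance(to_levels, Mapping):
        to_levels = [to_levels[p] for p in POLLUTANTS]
    _check_range(smooth, from_levels)
    _check_range(smooth, to_levels)
    te = smooth.constrained_row(to_levels) - smooth.constrained_row(from_levels)
    span = fit.columns("te")
    nu = fit.coefficients[span]
    Sigma = fit.covariance[span, span]
    log_rr = float(te @ nu)
    var = float(te @ Sigma @ te)
    contrast = (
        dict(zip(POLLUTANTS, map(float, from_levels))),
        dict(zip(POLLUTANTS, map(float, to_levels))),
    )
    return _estimate(log_rr, var, contrast, "IV", label)


def profile_contrast(
    fit: FitResult,
    built: BuiltDesign,
    from_levels: Mapping[str, float],
    to_levels: Mapping[str, float],
    *,
    label: str = "combined",
) -> EffectEstimate:
    """Model-appropriate RR for moving the exposure profile from -> to."""
    model = built.spec.model
    if model == "I":
        pol = built.spec.pollutant
        for other in POLLUTANTS:
            if other != pol and not np.isclose(
                from_levels.get(other, 0.0), to_levels.get(other, 0.0)
            ):
                raise ValueError("Model I can only contrast its own pollutant")
        inc = {pol: to_levels[pol] - from_levels[pol]}
        est = combined_rr_linear(fit, inc, model="I", label=label)
        return _estimate(
            est.log_rr, est.se_log_rr**2, (dict(from_levels), dict(to_levels)), "I", label
        )
    if model == "II":
        inc = {p: to_levels[p] - from_levels[p] for p in POLLUTANTS}
        est = combined_rr_linear(fit, inc, model="II", label=label)
        return _estimate(
            est.log_rr, est.se_log_rr**2, (dict(from_levels), dict(to_levels)), "II", label
        )
    if model == "III":
        return combined_rr_interaction(fit, from_levels, to_levels, label=label)
    return rr_tensor(fit, built.smooth, from_levels, to_levels, label=label)


@dataclass
class RRSurface:
    """RR over a grid of two pollutants, the third fixed at its reference."""

    fixed_pollutant: str
    fixed_level: float
    free_pollutants: tuple[str, str]
    grid1: np.ndarray
    grid2: np.ndarray
    rr_values: np.ndarray  # shape (len(grid1), len(grid2))
    se_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        g1, g2 = np.meshgrid(self.grid1, self.grid2, indexing="ij")
        return pd.DataFrame(
            {
                self.free_pollutants[0]: g1.ravel(),
                self.free_pollutants[1]: g2.ravel(),
                "rr": self.rr_values.ravel(),
                "se_log_rr": self.se_values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, fixed_pollutant: str, fixed_level: float) -> "RRSurface":
        df = pd.read_csv(path)
        free = tuple(df.columns[:2])
        g1 = np.unique(df[free[0]].to_numpy())
        g2 = np.unique(df[free[1]].to_numpy())
        shape = (len(g1), len(g2))
        return cls(
            fixed_pollutant=fixed_pollutant,
            fixed_level=fixed_level,
            free_pollutants=free,  # type: ignore[arg-type]
            grid1=g1,
            grid2=g2,
            rr_values=df["rr"].to_numpy().reshape(shape),
            se_values=df["se_log_rr"].to_numpy().reshape(shape),
        )


def rr_surface(
    fit: FitResult,
    built: BuiltDesign,
    fixed_pollutant: str,
    grid_resolution: int = 20,
) -> RRSurface:
    """Tensor-model RR surface with one pollutant held at its reference.

    The grid spans the central 1st-99th percentile range of the two free
    pollutants; the joint 25th-percentile profile is the RR = 1 reference.
    """
    if built.smooth is None:
        raise ValueError("RR surfaces require a tensor (Model IV) fit")
    free = tuple(p for p in POLLUTANTS if p != fixed_pollutant)
    ref = dict(built.reference_levels)
    grids = []
    for p in free:
        lo, hi = built.quantile(p, 0.01), built.quantile(p, 0.99)
        g = np.linspace(lo, hi, grid_resolution)
        # include the exact reference level so the surface contains RR = 1
        g = np.sort(np.unique(np.append(g, ref[p])))
        grids.append(g)
    rr = np.zeros((len(grids[0]), len(grids[1])))
    se = np.zeros_like(rr)
    for i, v1 in enumerate(grids[0]):
        for j, v2 in enumerate(grids[1]):
            to = dict(ref)
            to[free[0]] = float(v1)
            to[free[1]] = float(v2)
            est = rr_tensor(fit, built.smooth, ref, to)
            rr[i, j] = est.rr
            se[i, j] = est.se_log_rr
    return RRSurface(
        fixed_pollutant=fixed_pollutant,
        fixed_level=ref[fixed_pollutant],
        free_pollutants=free,  # type: ignore[arg-type]
        grid1=grids[0],
        grid2=grids[1],
        rr_values=rr,
        se_values=se,
    )


def exposure_response_curve(
    fit: FitResult,
    built: BuiltDesign,
    pollutant: str,
    n_points: int = 50,
) -> pd.DataFrame:
    """Pointwise RR and 95% band along one pollutant, others at reference.

    Log-linear by construction for Models I-III; evaluated through the
    tensor contrast for Model IV.
    """
    ref = dict(built.reference_levels)
    lo, hi = built.quantile(pollutant, 0.01), built.quantile(pollutant, 0.99)
    levels = np.sort(np.unique(np.append(np.linspace(lo, hi, n_points), ref[pollutant])))
    rows = []
    for x in levels:
        to = dict(ref)
        to[pollutant] = float(x)
        est = profile_contrast(fit, built, ref, to, label=pollutant)
        rows.append(
            {
                "level": float(x),
                "rr": est.rr,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "se_log_rr": est.se_log_rr,
            }
        )
    return pd.DataFrame(rows)
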