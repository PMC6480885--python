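"""Penalized quasi-Poisson estimation by PIRLS with GCV smoothness selection.

The model is log mu = X beta with Var(y) = phi * mu.  For fixed smoothing
parameters lambda the coefficients maximize the penalized quasi-likelihood

    l(beta) - 1/2 * sum_m lambda_m * beta' S_m beta,

which penalized iteratively re-weighted least squares (PIRLS) solves by
repeatedly regressing the working response z = eta + (y - mu)/mu on X with
weights W = diag(mu).  The dispersion phi does not enter the mean fit
(quasi-likelihood), only the coefficient covariance.

Smoothing parameters are selected by minimizing the generalized
cross-validation score GCV(lambda) = n * P(lambda) / (n - edf(lambda))^2,
with P the Pearson statistic — the scale-free choice when the dispersion is
unknown — over a per-coordinate log-scale grid with golden-section
refinement (cyclic coordinate descent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PenalizedDesign",
    "FitResult",
    "GCVConfig",
    "PIRLSError",
    "pirls_fit",
    "pearson_dispersion",
    "coef_covariance",
    "gcv_select",
]


class PIRLSError(RuntimeError):
    pass


@dataclass
class PenalizedDesign:
    """Model matrix, response and penalties embedded at full p x p size.

    ``column_map`` maps term labels to ``(start, stop)`` column spans of X.
    ``penalties`` is a list of ``(S, label)`` with S already embedded in the
    p x p coordinate system; each smoothing parameter multiplies one S.
    """

    X: np.ndarray
    y: np.ndarray
    penalties: list[tuple[np.ndarray, str]] = field(default_factory=list)
    column_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("y length must match rows of X")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.y)):
            raise ValueError("X and y must be finite (drop missing days first)")
        col_norms = np.abs(self.X).sum(axis=0)
        if np.any(col_norms == 0):
            bad = np.flatnonzero(col_norms == 0)
            raise ValueError(f"all-zero design columns at indices {bad.tolist()}")
        for S, label in self.penalties:
            if S.shape != (p, p):
                raise ValueError(f"penalty '{label}' is {S.shape}, expected {(p, p)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def columns(self, label: str) -> slice:
        start, stop = self.column_map[label]
        return slice(start, stop)


@dataclass
class FitResult:
    coefficients: np.ndarray
    covariance: np.ndarray            # default (sandwich or bayes per cov_type)
    covariance_bayes: np.ndarray      # phi * (X'WX + S)^-1
    dispersion: float
    lambdas: np.ndarray
    edf: float
    gcv: float
    fitted_mu: np.ndarray
    deviance: float
    pearson: float
    penalized_deviance: float
    iterations: int
    converged: bool
    column_map: dict[str, tuple[int, int]]
    cov_type: str = "sandwich"
    log: list[str] = field(default_factory=list)

    def columns(self, label: str) -> slice:
        start, stop = self.column_map[label]
        return slice(start, stop)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "covariance_bayes": self.covariance_bayes.tolist(),
            "dispersion": self.dispersion,
            "lambdas": np.asarray(self.lambdas).tolist(),
            "edf": self.edf,
            "gcv": self.gcv,
            "fitted_mu": self.fitted_mu.tolist(),
            "deviance": self.deviance,
            "pearson": self.pearson,
            "penalized_deviance": self.penalized_deviance,
            "iterations": self.iterations,
            "converged": self.converged,
            "column_map": {k: list(v) for k, v in self.column_map.items()},
            "cov_type": self.cov_type,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            covariance_bayes=np.asarray(d["covariance_bayes"], dtype=float),
            dispersion=float(d["dispersion"]),
            lambdas=np.asarray(d["lambdas"], dtype=float),
            edf=float(d["edf"]),
            gcv=float(d["gcv"]),
            fitted_mu=np.asarray(d["fitted_mu"], dtype=float),
            deviance=float(d["deviance"]),
            pearson=float(d["pearson"]),
            penalized_deviance=float(d["penalized_deviance"]),
            iterations=int(d["iterations"]),
            converged=bool(d["converged"]),
            column_map={k: tuple(v) for k, v in d["column_map"].items()},
            cov_type=d.get("cov_type", "sandwich"),
        )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def pirls_fit(
    design: PenalizedDesign,
    lambdas: np.ndarray | list[float] | None = None,
    *,
    cov_type: str = "sandwich",
    tol: float = 1e-8,
    max_iter: int = 200,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """Fit the penalized quasi-Poisson model at fixed smoothing parameters.

    ``lambdas`` must match ``design.penalties`` in length (empty for the
    unpenalized parametric models).  ``cov_type`` selects the default
    coefficient covariance: "sandwich" (frequentist,
    phi * H^-1 X'WX H^-1 with H = X'WX + sum lambda_m S_m) or "bayes"
    (phi * H^-1); both are stored on the result.  ``beta0`` warm-starts the
    iteration (used heavily by the GCV search).
    """
    X, y = design.X, design.y
    n, p = X.shape
    lambdas = np.asarray([] if lambdas is None else lambdas, dtype=float)
    if len(lambdas) != len(design.penalties):
        raise ValueError(
            f"got {len(lambdas)} lambdas for {len(design.penalties)} penalties"
        )
    if np.any(lambdas < 0):
        raise ValueError("smoothing parameters must be nonnegative")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")

    S_lam = np.zeros((p, p))
    for lam, (S, _) in zip(lambdas, design.penalties):
        if lam != 0:
            S_lam += lam * S

    log: list[str] = []

    def penalized_dev(beta: np.ndarray, mu: np.ndarray) -> float:
        return _poisson_deviance(y, mu) + float(beta @ S_lam @ beta)

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        pdev = penalized_dev(beta, mu)
    else:
        mu = y + 0.5  # guard against log(0)
        eta = np.log(mu)
        beta = None
        pdev = np.inf

    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        H = X.T @ Xw + S_lam
        rhs = Xw.T @ z
        try:
            chol = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as exc:
            evals, evecs = np.linalg.eigh(H)
            direction = evecs[:, 0]
            raise PIRLSError(
                f"rank-deficient penalized Hessian (min eig {evals[0]:.3e}); "
                f"null direction leading loadings {np.argsort(-np.abs(direction))[:3].tolist()}"
            ) from exc
        beta_new = cho_solve(chol, rhs)

        # step-halving keeps the penalized deviance non-increasing
        step = 1.0
        for _ in range(30):
            cand = beta_new if beta is None or step == 1.0 else beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -30, 30)
            mu_c = np.exp(eta_c)
            pdev_c = penalized_dev(cand, mu_c)
            if np.isfinite(pdev_c) and (pdev_c <= pdev + 1e-12 * (abs(pdev) + 1.0) or beta is None):
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        log.append(f"iter {it}: penalized deviance {pdev_c:.10g} (step {step:g})")
        if np.isfinite(pdev) and abs(pdev - pdev_c) < tol * (abs(pdev_c) + 0.1):
            pdev = pdev_c
            converged = True
            break
        pdev = pdev_c
    else:
        raise PIRLSError(
            "PIRLS did not converge in "
            f"{max_iter} iterations; trace:\n" + "\n".join(log[-10:])
        )

    # converged-weight quantities
    w = mu
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    H = XtWX + S_lam
    chol = cho_factor(H, lower=True)
    edf = float(np.trace(cho_solve(chol, XtWX)))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / (n - edf)
    Hinv = cho_solve(chol, np.eye(p))
    cov_bayes = phi * Hinv
    cov_sandwich = phi * (Hinv @ XtWX @ Hinv)
    if cov_type == "sandwich":
        cov = cov_sandwich
    elif cov_type == "bayes":
        cov = cov_bayes
    else:
        raise ValueError("cov_type must be 'sandwich' or 'bayes'")
    gcv = n * pearson / (n - edf) ** 2

    return FitResult(
        coefficients=beta,
        covariance=0.5 * (cov + cov.T),
        covariance_bayes=0.5 * (cov_bayes + cov_bayes.T),
        dispersion=phi,
        lambdas=lambdas,
        edf=edf,
        gcv=gcv,
        fitted_mu=mu,
        deviance=_poisson_deviance(y, mu),
        pearson=pearson,
        penalized_deviance=pdev,
        iterations=it,
        converged=converged,
        column_map=dict(design.column_map),
        cov_type=cov_type,
        log=log,
    )


def pearson_dispersion(fit: FitResult, y: np.ndarray) -> float:
    """phi-hat = sum[(y - mu)^2 / mu] / (n - edf)."""
    y = np.asarray(y, dtype=float)
    mu = fit.fitted_mu
    return float(np.sum((y - mu) ** 2 / mu) / (len(y) - fit.edf))


def coef_covariance(fit: FitResult, design: PenalizedDesign, cov_type: str = "sandwich") -> np.ndarray:
    """Recompute the coefficient covariance at the converged weights."""
    X = design.X
    w = fit.fitted_mu
    p = X.shape[1]
    S_lam = np.zeros((p, p))
    for lam, (S, _) in zip(fit.lambdas, design.penalties):
        S_lam += lam * S
    XtWX = X.T @ (X * w[:, None])
    H = XtWX + S_lam
    try:
        chol = cho_factor(H, lower=True)
    except np.linalg.LinAlgError as exc:
        raise PIRLSError("singular penalized Hessian") from exc
    Hinv = cho_solve(chol, np.eye(p))
    phi = pearson_dispersion(fit, design.y)
    if cov_type == "sandwich":
        V = phi * (Hinv @ XtWX @ Hinv)
    elif cov_type == "bayes":
        V = phi * Hinv
    else:
        raise ValueError("cov_type must be 'sandwich' or 'bayes'")
    return 0.5 * (V + V.T)


@dataclass
class GCVConfig:
    """Search settings for the smoothing-parameter selection.

    The grid spans ``[lambda_min, lambda_max]`` on a log scale with
    ``points_per_decade`` points per decade; coordinates are optimized
    cyclically with optional golden-section refinement between the grid
    neighbors of the minimizer.
    """

    lambda_min: float = 1e-4
    lambda_max: float = 1e6
    points_per_decade: float = 7.0
    cycles: int = 2
    refine: bool = True
    refine_tol: float = 0.05  # in log10 units
    start: float = 1.0


def gcv_select(
    design: PenalizedDesign,
    config: GCVConfig | None = None,
    *,
    cov_type: str = "sandwich",
) -> tuple[np.ndarray, FitResult]:
    """Select smoothing parameters by minimizing the Pearson GCV score.

    Deterministic cyclic coordinate descent over a log-spaced grid.  Returns
    the selected lambdas and the refitted model at the minimizer; a minimum
    on the grid boundary is recorded as a warning in the fit log.
    """
    config = config or GCVConfig()
    n_pen = len(design.penalties)
    if n_pen == 0:
        fit = pirls_fit(design, [], cov_type=cov_type)
        return np.array([]), fit

    lo, hi = math.log10(config.lambda_min), math.log10(config.lambda_max)
    n_grid = int(round((hi - lo) * config.points_per_decade)) + 1
    grid = np.linspace(lo, hi, max(n_grid, 2))

    cache: dict[tuple[float, ...], tuple[float, FitResult]] = {}
    warm: dict[str, np.ndarray | None] = {"beta": None}
    log: list[str] = []

    def evaluate(loglams: np.ndarray) -> tuple[float, FitResult]:
        key = tuple(np.round(loglams, 10))
        if key in cache:
            return cache[key]
        fit = pirls_fit(design, 10.0 ** loglams, cov_type=cov_type, beta0=warm["beta"])
        warm["beta"] = fit.coefficients
        cache[key] = (fit.gcv, fit)
        return cache[key]

    current = np.full(n_pen, math.log10(config.start))
    best_score, best_fit = evaluate(current)

    invphi = (math.sqrt(5) - 1) / 2
    for cycle in range(config.cycles):
        moved = False
        for m in range(n_pen):
            scores = []
            for g in grid:
                trial = current.copy()
                trial[m] = g
                scores.append(evaluate(trial)[0])
            j = int(np.argmin(scores))
            if j in (0, len(grid) - 1):
                log.append(
                    f"warning: GCV minimum for penalty {m} on grid boundary "
                    f"(lambda={10.0 ** grid[j]:.3g})"
                )
            a = grid[max(j - 1, 0)]
            b = grid[min(j + 1, len(grid) - 1)]
            if config.refine and b > a:
                # golden-section on the log scale between the bracketing neighbors
                x1 = b - invphi * (b - a)
                x2 = a + invphi * (b - a)
                t1, t2 = current.copy(), current.copy()
                t1[m], t2[m] = x1, x2
                f1, f2 = evaluate(t1)[0], evaluate(t2)[0]
                while b - a > config.refine_tol:
                    if f1 <= f2:
                        b, x2, f2 = x2, x1, f1
                        x1 = b - invphi * (b - a)
                        t1[m] = x1
                        f1 = evaluate(t1)[0]
                    else:
                        a, x1, f1 = x1, x2, f2
                        x2 = a + invphi * (b - a)
                        t2[m] = x2
                        f2 = evaluate(t2)[0]
                g_best = x1 if f1 <= f2 else x2
            else:
                g_best = grid[j]
            trial = current.copy()
            trial[m] = g_best
            score, fit = evaluate(trial)
            if score < best_score - 1e-12:
                best_score, best_fit = score, fit
                moved = abs(trial[m] - current[m]) > 1e-9 or moved
                current = trial
        if not moved and cycle > 0:
            break

    best_fit.log.extend(log)
    return 10.0 ** current, best_fit
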