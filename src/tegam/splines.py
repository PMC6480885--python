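"""Spline bases for confounders and pollutant smooths.

Two families are provided:

* :func:`natural_cubic_basis` — natural cubic splines (linear beyond the
  boundary knots) used as unpenalized parametric terms for temperature,
  humidity, pressure and calendar time.
* :func:`cubic_marginal` — cubic B-spline regression bases with an exact
  second-derivative roughness penalty, used as the marginal building blocks
  of the three-pollutant tensor-product smooth.

The tensor-product machinery (row construction, per-margin penalty
expansion, sum-to-zero centering) lives here as well.  The coefficient
layout of the tensor smooth is documented on :class:`TensorSmooth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "NaturalSplineBasis",
    "MarginalBasis",
    "TensorSmooth",
    "natural_cubic_basis",
    "cubic_marginal",
    "tensor_basis_row",
    "tensor_design_matrix",
    "expand_penalties",
    "apply_centering",
]


# ---------------------------------------------------------------------------
# natural cubic splines (confounders)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NaturalSplineBasis:
    """A natural cubic spline basis determined by its knot vector.

    The basis has ``df = len(knots) - 1`` columns (no intercept column):
    the identity function plus ``len(knots) - 2`` truncated-power
    combinations that are linear beyond the boundary knots.
    """

    knots: np.ndarray

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Return the n x df design matrix at ``x``."""
        x = np.asarray(x, dtype=float)
        xi = self.knots
        K = len(xi)
        cols = [x]

        def d(k: int) -> np.ndarray:
            # (x - xi_k)^3_+ - (x - xi_{K-1})^3_+, scaled
            num = np.clip(x - xi[k], 0.0, None) ** 3 - np.clip(x - xi[K - 1], 0.0, None) ** 3
            return num / (xi[K - 1] - xi[k])

        if K > 2:
            dlast = d(K - 2)
            for k in range(K - 2):
                cols.append(d(k) - dlast)
        return np.column_stack(cols)


def natural_cubic_basis(x: np.ndarray, df: int) -> tuple[np.ndarray, NaturalSplineBasis]:
    """Natural cubic spline basis with knots at equally spaced quantiles.

    Parameters
    ----------
    x : array
        Values of the covariate.
    df : int
        Degrees of freedom (number of basis columns, intercept excluded).
        ``df = 1`` reduces to the linear term.

    Returns
    -------
    (matrix, basis) : the n x df design matrix evaluated at ``x`` and the
        reusable :class:`NaturalSplineBasis` record.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    knots = np.quantile(x, np.linspace(0.0, 1.0, df + 1))
    knots = np.unique(knots)
    if len(knots) < df + 1:
        raise ValueError(
            f"need {df + 1} distinct quantile knots for df={df}, "
            f"found {len(knots)} distinct values"
        )
    basis = NaturalSplineBasis(knots=knots)
    return basis.evaluate(x), basis


# ---------------------------------------------------------------------------
# penalized cubic regression spline marginals (pollutants)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginalBasis:
    """One pollutant's cubic B-spline basis with its roughness penalty.

    ``penalty`` is the exact Gram matrix of second derivatives,
    ``S[i, j] = ∫ B_i''(x) B_j''(x) dx`` over the observed range, so that
    for a coefficient vector ``c`` the quadratic form ``c' S c`` equals the
    integrated squared second derivative of the represented function.  The
    null space of ``S`` contains every affine function.
    """

    variable_name: str
    knots: np.ndarray  # full (clamped) B-spline knot vector
    dimension: int
    penalty: np.ndarray

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """n x dimension matrix of basis evaluations (extrapolates cubically)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dm = BSpline.design_matrix(x, self.knots, 3, extrapolate=True)
        return np.asarray(dm.todense())

    def to_dict(self) -> dict:
        return {
            "variable_name": self.variable_name,
            "knots": self.knots.tolist(),
            "dimension": self.dimension,
            "penalty": self.penalty.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalBasis":
        return cls(
            variable_name=d["variable_name"],
            knots=np.asarray(d["knots"], dtype=float),
            dimension=int(d["dimension"]),
            penalty=np.asarray(d["penalty"], dtype=float),
        )


def _second_derivative_gram(knots: np.ndarray, dimension: int) -> np.ndarray:
    """Exact ∫ B_i'' B_j'' over [knots[3], knots[-4]] by 2-point Gauss rules.

    Second derivatives of cubic B-splines are piecewise linear, so the
    integrand is piecewise quadratic and the 2-point rule is exact on each
    knot interval.
    """
    spl2 = BSpline(knots, np.eye(dimension), 3).derivative(2)
    nodes, weights = leggauss(2)
    S = np.zeros((dimension, dimension))
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = mid + half * nodes
        D2 = spl2(pts)  # (2, dimension)
        S += half * (D2.T * weights) @ D2
    return 0.5 * (S + S.T)


def cubic_marginal(x: np.ndarray, dimension: int, name: str = "x") -> MarginalBasis:
    """Cubic regression spline marginal with knots at quantiles of ``x``.

    ``dimension`` is the number of basis functions; ``dimension - 4``
    interior knots are placed at equally spaced quantiles, the boundary
    knots at min/max.  The penalty is computed in closed form (the second
    derivatives are piecewise linear).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if dimension < 4:
        raise ValueError("cubic marginal basis needs dimension >= 4")
    n_interior = dimension - 4
    probs = np.linspace(0.0, 1.0, n_interior + 2)
    qs = np.quantile(x, probs)
    if len(np.unique(qs)) < len(qs):
        raise ValueError(
            f"dimension={dimension} requires {len(qs)} distinct quantile knots"
        )
    lo, hi = qs[0], qs[-1]
    knots = np.concatenate([[lo] * 4, qs[1:-1], [hi] * 4])
    penalty = _second_derivative_gram(knots, dimension)
    return MarginalBasis(variable_name=name, knots=knots, dimension=dimension, penalty=penalty)


# ---------------------------------------------------------------------------
# tensor product smooth
# ---------------------------------------------------------------------------


@dataclass
class TensorSmooth:
    """Three marginal bases combined by a row-wise Kronecker product.

    Margins are stored in the order (PM10, NO2, SO2).  The coefficient
    ``v[i, l, k]`` multiplies ``phi_i(PM10) * varphi_l(SO2) * eta_k(NO2)``
    and maps to flat index ``(i * L + l) * K + k`` where ``I, K, L`` are the
    dimensions of the PM10, NO2 and SO2 margins: PM10 index is slowest, SO2
    intermediate, NO2 fastest.  Equivalently a tensor design row is
    ``kron(phi(PM10), kron(varphi(SO2), eta(NO2)))``.

    ``centering`` (set by :func:`apply_centering`) is the orthonormal
    null-space transform Z enforcing that the fitted smooth sums to zero
    over the sample; constrained coefficients u relate to the raw layout by
    v = Z u.
    """

    margins: tuple[MarginalBasis, MarginalBasis, MarginalBasis]
    centering: np.ndarray | None = field(default=None)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(I, K, L) = dimensions of the PM10, NO2, SO2 margins."""
        return (self.margins[0].dimension, self.margins[1].dimension, self.margins[2].dimension)

    @property
    def dimension(self) -> int:
        I, K, L = self.dims
        return I * K * L

    def basis_row(self, levels: Sequence[float]) -> np.ndarray:
        """Raw (uncentered) tensor basis row at (pm10, no2, so2) levels."""
        return tensor_basis_row(self.margins, levels)

    def constrained_row(self, levels: Sequence[float]) -> np.ndarray:
        if self.centering is None:
            raise ValueError("centering transform not set; call apply_centering first")
        return self.basis_row(levels) @ self.centering

    def to_dict(self) -> dict:
        return {
            "margins": [m.to_dict() for m in self.margins],
            "centering": None if self.centering is None else self.centering.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensorSmooth":
        margins = tuple(MarginalBasis.from_dict(m) for m in d["margins"])
        centering = d.get("centering")
        return cls(
            margins=margins,  # type: ignore[arg-type]
            centering=None if centering is None else np.asarray(centering, dtype=float),
        )


def tensor_basis_row(margins: Sequence[MarginalBasis], levels: Sequence[float]) -> np.ndarray:
    """Kronecker product of the three marginal rows at the given levels.

    ``margins`` in order (PM10, NO2, SO2); ``levels`` likewise.  The layout
    follows :class:`TensorSmooth`: kron(PM10 row, SO2 row, NO2 row).
    """
    pm = margins[0].evaluate([levels[0]])[0]
    no2 = margins[1].evaluate([levels[1]])[0]
    so2 = margins[2].evaluate([levels[2]])[0]
    return np.kron(pm, np.kron(so2, no2))


def tensor_design_matrix(
    margins: Sequence[MarginalBasis],
    pm10: np.ndarray,
    no2: np.ndarray,
    so2: np.ndarray,
) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product over a data vector triple."""
    A = margins[0].evaluate(pm10)
    B = margins[2].evaluate(so2)
    C = margins[1].evaluate(no2)
    n = A.shape[0]
    T = np.einsum("ni,nl,nk->nilk", A, B, C)
    return T.reshape(n, -1)


def expand_penalties(margins: Sequence[MarginalBasis]) -> list[np.ndarray]:
    """Per-margin tensor penalties of size (I*K*L)^2, order (PM10, NO2, SO2).

    Each marginal roughness penalty is placed against identity blocks on
    the other two margins, consistent with the flat layout
    ``(i * L + l) * K + k``; at fit time each smoothing parameter
    multiplies exactly one of these matrices.
    """
    S_pm, S_no2, S_so2 = (m.penalty for m in margins)
    I, K, L = (m.dimension for m in margins)
    return [
        np.kron(S_pm, np.eye(L * K)),
        np.kron(np.eye(I * L), S_no2),
        np.kron(np.eye(I), np.kron(S_so2, np.eye(K))),
    ]


def apply_centering(
    smooth: TensorSmooth, design_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reparameterize so the fitted smooth sums to zero over the sample.

    Builds an orthonormal basis Z of the null space of the column-mean
    vector c = X' 1 / n and returns (X Z, Z).  The transform is stored on
    ``smooth`` for later contrast evaluation; differences of basis rows
    (contrasts) are invariant to it.
    """
    X = np.asarray(design_rows, dtype=float)
    c = X.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("degenerate centering constraint: zero column means")
    Q, _ = np.linalg.qr(c.reshape(-1, 1), mode="complete")
    Z = Q[:, 1:]
    smooth.centering = Z
    return X @ Z, Z
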