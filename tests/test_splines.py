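"""Spline bases: reproduction properties, exact penalties, tensor layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

import tegam as tg
from conftest import make_toy_margin

RNG = np.random.default_rng(7)
X_POLL = np.sort(RNG.lognormal(np.log(60), 0.5, 300))


class TestNaturalCubicBasis:
    def test_df1_is_linear_term(self):
        x = RNG.uniform(0, 10, 80)
        mat, basis = tg.natural_cubic_basis(x, df=1)
        assert mat.shape == (80, 1)
        # fitting y = 2x + 1 with an intercept recovers it exactly
        X = np.column_stack([np.ones(80), mat])
        coef, *_ = np.linalg.lstsq(X, 2 * x + 1, rcond=None)
        assert np.allclose(X @ coef, 2 * x + 1, atol=1e-10)

    def test_reproduces_any_linear_function(self):
        mat, basis = tg.natural_cubic_basis(X_POLL, df=3)
        X = np.column_stack([np.ones(len(X_POLL)), mat])
        y = -0.7 * X_POLL + 4.2
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ coef, y, atol=1e-8)

    def test_second_derivative_vanishes_beyond_boundary(self):
        _, basis = tg.natural_cubic_basis(X_POLL, df=3)
        coef = RNG.standard_normal(3)
        lo, hi = X_POLL.min(), X_POLL.max()
        h = 1e-3 * (hi - lo)
        for x0 in (lo - 5 * h, hi + 5 * h, lo - 50 * h, hi + 50 * h):
            pts = np.array([x0 - h, x0, x0 + h])
            vals = basis.evaluate(pts) @ coef
            d2 = (vals[0] - 2 * vals[1] + vals[2]) / h**2
            assert abs(d2) < 1e-5 * max(1.0, abs(vals[1]))

    def test_matches_textbook_natural_interpolation(self):
        """The span of {1, basis} on the knots is the natural interpolant."""
        _, basis = tg.natural_cubic_basis(X_POLL, df=4)
        knots = basis.knots
        yk = np.sin(knots / 30.0)
        # solve the square interpolation system in our basis
        A = np.column_stack([np.ones(len(knots)), basis.evaluate(knots)])
        coef = np.linalg.solve(A, yk)
        oracle = CubicSpline(knots, yk, bc_type="natural")
        grid = np.linspace(knots[0], knots[-1], 200)
        ours = np.column_stack([np.ones(200), basis.evaluate(grid)]) @ coef
        assert np.allclose(ours, oracle(grid), atol=1e-8)

    def test_too_few_distinct_values_errors(self):
        with pytest.raises(ValueError):
            tg.natural_cubic_basis(np.array([1.0, 1.0, 1.0, 2.0]), df=3)


class TestCubicMarginal:
    def test_penalty_exact_for_quadratic(self):
        m = tg.cubic_marginal(X_POLL, 6)
        lo, hi = X_POLL.min(), X_POLL.max()
        # coefficients representing f(x) = x^2 exactly (cubic splines span quadratics)
        pts = np.linspace(lo, hi, 200)
        c, *_ = np.linalg.lstsq(m.evaluate(pts), pts**2, rcond=None)
        assert np.allclose(m.evaluate(pts) @ c, pts**2, atol=1e-8)
        assert c @ m.penalty @ c == pytest.approx(4.0 * (hi - lo), rel=1e-6)

    def test_penalty_nullspace_contains_affine(self):
        m = tg.cubic_marginal(X_POLL, 5)
        pts = np.linspace(X_POLL.min(), X_POLL.max(), 100)
        for y in (np.ones_like(pts), 3.0 - 0.2 * pts):
            c, *_ = np.linalg.lstsq(m.evaluate(pts), y, rcond=None)
            assert abs(c @ m.penalty @ c) < 1e-10 * max(1.0, np.sum(c**2))

    def test_penalty_symmetric_psd(self):
        m = tg.cubic_marginal(X_POLL, 7)
        S = m.penalty
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_dimension_too_small_errors(self):
        with pytest.raises(ValueError):
            tg.cubic_marginal(X_POLL, 3)

    def test_affine_invariance_of_fitted_values(self):
        """Rescaling the units rescales knots; fitted values are unchanged."""
        y = RNG.standard_normal(len(X_POLL))
        m1 = tg.cubic_marginal(X_POLL, 5)
        m2 = tg.cubic_marginal(2.0 * X_POLL + 5.0, 5)
        B1, B2 = m1.evaluate(X_POLL), m2.evaluate(2.0 * X_POLL + 5.0)
        f1 = B1 @ np.linalg.lstsq(B1, y, rcond=None)[0]
        f2 = B2 @ np.linalg.lstsq(B2, y, rcond=None)[0]
        assert np.allclose(f1, f2, atol=1e-8)

    def test_roundtrip_serialization(self):
        m = tg.cubic_marginal(X_POLL, 5, name="pm10")
        m2 = tg.MarginalBasis.from_dict(m.to_dict())
        pts = np.linspace(X_POLL.min(), X_POLL.max(), 50)
        assert np.array_equal(m.evaluate(pts), m2.evaluate(pts))


class TestTensorRow:
    def test_triple_loop_oracle_2x2x2(self, toy_margins):
        levels = (0.3, -1.2, 2.5)
        row = tg.tensor_basis_row(toy_margins, levels)
        assert row.shape == (8,)
        pm = toy_margins[0].evaluate([levels[0]])[0]
        no2 = toy_margins[1].evaluate([levels[1]])[0]
        so2 = toy_margins[2].evaluate([levels[2]])[0]
        brute = np.empty(8)
        I = L = K = 2
        for i in range(I):
            for l in range(L):
                for k in range(K):
                    brute[(i * L + l) * K + k] = pm[i] * so2[l] * no2[k]
        assert np.allclose(row, brute, atol=1e-12)

    def test_zero_margin_gives_zero_row(self, toy_margins):
        zero = make_toy_margin("no2", 9)
        zero = type(zero)(
            variable_name="no2",
            dimension=2,
            funcs=(lambda x: np.zeros_like(x), lambda x: np.zeros_like(x)),
            penalty=zero.penalty,
            knots=zero.knots,
        )
        row = tg.tensor_basis_row((toy_margins[0], zero, toy_margins[2]), (1.0, 1.0, 1.0))
        assert np.all(row == 0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        pm=st.floats(-5, 5),
        no2=st.floats(-5, 5),
        so2=st.floats(-5, 5),
        seed=st.integers(0, 100),
    )
    def test_contraction_reproduces_smooth_value(self, toy_margins, pm, no2, so2, seed):
        """row @ v_flat equals the triple contraction with v[i, l, k]."""
        rng = np.random.default_rng(seed)
        I, K, L = (m.dimension for m in toy_margins)
        v = rng.standard_normal((I, L, K))
        row = tg.tensor_basis_row(toy_margins, (pm, no2, so2))
        a = toy_margins[0].evaluate([pm])[0]
        b = toy_margins[2].evaluate([so2])[0]
        c = toy_margins[1].evaluate([no2])[0]
        expected = np.einsum("ilk,i,l,k->", v, a, b, c)
        assert row @ v.reshape(-1) == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_kron_row_property_real_margins(self):
        margins = tuple(
            tg.cubic_marginal(np.sort(RNG.lognormal(4, 0.4, 200)), 5, name=n)
            for n in ("pm10", "no2", "so2")
        )
        levels = (55.0, 60.0, 40.0)
        row = tg.tensor_basis_row(margins, levels)
        manual = np.kron(
            margins[0].evaluate([levels[0]])[0],
            np.kron(margins[2].evaluate([levels[2]])[0], margins[1].evaluate([levels[1]])[0]),
        )
        assert np.allclose(row, manual, atol=1e-14)


class TestExpandPenalties:
    def test_brute_force_oracle_2x2x2(self, toy_margins):
        S1, S2, S3 = tg.expand_penalties(toy_margins)
        Spm, Sno2, Sso2 = (m.penalty for m in toy_margins)
        I = L = K = 2

        def idx(i, l, k):
            return (i * L + l) * K + k

        brute_pm = np.zeros((8, 8))
        brute_no2 = np.zeros((8, 8))
        brute_so2 = np.zeros((8, 8))
        for i in range(I):
            for l in range(L):
                for k in range(K):
                    for i2 in range(I):
                        for l2 in range(L):
                            for k2 in range(K):
                                a, b = idx(i, l, k), idx(i2, l2, k2)
                                if l == l2 and k == k2:
                                    brute_pm[a, b] = Spm[i, i2]
                                if i == i2 and l == l2:
                                    brute_no2[a, b] = Sno2[k, k2]
                                if i == i2 and k == k2:
                                    brute_so2[a, b] = Sso2[l, l2]
        assert np.allclose(S1, brute_pm)
        assert np.allclose(S2, brute_no2)
        assert np.allclose(S3, brute_so2)

    def test_constant_in_margin_has_zero_quadratic_form(self):
        margins = tuple(
            tg.cubic_marginal(np.sort(RNG.lognormal(4, 0.4, 200)), 5, name=n)
            for n in ("pm10", "no2", "so2")
        )
        S_pm, _, _ = tg.expand_penalties(margins)
        I, K, L = 5, 5, 5
        # coefficient tensor constant along the PM10 margin: affine in pm10 index?
        # a function constant in pm10 has v[i,l,k] = w[l,k] * c_i with c the
        # representation of the constant; B-splines represent 1 as all-ones.
        rng = np.random.default_rng(0)
        w = rng.standard_normal((L, K))
        v = np.ones((I, 1, 1)) * w[None, :, :]
        q = v.reshape(-1) @ S_pm @ v.reshape(-1)
        assert abs(q) < 1e-10 * np.sum(v**2)

    def test_quadratic_forms_nonnegative(self, toy_margins):
        rng = np.random.default_rng(5)
        expanded = tg.expand_penalties(toy_margins)
        V = rng.standard_normal((1000, 8))
        for S in expanded:
            q = np.einsum("ij,jk,ik->i", V, S, V)
            assert np.all(q >= -1e-10)


class TestCentering:
    def test_constrained_smooth_has_zero_sample_mean(self, built4, fit4):
        span = fit4.columns("te")
        smooth_fitted = built4.design.X[:, span] @ fit4.coefficients[span]
        assert abs(smooth_fitted.mean()) < 1e-10

    def test_fitted_values_match_unconstrained_least_squares(self):
        rng = np.random.default_rng(2)
        margins = tuple(
            tg.cubic_marginal(rng.lognormal(4, 0.4, 150), 4, name=n)
            for n in ("pm10", "no2", "so2")
        )
        x = np.column_stack([rng.lognormal(4, 0.4, 150) for _ in range(3)])
        T = tg.tensor_design_matrix(margins, x[:, 0], x[:, 1], x[:, 2])
        smooth = tg.TensorSmooth(margins=margins)
        TZ, Z = tg.apply_centering(smooth, T)
        y = rng.standard_normal(150)
        ones = np.ones((150, 1))
        Xc = np.hstack([ones, TZ])
        Xu = np.hstack([ones, T])
        fc = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        fu = Xu @ np.linalg.lstsq(Xu, y, rcond=None)[0]
        assert np.allclose(fc, fu, atol=1e-8)

    def test_contrasts_invariant_to_centering(self, built4):
        smooth = built4.smooth
        rng = np.random.default_rng(3)
        Z = smooth.centering
        for _ in range(5):
            a = [float(rng.uniform(m.knots[0], m.knots[-1])) for m in smooth.margins]
            b = [float(rng.uniform(m.knots[0], m.knots[-1])) for m in smooth.margins]
            raw_diff = smooth.basis_row(b) - smooth.basis_row(a)
            cons_diff = smooth.constrained_row(b) - smooth.constrained_row(a)
            # any raw coefficient vector v and its constrained image u = Z'v
            v = rng.standard_normal(smooth.dimension)
            assert raw_diff @ (Z @ Z.T @ v) == pytest.approx(cons_diff @ (Z.T @ v), abs=1e-10)
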