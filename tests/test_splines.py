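"""Spline bases: interpolation correctness, penalties, constraints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline

from phenogamm.splines import (
    DegenerateBasisError,
    SmoothTermSpec,
    build_basis,
    evaluate_smooth,
)
from phenogamm.splines import _natural_matrices, _cyclic_matrices, _raw_rows


def test_natural_basis_matches_independent_interpolant():
    """Basis rows reproduce a natural cubic spline through the knot values."""
    knots = np.linspace(0, 10, 6)
    vals = np.array([0.3, -1.1, 2.0, 0.5, -0.7, 1.4])
    F, _ = _natural_matrices(knots)
    spec = SmoothTermSpec("x", "cubic", 6)
    xs = np.linspace(0, 10, 201)
    ours = _raw_rows(spec, knots, F, xs) @ vals
    oracle = CubicSpline(knots, vals, bc_type="natural")(xs)
    np.testing.assert_allclose(ours, oracle, atol=1e-12)


def test_cyclic_basis_matches_periodic_interpolant():
    knots = np.linspace(0, 12, 7)
    free = np.array([0.5, -0.2, 1.1, -1.3, 0.8, 0.1])
    F, _ = _cyclic_matrices(knots)
    spec = SmoothTermSpec("m", "cyclic_cubic", 7, period=12)
    xs = np.linspace(0, 12, 241)
    ours = _raw_rows(spec, knots, F, xs) @ free
    oracle = CubicSpline(knots, np.append(free, free[0]), bc_type="periodic")(xs)
    np.testing.assert_allclose(ours, oracle, atol=1e-12)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_penalty_equals_integrated_squared_second_derivative(seed):
    """Quadratic form in the penalty = numerically integrated curvature."""
    rng = np.random.default_rng(seed)
    kind = "cubic" if seed % 2 == 0 else "cyclic_cubic"
    if kind == "cubic":
        knots = np.sort(rng.uniform(0, 10, 6))
        knots[0], knots[-1] = 0.0, 10.0
        F, S = _natural_matrices(knots)
        vals = rng.normal(size=6)
        cs = CubicSpline(knots, vals, bc_type="natural")
        xq = np.linspace(0, 10, 40001)
    else:
        knots = np.linspace(0, 12, 7)
        F, S = _cyclic_matrices(knots)
        vals = rng.normal(size=6)
        cs = CubicSpline(knots, np.append(vals, vals[0]), bc_type="periodic")
        xq = np.linspace(0, 12, 40001)
    quad = np.trapezoid(cs(xq, 2) ** 2, xq)
    assert vals @ S @ vals == pytest.approx(quad, rel=0.01)


def test_centred_columns_sum_to_zero_and_counts():
    t = np.arange(1, 121, dtype=float)
    be = build_basis(SmoothTermSpec("t", "cubic", 10), t)
    assert be.n_columns == 9
    np.testing.assert_allclose(be.design_block.sum(axis=0), 0, atol=1e-9)
    cal = ((t - 1) % 12) + 1
    bc = build_basis(
        SmoothTermSpec("m", "cyclic_cubic", 8, period=12), cal
    )
    assert bc.n_columns == 6
    np.testing.assert_allclose(bc.design_block.sum(axis=0), 0, atol=1e-9)


def test_penalty_null_space():
    """Second-derivative penalty annihilates linear (cubic) / constant parts."""
    t = np.arange(1, 121, dtype=float)
    be = build_basis(SmoothTermSpec("t", "cubic", 10), t)
    vals = np.linalg.eigvalsh(be.penalty)
    assert np.sum(vals < 1e-8 * vals.max()) == 1 == be.null_space_dim
    assert vals.min() > -1e-10
    bc = build_basis(
        SmoothTermSpec("m", "cyclic_cubic", 8, period=12),
        ((t - 1) % 12) + 1,
    )
    vals = np.linalg.eigvalsh(bc.penalty)
    assert np.sum(vals < 1e-8 * vals.max()) == 0 == bc.null_space_dim
    # constant function on the raw basis has zero curvature penalty
    F, S = _natural_matrices(np.linspace(0, 10, 6))
    const = np.ones(6)
    assert const @ S @ const == pytest.approx(0, abs=1e-12)


def test_cyclic_periodicity_exact():
    cal = np.arange(1, 13, dtype=float)
    bc = build_basis(SmoothTermSpec("m", "cyclic_cubic", 8, period=12), cal)
    r1 = bc.design_rows(np.array([0.5]))
    r2 = bc.design_rows(np.array([12.5]))
    np.testing.assert_array_equal(r1, r2)


def test_evaluate_smooth_contracts():
    t = np.arange(1, 61, dtype=float)
    be = build_basis(SmoothTermSpec("t", "cubic", 6), t)
    coef = np.arange(be.n_columns, dtype=float) / 10
    # training values reproduce the design block product exactly
    np.testing.assert_array_equal(
        evaluate_smooth(be, coef, t), be.design_block @ coef
    )
    # zero coefficients -> zero function
    np.testing.assert_array_equal(
        evaluate_smooth(be, np.zeros(be.n_columns), [3.3, 7.7]), [0.0, 0.0]
    )
    with pytest.raises(ValueError):
        evaluate_smooth(be, coef[:-1], t)


def test_basis_errors():
    with pytest.raises(DegenerateBasisError):
        build_basis(SmoothTermSpec("t", "cubic", 10), np.arange(5, dtype=float))
    with pytest.raises(ValueError):
        build_basis(SmoothTermSpec("t", "cubic", 5), np.array([1, 2, np.nan, 4, 5]))
    with pytest.raises(ValueError):
        SmoothTermSpec("t", "cubic", 2)
    with pytest.raises(ValueError):
        SmoothTermSpec("m", "cyclic_cubic", 8)  # no period
    with pytest.raises(ValueError):
        SmoothTermSpec("t", "cubic", 4, knots=(1.0, 3.0, 2.0, 4.0))
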