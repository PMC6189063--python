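"""B-spline bases, smoothing, LOO-CV knot selection and quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdamort.basis import (
    FunctionalSample,
    Interval,
    cross_gram,
    evaluate,
    gram_matrix,
    inner_product,
    make_basis,
    penalty,
    project_curve,
    select_knots_loocv,
    smooth,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def deboor_basis_value(t, degree, j, x, upper):
    """Cox-de Boor recursion, written independently of scipy."""
    if degree == 0:
        if t[j] <= x < t[j + 1]:
            return 1.0
        # right-closed last non-empty interval
        if x == upper and t[j] < t[j + 1] and t[j + 1] == upper:
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[j + degree] - t[j]
    if d1 > 0:
        out += (x - t[j]) / d1 * deboor_basis_value(t, degree - 1, j, x, upper)
    d2 = t[j + degree + 1] - t[j + 1]
    if d2 > 0:
        out += (t[j + degree + 1] - x) / d2 * deboor_basis_value(
            t, degree - 1, j + 1, x, upper
        )
    return out


def riemann_product_matrix(basis_a, basis_b, deriv_a=0, deriv_b=0, n=20_000):
    g = np.linspace(basis_a.domain.lower, basis_a.domain.upper, n)
    A = basis_a.design_matrix(g, derivative=deriv_a)
    B = basis_b.design_matrix(g, derivative=deriv_b)
    w = np.full(n, g[1] - g[0])
    w[0] = w[-1] = 0.5 * (g[1] - g[0])
    return (A * w[:, None]).T @ B


# ---------------------------------------------------------------------------
# Construction and evaluation
# ---------------------------------------------------------------------------

def test_dimension_formula():
    assert make_basis(Interval(0, 1), 0, order=1).dimension == 1
    assert make_basis(Interval(0, 24), 10, order=4).dimension == 14


def test_constant_order_one_basis_is_identically_one():
    b = make_basis(Interval(0, 1), 0, order=1)
    vals = b.design_matrix(np.linspace(0, 1, 11))
    assert np.allclose(vals, 1.0)


@pytest.mark.parametrize("bad", [
    dict(domain=(0.0, np.inf), knots=2, order=4),
    dict(domain=(0.0, 1.0), knots=2, order=0),
    dict(domain=(1.0, 1.0), knots=0, order=1),
])
def test_invalid_basis_arguments_rejected(bad):
    with pytest.raises(ValueError):
        make_basis(Interval(*bad["domain"]), bad["knots"], bad["order"])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    n_knots=st.integers(0, 12),
    order=st.integers(1, 5),
    x01=st.floats(0.0, 1.0, allow_nan=False),
)
def test_partition_of_unity_holds_for_any_configuration(n_knots, order, x01):
    basis = make_basis(Interval(0.0, 24.0), n_knots, order)
    x = 24.0 * x01
    row = basis.design_matrix([x])[0]
    assert row.min() >= -1e-14
    assert abs(row.sum() - 1.0) < 1e-12


def test_partition_of_unity_and_nonnegativity(any_basis, rng):
    pts = rng.uniform(any_basis.domain.lower, any_basis.domain.upper, 1000)
    pts = np.append(pts, [any_basis.domain.lower, any_basis.domain.upper])
    B = any_basis.design_matrix(pts)
    assert np.all(B >= -1e-14)
    assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12


def test_evaluation_matches_deboor_oracle(rng):
    basis = make_basis(Interval(0, 24), 6, order=4)
    coefs = rng.normal(size=(3, basis.dimension))
    sample = FunctionalSample(basis, coefs)
    grid = np.sort(rng.uniform(0, 24, 40))
    grid[-1] = 24.0
    got = evaluate(sample, grid)
    t = basis.knot_vector()
    oracle = np.array([
        [
            sum(
                c[j] * deboor_basis_value(t, basis.degree, j, x, 24.0)
                for j in range(basis.dimension)
            )
            for x in grid
        ]
        for c in coefs
    ])
    assert np.abs(got - oracle).max() < 1e-10


def test_evaluate_zero_and_constant_curves():
    basis = make_basis(Interval(0, 24), 4, order=4)
    grid = np.linspace(0, 24, 9)
    zero = FunctionalSample(basis, np.zeros((1, basis.dimension)))
    assert np.all(evaluate(zero, grid) == 0.0)
    const = FunctionalSample(basis, np.full((1, basis.dimension), 3.5))
    assert np.allclose(evaluate(const, grid), 3.5)


def test_evaluate_rejects_out_of_domain():
    basis = make_basis(Interval(0, 24), 4, order=4)
    sample = FunctionalSample(basis, np.zeros((1, basis.dimension)))
    with pytest.raises(ValueError, match="outside domain"):
        evaluate(sample, [25.0])


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def test_smooth_recovers_span_member_exactly(rng):
    basis = make_basis(Interval(0, 24), 5, order=4)
    true_coefs = rng.normal(size=basis.dimension)
    pos = np.linspace(0, 24, 25)
    vals = basis.design_matrix(pos) @ true_coefs
    fit = smooth({"d1": (pos, vals)}, basis)
    assert np.abs(fit.coefficients[0] - true_coefs).max() < 1e-8
    resid = vals - fit.evaluate(pos)[0]
    assert np.abs(resid).max() < 1e-8


def test_smooth_fits_diurnal_sinusoid_closely():
    basis = make_basis(Interval(0, 24), 7, order=4)  # dimension 11
    hours = np.arange(24.0)
    truth = lambda s: 20.0 + 5.0 * np.sin(2 * np.pi * (s - 9.0) / 24.0)
    fit = smooth((hours, truth(hours)[None, :]), basis)
    dense = np.linspace(0, 23.0, 200)
    assert np.abs(fit.evaluate(dense)[0] - truth(dense)).max() < 0.1


def test_smooth_treats_count_noise_as_noise(rng):
    basis = make_basis(Interval(0, 365), 8, order=4)
    days = np.arange(365.0) + 0.5
    counts = rng.poisson(17.0, size=365).astype(float)
    fit = smooth((days, counts[None, :]), basis)
    assert fit.evaluate(days)[0].var() < counts.var()


def test_smooth_is_a_projection(rng):
    basis = make_basis(Interval(0, 24), 6, order=4)
    sample = FunctionalSample(basis, rng.normal(size=(2, basis.dimension)))
    dense = np.linspace(0, 24, 120)
    again = smooth((dense, sample.evaluate(dense)), basis)
    assert np.abs(again.coefficients - sample.coefficients).max() < 1e-8


def test_smooth_rejects_underdetermined_curve():
    basis = make_basis(Interval(0, 24), 8, order=4)  # dimension 12
    pos = np.linspace(0, 24, 5)
    with pytest.raises(ValueError, match="curve 'short'"):
        smooth({"short": (pos, np.zeros(5))}, basis)


# ---------------------------------------------------------------------------
# LOO-CV knot selection
# ---------------------------------------------------------------------------

def test_loocv_prefers_smallest_feasible_basis_for_exact_data(rng):
    domain = Interval(0, 24)
    small = make_basis(domain, 2, order=4)
    pos = np.linspace(0, 24, 30)
    vals = small.design_matrix(pos) @ rng.normal(size=small.dimension)
    best, scores = select_knots_loocv(
        {"c": (pos, vals)}, domain, 4, [2, 4, 6]
    )
    assert best == 2
    assert scores.loc[scores.n_interior_knots == 2, "cv_score"].iloc[0] < 1e-12


def test_loocv_penalizes_extra_knots_under_white_noise(rng):
    domain = Interval(0, 24)
    pos = np.linspace(0, 24, 30)
    wins = 0
    for _ in range(50):
        vals = 10.0 + rng.normal(0, 1, size=30)
        best, _ = select_knots_loocv({"c": (pos, vals)}, domain, 4, [0, 6])
        wins += best == 0
    assert wins > 25


def test_loocv_shortcut_equals_brute_force(rng):
    domain = Interval(0, 24)
    basis = make_basis(domain, 3, order=4)
    pos = np.linspace(0, 24, 30)
    vals = np.sin(pos / 3.0) + rng.normal(0, 0.3, size=30)
    _, scores = select_knots_loocv({"c": (pos, vals)}, domain, 4, [3])
    shortcut = scores["cv_score"].iloc[0]
    sse = 0.0
    for i in range(30):
        keep = np.arange(30) != i
        B = basis.design_matrix(pos[keep])
        c, *_ = np.linalg.lstsq(B, vals[keep], rcond=None)
        pred = basis.design_matrix([pos[i]])[0] @ c
        sse += (vals[i] - pred) ** 2
    assert abs(shortcut - sse / 30) < 1e-8


def test_loocv_rejects_empty_candidates():
    with pytest.raises(ValueError, match="non-empty"):
        select_knots_loocv({"c": ([0, 1], [0, 1])}, Interval(0, 1), 1, [])


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------

def test_gram_matches_riemann_oracle(any_basis):
    G = gram_matrix(any_basis)
    R = riemann_product_matrix(any_basis, any_basis)
    assert np.abs(G - R).max() < 1e-6 * max(1.0, np.abs(R).max())
    assert np.allclose(G, G.T)


def test_inner_product_is_positive_semidefinite(rng):
    basis = make_basis(Interval(0, 24), 6, order=4)
    for _ in range(100):
        c = rng.normal(size=basis.dimension)
        f = FunctionalSample(basis, c[None, :])
        assert inner_product(f, f) >= -1e-12


def test_inner_product_rejects_mismatched_bases():
    b1 = make_basis(Interval(0, 24), 4, order=4)
    b2 = make_basis(Interval(0, 24), 5, order=4)
    f = FunctionalSample(b1, np.zeros((1, b1.dimension)))
    g = FunctionalSample(b2, np.zeros((1, b2.dimension)))
    with pytest.raises(ValueError, match="same basis"):
        inner_product(f, g)


def test_cross_gram_matches_riemann_oracle(rng):
    a = make_basis(Interval(0, 24), 8, order=4)
    b = make_basis(Interval(0, 24), 5, order=4)
    J = cross_gram(a, b)
    R = riemann_product_matrix(a, b)
    assert np.abs(J - R).max() < 1e-6 * np.abs(R).max()


def test_penalty_zero_for_straight_line():
    basis = make_basis(Interval(0, 10), 5, order=4)
    line = project_curve(lambda x: 2.0 + 3.0 * x, basis)
    P = penalty(basis, 2).matrix
    q = line.coefficients[0] @ P @ line.coefficients[0]
    assert abs(q) < 1e-10


def test_penalty_is_symmetric_psd():
    basis = make_basis(Interval(0, 24), 8, order=4)
    P = penalty(basis, 2).matrix
    assert np.allclose(P, P.T)
    assert np.linalg.eigvalsh(P).min() > -1e-10


def test_penalty_quadratic_form_matches_riemann(rng):
    basis = make_basis(Interval(0, 24), 6, order=4)
    c = rng.normal(size=basis.dimension)
    P = penalty(basis, 2).matrix
    R = riemann_product_matrix(basis, basis, deriv_a=2, deriv_b=2)
    qP, qR = c @ P @ c, c @ R @ c
    assert abs(qP - qR) < 1e-5 * abs(qR)


def test_penalty_rejects_derivative_at_or_above_order():
    basis = make_basis(Interval(0, 1), 3, order=2)
    with pytest.raises(ValueError, match="derivative_order"):
        penalty(basis, 2)
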