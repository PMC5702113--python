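"""Sigmoid evaluation, closed forms, and fitting behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from chipturn.sigmoid import (
    FlatDataError,
    LinearFit,
    SigmoidParams,
    fit_linear,
    fit_sigmoid,
    inflection_point,
    sigmoid_eval,
    turnover_time_index,
)

# --------------------------------------------------------------------------
# independent oracles


def tti_bisection(p: SigmoidParams, tol: float = 1e-12) -> float:
    """Solve sigmoid_eval(x) = (a+d)/2 by bisection, independent of the closed form."""
    target = 0.5 * (p.a + p.d)
    span = 10.0 / abs(p.b) + abs(math.log(max(p.f, 1 / p.f)) / p.b) + 1.0
    lo, hi = p.c - span, p.c + span
    g = lambda x: sigmoid_eval(p, x) - target
    assert g(lo) * g(hi) < 0
    return optimize.bisect(g, lo, hi, xtol=tol)


def inflection_fd(p: SigmoidParams) -> float:
    """Root of the finite-difference second derivative (grid bracket + bisect).

    Richardson-extrapolated central differences keep both truncation and
    rounding error well below the 1e-6 comparison tolerance.
    """
    h = 5e-3 / abs(p.b)

    def d2_step(x, s):
        return sigmoid_eval(p, x + s) - 2 * sigmoid_eval(p, x) + sigmoid_eval(p, x - s)

    def d2(x):
        # f'' ~ (16*delta2(h/2) - delta2(h)) / (3 h^2); constant factor is
        # irrelevant for the root
        return 16.0 * d2_step(x, h / 2) - d2_step(x, h)

    span = 8.0 / abs(p.b) + abs(math.log(max(p.f, 1 / p.f)) / p.b) + 1.0
    xs = np.linspace(p.c - span, p.c + span, 4001)
    vals = d2(xs)  # sigmoid_eval is vectorized
    # the true root separates the two O(max) lobes of d2; ignore sign flips
    # from rounding noise out on the plateaus
    floor = 1e-6 * np.max(np.abs(vals))
    candidates = np.nonzero(
        (vals[:-1] * vals[1:] < 0)
        & (np.minimum(np.abs(vals[:-1]), np.abs(vals[1:])) > floor)
    )[0]
    assert candidates.size == 1
    i = candidates[0]
    return optimize.bisect(d2, xs[i], xs[i + 1], xtol=1e-10)


def random_params(rng: np.random.Generator) -> SigmoidParams:
    a = rng.uniform(1.0, 50.0)
    d = rng.uniform(0.0, a - 0.5)
    b = rng.choice([-1, 1]) * rng.uniform(0.2, 5.0)
    c = rng.uniform(-5.0, 15.0)
    f = rng.uniform(0.2, 5.0)
    return SigmoidParams(a, b, c, d, f)


# --------------------------------------------------------------------------
# evaluation


@pytest.mark.parametrize(
    "params, x, expected",
    [
        (SigmoidParams(0, -1, 0, 1, 1), 0.0, 0.5),  # midpoint at c when f=1
        (SigmoidParams(0, 1, 2, 1, 2), 2.0, 0.75),  # 1 + (0-1)/2^2
        (SigmoidParams(0, -1, 0, 1, 1), 1e4, 0.0),  # late plateau -> a
        (SigmoidParams(0, -1, 0, 1, 1), -1e4, 1.0),  # early plateau -> d
    ],
)
def test_sigmoid_eval_known_values(params, x, expected):
    assert sigmoid_eval(params, x) == pytest.approx(expected, abs=1e-12)


def test_sigmoid_eval_no_overflow_at_extreme_arguments():
    p = SigmoidParams(5, -800.0, 0, 1, 1)
    y = sigmoid_eval(p, np.array([-50.0, 50.0]))
    assert np.all(np.isfinite(y))
    assert y[0] == pytest.approx(1.0) and y[1] == pytest.approx(5.0)


def test_direction_convention():
    assert SigmoidParams(10, -2, 5, 0).direction == "increasing"
    assert SigmoidParams(10, 2, 5, 0).direction == "decreasing"


# --------------------------------------------------------------------------
# closed forms


def test_inflection_point_is_c_for_symmetric_curve():
    assert inflection_point(SigmoidParams(0, -2.7, 3, 1, 1)) == 3.0


@pytest.mark.parametrize(
    "params, expected",
    [
        (SigmoidParams(0, 1, 0, 1, 2), -math.log(2)),
        (SigmoidParams(0, -2, 5, 1, 0.5), 5 - math.log(0.5) / -2),  # 4.6534...
    ],
)
def test_inflection_point_asymmetric(params, expected):
    x = inflection_point(params)
    assert x == pytest.approx(expected, abs=1e-12)
    assert x == pytest.approx(inflection_fd(params), abs=1e-6)


def test_tti_closed_form_examples():
    assert turnover_time_index(SigmoidParams(0, -1, 7, 1, 1)) == 7.0
    p = SigmoidParams(0, 2, 5, 1, 0.5)
    assert turnover_time_index(p) == pytest.approx(5 + math.log(3) / 2, abs=1e-12)


def test_tti_oracle_agreement_many_draws():
    """Closed-form TTI vs bisection, inflection vs FD root: 1000 draws."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = random_params(rng)
        assert turnover_time_index(p) == pytest.approx(tti_bisection(p), abs=1e-8)
        assert inflection_point(p) == pytest.approx(inflection_fd(p), abs=1e-6)


@given(
    a=st.floats(1.0, 50.0),
    d=st.floats(0.0, 0.9),
    b=st.floats(0.2, 5.0),
    sign=st.sampled_from([-1.0, 1.0]),
    c=st.floats(-5.0, 15.0),
    f=st.floats(0.2, 5.0),
)
@settings(derandomize=True, max_examples=200)
def test_tti_defining_property(a, d, b, sign, c, f):
    """The curve evaluated at the TTI equals the plateau midpoint."""
    p = SigmoidParams(a, sign * b, c, d, f)
    assert sigmoid_eval(p, turnover_time_index(p)) == pytest.approx(
        0.5 * (a + d), abs=1e-9
    )


def test_tti_errors():
    with pytest.raises(ValueError):
        turnover_time_index(SigmoidParams(1.0, 2.0, 0.0, 1.0, 1.0))  # a == d
    with pytest.raises(ValueError):
        SigmoidParams(0, 0, 0, 1, 1)  # b == 0 invalid outright


# --------------------------------------------------------------------------
# fitting


def test_fit_recovers_exact_data(times11):
    truth = SigmoidParams(10, -2, 5, 0)
    res = fit_sigmoid(times11, sigmoid_eval(truth, times11))
    assert res.converged
    assert res.rss < 1e-8
    for got, want in zip(res.params.as_array()[:4], truth.as_array()[:4]):
        assert got == pytest.approx(want, rel=1e-4, abs=1e-4)
    assert res.direction == "increasing"
    assert res.tti == pytest.approx(5.0, rel=1e-4)


def test_fit_clamps_negative_plateau(times11):
    # generator pushes the lower plateau to -3; the fit must stay >= 0
    y = np.maximum(sigmoid_eval(SigmoidParams(10, -2, 5, -3), times11), 0.0)
    res = fit_sigmoid(times11, y)
    assert res.params.lower_asymptote >= 0.0


def test_fit_time_shift_equivariance(times11):
    truth = SigmoidParams(8, 1.5, 4, 1)
    y = sigmoid_eval(truth, times11)
    base = fit_sigmoid(times11, y)
    shifted = fit_sigmoid(times11 + 3.5, y)
    assert shifted.params.c == pytest.approx(base.params.c + 3.5, abs=1e-4)
    assert shifted.tti == pytest.approx(base.tti + 3.5, abs=1e-4)
    for name in ("a", "b", "d"):
        assert getattr(shifted.params, name) == pytest.approx(
            getattr(base.params, name), rel=1e-4, abs=1e-6
        )


def test_fit_scale_equivariance(times11):
    truth = SigmoidParams(8, -1.5, 4, 1)
    y = sigmoid_eval(truth, times11)
    base = fit_sigmoid(times11, y)
    scaled = fit_sigmoid(times11, 3.0 * y)
    assert scaled.params.a == pytest.approx(3.0 * base.params.a, rel=1e-3)
    assert scaled.params.d == pytest.approx(3.0 * base.params.d, rel=1e-3, abs=1e-5)
    assert scaled.params.b == pytest.approx(base.params.b, rel=1e-3)
    assert scaled.params.c == pytest.approx(base.params.c, rel=1e-3)


def test_fit_input_validation(times11):
    with pytest.raises(FlatDataError):
        fit_sigmoid(times11, np.full(11, 2.0))
    with pytest.raises(ValueError):
        fit_sigmoid([0, 1, 2], [0, 1, 2])  # fewer points than parameters
    with pytest.raises(ValueError, match="least_squares"):
        fit_sigmoid(times11, np.linspace(0.1, 1.2, 11), objective="poisson")


def test_fit_reports_standard_errors(times11):
    rng = np.random.default_rng(0)
    y = sigmoid_eval(SigmoidParams(20, -2, 5, 1), times11) + rng.normal(0, 0.5, 11)
    res = fit_sigmoid(times11, np.maximum(y, 0))
    se = res.std_errors
    assert np.all(np.isfinite(se[:4])) and np.all(se[:4] >= 0)
    assert np.isnan(se[4])  # f held fixed


def test_fit_free_f_five_parameters(times11):
    truth = SigmoidParams(10, -2, 5, 0, 2.0)
    res = fit_sigmoid(times11, sigmoid_eval(truth, times11), fix_f=False)
    assert res.converged and res.rss < 1e-6
    assert res.params.f == pytest.approx(2.0, rel=0.05)


def test_poisson_fit_matches_grid_search_oracle(times11):
    truth = SigmoidParams(30, -1.5, 5, 1)
    rng = np.random.default_rng(7)
    counts = rng.poisson(sigmoid_eval(truth, times11)).astype(float)
    res = fit_sigmoid(times11, counts, objective="poisson")
    assert res.converged

    # coarse independent grid search over (b, c) with plateaus from the fit
    bs = np.linspace(-5, -0.1, 100)
    cs = np.linspace(0, 10, 100)
    best = (None, np.inf)
    for b in bs:
        for c in cs:
            mu = np.maximum(
                sigmoid_eval(SigmoidParams(res.params.a, b, c, res.params.d), times11),
                1e-9,
            )
            nll = float(np.sum(mu - counts * np.log(mu)))
            if nll < best[1]:
                best = ((b, c), nll)
    (b_grid, c_grid), _ = best
    assert res.params.c == pytest.approx(c_grid, abs=2 * (cs[1] - cs[0]))
    assert res.params.b == pytest.approx(b_grid, abs=2 * (bs[1] - bs[0]))


# --------------------------------------------------------------------------
# linear comparison fit


def test_linear_fit_exact_line():
    fit = fit_linear([0, 1, 2], [1, 2, 3])
    assert fit == LinearFit(pytest.approx(1.0), pytest.approx(1.0), pytest.approx(0.0))


def test_linear_fit_constant_series_flat_slope():
    fit = fit_linear([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0])
    assert fit.slope == pytest.approx(0.0)
    assert fit.rss == pytest.approx(0.0)


def test_sigmoid_beats_line_on_sigmoid_data(times11):
    y = sigmoid_eval(SigmoidParams(10, -3, 5, 0), times11)
    assert fit_linear(times11, y).rss > fit_sigmoid(times11, y).rss


def test_linear_fit_needs_two_points():
    with pytest.raises(ValueError):
        fit_linear([1.0], [1.0])
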