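"""Category prediction, segmented fitting, and the verification contract."""

import numpy as np
import pytest

from chipturn.classify import (
    ELIMINATED,
    FALL,
    HILL,
    RISE,
    UNDEFINED,
    UNDEFINED_FALL,
    UNDEFINED_RISE,
    VALLEY,
    FlatSeriesError,
    Thresholds,
    analyze_locus,
    genuine_point_count,
    locate_extrema,
    predict_category,
    segment_and_fit,
    verify_or_eliminate,
)
from chipturn.sigmoid import SigmoidParams, sigmoid_eval
from chipturn.simulate import double_sigmoid_series


# --------------------------------------------------------------------------
# extrema and genuine points


@pytest.mark.parametrize(
    "ys, expected",
    [
        ([1, 5, 2], (0, 1)),
        ([5, 1, 1, 7], (1, 3)),  # earliest tie wins for the minimum
        ([7, 1, 5, 7], (1, 0)),  # earliest tie wins for the maximum
    ],
)
def test_locate_extrema(ys, expected):
    assert locate_extrema(ys) == expected


def test_locate_extrema_flat_series_signals():
    with pytest.raises(FlatSeriesError):
        locate_extrema([3.0, 3.0, 3.0])


@pytest.mark.parametrize(
    "ys, idx, side, expected",
    [
        ([0, 2, 10, 9.9, 9.8], 2, "trailing", 0),  # deviations within the band
        ([0, 2, 10, 7, 5], 2, "trailing", 2),  # both trailing points genuine
        ([0, 2, 10, 7, 5], 4, "trailing", 0),  # extremum at the last index
        ([0, 2, 10, 7, 5], 2, "leading", 2),
    ],
)
def test_genuine_point_count(ys, idx, side, expected):
    assert genuine_point_count(ys, idx, side, Thresholds(0.1, 1)) == expected


# --------------------------------------------------------------------------
# prediction


@pytest.mark.parametrize(
    "ys, expected",
    [
        (np.linspace(0, 10, 11), RISE),
        (np.linspace(10, 0, 11), FALL),
        ([0, 1, 8, 9, 3, 1], HILL),  # two genuine trailing points after the max
        ([0, 1, 8, 9, 8.9, 8.8], RISE),  # trailing points are plateau fluctuation
        ([9, 8, 1, 0, 6, 8], VALLEY),
        ([3, 3, 3, 3], UNDEFINED),
    ],
)
def test_predict_category(ys, expected):
    assert predict_category(ys) == expected


def test_predict_adjacent_extrema_without_plateau_is_undefined():
    # a lone noise spike: min and max adjacent, single genuine point each
    # side (not enough to promote to hill), neither end anchoring a plateau
    ys = [5.0, 0.0, 10.0, 5.2]
    assert predict_category(ys) == UNDEFINED_RISE
    assert predict_category([10 - y for y in ys]) == UNDEFINED_FALL


def test_predict_promotes_spike_with_plateaus_to_hill():
    # same adjacency but flanked by genuine points on both sides -> hill
    ys = [5.0, 5.2, 4.8, 0.0, 10.0, 5.1, 4.9, 5.0]
    assert predict_category(ys) == HILL


def test_predict_step_with_anchored_plateaus_stays_single():
    # adjacent extrema but both ends hug their extremum: a clean step rise
    ys = [0.0, 0.05, 0.1, 10.0, 9.9, 9.95, 10.0]
    assert predict_category(ys) == RISE


def test_hill_threshold_zero_allows_single_trailing_point():
    """With leading_trailing_min=0 one genuine trailing point makes a hill."""
    # max at the 2nd time point; trailing points plateau within the band
    # except the final drop, so exactly one genuine trailing point exists
    y = np.array([0, 9.0, 8.95, 8.9, 8.85, 8.8, 8.75, 8.7, 8.65, 8.6, 3.0])
    assert predict_category(y, Thresholds(0.1, 1)) == RISE
    assert predict_category(y, Thresholds(0.1, 0)) == HILL


def test_threshold_monotonicity_on_noisy_series():
    """Looser plateau range / higher point threshold never create hills."""
    rng = np.random.default_rng(5)
    t = np.arange(11.0)
    series = [
        np.maximum(sigmoid_eval(SigmoidParams(10, -2, c, 0), t) + rng.normal(0, 1, 11), 0)
        for c in np.linspace(2, 8, 40)
    ]

    def n_double(frac, lt):
        th = Thresholds(frac, lt)
        return sum(predict_category(y, th) in (HILL, VALLEY) for y in series)

    fracs = [0.02, 0.05, 0.1, 0.2, 0.4]
    counts = [n_double(f, 1) for f in fracs]
    assert counts == sorted(counts, reverse=True)
    lts = [0, 1, 2, 3]
    counts_lt = [n_double(0.1, lt) for lt in lts]
    assert counts_lt == sorted(counts_lt, reverse=True)


# --------------------------------------------------------------------------
# segmented fitting


def test_segment_and_fit_noise_free_hill_recovers_both_ttis(times11):
    rise = SigmoidParams(10, -2, 2, 0)
    fall = SigmoidParams(10, 2, 8, 0)
    y = double_sigmoid_series(times11, rise, fall, 5.0)
    res = segment_and_fit(times11, y, HILL)
    assert res.final == HILL
    assert len(res.fits) == 2
    assert res.tti_rise == pytest.approx(2.0, rel=0.02)
    assert res.tti_fall == pytest.approx(8.0, rel=0.02)


def test_segment_and_fit_single_rise(times11):
    y = sigmoid_eval(SigmoidParams(10, -2, 5, 0), times11)
    res = segment_and_fit(times11, y, RISE)
    assert len(res.fits) == 1
    assert res.tti_fall is None
    assert res.tti_rise == pytest.approx(5.0, rel=0.01)


def test_segment_and_fit_hill_with_extremum_at_second_point(times11):
    """An extremum at the second time point still yields a two-segment fit.

    The 2-point rise segment is fitted with its plateaus pinned at the
    segment endpoints, leaving (b, c) free.
    """
    fall = SigmoidParams(9, 1.5, 4, 0.5)
    y = np.concatenate([[0.5], sigmoid_eval(fall, times11[1:])])
    assert predict_category(y, Thresholds(0.1, 0)) == HILL
    res = segment_and_fit(times11, y, HILL)
    assert len(res.fits) == 2
    out = verify_or_eliminate(res)
    assert out.final == HILL
    assert 0.0 <= out.tti_rise <= 1.0  # rise happens between the first two points
    assert out.tti_fall == pytest.approx(4.0, rel=0.2)


def test_segment_and_fit_flat_series_is_linear_only():
    t = np.arange(5.0)
    res = segment_and_fit(t, np.full(5, 2.0), UNDEFINED)
    assert res.fits == [] and res.final == UNDEFINED
    assert res.linear.slope == pytest.approx(0.0)


# --------------------------------------------------------------------------
# verification


def test_verify_keeps_correct_rise(times11):
    y = sigmoid_eval(SigmoidParams(10, -2, 5, 0), times11)
    res = verify_or_eliminate(segment_and_fit(times11, y, RISE))
    assert res.final == RISE and not res.eliminated


def test_verify_eliminates_contradicted_prediction(times11):
    # force a rise prediction onto genuinely falling data
    y = sigmoid_eval(SigmoidParams(10, 2, 5, 0), times11)
    res = verify_or_eliminate(segment_and_fit(times11, y, RISE))
    assert res.final == ELIMINATED and res.eliminated
    assert res.tti_rise is None and res.tti_fall is None


def test_verify_hill_needs_both_segments(times11):
    y = double_sigmoid_series(
        times11, SigmoidParams(10, -2, 2, 0), SigmoidParams(10, 2, 8, 0), 5.0
    )
    res = segment_and_fit(times11, y, HILL)
    res.fits[1].converged = False  # break one segment
    assert verify_or_eliminate(res).final == ELIMINATED


def test_analyze_locus_end_to_end_conserves_loci(times11):
    rng = np.random.default_rng(11)
    finals = []
    for c in [2.0, 5.0, 8.0]:
        y = np.maximum(
            sigmoid_eval(SigmoidParams(10, -2, c, 0), times11) + rng.normal(0, 0.5, 11), 0
        )
        finals.append(analyze_locus(times11, y).final)
    verified = sum(f != ELIMINATED for f in finals)
    eliminated = sum(f == ELIMINATED for f in finals)
    assert verified + eliminated == 3
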