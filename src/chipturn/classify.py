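"""Locus behavior prediction, segmented fitting, and verification.

Each locus's coverage series is first *predicted* into one of six
categories from the times of its absolute minimum and maximum and from
how many "genuine" points (points deviating from an extremum by more
than the plateau-range tolerance) lead or trail those extrema:

* rise / fall — single sigmoid, coverage increases / decreases;
* hill / valley — coverage rises then falls (or vice versa), modeled
  as two concatenated sigmoids sharing the extremum sample;
* undefined rise / undefined fall — extrema ordering suggests a
  direction but the series shows no anchored plateau structure; still
  modeled as a single sigmoid.

The prediction is then *verified* against the fitted curve(s): any
segment whose fitted direction contradicts the prediction, or whose fit
failed to converge, eliminates the locus.  This two-fold check removes
false positives rather than silently reporting bad fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .io_coverage import GenomicInterval
from .sigmoid import FitResult, FlatDataError, LinearFit, fit_linear, fit_sigmoid

__all__ = [
    "Thresholds",
    "LocusResult",
    "CATEGORIES",
    "locate_extrema",
    "genuine_point_count",
    "predict_category",
    "segment_and_fit",
    "verify_or_eliminate",
    "analyze_locus",
]

RISE = "rise"
FALL = "fall"
HILL = "hill"
VALLEY = "valley"
UNDEFINED_RISE = "undefined_rise"
UNDEFINED_FALL = "undefined_fall"
UNDEFINED = "undefined"  # flat series: linear-only, no sigmoid direction
ELIMINATED = "eliminated"

CATEGORIES = (RISE, FALL, HILL, VALLEY, UNDEFINED_RISE, UNDEFINED_FALL, UNDEFINED, ELIMINATED)

# fitted sign(b) expectations per predicted category; b < 0 is increasing
_EXPECTED_DIRECTIONS = {
    RISE: ("increasing",),
    UNDEFINED_RISE: ("increasing",),
    FALL: ("decreasing",),
    UNDEFINED_FALL: ("decreasing",),
    HILL: ("increasing", "decreasing"),
    VALLEY: ("decreasing", "increasing"),
    UNDEFINED: (),
}


class FlatSeriesError(ValueError):
    """Constant coverage series: no extrema, modeled linear-only."""


@dataclass(frozen=True)
class Thresholds:
    """User-tunable knobs of the category prediction.

    plateau_range_fraction: tolerated coverage variation around an
      extremum, as a fraction of the locus's overall coverage range,
      within which a point counts as plateau fluctuation rather than
      genuine change (default 0.1, i.e. 10% of the range).
    leading_trailing_min: the number of genuine leading/trailing points
      that must be EXCEEDED to promote a locus from single- to
      double-sigmoid (hill/valley) modeling (default 1, so at least two
      genuine points are required).
    """

    plateau_range_fraction: float = 0.1
    leading_trailing_min: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_range_fraction <= 1.0:
            raise ValueError("plateau_range_fraction must lie in [0, 1]")
        if self.leading_trailing_min < 0:
            raise ValueError("leading_trailing_min must be non-negative")


@dataclass
class LocusResult:
    """Predicted and verified behavior of one locus, with all fits."""

    locus: GenomicInterval
    times: np.ndarray
    ys: np.ndarray
    predicted: str
    final: str
    fits: List[FitResult]
    linear: Optional[LinearFit]
    tti_rise: Optional[float] = None
    tti_fall: Optional[float] = None

    @property
    def eliminated(self) -> bool:
        return self.final == ELIMINATED

    @property
    def tti(self) -> Optional[float]:
        """Primary TTI: the rise-segment TTI when present, else the fall's."""
        return self.tti_rise if self.tti_rise is not None else self.tti_fall


def locate_extrema(ys: Sequence[float]) -> Tuple[int, int]:
    """Indices of the absolute minimum and maximum; earliest wins ties."""
    y = np.asarray(ys, dtype=float)
    if np.ptp(y) == 0:
        raise FlatSeriesError("constant coverage series has no extrema")
    return int(np.argmin(y)), int(np.argmax(y))


def genuine_point_count(
    ys: Sequence[float],
    extremum_index: int,
    side: str,
    thresholds: Thresholds = Thresholds(),
) -> int:
    """Points beyond an extremum deviating more than the plateau band.

    A point strictly before (``side='leading'``) or after
    (``side='trailing'``) the extremum is *genuine* when
    ``|y - y_extremum|`` exceeds ``plateau_range_fraction`` times the
    locus's overall coverage range — i.e. it changes meaningfully over
    time instead of fluctuating about a plateau.
    """
    y = np.asarray(ys, dtype=float)
    band = thresholds.plateau_range_fraction * float(np.ptp(y))
    ref = y[extremum_index]
    segment = y[:extremum_index] if side == "leading" else y[extremum_index + 1 :]
    return int(np.sum(np.abs(segment - ref) > band))


def _side_anchored(y: np.ndarray, idx: int, side: str, band: float) -> bool:
    """True if the outer side of an extremum holds >=1 plateau-band point."""
    segment = y[:idx] if side == "leading" else y[idx + 1 :]
    if segment.size == 0:
        return False
    return bool(np.any(np.abs(segment - y[idx]) <= band))


def predict_category(
    ys: Sequence[float], thresholds: Thresholds = Thresholds()
) -> str:
    """Predict a locus's category from extrema order and genuine points.

    With the minimum before the maximum the base behavior is a rise; it
    is promoted to a hill when the genuine trailing points after the
    maximum (or, symmetrically, the genuine leading points before the
    minimum) exceed ``leading_trailing_min``.  Maximum-first series are
    the mirror image (fall, promoted to valley).  Series whose extrema
    are adjacent in time without an anchored plateau at either end are
    demoted to undefined rise/fall; constant series are undefined and
    modeled linear-only.
    """
    y = np.asarray(ys, dtype=float)
    try:
        i_min, i_max = locate_extrema(y)
    except FlatSeriesError:
        return UNDEFINED
    band = thresholds.plateau_range_fraction * float(np.ptp(y))
    if i_min < i_max:
        base, double = RISE, HILL
        first, second = i_min, i_max
    else:
        base, double = FALL, VALLEY
        first, second = i_max, i_min
    trailing = genuine_point_count(y, second, "trailing", thresholds)
    leading = genuine_point_count(y, first, "leading", thresholds)
    if max(trailing, leading) > thresholds.leading_trailing_min:
        return double
    # sanity demotion: adjacent extrema with no plateau anchored at either end
    if second - first == 1:
        lead_ok = first == 0 or _side_anchored(y, first, "leading", band)
        trail_ok = second == len(y) - 1 or _side_anchored(y, second, "trailing", band)
        if not lead_ok and not trail_ok:
            return UNDEFINED_RISE if base == RISE else UNDEFINED_FALL
    return base


def _default_fitter(times, ys, fixed_plateaus=None) -> FitResult:
    return fit_sigmoid(times, ys, fixed_plateaus=fixed_plateaus)


def _fit_segment(times, ys, increasing: bool, fitter) -> FitResult:
    """Fit one hill/valley segment; short segments pin the plateaus.

    A segment with fewer points than free parameters is refitted with
    the plateaus fixed at its endpoint values, leaving only (b, c) free
    — this is what makes extrema at the second time point fittable.
    """
    n = len(times)
    if n >= 4:
        return fitter(times, ys)
    if n >= 2 and ys[0] != ys[-1]:
        early, late = float(ys[0]), float(ys[-1])
        # a is the late plateau when increasing (b<0), the early one otherwise
        a, d = (late, early) if increasing else (early, late)
        return fitter(times, ys, fixed_plateaus=(a, d))
    raise ValueError(f"segment of {n} points cannot constrain a sigmoid")


def segment_and_fit(
    times: Sequence[float],
    ys: Sequence[float],
    predicted: str,
    fitter: Callable = _default_fitter,
    locus: Optional[GenomicInterval] = None,
) -> LocusResult:
    """Fit sigmoid(s) according to the predicted category.

    Single-sigmoid categories are fitted on all points.  A hill is split
    at its absolute maximum into a rise segment (start..max) and a fall
    segment (max..end) with the extremum sample shared by both; a valley
    is split symmetrically at its minimum.  A segment that cannot be
    fitted demotes the locus to undefined with a single-sigmoid
    fallback.  The linear comparison fit is always computed.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ys, dtype=float)
    if locus is None:
        locus = GenomicInterval("unplaced", 0, max(1, len(y)))
    linear = fit_linear(t, y) if t.size >= 2 else None

    if predicted == UNDEFINED:
        return LocusResult(locus, t, y, predicted, predicted, [], linear)

    if predicted in (HILL, VALLEY):
        i_min, i_max = locate_extrema(y)
        split = i_max if predicted == HILL else i_min
        first_inc = predicted == HILL  # hill: rise then fall
        try:
            fit1 = _fit_segment(t[: split + 1], y[: split + 1], first_inc, fitter)
            fit2 = _fit_segment(t[split:], y[split:], not first_inc, fitter)
        except (ValueError, FlatDataError):
            return _single_fallback(locus, t, y, predicted, linear, fitter, demote=True)
        rise_fit, fall_fit = (fit1, fit2) if predicted == HILL else (fit2, fit1)
        return LocusResult(
            locus, t, y, predicted, predicted, [fit1, fit2], linear,
            tti_rise=rise_fit.tti, tti_fall=fall_fit.tti,
        )

    return _single_fallback(locus, t, y, predicted, linear, fitter, demote=False)


def _single_fallback(locus, t, y, predicted, linear, fitter, demote: bool) -> LocusResult:
    final_pred = predicted
    if demote:
        i_min, i_max = locate_extrema(y)
        final_pred = UNDEFINED_RISE if i_min < i_max else UNDEFINED_FALL
    try:
        fit = fitter(t, y)
    except (ValueError, FlatDataError):
        return LocusResult(locus, t, y, final_pred, UNDEFINED, [], linear)
    tti_rise = fit.tti if fit.direction == "increasing" else None
    tti_fall = fit.tti if fit.direction == "decreasing" else None
    return LocusResult(
        locus, t, y, final_pred, final_pred, [fit], linear,
        tti_rise=tti_rise, tti_fall=tti_fall,
    )


def verify_or_eliminate(result: LocusResult) -> LocusResult:
    """Confirm the prediction against the fitted direction(s), or eliminate.

    A locus keeps its predicted category only when every fitted segment
    converged and its direction (the sign of b) matches what the
    prediction requires; otherwise the final category is 'eliminated'.
    """
    expected = _EXPECTED_DIRECTIONS.get(result.predicted, ())
    if result.predicted == UNDEFINED or not expected:
        return result
    ok = len(result.fits) == len(expected) and all(
        fit.converged and fit.direction == want
        for fit, want in zip(result.fits, expected)
    )
    if ok:
        result.final = result.predicted
    else:
        result.final = ELIMINATED
        result.tti_rise = None
        result.tti_fall = None
    return result


def analyze_locus(
    times: Sequence[float],
    ys: Sequence[float],
    thresholds: Thresholds = Thresholds(),
    fitter: Callable = _default_fitter,
    locus: Optional[GenomicInterval] = None,
) -> LocusResult:
    """Predict, fit, and verify a single locus (the per-locus pipeline)."""
    predicted = predict_category(ys, thresholds)
    result = segment_and_fit(times, ys, predicted, fitter, locus)
    return verify_or_eliminate(result)
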