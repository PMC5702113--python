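# Methods

## Model

Per-locus coverage across a time course is modeled by the log-logistic
sigmoid

    y(x) = d + (a − d) / (1 + exp(b (x − c)))^f ,

with both plateaus constrained non-negative (coverage cannot be
negative). The fit is parametrized internally as `a = d + δ, δ ≥ 0`, so
`a` is always the upper and `d` the lower plateau and the curve is
increasing exactly when `b < 0` — for the symmetric `f = 1` model this
costs nothing, because `(a, b, c, d)` and `(d, −b, c, a)` describe the
identical curve. This makes the sign of the fitted incorporation rate
index a reliable direction indicator, which the verification step
depends on.

Closed forms used throughout:

- inflection point `x = c − ln(f)/b` (root of the second derivative);
- turnover time index `TTI = c + ln(2^{1/f} − 1)/b`, the time at which
  `y = (a + d)/2`; for `f = 1` both reduce to `c` exactly.

The TTI is undefined for flat curves (`a = d`); such fits report NaN and
the locus contributes to no TTI summary.

## Fitting

Least squares (default) via bounded trust-region minimization, started
from both an increasing (`b < 0`) and a decreasing (`b > 0`) seed plus
one perturbed restart each; the lower objective wins, so the fitted
direction is decided by the data, not by the category prediction.
Bounds: plateaus in `[0, 3·max(y)]`, `c` within one time-span of the
sampled window, `|b| ∈ [1e−6, 1e3]`, `f ∈ [0.1, 10]` when free (the 5P
model is opt-in; `f` is fixed at 1 by default because a free asymmetry
factor is rarely biologically identifiable from ≤ a dozen time points).
Objective tolerances 1e−10; a fit whose residual is at the numerical
floor is treated as converged even if the optimizer exhausted its
evaluation budget wandering the flat ridge around an exact solution.
Standard errors come from the Gauss–Newton curvature
`s² (JᵀJ)⁻¹` with `s² = RSS/(n − p)`; `var(a)` follows from the full
covariance of `(d, δ)`. The Poisson objective (for raw counts)
maximizes `Σ(y ln ŷ − ŷ)` with `ŷ` floored at 1e−9 and takes standard
errors from the finite-difference observed information; it deliberately
rejects non-integer input, since continuous normalized coverage has no
Poisson likelihood — use least squares there. An ordinary least-squares
line is always fitted alongside as the degenerate comparison model.

Initialization: plateaus from the observed min/max, `c` from the first
midrange crossing, `|b| ≈ 4/(time span)`, `f = 1`.

## Category prediction and verification

Prediction uses only the observed series: the indices of the absolute
minimum and maximum (earliest wins ties, favoring the simpler
single-sigmoid path) order the base category (min first → rise, max
first → fall). Points beyond an extremum are *genuine* when they deviate
from it by more than `plateau_range_fraction × (coverage range)`;
genuine trailing points after the second extremum or leading points
before the first one exceeding `leading_trailing_min` promote the locus
to a double sigmoid (hill/valley), split at the interior extremum with
the extremum sample shared by both segments. Defaults:
`plateau_range_fraction = 0.1` (10% of the locus range; the CLI `-L`
flag takes percent) and `leading_trailing_min = 1` (more than one
genuine point required) — both are configuration, logged on every run,
and deliberately conservative: lowering `-t` to 0 lets a single genuine
trailing point trigger a hill, which matters when peaks emerge as early
as the second time point.

Two further rules handle degenerate series. A constant series has no
extrema and is reported as `undefined` with a linear fit only. A series
whose extrema are adjacent in time, not promoted to a double sigmoid,
and with no plateau-band point anchoring either end (a lone noise
spike) is demoted to `undefined_rise`/`undefined_fall` and fitted as a
single sigmoid.

Segments shorter than the free parameter count (possible when the
extremum sits at the second or second-to-last time point) are fitted
with the plateaus pinned at the segment endpoints, leaving `(b, c)`
free; a segment that still cannot be constrained demotes the locus to
undefined with a single-sigmoid fallback.

Verification: the final category equals the prediction only if every
fitted segment converged and its direction (sign of `b`) matches what
the prediction requires; otherwise the locus is `eliminated` but kept
in all output tables, so verified + eliminated always equals the input
locus count.

## Normalization

Raw coverage is the mean per-base depth over each interval (CIGAR-aware,
secondary/supplementary/unmapped reads excluded, strand ignored); the
mean rather than the sum keeps loci of different lengths comparable.
Each time point's column is divided by the maximum coverage over
background intervals sampled uniformly from the peak complement
(default 10,000 intervals of the median peak length, seeded and
logged) — a per-time-point scale, since its purpose is correcting
sequencing-depth differences between samples. Input controls are scaled
by their genome-wide maximum (approximated over background + peak
intervals; an exhaustive windowed scan is available) and subtracted
with a floor at zero; the resulting zero inflation is left as-is.
Replicates are averaged after normalization. User-supplied scale
factors (`-dm`) or a pre-normalized counts table bypass the respective
stages entirely.

## Synthetic data generator

The generator emulates a kinetic ChIP-seq time course on a toy
three-chromosome genome, with each locus following an exact sigmoid
sampled at 11 time points (0–10, relative units) plus additive Poisson
background noise. The four default groups vary one axis each: IRI
magnitude {0.5, 0.75, 1.0, 1.5, 2.0, 3.0} at inflection 5; inflection
{1 … 9} at IRI 3; peak length {250, 500, 1000, 2000, 4000} bp at
inflection 4.5; upper asymptote {2, 5, 10, 20, 50} coverage units at
inflection 5.5. Where a group does not vary them, peak length is 500 bp
and the upper asymptote 10; true lower plateaus are 0, matching the
non-negativity constraint. Falls mirror rises with `b = |IRI|`.
Reduced-time-point designs (staggered, first-six, first-and-last-five)
are pure subsets of `time_points`. Background noise is an independent
Poisson stream per time point with mean 1 by default, approximating 1X
random background coverage: noise enters as whole mapped reads, so an
integer-valued, non-negative perturbation is the natural model. The
generator can materialize the simulation as BED plus sorted, indexed
per-time-point BAMs whose mean per-base depth matches the simulated
coverage to within one read of depth quantization.

What the generator does *not* emulate: biological variability between
loci and replicates (typically larger than counting noise), mappability
and GC structure, read-level error profiles, and oscillating or
multi-phase trajectories. Passing recovery tests therefore demonstrates
correctness of the modeling machinery under the stated noise model, not
performance on any particular real dataset.

Benchmark scale: the recovery benchmark runs at 20 loci per grid level
(1,000 loci across rises and falls), which gives stable medians while
keeping a full run in tens of seconds; the per-group locus counts are
spec fields and scale up freely.

## Numerical and design choices

- Sigmoid evaluation uses `log1p(exp(·))` so extreme `|b(x − c)|`
  saturates to the correct plateau without overflow.
- Direction-vs-label convention: the literature labels `a` the lower
  and `d` the upper asymptote, yet assigns rises a negative IRI — which
  contradicts the formula's limits. Here the direction rule wins
  (increasing ⇔ `b < 0`), `a` is pinned to the upper plateau by the
  ordered parametrization, and reported lower/upper asymptotes are
  `min(a, d)`/`max(a, d)`.
- Extremum ties break to the earliest time point.
- Background sampling may place intervals that overlap each other (they
  never overlap peaks); sampling is uniform over candidate start
  positions and reproducible under the run seed.
- Hills contribute TTI_rise to signal-increase summaries; generic TTI
  summaries (feature boxplots, replicate ratios, cluster bins) use
  TTI_rise when present, else TTI_fall.
- Per-locus extraction and fitting are independent and may run
  concurrently; outputs are ordered by input locus order regardless of
  schedule.

## Known limitations

- Oscillating, multi-hill, or rise–plateau–rise trajectories are out of
  scope; at most one direction change is modeled.
- Standard errors are curvature-based (Gauss–Newton / observed
  information) and understate uncertainty for near-degenerate fits,
  e.g. when an inflection lies outside the sampled window.
- The Poisson objective requires integer counts; there is no
  negative-binomial or weighted option.
- Input subtraction can zero-inflate low-coverage loci; no correction
  is applied.
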