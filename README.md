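# chipturn

Sigmoidal modeling of time-course ChIP-seq coverage: locus-level binding
kinetics, turnover time indices, and temporal behavior classification.

## The problem

Time-course ChIP-seq (and related assays such as ChEC-seq and XR-seq)
measures protein–DNA occupancy at thousands of genomic loci across a
series of time points. The biologically interesting quantities are
kinetic: *when* does occupancy at a locus change, *how fast*, and in
*which direction*? `chipturn` answers these by fitting each locus's
normalized coverage trajectory to a four/five-parameter sigmoid

```
y = d + (a − d) / (1 + exp(b·(x − c)))^f
```

where `b` is the **incorporation rate index** (IRI, the steepness at the
inflection point; negative for rises, positive for falls), `c` a time
offset, `f` a positive asymmetry factor (fixed at 1 by default, the
symmetric 4P model), and `a`/`d` the two plateaus. The **turnover time
index** (TTI) is the time at which the curve crosses the plateau midpoint
`(a + d)/2` — the locus's occupancy half-change time. In closed form

```
TTI = c + ln(2^(1/f) − 1) / b        (= c exactly when f = 1)
```

and the inflection point (root of the second derivative) is
`x = c − ln(f)/b`.

Each locus is first **predicted** into one of six categories from the
timing of its absolute coverage minimum and maximum and the number of
"genuine" points (beyond a plateau-range tolerance) leading or trailing
those extrema: *rise*, *fall*, *hill* (rise then fall), *valley* (fall
then rise), or *undefined rise/fall*. Hills and valleys are fitted as two
concatenated sigmoids sharing the extremum sample, giving separate
TTI_rise and TTI_fall. The prediction is then **verified** against the
fitted direction(s); contradicted or non-converged loci are
**eliminated** rather than silently reported — a two-fold check that
removes false positives. A linear regression of the same points is always
reported alongside for residual comparison.

## Worked example

```python
import numpy as np
from chipturn import analyze_locus
from chipturn.sigmoid import SigmoidParams, sigmoid_eval

times = np.arange(11.0)                       # 11 time points, 0..10
rng = np.random.default_rng(0)
truth = SigmoidParams(a=12.0, b=-1.5, c=4.0, d=0.0)
coverage = sigmoid_eval(truth, times) + rng.poisson(1.0, 11)

result = analyze_locus(times, coverage)
fit = result.fits[0]
print("category :", result.final)
print("IRI (b)  : %.3f +/- %.3f" % (fit.params.b, fit.std_errors[1]))
print("TTI      : %.3f +/- %.3f" % (fit.tti, fit.std_errors[2]))
print("plateaus : %.3f -> %.3f" % (fit.params.lower_asymptote, fit.params.upper_asymptote))
print("sigmoid RSS %.3f vs linear RSS %.3f" % (fit.rss, result.linear.rss))
```

prints

```
category : rise
IRI (b)  : -1.360 +/- 0.333
TTI      : 3.473 +/- 0.205
plateaus : 0.055 -> 13.066
sigmoid RSS 5.941 vs linear RSS 48.164
```

The locus was generated as a rise with true inflection at t = 4 plus
Poisson background of mean 1; the verified category is `rise`, the fitted
TTI (3.47 ± 0.21) sits within ~13% of the truth at this noise level, and
the sigmoid beats the straight-line fit by an order of magnitude in
residual sum of squares.

## Command line

The same pipeline runs from a shell on BAM + BED input:

```bash
chipturn -bed loci.bed -bam timecourse_rep1/ -bam timecourse_rep2/ \
         -input input_tc/ -L 10 -t 1 -o out/
```

- one coordinate-sorted, indexed BAM per time point per folder;
- per-time-point depth scaling by the maximum coverage over sampled
  non-peak background intervals (or user factors via `-dm scales.tsv`);
- input-control subtraction floored at zero, replicate averaging;
- `-L` sets the plateau range threshold in percent of each locus's
  coverage range, `-t` the genuine leading/trailing points threshold;
- `-counts table.tsv` accepts a pre-normalized counts matrix instead of
  BAMs and skips normalization.

Outputs: `results.tsv` (per-segment parameters a, b/IRI, c, d, f with
standard errors, TTI, RSS, linear fit, elimination flag),
`normalized_coverage.tsv`, `heatmap.tsv` (per-locus 0–1 scaling),
`category_proportions.tsv`, `extrema_incidence.tsv`, optional
`feature_tti.tsv`, and `manifest.json` recording every applied default.

## Simulation benchmark

`chipturn.simulate` generates synthetic time courses with known truth on
a three-chromosome toy genome: four locus groups varying IRI
({−0.5 … −3.0}), inflection point ({1 … 9}), peak length, and upper
asymptote, sampled at 11 time points with additive Poisson background.
`evaluate_recovery` scores fitted TTIs against the true inflection points
and crosses true against assigned categories. The same module emits
BED + indexed BAM fixtures whose per-base depth reproduces the simulated
coverage, for end-to-end pipeline testing.

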