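"""End-to-end orchestration and summary analytics.

The full chain: read loci and alignments -> per-time-point depth
scaling against sampled background -> optional input subtraction ->
replicate averaging -> per-locus category prediction, sigmoid fitting
and verification -> result tables, summaries and a run manifest.
Pre-normalized counts tables skip normalization entirely.
Per-locus work is independent; results are always ordered by input
locus order.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from functools import partial
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from . import __version__
from .classify import LocusResult, Thresholds, analyze_locus
from .io_coverage import (
    CoverageMatrix,
    GenomicInterval,
    TimeCourseExperiment,
    build_coverage_matrix,
    read_bed,
    read_counts_table,
    write_results_table,
)
from .normalize import (
    ScaleVector,
    average_replicates,
    background_scale,
    genome_max_coverage,
    make_background_intervals,
    normalize_matrix,
    read_scale_file,
    subtract_input,
)
from .sigmoid import fit_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ResultSet",
    "run",
    "analyze_matrix",
    "heatmap_matrix",
    "category_summary",
    "tti_histogram",
    "feature_tti_distributions",
    "replicate_tti_ratio",
    "tti_cluster_bins",
]


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one coverage source."""

    bed_path: Optional[str] = None
    bam_folders: List[str] = field(default_factory=list)
    input_folders: List[str] = field(default_factory=list)
    counts_path: Optional[str] = None
    scale_file: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    objective: str = "least_squares"
    fix_f: bool = True
    feature_beds: Dict[str, str] = field(default_factory=dict)
    cluster_bin_size: int = 200_000
    cluster_min_loci: int = 30
    output_dir: str = "chipturn_out"
    seed: int = 0
    time_labels: Optional[List[float]] = None
    n_background: int = 10_000
    background_length: Optional[int] = None

    def __post_init__(self) -> None:
        has_bam = bool(self.bam_folders)
        has_counts = self.counts_path is not None
        if has_bam == has_counts:
            raise ValueError(
                "exactly one coverage source required: BAM folders or a counts table"
            )
        if has_bam and self.bed_path is None:
            raise ValueError("BAM input requires a BED file of loci")


@dataclass
class ResultSet:
    results: List[LocusResult]
    matrix: CoverageMatrix
    config: RunConfig
    results_table: Optional[pd.DataFrame] = None


def _bam_files(folder: str) -> List[str]:
    files = sorted(
        os.path.join(folder, f)
        for f in os.listdir(folder)
        if f.endswith((".bam", ".sam", ".cram"))
    )
    if not files:
        raise ValueError(f"no alignment files found in {folder}")
    return files


def _genome_sizes(bam_path: str) -> Dict[str, int]:
    with pysam.AlignmentFile(bam_path) as af:
        return dict(zip(af.references, af.lengths))


def _normalized_matrix(config: RunConfig, loci: List[GenomicInterval]) -> CoverageMatrix:
    """Coverage extraction + the full normalization chain for BAM input."""
    rep_files = [_bam_files(f) for f in config.bam_folders]
    input_files = [_bam_files(f) for f in config.input_folders]
    n_times = len(rep_files[0])
    times = list(config.time_labels) if config.time_labels else list(range(n_times))
    exp = TimeCourseExperiment(times, rep_files, loci, input_files)

    sizes = _genome_sizes(rep_files[0][0])
    background = make_background_intervals(
        sizes, loci, n=config.n_background,
        length=config.background_length, seed=config.seed,
    )
    logger.info(
        "sampled %d background intervals (seed %d)", config.n_background, config.seed
    )

    def scaled(paths: List[str], for_input: bool) -> CoverageMatrix:
        mat = build_coverage_matrix(
            TimeCourseExperiment(times, [paths], loci, []), 0
        )
        if config.scale_file:
            scales = read_scale_file(config.scale_file, times)
        elif for_input:
            factors = [
                genome_max_coverage(p, background + loci) for p in paths
            ]
            scales = ScaleVector(np.array(factors), source="genome_max")
        else:
            factors = [background_scale(p, loci, background) for p in paths]
            scales = ScaleVector(np.array(factors), source="background_max")
        return normalize_matrix(mat, scales)

    reps = [scaled(paths, for_input=False) for paths in rep_files]
    if input_files:
        inputs = [scaled(paths, for_input=True) for paths in input_files]
        mean_input = average_replicates(inputs)
        reps = [
            subtract_input(rep, mean_input.replace(mean_input.values, "scaled"))
            for rep in reps
        ]
    return average_replicates(reps)


def analyze_matrix(
    matrix: CoverageMatrix,
    loci: Optional[Sequence[GenomicInterval]] = None,
    thresholds: Thresholds = Thresholds(),
    objective: str = "least_squares",
    fix_f: bool = True,
) -> List[LocusResult]:
    """Classify, fit and verify every row of a coverage matrix, in order."""
    if loci is None:
        loci = [
            GenomicInterval("unplaced", i * 1000, i * 1000 + 999, lid)
            for i, lid in enumerate(matrix.locus_ids)
        ]
    fitter = partial(fit_sigmoid, objective=objective, fix_f=fix_f)

    def _fit(t, y, fixed_plateaus=None):
        return fitter(t, y, fixed_plateaus=fixed_plateaus)

    return [
        analyze_locus(matrix.time_labels, matrix.values[i], thresholds, _fit, loci[i])
        for i in range(len(matrix.locus_ids))
    ]


def run(config: RunConfig) -> ResultSet:
    """Execute the full pipeline and write all output tables."""
    os.makedirs(config.output_dir, exist_ok=True)
    try:
        if config.counts_path:
            matrix = read_counts_table(config.counts_path)
            loci = (
                read_bed(config.bed_path)
                if config.bed_path
                else None
            )
            logger.info("counts table supplied: normalization skipped")
        else:
            loci = read_bed(config.bed_path)
            matrix = _normalized_matrix(config, loci)
    except Exception as exc:
        raise RuntimeError(f"[input/normalization] {exc}") from exc

    if loci is not None and len(loci) != len(matrix.locus_ids):
        raise RuntimeError(
            f"[input] {len(loci)} BED loci vs {len(matrix.locus_ids)} matrix rows"
        )
    try:
        results = analyze_matrix(
            matrix, loci, config.thresholds, config.objective, config.fix_f
        )
    except Exception as exc:
        raise RuntimeError(f"[modeling] {exc}") from exc

    try:
        table = write_results_table(
            results, os.path.join(config.output_dir, "results.tsv")
        )
        _write_summaries(results, matrix, config)
        _write_manifest(config)
    except Exception as exc:
        raise RuntimeError(f"[reporting] {exc}") from exc
    return ResultSet(results, matrix, config, table)


def _write_summaries(results, matrix, config) -> None:
    matrix.to_dataframe().to_csv(
        os.path.join(config.output_dir, "normalized_coverage.tsv"), sep="\t"
    )
    heatmap_matrix(matrix).to_csv(
        os.path.join(config.output_dir, "heatmap.tsv"), sep="\t"
    )
    props, min_inc, max_inc = category_summary(results)
    props.to_csv(
        os.path.join(config.output_dir, "category_proportions.tsv"),
        sep="\t", header=["proportion"],
    )
    pd.DataFrame({"min_incidence": min_inc, "max_incidence": max_inc}).to_csv(
        os.path.join(config.output_dir, "extrema_incidence.tsv"), sep="\t"
    )
    if config.feature_beds:
        samples = feature_tti_distributions(results, config.feature_beds)
        rows = [
            {"feature": name, "locus_id": lid, "tti": tti}
            for name, pairs in samples.items()
            for lid, tti in pairs
        ]
        pd.DataFrame(rows, columns=["feature", "locus_id", "tti"]).to_csv(
            os.path.join(config.output_dir, "feature_tti.tsv"), sep="\t", index=False
        )


def _write_manifest(config) -> None:
    manifest = {
        "chipturn_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "pysam": pysam.__version__,
        "seed": config.seed,
        "thresholds": {
            "plateau_range_fraction": config.thresholds.plateau_range_fraction,
            "leading_trailing_min": config.thresholds.leading_trailing_min,
        },
        "objective": config.objective,
        "fix_f": config.fix_f,
        "coverage_source": "counts" if config.counts_path else "bam",
    }
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# summary analytics


def heatmap_matrix(matrix: CoverageMatrix) -> pd.DataFrame:
    """Per-locus min-max scaling to [0, 1] (heatmap input).

    Constant loci cannot be scaled and map to all-zero rows (warned).
    """
    values = matrix.values
    lo = values.min(axis=1, keepdims=True)
    rng = np.ptp(values, axis=1, keepdims=True)
    flat = rng[:, 0] == 0
    if flat.any():
        logger.warning("%d constant loci mapped to all-zero heatmap rows", flat.sum())
    scaled = np.where(rng > 0, (values - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return pd.DataFrame(scaled, index=matrix.locus_ids, columns=matrix.time_labels)


def category_summary(
    results: Sequence[LocusResult],
) -> Tuple[pd.Series, pd.Series, pd.Series]:
    """Category proportions plus per-time incidence of the extrema.

    Returns (proportions over final categories, fraction of loci whose
    absolute minimum falls at each time, same for the maximum); each
    vector sums to 1.
    """
    if not results:
        raise ValueError("no results to summarize")
    props = (
        pd.Series([r.final for r in results]).value_counts(normalize=True).sort_index()
    )
    times = results[0].times
    min_counts = np.zeros(times.size)
    max_counts = np.zeros(times.size)
    for r in results:
        min_counts[int(np.argmin(r.ys))] += 1
        max_counts[int(np.argmax(r.ys))] += 1
    n = len(results)
    return (
        props,
        pd.Series(min_counts / n, index=times),
        pd.Series(max_counts / n, index=times),
    )


def _contributing_tti(r: LocusResult, signal_increase_only: bool) -> Optional[float]:
    if r.eliminated:
        return None
    if signal_increase_only:
        return r.tti_rise  # hills contribute their rise-segment TTI
    return r.tti


def tti_histogram(
    results: Sequence[LocusResult],
    bins: Sequence[float],
    by_category: bool = False,
    signal_increase_only: bool = False,
):
    """Histogram of TTIs over user bins, optionally split by category."""
    pairs = [
        (r.final, tti)
        for r in results
        if (tti := _contributing_tti(r, signal_increase_only)) is not None
        and np.isfinite(tti)
    ]
    if not pairs:
        logger.warning("no verified loci contribute a TTI; empty histogram")
        return pd.Series(np.zeros(len(bins) - 1), dtype=int) if not by_category else pd.DataFrame()
    edges = np.asarray(bins, dtype=float)
    if not by_category:
        counts, _ = np.histogram([t for _, t in pairs], bins=edges)
        return pd.Series(counts)
    cats = sorted({c for c, _ in pairs})
    return pd.DataFrame(
        {
            cat: np.histogram([t for c, t in pairs if c == cat], bins=edges)[0]
            for cat in cats
        }
    )


def feature_tti_distributions(
    results: Sequence[LocusResult],
    feature_beds: Dict[str, object],
) -> Dict[str, List[Tuple[str, float]]]:
    """TTI samples per genome feature, by >=1 bp interval intersection.

    ``feature_beds`` maps a feature name to a BED path or a list of
    intervals.  A locus contributes its TTI to every feature it
    overlaps (half-open semantics); loci without a TTI contribute
    nowhere.
    """
    out: Dict[str, List[Tuple[str, float]]] = {}
    for name, src in feature_beds.items():
        try:
            intervals = read_bed(src) if isinstance(src, (str, os.PathLike)) else src
        except OSError as exc:
            raise ValueError(f"feature {name!r}: cannot read {src}: {exc}") from exc
        trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        samples: List[Tuple[str, float]] = []
        for r in results:
            tti = r.tti
            if r.eliminated or tti is None or not np.isfinite(tti):
                continue
            tree = trees.get(r.locus.chrom)
            if tree is not None and tree.overlap(r.locus.start, r.locus.end):
                samples.append((r.locus.name, tti))
        out[name] = samples
    return out


def replicate_tti_ratio(
    results_rep1: Sequence[LocusResult],
    results_rep2: Sequence[LocusResult],
) -> Tuple[pd.Series, int]:
    """Per-locus log2(TTI_rep1 / TTI_rep2) over loci verified in both.

    Returns the ratio series (indexed by locus id) and the number of
    common loci excluded because either replicate eliminated them or
    lacked a TTI.
    """
    t1 = {r.locus.name: r for r in results_rep1}
    t2 = {r.locus.name: r for r in results_rep2}
    common = [k for k in t1 if k in t2]
    if not common:
        raise ValueError("replicates share no loci")
    ratios, excluded = {}, 0
    for k in common:
        a, b = t1[k], t2[k]
        if (
            a.eliminated or b.eliminated
            or a.tti is None or b.tti is None
            or a.tti <= 0 or b.tti <= 0
        ):
            excluded += 1
            continue
        ratios[k] = float(np.log2(a.tti / b.tti))
    return pd.Series(ratios, dtype=float), excluded


def tti_cluster_bins(
    results: Sequence[LocusResult],
    genome_sizes: Dict[str, int],
    bin_size: int = 200_000,
    min_loci: int = 30,
) -> pd.DataFrame:
    """Fixed-width genome bins with per-bin TTI statistics.

    Loci are assigned to the bin containing their interval midpoint;
    bins holding at least ``min_loci`` loci are flagged as TTI clusters.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for r in results:
        tti = r.tti
        if r.eliminated or tti is None or not np.isfinite(tti):
            continue
        rows.append({
            "chrom": r.locus.chrom,
            "bin_start": (r.locus.midpoint // bin_size) * bin_size,
            "tti": tti,
        })
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "bin_start", "bin_end", "count", "mean_tti", "sd_tti", "is_cluster"]
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["chrom", "bin_start"])["tti"]
        .agg(count="size", mean_tti="mean", sd_tti="std")
        .reset_index()
    )
    agg["bin_end"] = agg["bin_start"] + bin_size
    agg["is_cluster"] = agg["count"] >= min_loci
    return agg[["chrom", "bin_start", "bin_end", "count", "mean_tti", "sd_tti", "is_cluster"]]
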