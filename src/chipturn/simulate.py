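"""Synthetic time-course coverage with known sigmoidal truth.

The generator lays loci on a three-chromosome toy genome and gives each
a true sigmoid trajectory sampled at 11 time points (0..10, relative
units).  Four locus groups probe the method along one axis each:

* ``2L.1`` — inflection fixed at 5; IRI varies over
  {-0.5, -0.75, -1.0, -1.5, -2.0, -3.0} (absolute values for falls);
* ``2L.2`` — IRI fixed at -3; inflection varies over 1..9;
* ``2R``   — inflection 4.5, IRI -1.5; peak length varies;
* ``3R``   — inflection 5.5, IRI -1.5; upper asymptote varies.

Background noise is additive Poisson with configurable mean (default 1,
approximating 1X random background coverage).  The truth table of
per-locus parameters supports recovery scoring: percent deviation of
the fitted turnover time index from the true inflection point, plus a
category confusion table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .io_coverage import CoverageMatrix, GenomicInterval, write_bed
from .sigmoid import SigmoidParams, sigmoid_eval

__all__ = [
    "SimGroup",
    "NoiseModel",
    "SimulationSpec",
    "default_spec",
    "simulate_true_coverage",
    "add_noise",
    "simulate_dataset",
    "genome_sizes_for",
    "emit_fixture_files",
    "evaluate_recovery",
    "double_sigmoid_series",
]

DEFAULT_IRI_GRID = (-0.5, -0.75, -1.0, -1.5, -2.0, -3.0)
DEFAULT_INFLECTION_GRID = tuple(range(1, 10))
DEFAULT_PEAK_LENGTH_GRID = (250, 500, 1000, 2000, 4000)
DEFAULT_UPPER_GRID = (2.0, 5.0, 10.0, 20.0, 50.0)
DEFAULT_PEAK_LENGTH = 500
DEFAULT_UPPER = 10.0
LOCUS_GAP = 500  # bp between adjacent simulated peaks


@dataclass(frozen=True)
class SimGroup:
    """One simulated locus group: a grid over the varied parameter(s)."""

    group_id: str
    chrom: str
    n_loci: int
    inflection_grid: Tuple[float, ...]
    iri_grid: Tuple[float, ...]
    peak_length_grid: Tuple[int, ...] = (DEFAULT_PEAK_LENGTH,)
    upper_asymptote_grid: Tuple[float, ...] = (DEFAULT_UPPER,)

    @property
    def levels(self) -> List[Tuple[float, float, int, float]]:
        return list(
            product(
                self.inflection_grid,
                self.iri_grid,
                self.peak_length_grid,
                self.upper_asymptote_grid,
            )
        )

    def __post_init__(self) -> None:
        n_levels = len(self.levels)
        if self.n_loci % n_levels:
            raise ValueError(
                f"group {self.group_id}: {self.n_loci} loci not divisible "
                f"across {n_levels} grid levels"
            )


@dataclass(frozen=True)
class NoiseModel:
    model: str = "poisson"  # poisson | none
    mean_background: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_background < 0:
            raise ValueError("mean background must be non-negative")
        if self.model not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.model!r}")


@dataclass(frozen=True)
class SimulationSpec:
    direction: str  # rise | fall | both
    groups: Tuple[SimGroup, ...]
    time_points: Tuple[float, ...] = tuple(float(t) for t in range(11))
    noise: NoiseModel = NoiseModel()

    def __post_init__(self) -> None:
        if len(self.time_points) < 2:
            raise ValueError("need at least 2 time points")
        if self.direction not in ("rise", "fall", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def subset_times(self, keep: Sequence[float]) -> "SimulationSpec":
        """Reduced-time-point designs are pure subsets of time_points."""
        keep = tuple(float(t) for t in keep)
        missing = set(keep) - set(self.time_points)
        if missing:
            raise ValueError(f"times {sorted(missing)} not in the design")
        return replace(self, time_points=keep)


def default_spec(
    direction: str = "rise",
    loci_per_level: int = 20,
    noise: NoiseModel = NoiseModel(),
) -> SimulationSpec:
    """The standard four-group benchmark design (see module docstring)."""
    groups = (
        SimGroup("2L.1", "2L", 6 * loci_per_level, (5.0,), DEFAULT_IRI_GRID),
        SimGroup("2L.2", "2L", 9 * loci_per_level, DEFAULT_INFLECTION_GRID, (-3.0,)),
        SimGroup(
            "2R", "2R", 5 * loci_per_level, (4.5,), (-1.5,),
            peak_length_grid=DEFAULT_PEAK_LENGTH_GRID,
        ),
        SimGroup(
            "3R", "3R", 5 * loci_per_level, (5.5,), (-1.5,),
            upper_asymptote_grid=DEFAULT_UPPER_GRID,
        ),
    )
    return SimulationSpec(direction=direction, groups=groups, noise=noise)


def _truth_rows(spec: SimulationSpec) -> pd.DataFrame:
    """Per-locus true parameters and peak coordinates on the toy genome.

    Rises have b < 0 and start at a zero lower plateau; falls mirror the
    same magnitudes with b > 0.  For 'both', every group is emitted once
    per direction with the direction suffixed to the group id.
    """
    directions = ("rise", "fall") if spec.direction == "both" else (spec.direction,)
    rows = []
    cursors: Dict[str, int] = {}
    for group in spec.groups:
        per_level = group.n_loci // len(group.levels)
        for direction in directions:
            gid = group.group_id if spec.direction != "both" else f"{group.group_id}.{direction}"
            for c, iri, length, upper in group.levels:
                for k in range(per_level):
                    chrom = group.chrom
                    start = cursors.get(chrom, LOCUS_GAP)
                    cursors[chrom] = start + length + LOCUS_GAP
                    b = iri if direction == "rise" else abs(iri)
                    # a is the upper plateau either way: rises (b<0) run from
                    # d=0 up to a; falls (b>0) run from a down to d=0
                    a, d = upper, 0.0
                    rows.append({
                        "locus_id": f"{gid}_c{c}_b{b}_L{length}_u{upper}_{k}",
                        "group_id": gid,
                        "direction": direction,
                        "chrom": chrom,
                        "start": start,
                        "end": start + length,
                        "a": a, "b": b, "c": float(c), "d": d, "f": 1.0,
                    })
    return pd.DataFrame(rows)


def simulate_true_coverage(spec: SimulationSpec) -> Tuple[CoverageMatrix, pd.DataFrame]:
    """Noise-free trajectories (loci x times) plus the truth table."""
    truth = _truth_rows(spec)
    times = np.asarray(spec.time_points, dtype=float)
    values = np.empty((len(truth), times.size))
    for i, row in truth.iterrows():
        p = SigmoidParams(row["a"], row["b"], row["c"], row["d"], row["f"])
        values[i] = sigmoid_eval(p, times)
    matrix = CoverageMatrix(
        values, times, list(truth["locus_id"]), stage="user_supplied"
    )
    return matrix, truth


def add_noise(
    matrix: CoverageMatrix,
    noise: NoiseModel,
    seed: Optional[int] = None,
) -> CoverageMatrix:
    """Add background noise; independent stream per time point.

    Poisson noise with the configured mean is drawn independently for
    each time point's column from streams spawned off ``seed`` (falling
    back to the model's own seed), so subsetting or reordering time
    points never couples their draws.
    """
    if noise.model == "none" or noise.mean_background == 0:
        return matrix.replace(matrix.values.copy(), stage=matrix.stage)
    seed = noise.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(matrix.time_labels.size)
    values = matrix.values.copy()
    for t_idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        values[:, t_idx] += rng.poisson(noise.mean_background, size=values.shape[0])
    return matrix.replace(values, stage=matrix.stage)


def simulate_dataset(
    spec: SimulationSpec, seed: Optional[int] = None
) -> Tuple[CoverageMatrix, pd.DataFrame]:
    """Convenience: true coverage plus configured noise in one call."""
    matrix, truth = simulate_true_coverage(spec)
    return add_noise(matrix, spec.noise, seed), truth


def genome_sizes_for(truth: pd.DataFrame, margin: int = 100_000) -> Dict[str, int]:
    """Toy-genome contig sizes covering all simulated peaks plus margin."""
    return {
        chrom: int(sub["end"].max()) + margin
        for chrom, sub in truth.groupby("chrom")
    }


def emit_fixture_files(
    spec: SimulationSpec,
    outdir: str,
    seed: Optional[int] = None,
    read_length: Optional[int] = None,
) -> Dict[str, object]:
    """Materialize the simulation as BED + per-time-point indexed BAMs.

    Each locus receives ``round(coverage)`` reads spanning its full
    interval at every time point, so the mean per-base depth matches the
    simulated value up to depth quantization (|error| <= 1 read depth).
    Returns the paths plus the truth table.
    """
    os.makedirs(outdir, exist_ok=True)
    matrix, truth = simulate_dataset(spec, seed)
    sizes = genome_sizes_for(truth)
    loci = [
        GenomicInterval(r.chrom, r.start, r.end, r.locus_id)
        for r in truth.itertuples()
    ]
    bed_path = os.path.join(outdir, "loci.bed")
    write_bed(loci, bed_path)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": sizes[c]} for c in sorted(sizes)],
    }
    ref_ids = {c: i for i, c in enumerate(sorted(sizes))}
    bam_dir = os.path.join(outdir, "bam")
    os.makedirs(bam_dir, exist_ok=True)
    bam_paths = []
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start))
    for t_idx, t in enumerate(matrix.time_labels):
        path = os.path.join(bam_dir, f"t{t_idx:02d}.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for i in order:
                iv = loci[i]
                n_reads = int(round(matrix.values[i, t_idx]))
                for r in range(n_reads):
                    seg = pysam.AlignedSegment()
                    seg.query_name = f"{iv.name}_r{r}"
                    seg.reference_id = ref_ids[iv.chrom]
                    seg.reference_start = iv.start
                    seg.cigartuples = [(0, len(iv))]
                    seg.query_sequence = "A" * len(iv)
                    seg.query_qualities = pysam.qualitystring_to_array("I" * len(iv))
                    seg.mapping_quality = 60
                    seg.flag = 0
                    bam.write(seg)
        pysam.index(path)
        bam_paths.append(path)
    return {
        "bed": bed_path,
        "truth": truth_path,
        "bams": bam_paths,
        "matrix": matrix,
        "truth_table": truth,
        "genome_sizes": sizes,
    }


def double_sigmoid_series(
    times: Sequence[float],
    rise: SigmoidParams,
    fall: SigmoidParams,
    split_time: float,
) -> np.ndarray:
    """Noise-free hill/valley trajectory: one sigmoid per side of the split."""
    t = np.asarray(times, dtype=float)
    return np.where(
        t <= split_time, sigmoid_eval(rise, t), sigmoid_eval(fall, t)
    )


_CONFUSION_CATEGORIES = ("rise", "fall", "hill", "valley", "undefined", "eliminated")


def evaluate_recovery(
    results: Sequence, truth: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Score fitted TTIs and categories against simulated truth.

    Per locus: ``deviation = 100 * |TTI_fit - c_true| / c_true`` using
    the TTI of the segment matching the true direction (rise loci score
    their TTI_rise, falls their TTI_fall).  Loci without a usable TTI
    (eliminated or flat) get NaN deviation but still appear in the
    confusion table, which crosses true direction with the final
    category (undefined rises/falls pooled as 'undefined').
    """
    by_id = {r.locus.name: r for r in results}
    missing = set(truth["locus_id"]) - set(by_id)
    if missing:
        raise ValueError(f"results missing {len(missing)} truth loci, e.g. {sorted(missing)[:3]}")
    rows = []
    for row in truth.itertuples():
        r = by_id[row.locus_id]
        tti = r.tti_rise if row.direction == "rise" else r.tti_fall
        dev = 100.0 * abs(tti - row.c) / row.c if tti is not None else np.nan
        final = r.final
        if final in ("undefined_rise", "undefined_fall"):
            final = "undefined"
        rows.append({
            "locus_id": row.locus_id,
            "group_id": row.group_id,
            "true_direction": row.direction,
            "c_true": row.c,
            "b_true": row.b,
            "peak_length": row.end - row.start,
            "upper_true": max(row.a, row.d),
            "tti_fit": np.nan if tti is None else tti,
            "percent_deviation": dev,
            "final": final,
        })
    per_locus = pd.DataFrame(rows)
    confusion = (
        per_locus.groupby(["true_direction", "final"]).size().unstack(fill_value=0)
        .reindex(columns=_CONFUSION_CATEGORIES, fill_value=0)
    )
    return per_locus, confusion
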