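"""Reading loci and alignments, coverage extraction, and result tables.

Loci come in as BED (0-based half-open); coverage comes from
coordinate-sorted, indexed BAM files, summarized as the MEAN per-base
read depth over each interval so that loci of different lengths are
comparable.  Reads contribute per aligned base (CIGAR-aware); secondary,
supplementary and unmapped records are excluded; strand is ignored.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TimeCourseExperiment",
    "CoverageMatrix",
    "read_bed",
    "write_bed",
    "locus_coverage",
    "build_coverage_matrix",
    "read_counts_table",
    "write_results_table",
]

STAGES = ("raw", "scaled", "input_subtracted", "replicate_mean", "user_supplied")


@dataclass(frozen=True)
class GenomicInterval:
    """A BED locus in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.name is None:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TimeCourseExperiment:
    """Time labels plus per-replicate (and per-input) ordered BAM paths."""

    time_labels: Sequence[float]
    replicate_sets: List[List[str]]
    loci: List[GenomicInterval]
    input_sets: List[List[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_labels, dtype=float)
        if t.size < 3:
            raise ValueError("need at least 3 time points to constrain a sigmoid")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time labels must be strictly increasing")
        for kind, sets in (("replicate", self.replicate_sets), ("input", self.input_sets)):
            for i, paths in enumerate(sets):
                if len(paths) != t.size:
                    raise ValueError(
                        f"{kind} set {i} has {len(paths)} files for {t.size} time points"
                    )


@dataclass
class CoverageMatrix:
    """Loci x time-points coverage with provenance ('stage')."""

    values: np.ndarray
    time_labels: np.ndarray
    locus_ids: List[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_labels = np.asarray(self.time_labels, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (loci x time points)")
        if self.values.shape != (len(self.locus_ids), self.time_labels.size):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.locus_ids)} loci x {self.time_labels.size} time points"
            )
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.locus_ids, columns=self.time_labels)

    def replace(self, values: np.ndarray, stage: str) -> "CoverageMatrix":
        return CoverageMatrix(values, self.time_labels, list(self.locus_ids), stage)


def read_bed(path: Union[str, os.PathLike]) -> List[GenomicInterval]:
    """Parse a BED file (>=3 columns) into intervals, preserving file order.

    ``track``/``browser`` lines, ``#`` comments and blank lines are
    skipped; a malformed line raises with its line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def _include_read(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def locus_coverage(
    alignment_file: Union[str, os.PathLike, pysam.AlignmentFile],
    interval: GenomicInterval,
) -> float:
    """Mean per-base read depth over [start, end) of a sorted, indexed BAM.

    A chromosome absent from the alignment header yields 0.0 with a
    logged warning (this usually signals an assembly mismatch).
    """
    owns = not isinstance(alignment_file, pysam.AlignmentFile)
    af = pysam.AlignmentFile(os.fspath(alignment_file)) if owns else alignment_file
    try:
        if interval.chrom not in af.references:
            logger.warning(
                "chromosome %s absent from %s header; coverage set to 0",
                interval.chrom,
                af.filename.decode() if isinstance(af.filename, bytes) else af.filename,
            )
            return 0.0
        acgt = af.count_coverage(
            interval.chrom,
            interval.start,
            interval.end,
            quality_threshold=0,
            read_callback=_include_read,
        )
        depth = np.sum(acgt, axis=0)
        return float(depth.sum() / len(interval))
    finally:
        if owns:
            af.close()


def build_coverage_matrix(
    experiment: TimeCourseExperiment,
    which: int = 0,
    kind: str = "replicate",
) -> CoverageMatrix:
    """Raw loci x time-points matrix for one replicate (or input) set."""
    if not experiment.loci:
        raise ValueError("no loci supplied")
    paths = (
        experiment.replicate_sets if kind == "replicate" else experiment.input_sets
    )[which]
    values = np.zeros((len(experiment.loci), len(paths)))
    for t_idx, path in enumerate(paths):
        with pysam.AlignmentFile(os.fspath(path)) as af:
            for i, locus in enumerate(experiment.loci):
                try:
                    values[i, t_idx] = locus_coverage(af, locus)
                except Exception as exc:
                    raise RuntimeError(
                        f"coverage failed at locus {locus.name}, "
                        f"time point {experiment.time_labels[t_idx]} ({path})"
                    ) from exc
    return CoverageMatrix(
        values, experiment.time_labels, [iv.name for iv in experiment.loci], stage="raw"
    )


def read_counts_table(path: Union[str, os.PathLike]) -> CoverageMatrix:
    """Load a pre-normalized counts table (locus id column + numeric time header).

    Matrices read this way carry ``stage='user_supplied'`` and bypass all
    downstream normalization.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(
            f"{path}: header must contain numeric time labels, got {list(df.columns)}"
        ) from exc
    values = df.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError(f"{path}: ragged or non-numeric rows detected")
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: negative count at locus {df.index[i]!r}, time {times[j]}"
        )
    return CoverageMatrix(values, times, [str(i) for i in df.index], stage="user_supplied")


RESULT_COLUMNS = [
    "locus_id", "chrom", "start", "end", "predicted", "final", "segment",
    "a", "b_iri", "c", "d", "f",
    "se_a", "se_b", "se_c", "se_d", "se_f",
    "tti", "rss",
    "linear_slope", "linear_intercept", "linear_rss",
    "eliminated",
]


def write_results_table(results, path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Write the per-locus modeling report (one row per fitted segment).

    Single-sigmoid categories emit one row; hills and valleys emit two
    (their rise and fall segments) sharing the locus id.  Eliminated loci
    keep their rows, flagged, so no locus disappears from the audit trail.
    Parameter standard errors accompany every fitted curve.
    """
    rows = []
    for r in results:
        iv = r.locus
        base = {
            "locus_id": iv.name,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "predicted": r.predicted,
            "final": r.final,
            "linear_slope": r.linear.slope if r.linear else np.nan,
            "linear_intercept": r.linear.intercept if r.linear else np.nan,
            "linear_rss": r.linear.rss if r.linear else np.nan,
            "eliminated": r.final == "eliminated",
        }
        if not r.fits:
            rows.append({**base, "segment": "none", "tti": np.nan, "rss": np.nan})
            continue
        for fit in r.fits:
            seg = "rise" if fit.direction == "increasing" else "fall"
            p, se = fit.params, fit.std_errors
            rows.append({
                **base,
                "segment": seg,
                "a": p.a, "b_iri": p.b, "c": p.c, "d": p.d, "f": p.f,
                "se_a": se[0], "se_b": se[1], "se_c": se[2],
                "se_d": se[3], "se_f": se[4],
                "tti": fit.tti, "rss": fit.rss,
            })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
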