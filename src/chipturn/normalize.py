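"""Coverage normalization: depth scaling, input subtraction, replicates.

Sequencing-depth differences between time points are corrected by
dividing each time point's coverage by the maximum coverage observed at
non-peak (background) loci in that sample — background captures true
sequencing depth uncontaminated by signal.  Input-control coverage,
scaled by its genome-wide maximum, is subtracted from experiment
coverage with a floor at zero.  Replicates are averaged after
normalization.  Matrices read as pre-normalized counts bypass all of
this.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pysam

from .io_coverage import CoverageMatrix, GenomicInterval, locus_coverage

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleVector",
    "background_scale",
    "make_background_intervals",
    "genome_max_coverage",
    "normalize_matrix",
    "subtract_input",
    "average_replicates",
    "read_scale_file",
]

DEFAULT_N_BACKGROUND = 10_000


class _opened:
    """Open an alignment path once for repeated coverage queries."""

    def __init__(self, alignment_file):
        self._given = alignment_file
        self._owns = not isinstance(alignment_file, pysam.AlignmentFile)

    def __enter__(self):
        self._af = (
            pysam.AlignmentFile(os.fspath(self._given)) if self._owns else self._given
        )
        return self._af

    def __exit__(self, *exc):
        if self._owns:
            self._af.close()
        return False


@dataclass
class ScaleVector:
    """Per-time-point positive scale factors with their provenance."""

    factors: np.ndarray
    source: str  # background_max | genome_max | user_defined

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("scale factors must be positive")


def background_scale(
    alignment_file,
    peaks: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
) -> float:
    """Max coverage over background (non-peak) intervals in one sample.

    An all-zero background returns 1.0 with a warning so the column
    passes through unrescaled.
    """
    if not background:
        raise ValueError("background interval set is empty")
    peak_spans: Dict[str, List] = {}
    for p in peaks:
        peak_spans.setdefault(p.chrom, []).append((p.start, p.end))
    for b in background:
        for s, e in peak_spans.get(b.chrom, ()):
            if b.start < e and s < b.end:
                raise ValueError(f"background interval {b.name} overlaps peak {s}-{e}")
    with _opened(alignment_file) as af:
        mx = max(locus_coverage(af, iv) for iv in background)
    if mx == 0:
        logger.warning("all background intervals have zero coverage; scale set to 1")
        return 1.0
    return mx


def make_background_intervals(
    genome_sizes: Dict[str, int],
    peaks: Sequence[GenomicInterval],
    n: int = DEFAULT_N_BACKGROUND,
    length: Optional[int] = None,
    seed: int = 0,
) -> List[GenomicInterval]:
    """Sample n intervals uniformly from the genome complement of peaks.

    ``length`` defaults to the median peak length.  Reproducible under
    ``seed``; intervals may overlap one another but never a peak.
    """
    if length is None:
        if not peaks:
            raise ValueError("need peaks to derive a default background length")
        length = int(np.median([len(p) for p in peaks]))
    # complement gaps per chromosome
    gaps: List[tuple] = []  # (chrom, gap_start, n_positions)
    for chrom, size in sorted(genome_sizes.items()):
        spans = sorted(
            (p.start, p.end) for p in peaks if p.chrom == chrom
        )
        merged: List[List[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        prev = 0
        for s, e in merged + [[size, size]]:
            npos = (s - prev) - length + 1
            if npos > 0:
                gaps.append((chrom, prev, npos))
            prev = e
    total = sum(g[2] for g in gaps)
    if total < n:
        raise ValueError(
            f"peak complement hosts only {total} candidate starts for {n} intervals"
        )
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.integers(0, total, size=n))
    out: List[GenomicInterval] = []
    gi, base = 0, 0
    for k, off in enumerate(offsets):
        while off >= base + gaps[gi][2]:
            base += gaps[gi][2]
            gi += 1
        chrom, gstart, _ = gaps[gi]
        start = gstart + int(off - base)
        out.append(GenomicInterval(chrom, start, start + length, f"bg_{k}"))
    return out


def genome_max_coverage(
    alignment_file,
    intervals: Sequence[GenomicInterval],
    exhaustive: bool = False,
    window: int = 10_000,
) -> float:
    """Approximate genome-wide maximum coverage for input scaling.

    By default the maximum is taken over the supplied intervals
    (sampled background plus the peak loci); ``exhaustive=True`` scans
    every contig in fixed windows instead.
    """
    if exhaustive:
        with _opened(alignment_file) as af:
            mx = 0.0
            for chrom, size in zip(af.references, af.lengths):
                for start in range(0, size, window):
                    iv = GenomicInterval(chrom, start, min(start + window, size))
                    mx = max(mx, locus_coverage(af, iv))
        return mx if mx > 0 else 1.0
    if not intervals:
        raise ValueError("no intervals supplied for genome maximum")
    with _opened(alignment_file) as af:
        mx = max(locus_coverage(af, iv) for iv in intervals)
    return mx if mx > 0 else 1.0


def normalize_matrix(matrix: CoverageMatrix, scales: ScaleVector) -> CoverageMatrix:
    """Divide each time point's column by its scale factor (stage 'scaled')."""
    if scales.factors.size != matrix.time_labels.size:
        raise ValueError(
            f"{scales.factors.size} scale factors for "
            f"{matrix.time_labels.size} time points"
        )
    return matrix.replace(matrix.values / scales.factors[np.newaxis, :], stage="scaled")


def subtract_input(exp: CoverageMatrix, input_: CoverageMatrix) -> CoverageMatrix:
    """Elementwise exp - input, floored at zero (stage 'input_subtracted')."""
    if exp.values.shape != input_.values.shape:
        raise ValueError(
            f"shape mismatch: experiment {exp.values.shape} vs input {input_.values.shape}"
        )
    return exp.replace(np.maximum(exp.values - input_.values, 0.0), stage="input_subtracted")


def average_replicates(matrices: Sequence[CoverageMatrix]) -> CoverageMatrix:
    """Elementwise mean across replicates (stage 'replicate_mean')."""
    if not matrices:
        raise ValueError("no replicate matrices supplied")
    shape = matrices[0].values.shape
    for m in matrices[1:]:
        if m.values.shape != shape:
            raise ValueError("replicate matrices have heterogeneous shapes")
    mean = np.mean([m.values for m in matrices], axis=0)
    return matrices[0].replace(mean, stage="replicate_mean")


def read_scale_file(path: Union[str, os.PathLike], time_labels: Sequence[float]) -> ScaleVector:
    """Two-column TSV (time label -> positive factor), ordered by time_labels."""
    mapping: Dict[float, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            mapping[float(parts[0])] = float(parts[1])
    try:
        factors = [mapping[float(t)] for t in time_labels]
    except KeyError as exc:
        raise ValueError(f"{path}: no scale value for time point {exc}") from exc
    return ScaleVector(np.array(factors), source="user_defined")
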