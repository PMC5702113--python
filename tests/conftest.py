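"""Shared fixtures: tiny in-memory BAM builder and pileup oracle."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pysam
import pytest

from chipturn.io_coverage import GenomicInterval

Read = Tuple[str, int, int]  # chrom, 0-based start, aligned length


def brute_force_mean_depth(reads: Sequence[Read], interval: GenomicInterval) -> float:
    """Independent per-base pileup: the oracle for locus_coverage."""
    depth = np.zeros(len(interval), dtype=int)
    for chrom, start, length in reads:
        if chrom != interval.chrom:
            continue
        lo = max(start, interval.start)
        hi = min(start + length, interval.end)
        if hi > lo:
            depth[lo - interval.start : hi - interval.start] += 1
    return float(depth.sum() / len(interval))


@pytest.fixture
def make_bam(tmp_path):
    """Write a sorted, indexed BAM from (chrom, start, length) read tuples."""

    counter = {"n": 0}

    def _make(reads: Sequence[Read], chrom_sizes: Dict[str, int]) -> str:
        counter["n"] += 1
        path = str(tmp_path / f"reads_{counter['n']}.bam")
        chroms = sorted(chrom_sizes)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
        }
        ids = {c: i for i, c in enumerate(chroms)}
        ordered = sorted(reads, key=lambda r: (ids[r[0]], r[1]))
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for k, (chrom, start, length) in enumerate(ordered):
                seg = pysam.AlignedSegment()
                seg.query_name = f"read{k}"
                seg.reference_id = ids[chrom]
                seg.reference_start = start
                seg.cigartuples = [(0, length)]
                seg.query_sequence = "A" * length
                seg.query_qualities = pysam.qualitystring_to_array("I" * length)
                seg.mapping_quality = 60
                seg.flag = 0
                bam.write(seg)
        pysam.index(path)
        return path

    return _make


@pytest.fixture
def times11() -> np.ndarray:
    return np.arange(11, dtype=float)
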