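"""Motif-read clustering and depth-based confidence partitioning.

Short motif-bearing reads mapped back to enriched loci stack into clusters
of overlapping reads.  The frequency distribution of cluster depths (the
maximum number of mutually overlapping reads, the "height" of the stack)
is typically bimodal: a power law at low depths from spurious matches and
an excess of deep clusters from genuine binding sites.  A depth threshold
(10 by default) partitions clusters into low- and high-confidence groups;
depths strictly above the threshold are high-confidence.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadCluster",
    "DepthSpectrum",
    "cluster_reads",
    "depth_spectrum",
    "partition_confidence",
    "confidence_counts",
]

HIGH = "high"
LOW = "low"


@dataclass
class ReadCluster:
    """A chain of overlapping reads with its maximum coverage depth."""

    chrom: str
    start: int
    end: int
    depth: int
    confidence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster end must be > start")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class DepthSpectrum:
    """Depth histogram with a power-law fit over low depths.

    ``exponent`` is the negative slope of an unweighted least-squares line
    through (log10 depth, log10 count) over depths 1..threshold with
    nonzero counts; NaN when fewer than two such depths exist.
    """

    counts: dict[int, int]
    threshold: int = 10
    exponent: float = math.nan
    intercept: float = math.nan
    n_fit_points: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _overlaps_any(start: int, end: int, loci: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in loci)


def cluster_reads(
    reads: Iterable[tuple[str, int, int]],
    loci: Iterable[tuple[str, int, int]] | None = None,
) -> list[ReadCluster]:
    """Chain reads overlapping by >= 1 bp into clusters.

    ``reads`` are (chrom, start, end) intervals, 0-based half-open.  Depth
    is the maximum simultaneous coverage within the cluster, computed by
    an event sweep.  When ``loci`` is given, only clusters intersecting a
    locus are kept; otherwise clustering is genome-wide.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in reads:
        if end <= start:
            raise ValueError("read end must be > start")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    loci_by_chrom: dict[str, list[tuple[int, int]]] | None = None
    if loci is not None:
        loci_by_chrom = {}
        for chrom, start, end in loci:
            loci_by_chrom.setdefault(chrom, []).append((int(start), int(end)))

    out: list[ReadCluster] = []
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        i = 0
        while i < len(ivals):
            c_start, c_end = ivals[i]
            members = [ivals[i]]
            j = i + 1
            while j < len(ivals) and ivals[j][0] < c_end:
                c_end = max(c_end, ivals[j][1])
                members.append(ivals[j])
                j += 1
            events = sorted(
                [(s, 1) for s, _ in members] + [(e, -1) for _, e in members]
            )
            depth = best = 0
            for _, delta in events:
                depth += delta
                best = max(best, depth)
            if loci_by_chrom is None or _overlaps_any(
                c_start, c_end, loci_by_chrom.get(chrom, [])
            ):
                out.append(ReadCluster(chrom, c_start, c_end, best))
            i = j
    return out


def depth_spectrum(clusters: Sequence[ReadCluster], threshold: int = 10) -> DepthSpectrum:
    """Exact depth histogram plus a log-log power-law fit at low depths."""
    if not clusters:
        raise ValueError("no clusters")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = dict(sorted(Counter(c.depth for c in clusters).items()))
    fit_d = np.array(
        [d for d in counts if 1 <= d <= threshold and counts[d] > 0], dtype=float
    )
    spec = DepthSpectrum(counts=counts, threshold=threshold)
    if fit_d.size >= 2:
        x = np.log10(fit_d)
        y = np.log10(np.array([counts[int(d)] for d in fit_d], dtype=float))
        slope, intercept = np.polyfit(x, y, 1)
        spec.exponent = float(-slope)
        spec.intercept = float(intercept)
        spec.n_fit_points = int(fit_d.size)
    return spec


def partition_confidence(
    clusters: Iterable[ReadCluster], threshold: int = 10
) -> list[ReadCluster]:
    """Label clusters: depth > threshold is high-confidence, else low.

    Depth exactly at the threshold is low-confidence (the deep-cluster
    excess sits strictly above it).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = []
    for c in clusters:
        out.append(
            ReadCluster(c.chrom, c.start, c.end, c.depth,
                        HIGH if c.depth > threshold else LOW)
        )
    return out


def confidence_counts(clusters: Sequence[ReadCluster]) -> dict[str, int]:
    """Counts of high- and low-confidence clusters (must be labelled)."""
    counts = {HIGH: 0, LOW: 0}
    for c in clusters:
        if c.confidence not in counts:
            raise ValueError("clusters must be labelled by partition_confidence")
        counts[c.confidence] += 1
    return counts
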