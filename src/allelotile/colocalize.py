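"""Pairing of two chromatin marks' peaks and genomic-context annotation.

Peaks from two marks (e.g. a transcription factor and a repressive histone
modification) are paired when their midpoints lie within a distance cutoff
(strictly less than 500 bp by default).  Paired loci are then classified
against a gene annotation as promoter, intragenic or intergenic, with
intergenic loci further flagged distal when the nearest gene 5' end is
more than 10 kb away.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .peaks import Peak

__all__ = [
    "GeneModel",
    "ColocalizedLocus",
    "colocalize",
    "classify_locus",
    "annotate_loci",
    "summarize_contexts",
    "overlap_with_gene_list",
]

PROMOTER = "promoter"
INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gene start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """5'-end coordinate: start on '+', end on '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass
class ColocalizedLocus:
    """A paired two-mark site."""

    chrom: str
    peak_a: Peak
    peak_b: Peak
    distance: float
    context: str | None = None
    tss_distance: float = math.nan
    distal: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.peak_a.midpoint + self.peak_b.midpoint)


def _midpoints(peaks: Sequence[Peak]) -> np.ndarray:
    return np.array([p.midpoint for p in peaks], dtype=float)


def colocalize(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    max_distance: float = 500.0,
    mode: str = "midpoint",
) -> list[ColocalizedLocus]:
    """Pair each mark-A peak with the nearest same-chromosome mark-B peak.

    Matching is greedy nearest-first and one-to-one: candidate pairs with
    distance strictly below ``max_distance`` are accepted in order of
    increasing distance, each peak joining at most one pair.  Unpaired
    peaks are dropped.  ``mode='midpoint'`` measures center-to-center;
    ``mode='edge'`` measures the gap between intervals (0 if overlapping).
    """
    if mode not in ("midpoint", "edge"):
        raise ValueError("mode must be 'midpoint' or 'edge'")
    out: list[ColocalizedLocus] = []
    chroms = sorted({p.chrom for p in peaks_a} & {p.chrom for p in peaks_b})
    for chrom in chroms:
        a_pk = [p for p in peaks_a if p.chrom == chrom]
        b_pk = [p for p in peaks_b if p.chrom == chrom]
        if mode == "midpoint":
            dist = np.abs(_midpoints(a_pk)[:, None] - _midpoints(b_pk)[None, :])
        else:
            a_s = np.array([p.start for p in a_pk])[:, None]
            a_e = np.array([p.end for p in a_pk])[:, None]
            b_s = np.array([p.start for p in b_pk])[None, :]
            b_e = np.array([p.end for p in b_pk])[None, :]
            dist = np.maximum(0, np.maximum(a_s - b_e, b_s - a_e)).astype(float)
        ia, ib = np.nonzero(dist < max_distance)
        order = np.lexsort((ib, ia, dist[ia, ib]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for k in order:
            i, j = int(ia[k]), int(ib[k])
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            out.append(
                ColocalizedLocus(chrom, a_pk[i], b_pk[j], float(dist[i, j]))
            )
    return sorted(out, key=lambda l: (l.chrom, l.peak_a.start))


def classify_locus(
    chrom: str,
    midpoint: float,
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
    distal_cut: int = 10000,
) -> tuple[str, float, bool]:
    """Classify a genomic point against a gene annotation.

    Returns ``(label, distance_to_nearest_5'_end, distal_flag)``.
    Precedence is promoter > intragenic > intergenic.  The promoter window
    extends ``promoter_up`` bp upstream to ``promoter_down`` bp downstream
    of a gene's 5' end, strand-appropriately.  With no genes on the
    chromosome everything is intergenic at infinite distance, flagged
    distal.
    """
    here = [g for g in genes if g.chrom == chrom]
    if not here:
        return INTERGENIC, math.inf, True
    tss = np.array([g.tss for g in here], dtype=float)
    tss_dist = float(np.min(np.abs(tss - midpoint)))
    for g in here:
        if g.strand == "+":
            lo, hi = g.tss - promoter_up, g.tss + promoter_down
        else:
            lo, hi = g.tss - promoter_down, g.tss + promoter_up
        if lo <= midpoint <= hi:
            return PROMOTER, tss_dist, False
    for g in here:
        if g.start <= midpoint < g.end:
            return INTRAGENIC, tss_dist, False
    return INTERGENIC, tss_dist, tss_dist > distal_cut


def annotate_loci(
    loci: Iterable[ColocalizedLocus],
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
    distal_cut: int = 10000,
) -> list[ColocalizedLocus]:
    """Classify every colocalized locus in place and return the list."""
    loci = list(loci)
    for loc in loci:
        label, dist, distal = classify_locus(
            loc.chrom, loc.midpoint, genes, promoter_up, promoter_down, distal_cut
        )
        loc.context = label
        loc.tss_distance = dist
        loc.distal = distal
    return loci


def summarize_contexts(loci: Sequence[ColocalizedLocus]) -> dict:
    """Counts and fractions per context label; fractions sum to 1."""
    loci = list(loci)
    if not loci:
        raise ValueError("no loci to summarize")
    counts = {PROMOTER: 0, INTRAGENIC: 0, INTERGENIC: 0}
    distal = 0
    for loc in loci:
        if loc.context not in counts:
            raise ValueError("loci must be annotated before summarizing")
        counts[loc.context] += 1
        if loc.context == INTERGENIC and loc.distal:
            distal += 1
    total = len(loci)
    return {
        "total": total,
        "counts": counts,
        "fractions": {k: v / total for k, v in counts.items()},
        "intergenic_distal": distal,
    }


def overlap_with_gene_list(
    loci: Sequence[ColocalizedLocus],
    gene_list: Sequence[GeneModel | str],
    annotation: Sequence[GeneModel] | None = None,
    window: int = 0,
) -> tuple[int, list[str]]:
    """Count loci whose midpoint falls within ``window`` bp of a listed
    gene's span; returns the count and the names of genes hit.

    Entries given as bare names are resolved against ``annotation``;
    unresolvable names are skipped with a warning.
    """
    resolved: list[GeneModel] = []
    by_name = {g.name: g for g in (annotation or [])}
    for item in gene_list:
        if isinstance(item, GeneModel):
            resolved.append(item)
        elif item in by_name:
            resolved.append(by_name[item])
        else:
            warnings.warn(f"gene name {item!r} not found in annotation; skipped")
    count = 0
    names: set[str] = set()
    for loc in loci:
        for g in resolved:
            if g.chrom == loc.chrom and g.start - window <= loc.midpoint < g.end + window:
                count += 1
                names.add(g.name)
                break
    return count, sorted(names)
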