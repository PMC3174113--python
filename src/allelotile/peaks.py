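"""Windowed tiling-array peak detection with permutation false-positive rates.

A probe on a tiling array seeds a candidate binding site when enough of its
neighbours within a fixed flanking window exceed a chromosome-specific log2
IP:input cutoff.  The cutoff is a percentage *P* of (mean + 6 x SD) of all
probe ratios on the chromosome.  Sweeping *P* from stringent to permissive
and scrambling probe ratios to build an empirical null yields, for each
peak, the false-positive rate (FPR) at the cutoff where it is first
detected: FPR = mean peak count over randomized tracks / observed peak
count.  High-confidence sites are peaks present in every biological
replicate with FPR below a threshold (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProbeTrack",
    "Peak",
    "CutoffSchedule",
    "PermutationPlan",
    "compute_cutoff",
    "detect_peaks",
    "permute_track",
    "estimate_fpr",
    "call_peaks",
    "consensus_peaks",
]

DEFAULT_MIN_PROBES = 4
DEFAULT_FLANK = 250


@dataclass
class ProbeTrack:
    """One chromosome's ordered probes with log2 IP:input ratios.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    starts : array of int
        Probe start coordinates (bp, 0-based), strictly increasing.
    ratios : array of float
        log2 IP:input ratio per probe; must be finite.
    probe_length : int
        Probe length in bp (50-mer oligos by default).
    """

    chrom: str
    starts: np.ndarray
    ratios: np.ndarray
    probe_length: int = 50

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if self.starts.ndim != 1 or self.starts.size == 0:
            raise ValueError("track needs at least one probe")
        if self.starts.size != self.ratios.size:
            raise ValueError("starts and ratios differ in length")
        if self.starts.size > 1 and not np.all(np.diff(self.starts) > 0):
            raise ValueError("probe starts must be strictly increasing")
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("ratios must be finite")
        if self.probe_length <= 0:
            raise ValueError("probe_length must be positive")

    @property
    def n_probes(self) -> int:
        return int(self.starts.size)


@dataclass
class Peak:
    """A called enriched interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    height: float
    cutoff_percent: float | None = None
    fpr: float = math.nan
    support: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must be < end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CutoffSchedule:
    """Descending sweep of cutoff percentages applied to (mean + 6 x SD)."""

    percentages: tuple[float, ...] = tuple(range(100, 15, -5))

    def __post_init__(self) -> None:
        p = np.asarray(self.percentages, dtype=float)
        if p.size == 0:
            raise ValueError("schedule is empty")
        if np.any(p <= 0) or np.any(p > 100):
            raise ValueError("percentages must lie in (0, 100]")
        if p.size > 1 and not np.all(np.diff(p) < 0):
            raise ValueError("percentages must be strictly descending")

    @classmethod
    def from_string(cls, text: str) -> "CutoffSchedule":
        """Parse ``"high:low:step"``, e.g. ``"100:20:5"``."""
        hi, lo, step = (float(x) for x in text.split(":"))
        if step <= 0 or hi < lo:
            raise ValueError("schedule must be high:low:step with step > 0")
        vals = np.arange(hi, lo - 1e-9, -step)
        return cls(tuple(float(v) for v in vals))


@dataclass(frozen=True)
class PermutationPlan:
    """Number of ratio-scrambled null data sets per chromosome, and a seed."""

    n_permutations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


def compute_cutoff(track: ProbeTrack, percent: float) -> float:
    """Chromosome-level threshold: (percent/100) x (mean + 6 x sample SD).

    The base value is computed over all the chromosome's probe ratios; the
    sample standard deviation uses the n - 1 denominator.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    if track.n_probes < 2:
        raise ValueError("insufficient probes to compute a cutoff")
    base = float(np.mean(track.ratios)) + 6.0 * float(np.std(track.ratios, ddof=1))
    return percent / 100.0 * base


def _detect(
    chrom: str,
    starts: np.ndarray,
    ratios: np.ndarray,
    probe_length: int,
    threshold: float,
    min_probes: int,
    flank: int,
) -> list[Peak]:
    """Core detector on bare arrays (reused on permuted ratio vectors)."""
    above = ratios > threshold
    if int(above.sum()) < min_probes:
        return []
    csum = np.concatenate(([0], np.cumsum(above)))
    # closed window [start - flank, start + flank], membership by probe start
    lo = np.searchsorted(starts, starts - flank, side="left")
    hi = np.searchsorted(starts, starts + flank, side="right")
    seed_mask = (csum[hi] - csum[lo]) >= min_probes
    seed_idx = np.flatnonzero(seed_mask)
    if seed_idx.size == 0:
        return []

    peaks: list[Peak] = []
    win_start = starts[seed_idx] - flank
    win_end = starts[seed_idx] + flank
    # merge overlapping/adjacent seed windows
    cur_a, cur_b = int(win_start[0]), int(win_end[0])
    merged: list[tuple[int, int]] = []
    for a, b in zip(win_start[1:], win_end[1:]):
        if a <= cur_b:
            cur_b = max(cur_b, int(b))
        else:
            merged.append((cur_a, cur_b))
            cur_a, cur_b = int(a), int(b)
    merged.append((cur_a, cur_b))

    for a, b in merged:
        i = np.searchsorted(starts, a, side="left")
        j = np.searchsorted(starts, b, side="right")
        sel = np.flatnonzero(above[i:j]) + i
        # a merged window contains >= min_probes above-threshold probes
        p_start = int(starts[sel[0]])
        p_end = int(starts[sel[-1]]) + probe_length
        height = float(ratios[sel].max())
        peaks.append(Peak(chrom, p_start, p_end, height))
    return peaks


def detect_peaks(
    track: ProbeTrack,
    threshold: float,
    min_probes: int = DEFAULT_MIN_PROBES,
    flank: int = DEFAULT_FLANK,
) -> list[Peak]:
    """Call peaks at a single threshold.

    A probe seeds a peak when at least ``min_probes`` probes (itself
    included) whose starts fall in the closed window
    ``[start - flank, start + flank]`` have ratio strictly above
    ``threshold``.  Overlapping or adjacent seed windows merge into one
    peak spanning their above-threshold probes; peak height is the maximum
    ratio inside.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_probes < 1 or flank < 0:
        raise ValueError("min_probes >= 1 and flank >= 0 required")
    return _detect(
        track.chrom, track.starts, track.ratios, track.probe_length,
        threshold, min_probes, flank,
    )


def permute_track(track: ProbeTrack, seed: int | np.random.Generator) -> ProbeTrack:
    """Scramble ratios among probes; coordinates are untouched.

    The ratio multiset is preserved exactly, so peak counts on the
    permuted track estimate the null expectation at any cutoff.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return ProbeTrack(
        track.chrom,
        track.starts.copy(),
        rng.permutation(track.ratios),
        track.probe_length,
    )


def estimate_fpr(
    track: ProbeTrack,
    percent: float,
    plan: PermutationPlan,
    min_probes: int = DEFAULT_MIN_PROBES,
    flank: int = DEFAULT_FLANK,
) -> float:
    """FPR at cutoff percentage ``percent``.

    Ratio of the mean peak count over the plan's randomized tracks to the
    observed peak count at the same cutoff.  Zero observed peaks gives NaN
    (undefined), never a division error.  Values above 1 are reported as
    computed; the quantity is a count ratio, not a probability.
    """
    threshold = compute_cutoff(track, percent)
    observed = len(detect_peaks(track, threshold, min_probes, flank))
    if observed == 0:
        return math.nan
    rng = np.random.default_rng(plan.seed)
    counts = [
        len(
            _detect(
                track.chrom, track.starts, rng.permutation(track.ratios),
                track.probe_length, threshold, min_probes, flank,
            )
        )
        for _ in range(plan.n_permutations)
    ]
    return float(np.mean(counts)) / observed


def call_peaks(
    track: ProbeTrack,
    schedule: CutoffSchedule | None = None,
    plan: PermutationPlan | None = None,
    min_probes: int = DEFAULT_MIN_PROBES,
    flank: int = DEFAULT_FLANK,
) -> list[Peak]:
    """Sweep cutoffs from stringent to permissive and assign each peak the
    FPR of the cutoff at which it is first detected.

    Lowering the cutoff only adds and widens peaks, so the final peak set
    is the one called at the least stringent schedule entry; each final
    peak inherits the FPR of the most stringent percentage at which any
    overlapping peak was already present.  One set of permuted ratio
    vectors (from ``plan``) is reused across all cutoffs, matching a
    per-chromosome randomization design.
    """
    schedule = schedule or CutoffSchedule()
    plan = plan or PermutationPlan()
    rng = np.random.default_rng(plan.seed)
    perms = [rng.permutation(track.ratios) for _ in range(plan.n_permutations)]

    percents = schedule.percentages  # descending
    final = detect_peaks(track, compute_cutoff(track, percents[-1]), min_probes, flank)
    if not final:
        return []
    f_start = np.array([p.start for p in final])
    f_end = np.array([p.end for p in final])
    assigned = np.zeros(len(final), dtype=bool)

    for pct in percents:
        threshold = compute_cutoff(track, pct)
        level = detect_peaks(track, threshold, min_probes, flank)
        if not level:
            continue
        null_counts = [
            len(
                _detect(
                    track.chrom, track.starts, r, track.probe_length,
                    threshold, min_probes, flank,
                )
            )
            for r in perms
        ]
        fpr = float(np.mean(null_counts)) / len(level)
        for pk in level:
            # peaks only widen down the sweep: pk lies inside one final peak
            hits = np.flatnonzero((pk.start < f_end) & (f_start < pk.end))
            for k in hits:
                if not assigned[k]:
                    final[k].cutoff_percent = pct
                    final[k].fpr = fpr
                    assigned[k] = True
        if assigned.all():
            break
    return final


def consensus_peaks(
    peak_sets: Sequence[Iterable[Peak]],
    required_support: int | None = None,
    max_fpr: float = 0.05,
) -> list[Peak]:
    """Replicate-consensus filter.

    Keeps genomic regions where peaks from at least ``required_support``
    distinct replicates (default: all supplied) mutually overlap by >= 1 bp
    and every contributing peak has FPR strictly below ``max_fpr``.  The
    consensus interval is the intersection of the contributors; height is
    their mean height; the consensus FPR is the worst contributor FPR.
    """
    if required_support is None:
        required_support = len(peak_sets)
    if required_support < 1:
        raise ValueError("required_support must be >= 1")
    if len(peak_sets) < required_support:
        raise ValueError(
            f"need >= {required_support} replicate peak sets, got {len(peak_sets)}"
        )

    kept: list[list[Peak]] = [
        [p for p in peaks if math.isfinite(p.fpr) and p.fpr < max_fpr]
        for peaks in peak_sets
    ]
    chroms = sorted({p.chrom for peaks in kept for p in peaks})
    out: list[Peak] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []  # (position, +1/-1)
        per_chrom: list[Peak] = []
        for peaks in kept:
            # peaks within one replicate are disjoint, so a plain coverage
            # count equals the distinct-replicate count
            for p in peaks:
                if p.chrom == chrom:
                    events.append((p.start, +1))
                    events.append((p.end, -1))
                    per_chrom.append(p)
        events.sort()
        depth = 0
        region_start: int | None = None
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < required_support <= depth:
                region_start = pos
            elif prev >= required_support > depth and region_start is not None:
                if pos > region_start:
                    contributors = [
                        p for p in per_chrom if p.start < pos and region_start < p.end
                    ]
                    reps = {
                        i
                        for i, peaks in enumerate(kept)
                        for p in peaks
                        if p.chrom == chrom and p.start < pos and region_start < p.end
                    }
                    out.append(
                        Peak(
                            chrom,
                            region_start,
                            pos,
                            height=float(np.mean([p.height for p in contributors])),
                            fpr=max(p.fpr for p in contributors),
                            support=len(reps),
                        )
                    )
                region_start = None
    for p in out:
        assert p.fpr < max_fpr  # filter postcondition
    return sorted(out, key=lambda p: (p.chrom, p.start))
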