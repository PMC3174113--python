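"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: per-chromosome
tiling-array probe grids with Gaussian background log2 ratios and spiked
enriched sites shared across biological replicates; paired two-mark
experiments with a controllable colocalized fraction; gene annotations;
motif-read clusters whose depth frequencies follow a truncated power law
plus a deep-cluster excess; bisulfite read-call matrices with per-CpG
methylation probabilities and a conversion-failure rate; and two-channel
allelic mixture assays at known ratios.  Each generator draws from a
single seeded numpy Generator, so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allelic import NONCPG_PREFIX
from .colocalize import GeneModel
from .motifs import ReadCluster
from .peaks import ProbeTrack

__all__ = [
    "TilingSimConfig",
    "GroundTruth",
    "simulate_tiling_experiment",
    "simulate_dual_mark",
    "simulate_gene_annotation",
    "simulate_motif_clusters",
    "clusters_to_reads",
    "simulate_bisulfite_reads",
    "simulate_allelic_mixtures",
    "PAPER_MIXTURE_LABELS",
    "DEFAULT_MIXTURE_FRACTIONS",
]

# Published two-channel dilution series labels (allele B : allele A) and the
# allele-A fractions they imply.  The odd "40:20" label is taken literally,
# giving fraction 20/60 = 1/3.
PAPER_MIXTURE_LABELS = ("100:0", "80:20", "60:40", "50:50", "40:20", "20:80", "0:100")
DEFAULT_MIXTURE_FRACTIONS = (0.0, 0.2, 0.4, 0.5, 1.0 / 3.0, 0.8, 1.0)


@dataclass(frozen=True)
class TilingSimConfig:
    """Configuration for a spike-in tiling-array experiment.

    Defaults emulate a 100-bp probe grid of 50-mers hybridized in three
    biological replicates, with N(0, 0.5) background log2 ratios and ten
    spiked sites of +3.0 log2 units (six background SDs) spanning five
    probes each.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    spacing: int = 100
    probe_length: int = 50
    n_replicates: int = 3
    background_mean: float = 0.0
    background_sd: float = 0.5
    n_sites: int = 10
    site_width_probes: int = 5
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.background_sd <= 0:
            raise ValueError("background SD must be > 0")
        if self.site_width_probes < 1:
            raise ValueError("site width must be >= 1 probe")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        for chrom, length in self.chrom_lengths.items():
            if length < self.spacing:
                raise ValueError(f"chromosome {chrom} shorter than probe spacing")

    def n_probes(self, chrom: str) -> int:
        return self.chrom_lengths[chrom] // self.spacing


@dataclass
class GroundTruth:
    """What the generators actually planted.

    ``sites`` maps chromosome -> list of (start, end) spiked intervals;
    ``mark_membership`` labels each site 'A', 'B' or 'both' for dual-mark
    simulations.  Unused fields stay None.
    """

    sites: dict[str, list[tuple[int, int]]] | None = None
    mark_membership: dict[str, list[str]] | None = None
    sites_b: dict[str, list[tuple[int, int]]] | None = None
    genes: list[GeneModel] | None = None
    methylation_probs: dict[float, float] | None = None
    mixture_fractions: list[float] | None = None
    under_covered_sites: list[tuple[str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.genes is not None:
            d["genes"] = [dataclasses.asdict(g) for g in self.genes]
        return d


def _plant_sites(
    config: TilingSimConfig, rng: np.random.Generator
) -> dict[str, list[tuple[int, int]]]:
    """Choose non-overlapping spiked-site probe runs across chromosomes."""
    chroms = list(config.chrom_lengths)
    weights = np.array([config.n_probes(c) for c in chroms], dtype=float)
    for c, w in zip(chroms, weights):
        if config.n_sites and config.site_width_probes > w:
            raise ValueError(
                f"spiked site of {config.site_width_probes} probes exceeds "
                f"chromosome {c} bounds"
            )
    weights /= weights.sum()
    sites: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    planted = 0
    while planted < config.n_sites:
        attempts += 1
        if attempts > 1000 * max(1, config.n_sites):
            raise ValueError("could not place non-overlapping spiked sites")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        n = config.n_probes(chrom)
        i0 = int(rng.integers(0, n - config.site_width_probes + 1))
        i1 = i0 + config.site_width_probes
        # keep sites disjoint and separated by one probe
        if any(i0 < b + 1 and a - 1 < i1 for a, b in taken[chrom]):
            continue
        taken[chrom].append((i0, i1))
        start = i0 * config.spacing
        end = (i1 - 1) * config.spacing + config.probe_length
        sites[chrom].append((start, end))
        planted += 1
    for c in sites:
        sites[c].sort()
        taken[c].sort()
    return sites


def _tracks_for_sites(
    config: TilingSimConfig,
    sites: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> list[dict[str, ProbeTrack]]:
    replicates: list[dict[str, ProbeTrack]] = []
    for _ in range(config.n_replicates):
        tracks: dict[str, ProbeTrack] = {}
        for chrom in config.chrom_lengths:
            n = config.n_probes(chrom)
            starts = np.arange(n, dtype=np.int64) * config.spacing
            ratios = rng.normal(config.background_mean, config.background_sd, n)
            for s, e in sites.get(chrom, []):
                covered = (starts >= s) & (starts < e)
                ratios[covered] += config.effect_size
            tracks[chrom] = ProbeTrack(chrom, starts, ratios, config.probe_length)
        replicates.append(tracks)
    return replicates


def simulate_tiling_experiment(
    config: TilingSimConfig,
) -> tuple[list[dict[str, ProbeTrack]], GroundTruth]:
    """Spike-in tiling experiment: background plus shared enriched sites.

    Returns one {chromosome: ProbeTrack} mapping per replicate and the
    ground truth.  Background ratios are i.i.d. Gaussian; every probe a
    spiked site covers gains the effect size, in all replicates (the
    replicates share biology, not noise).  Sites narrower than the probe
    spacing that no probe covers are flagged in the truth.
    """
    rng = np.random.default_rng(config.seed)
    sites = _plant_sites(config, rng)
    replicates = _tracks_for_sites(config, sites, rng)
    truth = GroundTruth(sites=sites)
    for chrom, ivals in sites.items():
        starts = replicates[0][chrom].starts
        for s, e in ivals:
            if not np.any((starts >= s) & (starts < e)):
                truth.under_covered_sites.append((chrom, s, e))
    return replicates, truth


def simulate_dual_mark(
    config: TilingSimConfig,
    colocalized_fraction: float,
    offset_sd: float,
) -> tuple[
    tuple[list[dict[str, ProbeTrack]], list[dict[str, ProbeTrack]]], GroundTruth
]:
    """Two-mark experiment with a planted colocalized fraction.

    Mark-A sites are placed as in a single-mark experiment; each gets a
    mark-B partner independently with probability ``colocalized_fraction``
    (so the pair count is binomial), jittered by a zero-mean Gaussian of
    SD ``offset_sd`` bp and clipped to the chromosome.  Remaining A sites
    are mark-exclusive.  Returns (tracks for A, tracks for B) and truth
    with per-site mark membership.
    """
    if not 0.0 <= colocalized_fraction <= 1.0:
        raise ValueError("colocalized_fraction must lie in [0, 1]")
    if offset_sd < 0:
        raise ValueError("offset_sd must be >= 0")
    rng = np.random.default_rng(config.seed)
    sites_a = _plant_sites(config, rng)
    membership: dict[str, list[str]] = {}
    sites_b: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in sites_a.items():
        membership[chrom] = []
        sites_b[chrom] = []
        length = config.chrom_lengths[chrom]
        for s, e in ivals:
            if rng.random() < colocalized_fraction:
                membership[chrom].append("both")
                shift = int(round(rng.normal(0.0, offset_sd))) if offset_sd > 0 else 0
                b_s = int(np.clip(s + shift, 0, max(0, length - (e - s))))
                sites_b[chrom].append((b_s, b_s + (e - s)))
            else:
                membership[chrom].append("A")
    tracks_a = _tracks_for_sites(config, sites_a, rng)
    tracks_b = _tracks_for_sites(config, sites_b, rng)
    truth = GroundTruth(sites=sites_a, mark_membership=membership, sites_b=sites_b)
    return (tracks_a, tracks_b), truth


def simulate_gene_annotation(
    n_genes: int,
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    min_length: int = 2_000,
    max_length: int = 20_000,
) -> list[GeneModel]:
    """Random stranded gene bodies, sorted by position.

    Gene lengths are uniform in [min_length, max_length], starts uniform
    along the chromosome (clipped so the body fits), strands fair coin.
    Bodies may overlap, as in real annotations.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = chrom_lengths[chrom]
        glen = int(rng.integers(min_length, max_length + 1))
        glen = min(glen, clen - 1)
        start = int(rng.integers(0, max(1, clen - glen)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(chrom, start, start + glen, strand, f"gene{i:05d}"))
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def simulate_motif_clusters(
    n_clusters: int,
    power_exponent: float,
    excess_count: int,
    excess_depth_range: tuple[int, int] = (15, 40),
    seed: int = 0,
    chrom: str = "chr1",
    read_length: int = 36,
    gap: int = 500,
) -> list[ReadCluster]:
    """Cluster depths from a truncated discrete power law plus an excess.

    ``n_clusters`` depths are drawn by inverse-CDF sampling from
    P(depth = h) proportional to h^(-power_exponent) on support 1..10;
    ``excess_count`` additional clusters get depths uniform over
    ``excess_depth_range`` (inclusive), emulating the deep-cluster excess
    above the confidence threshold.  Clusters are laid out left to right
    with ``gap`` bp between them.
    """
    if power_exponent <= 0:
        raise ValueError("power_exponent must be > 0")
    if n_clusters < 0 or excess_count < 0:
        raise ValueError("cluster counts must be >= 0")
    lo, hi = excess_depth_range
    if excess_count > 0 and (lo > hi or lo < 1):
        raise ValueError("bad excess_depth_range")
    rng = np.random.default_rng(seed)
    support = np.arange(1, 11)
    pmf = support.astype(float) ** (-power_exponent)
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    depths = support[np.searchsorted(cdf, rng.random(n_clusters), side="left")]
    if excess_count:
        depths = np.concatenate(
            [depths, rng.integers(lo, hi + 1, size=excess_count)]
        )
    clusters = []
    pos = 0
    for d in depths:
        clusters.append(ReadCluster(chrom, pos, pos + read_length, int(d)))
        pos += read_length + gap
    return clusters


def clusters_to_reads(clusters: Sequence[ReadCluster]) -> list[tuple[str, int, int]]:
    """Expand each cluster into ``depth`` identical stacked reads, so that
    re-clustering recovers the depths exactly."""
    reads = []
    for c in clusters:
        reads.extend((c.chrom, c.start, c.end) for _ in range(c.depth))
    return reads


def simulate_bisulfite_reads(
    n_reads: int,
    methylation_probs: Mapping[float, float] | Sequence[float],
    conversion_failure_rate: float = 0.02,
    seed: int = 0,
    n_non_cpg: int = 20,
    na_rate: float = 0.0,
) -> pd.DataFrame:
    """Read x site bisulfite call matrix.

    CpG columns are named by site coordinate and hold 'M'/'U' Bernoulli
    calls at the stated per-site methylation probability ('NA' dropouts
    at ``na_rate``).  ``n_non_cpg`` extra columns (``nonCpG_<j>``) hold
    the conversion readout at non-CpG cytosines: 'C' marks a conversion
    failure (probability ``conversion_failure_rate``), 'T' a converted
    residue.
    """
    if n_reads < 1:
        raise ValueError("need >= 1 read")
    if isinstance(methylation_probs, Mapping):
        sites = sorted(methylation_probs)
        probs = np.array([methylation_probs[s] for s in sites], dtype=float)
    else:
        probs = np.asarray(methylation_probs, dtype=float)
        sites = list(range(1, probs.size + 1))
    if probs.size == 0:
        raise ValueError("need >= 1 CpG site")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("methylation probabilities must lie in [0, 1]")
    if not 0 <= conversion_failure_rate <= 1 or not 0 <= na_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = np.where(rng.random((n_reads, probs.size)) < probs, "M", "U")
    if na_rate > 0:
        calls = np.where(rng.random(calls.shape) < na_rate, "NA", calls)
    df = pd.DataFrame(calls, columns=[str(s) for s in sites])
    if n_non_cpg > 0:
        fails = rng.random((n_reads, n_non_cpg)) < conversion_failure_rate
        noncpg = np.where(fails, "C", "T")
        for j in range(n_non_cpg):
            df[f"{NONCPG_PREFIX}{j}"] = noncpg[:, j]
    return df


def simulate_allelic_mixtures(
    fractions: Sequence[float] = DEFAULT_MIXTURE_FRACTIONS,
    slope_a: float = 1.02,
    intercept_a: float = 0.0415,
    slope_b: float = -0.85,
    intercept_b: float = 0.9796,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-channel assay table over known allele-A mixture fractions.

    Each channel's signal is linear in the fraction plus i.i.d. Gaussian
    noise; default lines are the published dilution-series calibration
    rescaled from the percent axis to fraction units, with the error bars'
    ~2% scale as the noise.  Columns: sample, known_fraction, signal_A,
    signal_B, replicate.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("mixture fractions must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if labels is None:
        if tuple(np.round(fr, 6)) == tuple(np.round(DEFAULT_MIXTURE_FRACTIONS, 6)):
            labels = PAPER_MIXTURE_LABELS
        else:
            labels = [f"mix_{f:g}" for f in fr]
    if len(labels) != fr.size:
        raise ValueError("labels and fractions differ in length")
    rng = np.random.default_rng(seed)
    rows = []
    for label, f in zip(labels, fr):
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample": label,
                    "known_fraction": float(f),
                    "signal_A": slope_a * f + intercept_a
                    + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    "signal_B": slope_b * f + intercept_b
                    + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
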