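"""Plain-text readers and writers for the pipeline's interchange formats.

All genomic coordinates are 0-based half-open (BED semantics).  Probe
tracks travel as bedGraph (`chrom start end log2ratio`), peaks as BED4+
(`chrom start end name height fpr support`), genes as BED6 or minimal
GFF3, read clusters as BED4+ with depth and confidence columns, and
ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .colocalize import ColocalizedLocus, GeneModel
from .motifs import ReadCluster
from .peaks import Peak, ProbeTrack

__all__ = [
    "write_probe_tracks",
    "read_probe_tracks",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_genes_bed",
    "read_genes_bed",
    "write_genes_gff3",
    "write_clusters_bed",
    "read_intervals_bed",
    "write_loci_tsv",
    "write_truth_json",
    "read_truth_json",
]


def write_probe_tracks(tracks: Mapping[str, ProbeTrack], path: str | Path) -> None:
    """Write one replicate's probe tracks as bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for start, ratio in zip(t.starts, t.ratios):
                fh.write(f"{t.chrom}\t{start}\t{start + t.probe_length}\t{ratio:.6g}\n")


def read_probe_tracks(path: str | Path) -> dict[str, ProbeTrack]:
    """Read a bedGraph probe file into per-chromosome tracks.

    Probe length is inferred from the interval widths (must be uniform).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "ratio"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"no probes in {path}")
    widths = (df["end"] - df["start"]).unique()
    if widths.size != 1:
        raise ValueError("probe lengths are not uniform")
    out: dict[str, ProbeTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        out[str(chrom)] = ProbeTrack(
            str(chrom),
            grp["start"].to_numpy(),
            grp["ratio"].to_numpy(),
            int(widths[0]),
        )
    return out


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """`chrom start end name height fpr support`, NaN FPR written as 'NA'."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fpr = "NA" if math.isnan(p.fpr) else f"{p.fpr:.6g}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i:05d}\t"
                f"{p.height:.6g}\t{fpr}\t{p.support}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            height = float(parts[4]) if len(parts) > 4 else math.nan
            fpr = (
                math.nan
                if len(parts) <= 5 or parts[5] == "NA"
                else float(parts[5])
            )
            support = int(parts[6]) if len(parts) > 6 else 1
            peaks.append(Peak(chrom, start, end, height, fpr=fpr, support=support))
    return peaks


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(parts[0], int(parts[1]), int(parts[2]),
                          parts[5] if len(parts) > 5 else "+",
                          parts[3] if len(parts) > 3 else "")
            )
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Minimal GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tallelotile\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.name}\n"
            )


def write_clusters_bed(clusters: Sequence[ReadCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i:05d}\t"
                f"{c.depth}\t{c.confidence or 'NA'}\n"
            )


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_loci_tsv(loci: Sequence[ColocalizedLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tmidA\tmidB\tdist\tcontext\tdist_to_5prime\tdistal\n")
        for loc in loci:
            dist5 = "inf" if math.isinf(loc.tss_distance) else f"{loc.tss_distance:.6g}"
            fh.write(
                f"{loc.chrom}\t{loc.peak_a.midpoint:.1f}\t{loc.peak_b.midpoint:.1f}\t"
                f"{loc.distance:.6g}\t{loc.context or 'NA'}\t{dist5}\t"
                f"{int(loc.distal)}\n"
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_truth_json(truth, path: str | Path) -> None:
    payload = truth.to_dict() if hasattr(truth, "to_dict") else truth
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
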