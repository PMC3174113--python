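"""Allele-specific analytics: bisulfite methylation scoring, allelic-mixture
calibration, genotype-cluster classification and mono/biallelic calls.

Bisulfite scoring works on pre-extracted per-read CpG calls (M/U/NA);
reads whose non-CpG cytosine conversion rate falls below a floor are
discarded as incompletely converted, and the per-site methylation
percentage is M / (M + U) over the retained reads.

Two-channel allelic assays (e.g. fluorogenic allele-discrimination PCR)
are calibrated on known DNA mixtures: each channel's endpoint signal is
linear in the mixture fraction, so an OLS line per channel inverts raw
signals into allelic fractions.  Heterozygous samples whose cDNA
minor-allele fraction falls below a cut (default 1/6, the demonstrated
1:5 discrimination limit) are called monoallelic; homozygous genotypes
are uninformative by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylationProfile",
    "CalibrationCurve",
    "AllelicCall",
    "score_methylation",
    "fit_calibration",
    "estimate_allelic_fraction",
    "classify_genotypes",
    "call_monoallelic",
    "plot_methylation_heatmap",
]

NONCPG_PREFIX = "nonCpG_"
MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
UNINFORMATIVE = "uninformative"


@dataclass
class MethylationProfile:
    """Per-CpG methylation fractions with read depths."""

    sites: np.ndarray            # CpG site coordinates, ordered
    fractions: np.ndarray        # methylated-call fraction, NaN if depth 0
    depths: np.ndarray           # informative (M or U) read count per site
    n_reads_used: int
    n_reads_discarded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.sites,
                "fraction_methylated": self.fractions,
                "percent_methylated": 100.0 * self.fractions,
                "depth": self.depths,
            }
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line signal = slope * fraction + intercept for one channel."""

    channel: str
    slope: float
    intercept: float
    r_squared: float
    fraction_range: tuple[float, float] = (0.0, 1.0)

    def invert(self, signal: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope calibration")
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class AllelicCall:
    """Mono/biallelic verdict for one sample."""

    sample: str
    genotype: str                 # gDNA genotype, e.g. "AA", "AB", "BB"
    cdna_minor_fraction: float
    verdict: str


def _conversion_rates(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split off non-CpG cytosine columns and compute per-read conversion.

    Non-CpG columns (named ``nonCpG_*``) hold 'T' for converted and 'C'
    for a conversion failure.  With no such columns every read is treated
    as fully converted.
    """
    noncpg = [c for c in matrix.columns if str(c).startswith(NONCPG_PREFIX)]
    cpg = matrix[[c for c in matrix.columns if c not in noncpg]]
    if noncpg:
        converted = (matrix[noncpg] == "T").sum(axis=1)
        informative = matrix[noncpg].isin(["T", "C"]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rates = converted / informative.replace(0, np.nan)
        rates = rates.fillna(1.0)
    else:
        rates = pd.Series(1.0, index=matrix.index)
    return cpg, rates


def score_methylation(
    matrix: pd.DataFrame,
    min_conversion: float = 0.9,
) -> MethylationProfile:
    """Per-CpG methylation fractions from a read x site call matrix.

    Rows are reads; CpG columns (named by site coordinate) hold calls in
    {M, U, NA}.  Reads with non-CpG conversion rate strictly below
    ``min_conversion`` are discarded.  Sites with zero informative
    coverage get NaN.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty call matrix")
    cpg, rates = _conversion_rates(matrix)
    if cpg.shape[1] == 0:
        raise ValueError("no CpG columns in call matrix")
    keep = rates >= min_conversion
    retained = cpg.loc[keep]
    m = (retained == "M").sum(axis=0).to_numpy(dtype=float)
    u = (retained == "U").sum(axis=0).to_numpy(dtype=float)
    depth = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, m / np.where(depth > 0, depth, 1), np.nan)
    try:
        sites = np.array([float(c) for c in cpg.columns])
    except (TypeError, ValueError):
        sites = np.arange(cpg.shape[1], dtype=float)
    order = np.argsort(sites)
    return MethylationProfile(
        sites=sites[order],
        fractions=frac[order],
        depths=depth[order].astype(int),
        n_reads_used=int(keep.sum()),
        n_reads_discarded=int((~keep).sum()),
    )


def fit_calibration(
    assay: pd.DataFrame,
    fraction_col: str = "known_fraction",
    signal_cols: Sequence[str] = ("signal_A", "signal_B"),
) -> dict[str, CalibrationCurve]:
    """OLS calibration line per channel from known-mixture assays.

    Requires at least three distinct mixture fractions with nonzero
    variance.  A constant signal yields slope 0 with R-squared 0 by
    convention.
    """
    frac = assay[fraction_col].to_numpy(dtype=float)
    if np.unique(frac).size < 3:
        raise ValueError("need >= 3 distinct mixture fractions")
    if np.var(frac) == 0:
        raise ValueError("zero variance in mixture fractions")
    curves: dict[str, CalibrationCurve] = {}
    for col in signal_cols:
        y = assay[col].to_numpy(dtype=float)
        if np.var(y) == 0:
            curves[col] = CalibrationCurve(
                channel=col, slope=0.0, intercept=float(y.mean()), r_squared=0.0,
                fraction_range=(float(frac.min()), float(frac.max())),
            )
            continue
        res = stats.linregress(frac, y)
        curves[col] = CalibrationCurve(
            channel=col,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            fraction_range=(float(frac.min()), float(frac.max())),
        )
    return curves


def estimate_allelic_fraction(
    signals: Mapping[str, float],
    curves: Mapping[str, CalibrationCurve],
    min_abs_slope: float = 1e-9,
) -> float:
    """Invert each channel's calibration line and average the estimates.

    Channels with near-zero slope carry no information and are excluded
    with a warning; the result is clamped to [0, 1].
    """
    estimates = []
    for channel, curve in curves.items():
        if channel not in signals:
            continue
        if abs(curve.slope) < min_abs_slope:
            warnings.warn(f"channel {channel!r} has ~zero slope; excluded")
            continue
        estimates.append(curve.invert(signals[channel]))
    if not estimates:
        raise ValueError("no usable calibration channel")
    return float(np.clip(np.mean(estimates), 0.0, 1.0))


def classify_genotypes(
    points: np.ndarray | Sequence[Sequence[float]],
    controls: Mapping[str, Sequence[float]],
    margin: float = 1.2,
) -> list[str]:
    """Nearest-centroid genotype assignment in the two-channel plane.

    ``controls`` maps labels (typically AA, AB, BB and NTC) to centroid
    coordinates.  A point is labelled ``undetermined`` when its
    second-nearest centroid is less than ``margin`` times farther than the
    nearest (ambiguous assignment).  Order of input points is respected;
    classification is independent per point.
    """
    if not controls:
        raise ValueError("control centroids (or thresholds) are required")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of channel signals")
    labels = list(controls)
    cents = np.array([controls[k] for k in labels], dtype=float)
    out: list[str] = []
    for p in pts:
        d = np.linalg.norm(cents - p, axis=1)
        order = np.argsort(d)
        if len(labels) > 1 and d[order[0]] > 0 and d[order[1]] / d[order[0]] < margin:
            out.append("undetermined")
        else:
            out.append(labels[int(order[0])])
    return out


def call_monoallelic(
    sample: str,
    genotype: str,
    cdna_fraction: float,
    minor_cut: float = 1.0 / 6.0,
) -> AllelicCall:
    """Mono/biallelic verdict from gDNA genotype and cDNA allelic fraction.

    Homozygous genotypes are uninformative (allele-specific expression is
    undefined without a heterozygous marker).  For heterozygotes the cDNA
    minor-allele fraction min(f, 1 - f) below ``minor_cut`` calls
    monoallelic expression, else biallelic.
    """
    if not 0.0 <= cdna_fraction <= 1.0:
        raise ValueError("cdna_fraction must lie in [0, 1]")
    if len(genotype) != 2:
        raise ValueError("genotype must be a two-letter call like 'AB'")
    minor = min(cdna_fraction, 1.0 - cdna_fraction)
    if genotype[0] == genotype[1]:
        verdict = UNINFORMATIVE
    elif minor < minor_cut:
        verdict = MONOALLELIC
    else:
        verdict = BIALLELIC
    return AllelicCall(sample, genotype, minor, verdict)


def plot_methylation_heatmap(
    profiles: Mapping[str, MethylationProfile],
    ax=None,
    cmap: str = "viridis",
):
    """Heat map of percent methylation, one row per sample, one column
    per CpG site (sites must match across profiles)."""
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("no profiles to plot")
    names = list(profiles)
    mat = np.vstack([100.0 * profiles[n].fractions for n in names])
    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * mat.shape[1] + 2, 0.5 * len(names) + 1))
    im = ax.imshow(mat, aspect="auto", cmap=cmap, vmin=0, vmax=100)
    ax.set_yticks(range(len(names)), names)
    ax.set_xticks(range(mat.shape[1]),
                  [f"{s:g}" for s in profiles[names[0]].sites], rotation=90)
    ax.set_xlabel("CpG site")
    ax.figure.colorbar(im, ax=ax, label="% methylated")
    return ax
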