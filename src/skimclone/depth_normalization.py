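"""Bin-level depth normalisation: genome layout, LogR computation and PON denoising.

Raw per-sample read counts in fixed-width genomic bins are converted into
log2 depth-ratio (LogR) profiles against a panel of normals (PON), optionally
denoised by projecting out the top principal components of the normals'
centred LogR matrix ("tangent" denoising).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BinCountMatrix",
    "LogRProfile",
    "PanelOfNormals",
    "build_mask",
    "build_pon",
    "compute_logr",
    "tangent_denoise",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and a fixed bin size.

    Chromosomes are expected in numeric order with X last; the circular
    order used by permutation tests follows this ordering, with the end of
    the last chromosome joined back to the start of the first.

    Bins tile each chromosome as ``[i*bin_size, (i+1)*bin_size)``; a trailing
    partial bin is dropped.
    """

    names: tuple[str, ...]
    lengths: dict[str, int] = field(hash=False)
    bin_size: int = 100_000

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("genome must contain at least one chromosome")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def n_bins_of(self, chrom: str) -> int:
        return self.lengths[chrom] // self.bin_size

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.names)

    def bins(self) -> pd.DataFrame:
        """Bin index as a DataFrame with columns chrom/start/end."""
        recs = []
        for chrom in self.names:
            for i in range(self.n_bins_of(chrom)):
                recs.append((chrom, i * self.bin_size, (i + 1) * self.bin_size))
        return pd.DataFrame(recs, columns=["chrom", "start", "end"])

    def autosome_mask(self) -> np.ndarray:
        """Boolean per-bin array, True on autosomal bins (chrom not named X)."""
        bins = self.bins()
        return (bins["chrom"] != "X").to_numpy()

    def chrom_offsets(self) -> dict[str, int]:
        """Cumulative bin offset of each chromosome in circular order."""
        offsets: dict[str, int] = {}
        pos = 0
        for chrom in self.names:
            offsets[chrom] = pos
            pos += self.n_bins_of(chrom)
        return offsets

    def binned_length(self) -> int:
        """Total genome length covered by full bins, in bp."""
        return self.n_bins * self.bin_size


@dataclass
class BinCountMatrix:
    """Per-bin integer read counts for one or more samples.

    ``counts`` is indexed like ``genome.bins()`` (one row per bin, in genome
    order) with one column per sample. ``mask`` marks bins excluded from all
    computation (True = excluded).
    """

    genome: GenomeLayout
    counts: pd.DataFrame
    mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.counts) != self.genome.n_bins:
            raise ValueError("count matrix does not match genome binning")
        if len(self.mask) != len(self.counts):
            raise ValueError("mask length does not match bin count")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy(dtype=float)


@dataclass
class LogRProfile:
    """Per-bin log2 tumour/reference depth ratios for one sample.

    Masked bins carry NaN; unmasked values are finite.
    """

    sample: str
    genome: GenomeLayout
    values: np.ndarray
    mask: np.ndarray
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.values) != self.genome.n_bins:
            raise ValueError("LogR length does not match genome binning")


@dataclass
class PanelOfNormals:
    """Reference levels and principal directions from a set of normal genomes."""

    genome: GenomeLayout
    median_depth: np.ndarray        # per-bin median of depth-normalised normals
    centred_logr: np.ndarray        # (n_normals, n_bins) centred normal LogR
    components: np.ndarray          # (k, n_bins) orthonormal principal directions
    mask: np.ndarray
    logr_mean: np.ndarray           # per-bin mean used for centring

    @property
    def n_normals(self) -> int:
        return self.centred_logr.shape[0]

    @property
    def max_k(self) -> int:
        return self.components.shape[0]


def build_mask(genome: GenomeLayout, excluded_intervals: list[tuple[str, int, int]]) -> np.ndarray:
    """Per-bin exclusion mask from a list of (chrom, start, end) intervals.

    A bin is masked when it overlaps any excluded interval. Trailing partial
    bins are not represented at all (dropped by the tiling rule), so they do
    not appear in the mask.

    Raises ``ValueError`` for intervals outside the genome bounds.
    """
    bins = genome.bins()
    mask = np.zeros(len(bins), dtype=bool)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    for chrom, lo, hi in excluded_intervals:
        if chrom not in genome.lengths:
            raise ValueError(f"excluded interval on unknown chromosome {chrom!r}")
        if lo < 0 or hi > genome.lengths[chrom] or lo >= hi:
            raise ValueError(f"interval {chrom}:{lo}-{hi} outside genome bounds")
        mask |= (chroms == chrom) & (starts < hi) & (ends > lo)
    return mask


def _depth_normalise(counts: np.ndarray, autosomal: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scale a count vector by its own autosomal median over unmasked bins."""
    keep = autosomal & ~mask
    med = np.median(counts[keep])
    if med <= 0:
        raise ValueError("zero autosomal median depth; degenerate input")
    return counts / med


def build_pon(
    normals: BinCountMatrix,
    k: int | None = None,
) -> PanelOfNormals:
    """Build a panel of normals from normal-genome bin counts.

    Each normal is depth-normalised by its own autosomal median; the per-bin
    median across normals becomes the reference level. The normals' LogR
    matrix (against that reference) is centred and decomposed by SVD; the top
    ``k`` right singular vectors (default ``min(20, n_normals - 1)``) are kept
    as the tangent-denoising directions.
    """
    genome = normals.genome
    mask = normals.mask.copy()
    autosomal = genome.autosome_mask()
    depth = np.stack(
        [_depth_normalise(normals.column(s), autosomal, mask) for s in normals.samples]
    )
    median_depth = np.median(depth, axis=0)
    # bins where the reference level is non-positive cannot be normalised
    mask = mask | (median_depth <= 0)

    n_normals = depth.shape[0]
    if k is None:
        k = min(20, n_normals - 1)
    k = max(k, 0)
    if k > n_normals - 1:
        raise ValueError(f"k={k} exceeds available components ({n_normals - 1})")

    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log2(depth / median_depth)
    logr[:, mask] = 0.0
    mean = logr.mean(axis=0)
    centred = logr - mean
    if k > 0:
        # SVD on unmasked columns only; directions are zero on masked bins
        _, _, vt = np.linalg.svd(centred[:, ~mask], full_matrices=False)
        components = np.zeros((k, genome.n_bins))
        components[:, ~mask] = vt[:k]
    else:
        components = np.zeros((0, genome.n_bins))
    return PanelOfNormals(
        genome=genome,
        median_depth=median_depth,
        centred_logr=centred,
        components=components,
        mask=mask,
        logr_mean=mean,
    )


def compute_logr(
    tumour: BinCountMatrix,
    sample: str,
    pon: PanelOfNormals,
    mode: str = "per_bin",
) -> LogRProfile:
    """LogR profile of one tumour sample against the PON.

    The tumour is first depth-normalised by its own autosomal median; each
    bin is then divided by the PON per-bin median and log2-transformed
    (``mode="per_bin"``, default). ``mode="global"`` skips the per-bin
    reference and uses the flat autosomal-median baseline only.
    """
    if mode not in ("per_bin", "global"):
        raise ValueError(f"unknown logr mode {mode!r}")
    genome = tumour.genome
    mask = tumour.mask | pon.mask
    counts = tumour.column(sample)
    depth = _depth_normalise(counts, genome.autosome_mask(), mask)
    values = np.full(genome.n_bins, np.nan)
    keep = ~mask
    with np.errstate(divide="ignore"):
        if mode == "per_bin":
            values[keep] = np.log2(depth[keep] / pon.median_depth[keep])
        else:
            values[keep] = np.log2(depth[keep])
    # zero-count bins give -inf; treat as masked rather than propagate
    bad = keep & ~np.isfinite(values)
    mask = mask | bad
    values[bad] = np.nan
    return LogRProfile(sample=sample, genome=genome, values=values, mask=mask, raw_counts=counts)


def tangent_denoise(logr: LogRProfile, pon: PanelOfNormals, k: int | None = None) -> LogRProfile:
    """Subtract the projection of the centred profile onto the PON's top-k
    principal directions. ``k=0`` returns the input unchanged."""
    if k is None:
        k = pon.max_k
    if k > pon.max_k:
        raise ValueError(f"k={k} exceeds available components ({pon.max_k})")
    if k == 0:
        return LogRProfile(
            sample=logr.sample,
            genome=logr.genome,
            values=logr.values.copy(),
            mask=logr.mask.copy(),
            raw_counts=logr.raw_counts,
        )
    mask = logr.mask | pon.mask
    keep = ~mask
    centred = logr.values[keep] - pon.logr_mean[keep]
    comps = pon.components[:k][:, keep]
    proj = comps.T @ (comps @ centred)
    values = np.full_like(logr.values, np.nan)
    values[keep] = pon.logr_mean[keep] + (centred - proj)
    return LogRProfile(
        sample=logr.sample,
        genome=logr.genome,
        values=values,
        mask=mask,
        raw_counts=logr.raw_counts,
    )
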