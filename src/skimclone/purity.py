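"""Tumour purity estimation.

Two independent estimators are provided and combined by their mean:

* depth over lineage-fixed single-copy-loss (LOH) and homozygous-deletion
  (Homdel) regions, relative to genome-wide depth;
* twice the median variant allele fraction of well-supported panel variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PurityRegions",
    "PurityEstimate",
    "sliding_window_depth",
    "purity_from_regions",
    "purity_from_vaf",
    "combine_purity",
]

VALID_CLASSES = ("LOH", "Homdel")


@dataclass(frozen=True)
class PurityRegions:
    """Regions fixed at copy number 1 (LOH) or 0 (Homdel) across the lineage."""

    regions: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, class)

    def __post_init__(self) -> None:
        for chrom, start, end, cls in self.regions:
            if cls not in VALID_CLASSES:
                raise ValueError(f"unknown deletion class {cls!r}")
            if start >= end:
                raise ValueError(f"empty region {chrom}:{start}-{end}")

    @property
    def n_homdel(self) -> int:
        return sum(1 for r in self.regions if r[3] == "Homdel")

    @property
    def n_loh(self) -> int:
        return sum(1 for r in self.regions if r[3] == "LOH")

    @classmethod
    def from_bed(cls, path) -> "PurityRegions":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "class"])
        return cls(tuple(df.itertuples(index=False, name=None)))


@dataclass
class PurityEstimate:
    rho: float
    method: str  # regions | mip | combined
    components: dict[str, float] = field(default_factory=dict)
    clipped: bool = False
    single_source: bool = False


def sliding_window_depth(
    depth_bins: pd.DataFrame,
    window: int = 10_000,
    slide: int = 5_000,
) -> pd.DataFrame:
    """Mean depth in sliding windows over a per-position depth table.

    ``depth_bins`` must have columns chrom/start/end/depth with contiguous
    intervals; windows average the depth of intervals they overlap, weighted
    by overlap length.
    """
    out = []
    for chrom, grp in depth_bins.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        depth = grp["depth"].to_numpy(dtype=float)
        chrom_end = int(ends.max())
        w0 = 0
        while w0 + window <= chrom_end:
            w1 = w0 + window
            ov = np.minimum(ends, w1) - np.maximum(starts, w0)
            ov = np.clip(ov, 0, None)
            tot = ov.sum()
            if tot > 0:
                out.append((chrom, w0, w1, float((depth * ov).sum() / tot)))
            w0 += slide
    return pd.DataFrame(out, columns=["chrom", "start", "end", "depth"])


def purity_from_regions(depth_windows: pd.DataFrame, regions: PurityRegions) -> PurityEstimate:
    """Purity from mean depth over LOH/Homdel regions.

    Each region yields its own estimate by inverting the host-dilution model
    at the region's copy number: ``1 - r/r_genome`` at CN0 (Homdel) and
    ``2 * (1 - r/r_genome)`` at CN1 (LOH), where ``r`` is the region's mean
    window depth and ``r_genome`` the genome-wide mean. The returned purity
    is the mean of the per-region estimates, clipped to [0, 1].
    """
    if not regions.regions:
        raise ValueError("empty region list")
    genome_mean = float(depth_windows["depth"].mean())
    if not genome_mean > 0:
        raise ValueError("genome-wide mean depth must be positive")
    chroms = depth_windows["chrom"].to_numpy()
    starts = depth_windows["start"].to_numpy()
    ends = depth_windows["end"].to_numpy()
    depth = depth_windows["depth"].to_numpy(dtype=float)

    components: dict[str, float] = {}
    estimates = []
    for i, (chrom, lo, hi, cls) in enumerate(regions.regions):
        inside = (chroms == chrom) & (starts >= lo) & (ends <= hi)
        if not inside.any():
            raise ValueError(f"region {chrom}:{lo}-{hi} covers no depth window")
        ratio = float(depth[inside].mean()) / genome_mean
        est = 1.0 - ratio if cls == "Homdel" else 2.0 * (1.0 - ratio)
        components[f"{cls}_{i}"] = est
        estimates.append(est)
    rho = float(np.mean(estimates))
    clipped = rho < 0 or rho > 1
    return PurityEstimate(
        rho=float(np.clip(rho, 0.0, 1.0)),
        method="regions",
        components=components,
        clipped=clipped,
    )


def purity_from_vaf(
    vafs,
    read_support=None,
    min_variant_reads: int = 3,
) -> PurityEstimate:
    """Purity as twice the median VAF of variants passing a read-support floor.

    ``read_support`` gives per-variant supporting-read counts; when omitted,
    all variants pass.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    if read_support is not None:
        support = np.asarray(list(read_support))
        if len(support) != len(vafs):
            raise ValueError("read_support length mismatch")
        vafs = vafs[support >= min_variant_reads]
    if len(vafs) == 0:
        raise ValueError("no variants pass the read-support threshold")
    raw = 2.0 * float(np.median(vafs))
    clipped = raw < 0 or raw > 1
    return PurityEstimate(
        rho=float(np.clip(raw, 0.0, 1.0)),
        method="mip",
        components={"median_vaf_x2": raw},
        clipped=clipped,
    )


def combine_purity(a: PurityEstimate | None, b: PurityEstimate | None) -> PurityEstimate:
    """Mean of two purity estimates; passes through a lone defined one, flagged."""
    defined = [e for e in (a, b) if e is not None]
    if not defined:
        raise ValueError("both purity estimates undefined")
    if len(defined) == 1:
        e = defined[0]
        return PurityEstimate(
            rho=e.rho, method="combined", components=dict(e.components),
            clipped=e.clipped, single_source=True,
        )
    rho = (defined[0].rho + defined[1].rho) / 2.0
    comps = {f"{e.method}": e.rho for e in defined}
    return PurityEstimate(rho=rho, method="combined", components=comps)
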