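"""Piecewise-constant segmentation of LogR profiles.

Single-sample and multi-sample segmentation are exact penalised least-squares
minimisers found by dynamic programming, followed by the within-sample merge
rules (95%-overlap reconciliation between the two segmentations, then
rank-test merging of adjacent segments) and cross-sample consolidation of
non-diploid segments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .depth_normalization import LogRProfile

__all__ = [
    "Segment",
    "pcf_core",
    "pcf_segment",
    "multipcf_segment",
    "merge_within_sample",
    "harmonize_across_samples",
]


@dataclass
class Segment:
    """A genomic interval with constant copy-number state in one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_logr: float
    provenance: str = "pcf"  # pcf | multipcf | merged
    cn_state: float | None = None
    subclonal: bool = False
    flagged: bool = False
    mean_count: float | None = None
    event_key: str | None = None
    post_wgd: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Segment") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _noise_variance(x: np.ndarray) -> float:
    """Per-bin noise variance from the MAD of first differences."""
    d = np.diff(x)
    if len(d) == 0:
        return 1.0
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / (0.6744897501960817 * np.sqrt(2.0))
    return max(sigma**2, 1e-12)


def pcf_core(x: np.ndarray, penalty: float, kmin: int = 1) -> list[tuple[int, int]]:
    """Exact minimiser of sum((x - mu)^2) + penalty * n_breakpoints.

    Returns half-open index intervals covering ``x``, each spanning at least
    ``kmin`` points (a single shorter segment is returned when
    ``len(x) < kmin``). Dynamic programming over all admissible breakpoint
    placements; O(n^2).
    """
    n = len(x)
    if n == 0:
        return []
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if n < kmin:
        return [(0, n)]
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -penalty  # first segment carries no breakpoint cost
    for j in range(kmin, n + 1):
        for i in range(0, j - kmin + 1):
            if not np.isfinite(best[i]):
                continue
            cand = best[i] + penalty + sse(i, j)
            if cand < best[j]:
                best[j] = cand
                prev[j] = i
    bounds = []
    j = n
    while j > 0:
        i = prev[j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def _multipcf_core(xs: np.ndarray, penalty: float, kmin: int = 1) -> list[tuple[int, int]]:
    """Shared-breakpoint DP over a (n_samples, n_bins) matrix.

    The objective is the summed per-sample SSE plus ``penalty`` per
    breakpoint (the caller folds the per-sample multiplicity into
    ``penalty``).
    """
    n = xs.shape[1]
    if n == 0:
        return []
    if n < kmin:
        return [(0, n)]
    c1 = np.concatenate([np.zeros((xs.shape[0], 1)), np.cumsum(xs, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((xs.shape[0], 1)), np.cumsum(xs * xs, axis=1)], axis=1)

    def sse(i: int, j: int) -> float:
        s = c1[:, j] - c1[:, i]
        return float(np.sum((c2[:, j] - c2[:, i]) - s * s / (j - i)))

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -penalty
    for j in range(kmin, n + 1):
        for i in range(0, j - kmin + 1):
            if not np.isfinite(best[i]):
                continue
            cand = best[i] + penalty + sse(i, j)
            if cand < best[j]:
                best[j] = cand
                prev[j] = i
    bounds = []
    j = n
    while j > 0:
        i = prev[j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def _chromosome_blocks(logr: LogRProfile):
    """Yield (chrom, bin_slice, unmasked_index, values) per chromosome."""
    genome = logr.genome
    pos = 0
    for chrom in genome.names:
        n = genome.n_bins_of(chrom)
        sl = slice(pos, pos + n)
        keep = ~logr.mask[sl]
        idx = np.nonzero(keep)[0]
        yield chrom, sl, idx, logr.values[sl][keep]
        pos += n


def _segments_from_bounds(
    logr: LogRProfile, chrom: str, sl: slice, idx: np.ndarray, vals: np.ndarray,
    bounds: list[tuple[int, int]], provenance: str,
) -> list[Segment]:
    """Map index-space segment bounds back to bp coordinates, tiling the chromosome."""
    genome = logr.genome
    bin_size = genome.bin_size
    n_chrom = genome.n_bins_of(chrom)
    segs = []
    counts = logr.raw_counts[sl] if logr.raw_counts is not None else None
    for si, (i, j) in enumerate(bounds):
        start_bin = 0 if si == 0 else int(idx[i])
        end_bin = n_chrom if si == len(bounds) - 1 else int(idx[bounds[si + 1][0]])
        member = idx[i:j]
        segs.append(
            Segment(
                sample=logr.sample,
                chrom=chrom,
                start=start_bin * bin_size,
                end=end_bin * bin_size,
                n_bins=end_bin - start_bin,
                mean_logr=float(np.mean(vals[i:j])),
                provenance=provenance,
                mean_count=float(np.mean(counts[member])) if counts is not None else None,
            )
        )
    return segs


def pcf_segment(
    logr: LogRProfile,
    gamma: float = 40.0,
    kmin: int = 5,
    scale_gamma: bool = True,
) -> list[Segment]:
    """Single-sample exact pcf segmentation, run per chromosome.

    ``gamma`` is expressed in units of the per-bin noise variance (MAD of
    first differences) unless ``scale_gamma`` is False, in which case it is
    the absolute breakpoint penalty.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    all_vals = logr.values[~logr.mask]
    if len(all_vals) == 0:
        return []
    penalty = gamma * _noise_variance(all_vals) if scale_gamma else gamma
    segs: list[Segment] = []
    for chrom, sl, idx, vals in _chromosome_blocks(logr):
        if len(vals) == 0:
            continue
        bounds = pcf_core(vals, penalty, kmin)
        segs.extend(_segments_from_bounds(logr, chrom, sl, idx, vals, bounds, "pcf"))
    return segs


def multipcf_segment(
    logrs: list[LogRProfile],
    gamma: float = 40.0,
    kmin: int = 5,
    scale_gamma: bool = True,
) -> dict[str, list[Segment]]:
    """Multi-sample segmentation with a breakpoint set shared by the group.

    The penalty per breakpoint is ``gamma`` (variance units, summed over
    samples), so a group of one reduces exactly to ``pcf_segment``.
    """
    if not logrs:
        raise ValueError("empty multipcf group")
    ref = logrs[0]
    for lr in logrs[1:]:
        if lr.genome is not ref.genome and lr.genome != ref.genome:
            raise ValueError("profiles do not share a genome layout")
    mask = np.zeros(ref.genome.n_bins, dtype=bool)
    for lr in logrs:
        mask |= lr.mask
    if scale_gamma:
        penalty = gamma * sum(
            _noise_variance(lr.values[~mask]) for lr in logrs
        )
    else:
        penalty = gamma * len(logrs)

    out: dict[str, list[Segment]] = {lr.sample: [] for lr in logrs}
    genome = ref.genome
    pos = 0
    for chrom in genome.names:
        n = genome.n_bins_of(chrom)
        sl = slice(pos, pos + n)
        keep = ~mask[sl]
        idx = np.nonzero(keep)[0]
        if len(idx) > 0:
            xs = np.stack([lr.values[sl][keep] for lr in logrs])
            bounds = _multipcf_core(xs, penalty, kmin)
            for lr, vals in zip(logrs, xs):
                shared = LogRProfile(
                    sample=lr.sample, genome=genome, values=lr.values,
                    mask=mask, raw_counts=lr.raw_counts,
                )
                out[lr.sample].extend(
                    _segments_from_bounds(shared, chrom, sl, idx, vals, bounds, "multipcf")
                )
        pos += n
    return out


def _provisional_state(mean_logr: float, rho: float = 1.0, psi: float = 2.0) -> int:
    """Nearest-integer copy number from a segment mean LogR."""
    cn = (psi * 2.0**mean_logr - 2.0 * (1.0 - rho)) / rho
    return int(max(round(cn), 0))


def _bin_values(logr: LogRProfile, seg: Segment) -> np.ndarray:
    genome = logr.genome
    offset = genome.chrom_offsets()[seg.chrom]
    lo = offset + seg.start // genome.bin_size
    hi = offset + seg.end // genome.bin_size
    vals = logr.values[lo:hi]
    return vals[~logr.mask[lo:hi]]


def _rebuild(logr: LogRProfile, chrom: str, breaks: list[int], provenance: str) -> list[Segment]:
    """Segments for one chromosome from a sorted list of internal bp breakpoints."""
    genome = logr.genome
    bin_size = genome.bin_size
    n_chrom = genome.n_bins_of(chrom)
    edges = [0] + sorted(set(breaks)) + [n_chrom * bin_size]
    offset = genome.chrom_offsets()[chrom]
    segs = []
    counts = logr.raw_counts
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        b0 = offset + lo // bin_size
        b1 = offset + hi // bin_size
        keep = ~logr.mask[b0:b1]
        vals = logr.values[b0:b1][keep]
        segs.append(
            Segment(
                sample=logr.sample,
                chrom=chrom,
                start=lo,
                end=hi,
                n_bins=(hi - lo) // bin_size,
                mean_logr=float(np.mean(vals)) if len(vals) else 0.0,
                provenance=provenance,
                mean_count=(
                    float(np.mean(counts[b0:b1][keep]))
                    if counts is not None and keep.any() else None
                ),
            )
        )
    return segs


def merge_within_sample(
    pcf_segs: list[Segment],
    multipcf_segs: list[Segment],
    logr: LogRProfile,
    alpha: float = 0.05,
    rho: float = 1.0,
    psi: float = 2.0,
    merge_rule: str = "both",
) -> list[Segment]:
    """Reconcile single- and multi-sample segmentations within one sample.

    Where a pcf and a multipcf segment share a provisional copy-number state
    and reciprocally overlap >95% of their length, the multipcf breakpoints
    are retained; elsewhere the union of breakpoints is kept. Adjacent
    segments are then merged iteratively (leftmost pair first) when rank
    location (Wilcoxon) and rank dispersion (Ansari-Bradley) tests on their
    member-bin LogR values are non-significant at ``alpha`` — both tests with
    ``merge_rule="both"`` (default), either with ``"either"``.
    """
    if merge_rule not in ("both", "either"):
        raise ValueError(f"unknown merge rule {merge_rule!r}")
    out: list[Segment] = []
    for chrom in logr.genome.names:
        p_ch = [s for s in pcf_segs if s.chrom == chrom]
        m_ch = [s for s in multipcf_segs if s.chrom == chrom]
        if not p_ch and not m_ch:
            continue
        # 1) overlap reconciliation on the breakpoint sets
        matched_regions = []
        for p, m in itertools.product(p_ch, m_ch):
            ov = p.overlap(m)
            if ov == 0:
                continue
            if ov > 0.95 * p.length and ov > 0.95 * m.length:
                sp = _provisional_state(p.mean_logr, rho, psi)
                sm = _provisional_state(m.mean_logr, rho, psi)
                if sp == sm:
                    matched_regions.append((min(p.start, m.start), max(p.end, m.end)))
        m_breaks = sorted({s.start for s in m_ch} | {s.end for s in m_ch})
        p_breaks = sorted({s.start for s in p_ch} | {s.end for s in p_ch})
        chrom_len = logr.genome.n_bins_of(chrom) * logr.genome.bin_size
        keep_p = [
            b for b in p_breaks
            if 0 < b < chrom_len
            and not any(lo < b < hi for lo, hi in matched_regions)
        ]
        keep_m = [b for b in m_breaks if 0 < b < chrom_len]
        segs = _rebuild(logr, chrom, keep_p + keep_m, "merged")

        # 2) iterative rank-test merging of adjacent segments
        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(segs) - 1:
                a = _bin_values(logr, segs[i])
                b = _bin_values(logr, segs[i + 1])
                if _mergeable(a, b, alpha, merge_rule):
                    segs[i: i + 2] = [_fuse(segs[i], segs[i + 1], logr)]
                    changed = True
                else:
                    i += 1
        out.extend(segs)
    return out


def _mergeable(a: np.ndarray, b: np.ndarray, alpha: float, rule: str) -> bool:
    if len(a) < 2 or len(b) < 2:
        return True  # too little data to reject equality
    try:
        p_loc = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    except ValueError:
        p_loc = 1.0
    try:
        p_disp = stats.ansari(a, b).pvalue
    except ValueError:
        p_disp = 1.0
    if rule == "both":
        return p_loc > alpha and p_disp > alpha
    return p_loc > alpha or p_disp > alpha


def _fuse(a: Segment, b: Segment, logr: LogRProfile) -> Segment:
    merged = replace(
        a,
        end=b.end,
        n_bins=a.n_bins + b.n_bins,
        provenance="merged",
    )
    vals = _bin_values(logr, merged)
    merged.mean_logr = float(np.mean(vals)) if len(vals) else 0.0
    if a.mean_count is not None and b.mean_count is not None:
        w = a.n_bins + b.n_bins
        merged.mean_count = (a.mean_count * a.n_bins + b.mean_count * b.n_bins) / max(w, 1)
    return merged


def _lower_median(values: list[int]) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def harmonize_across_samples(
    all_segments: dict[str, list[Segment]],
    min_len: int = 500_000,
    overlap_frac: float = 0.95,
    max_breakpoint_dist: int = 500_000,
    bin_size: int = 100_000,
) -> dict[str, list[Segment]]:
    """Consolidate non-diploid segments across samples and drop short segments.

    Segments (provisional state != 2) from different samples whose reciprocal
    overlap exceeds ``overlap_frac`` and whose corresponding breakpoints lie
    within ``max_breakpoint_dist`` are given a common identity, with both
    boundaries set to the (lower) median of the observed boundaries. Segments
    shorter than ``min_len`` are deleted and absorbed into their left
    neighbour. Order-free: identical output for any sample ordering.
    """
    flat: list[tuple[str, int, Segment]] = []
    for sample in sorted(all_segments):
        for i, seg in enumerate(all_segments[sample]):
            flat.append((sample, i, seg))
    non2 = [
        k for k, (_, _, seg) in enumerate(flat)
        if seg.cn_state is not None and seg.cn_state != 2
        or seg.cn_state is None and _provisional_state(seg.mean_logr) != 2
    ]
    # union-find over consolidatable segments
    parent = list(range(len(flat)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a, b in itertools.combinations(non2, 2):
        sa, _, ga = flat[a]
        sb, _, gb = flat[b]
        if sa == sb or ga.chrom != gb.chrom:
            continue
        ov = ga.overlap(gb)
        if (
            ov > overlap_frac * ga.length
            and ov > overlap_frac * gb.length
            and abs(ga.start - gb.start) <= max_breakpoint_dist
            and abs(ga.end - gb.end) <= max_breakpoint_dist
        ):
            union(a, b)

    clusters: dict[int, list[int]] = {}
    for k in non2:
        clusters.setdefault(find(k), []).append(k)

    new_coords: dict[int, tuple[int, int, str]] = {}
    for root, members in clusters.items():
        if len(members) < 2:
            continue
        start = _lower_median([flat[k][2].start for k in members])
        end = _lower_median([flat[k][2].end for k in members])
        seg0 = flat[members[0]][2]
        key = f"{seg0.chrom}:{start}-{end}"
        for k in members:
            new_coords[k] = (start, end, key)

    out: dict[str, list[Segment]] = {}
    by_sample: dict[str, list[tuple[int, Segment]]] = {}
    for k, (sample, i, seg) in enumerate(flat):
        by_sample.setdefault(sample, []).append((k, seg))

    for sample, items in by_sample.items():
        segs = []
        for k, seg in items:
            seg = replace(seg)
            if k in new_coords:
                seg.start, seg.end, seg.event_key = new_coords[k]
            segs.append(seg)
        # restore tiling: neighbour boundaries follow consolidated ones
        segs.sort(key=lambda s: (s.chrom, s.start))
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.chrom == b.chrom and a.end != b.start:
                if b.event_key is not None and a.event_key is None:
                    a.end = b.start
                else:
                    b.start = a.end
        segs = [s for s in segs if s.end > s.start]
        # drop + absorb short segments
        cleaned: list[Segment] = []
        for seg in segs:
            if seg.length < min_len and cleaned and cleaned[-1].chrom == seg.chrom:
                prev = cleaned[-1]
                prev.end = seg.end
            elif seg.length < min_len and len(cleaned) == 0:
                seg.meta["absorb_into_next"] = True
                cleaned.append(seg)
            else:
                if cleaned and cleaned[-1].meta.pop("absorb_into_next", False):
                    seg.start = cleaned[-1].start
                    cleaned[-1] = seg
                else:
                    cleaned.append(seg)
        for seg in cleaned:
            seg.n_bins = seg.length // bin_size
            seg.meta.pop("absorb_into_next", None)
        out[sample] = cleaned
    return out
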