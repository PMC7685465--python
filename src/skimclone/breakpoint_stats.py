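"""Breakpoint reuse and CNV clustering statistics with a circular-genome
permutation null.

The null keeps every event's length and redraws its start position uniformly
on the circularised genome (chromosomes concatenated in layout order, the
end of the last wrapping to the start of the first); events crossing the
origin are split into two arcs. Empirical p-values use the (b + 1) / (n + 1)
estimator and therefore never return 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv_catalogue import CNVEvent
from .depth_normalization import GenomeLayout

__all__ = [
    "ReuseResult",
    "count_breakpoint_reuse",
    "clustering_stats",
    "circular_permutation_null",
]


@dataclass
class ReuseResult:
    observed: float
    null: np.ndarray
    p_value: float

    @property
    def n_perm(self) -> int:
        return len(self.null)


def count_breakpoint_reuse(
    events: list[CNVEvent],
    genome: GenomeLayout,
    resolution: int = 100_000,
    exclude_chrom_ends: bool = True,
    exclude_m5: bool = True,
    exclude_within_sample: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Count breakpoints used by two or more independent events.

    A breakpoint is an event boundary assigned to its ``resolution``-sized
    bin. Breakpoints at chromosome starts/ends, boundaries of cassette
    (``m5_component``) events, and repeated use by events sharing a carrier
    sample (counted once) are excluded per the stated rules. Returns the
    reused-breakpoint count and a per-breakpoint usage table. Invariant to
    event input order.
    """
    usage: dict[tuple[str, int], list[CNVEvent]] = {}
    for ev in sorted(events, key=lambda e: e.extended_id):
        if exclude_m5 and ev.m5_component:
            continue
        chrom_len = genome.n_bins_of(ev.chrom) * genome.bin_size
        for pos in (ev.start, ev.end):
            if exclude_chrom_ends and (pos <= 0 or pos >= chrom_len):
                continue
            key = (ev.chrom, pos // resolution)
            usage.setdefault(key, []).append(ev)

    rows = []
    reused = 0
    for (chrom, bin_idx), evs in sorted(usage.items()):
        n_uses = _independent_uses(evs) if exclude_within_sample else len(evs)
        if n_uses >= 2:
            reused += 1
        rows.append((chrom, bin_idx * resolution, n_uses,
                     ",".join(e.extended_id for e in evs)))
    table = pd.DataFrame(rows, columns=["chrom", "position", "n_uses", "events"])
    return reused, table


def _independent_uses(events: list[CNVEvent]) -> int:
    """Uses of one breakpoint, counting events that share a carrier sample
    once (connected components of the shared-carrier graph)."""
    n = len(events)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if events[i].carrier_set & events[j].carrier_set:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    return len({find(i) for i in range(n)})


def clustering_stats(events: list[CNVEvent]) -> tuple[int, int]:
    """(number of overlapping independent event pairs, total pairwise
    intersection length in bp)."""
    n_pairs = 0
    total = 0
    for a, b in itertools.combinations(events, 2):
        ov = 0
        if a.chrom == b.chrom:
            ov = max(0, min(a.end, b.end) - max(a.start, b.start))
        if ov > 0:
            n_pairs += 1
            total += ov
    return n_pairs, total


def _to_circular(events: list[CNVEvent], genome: GenomeLayout) -> list[tuple[int, int]]:
    """Events as (start_bin, length_bins) on the circular bin axis."""
    offsets = genome.chrom_offsets()
    out = []
    for ev in events:
        start = offsets[ev.chrom] + ev.start // genome.bin_size
        length = max(ev.length // genome.bin_size, 1)
        out.append((start, length))
    return out


def _from_circular(
    placements: list[tuple[int, int]], genome: GenomeLayout, template: list[CNVEvent]
) -> list[CNVEvent]:
    """Rebuild events from circular placements; wrap-arounds split in two."""
    bins = genome.bins()
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    n_total = genome.n_bins
    bs = genome.bin_size
    out = []
    for (start_bin, length), tmpl in zip(placements, template):
        arcs = []
        end_bin = start_bin + length
        if end_bin <= n_total:
            arcs.append((start_bin, end_bin))
        else:
            arcs.append((start_bin, n_total))
            arcs.append((0, end_bin - n_total))
        for k, (lo, hi) in enumerate(arcs):
            pos = lo
            while pos < hi:
                chrom = chroms[pos]
                j = pos
                while j < hi and chroms[j] == chrom:
                    j += 1
                out.append(CNVEvent(
                    basic_id=tmpl.basic_id,
                    extended_id=f"{tmpl.extended_id}~{k}~{chrom}",
                    type=tmpl.type,
                    chrom=str(chrom),
                    start=int(starts[pos]),
                    end=int(starts[j - 1]) + bs,
                    carriers=dict(tmpl.carriers),
                    m5_component=tmpl.m5_component,
                ))
                pos = j
    return out


def circular_permutation_null(
    events: list[CNVEvent],
    genome: GenomeLayout,
    statistic,
    n_perm: int = 2000,
    seed: int = 0,
    permute_unit: str = "event",
) -> ReuseResult:
    """Permutation null for any statistic over an event list.

    For each replicate every event (or linkage group, with
    ``permute_unit="group"``) is given a uniform random start bin on the
    circularised genome, keeping its length; the statistic is recomputed on
    the relocated events. Deterministic per seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if permute_unit not in ("event", "group"):
        raise ValueError(f"unknown permute unit {permute_unit!r}")
    n_total = genome.n_bins
    circ = _to_circular(events, genome)
    for (_, length), ev in zip(circ, events):
        if length > n_total:
            raise ValueError(f"event {ev.extended_id} longer than the genome")

    if permute_unit == "group":
        group_of = [
            ev.linkage_group if ev.linkage_group is not None else f"solo{idx}"
            for idx, ev in enumerate(events)
        ]
        group_ids = sorted(set(group_of), key=str)
    observed = float(statistic(events))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        if permute_unit == "event":
            new_starts = rng.integers(0, n_total, size=len(events))
        else:
            shift_of = {g: int(rng.integers(0, n_total)) for g in group_ids}
            new_starts = np.array([
                (circ[idx][0] + shift_of[group_of[idx]]) % n_total
                for idx in range(len(events))
            ])
        placements = [
            (int(s), length) for s, (_, length) in zip(new_starts, circ)
        ]
        null[r] = float(statistic(_from_circular(placements, genome, events)))
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return ReuseResult(observed=observed, null=null, p_value=p)
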