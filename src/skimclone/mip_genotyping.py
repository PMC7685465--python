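"""Targeted-panel (MIP) genotyping.

Calls variant presence/absence/ambiguous from per-probe read counts with
purity- and contamination-aware thresholds, applies the matrix-level filters,
computes probe QC/rebalancing factors, and fits allele-specific copy-number
genotypes from VAFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MipReadTable",
    "MipGenotypeMatrix",
    "AllelicGenotype",
    "expected_variant_reads",
    "estimate_contamination_threshold",
    "call_genotype",
    "call_matrix",
    "filter_matrix",
    "probe_rebalance",
    "expected_vaf",
    "best_fit_genotype",
]

PRESENT = "1"
ABSENT = "0"
AMBIGUOUS = "N"


@dataclass
class MipReadTable:
    """Per (sample, probe) total and variant-supporting read counts.

    ``total`` and ``variant`` are DataFrames indexed by probe id with one
    column per sample; 0 <= variant <= total elementwise.
    """

    total: pd.DataFrame
    variant: pd.DataFrame
    probe_meta: pd.DataFrame | None = None  # target coordinate, ref/alt alleles

    def __post_init__(self) -> None:
        if not self.total.index.equals(self.variant.index) or list(
            self.total.columns
        ) != list(self.variant.columns):
            raise ValueError("total and variant tables must share probe/sample axes")
        if ((self.variant.to_numpy() > self.total.to_numpy()).any()
                or (self.variant.to_numpy() < 0).any()):
            raise ValueError("variant reads must satisfy 0 <= variant <= total")

    @property
    def samples(self) -> list[str]:
        return list(self.total.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.total.index)

    def merged_with(self, other: "MipReadTable") -> "MipReadTable":
        """Sum read counts across duplicate sequencing runs."""
        return MipReadTable(
            total=self.total.add(other.total, fill_value=0).astype(int),
            variant=self.variant.add(other.variant, fill_value=0).astype(int),
            probe_meta=self.probe_meta,
        )


@dataclass
class MipGenotypeMatrix:
    """Per (sample, probe) call from the 3-symbol alphabet {1, 0, N}."""

    calls: pd.DataFrame  # probes x samples, values in {"1", "0", "N"}

    def __post_init__(self) -> None:
        bad = ~self.calls.isin([PRESENT, ABSENT, AMBIGUOUS])
        if bad.to_numpy().any():
            raise ValueError("calls must be '1', '0' or 'N'")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.calls.index)


@dataclass
class AllelicGenotype:
    ref: float
    alt: float
    residual: float

    @property
    def total(self) -> float:
        return self.ref + self.alt

    def __str__(self) -> str:
        return f"{self.ref:.1f}|{self.alt:.1f}"


def expected_variant_reads(total_reads: float, purity: float) -> float:
    """Expected variant-supporting reads at a heterozygous diploid site:
    ``total_reads * purity * 0.5``."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    return total_reads * purity * 0.5


def estimate_contamination_threshold(
    read_table: MipReadTable,
    known_absent_sites: dict[str, list[str]],
    quantile: float = 0.95,
    floor: int = 3,
) -> dict[str, int]:
    """Per-sample contaminating-read threshold.

    Takes the ceiling of the ``quantile`` of variant-read counts at probes
    known to be absent from the sample's lineage, with a minimum of
    ``floor``. Samples with no listed absent sites fall back to the floor.
    """
    out: dict[str, int] = {}
    for sample in read_table.samples:
        absent = known_absent_sites.get(sample, [])
        absent = [p for p in absent if p in read_table.variant.index]
        if not absent:
            out[sample] = floor
            continue
        counts = read_table.variant.loc[absent, sample].to_numpy(dtype=float)
        thr = math.ceil(np.quantile(counts, quantile, method="higher"))
        out[sample] = max(thr, floor)
    return out


def call_genotype(
    variant_reads: int,
    total_reads: int,
    purity: float,
    threshold: int,
) -> str:
    """Three-tier presence call.

    With E = expected_variant_reads(total_reads, purity):
      E >= 10:     present if variant_reads > threshold; N if
                   threshold >= variant_reads > 2; absent if variant_reads <= 2
      5 <= E < 10: present if variant_reads > threshold, else N
      E < 5:       N
    Threshold comparison is strict, per the decision tree.
    """
    if variant_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    e = expected_variant_reads(total_reads, purity)
    if e >= 10:
        if variant_reads > threshold:
            return PRESENT
        if variant_reads > 2:
            return AMBIGUOUS
        return ABSENT
    if e >= 5:
        return PRESENT if variant_reads > threshold else AMBIGUOUS
    return AMBIGUOUS


def call_matrix(
    read_table: MipReadTable,
    purities: dict[str, float],
    thresholds: dict[str, int],
) -> MipGenotypeMatrix:
    """Apply :func:`call_genotype` over a whole read table."""
    calls = pd.DataFrame(index=read_table.total.index, columns=read_table.samples,
                         dtype=object)
    for sample in read_table.samples:
        rho = purities[sample]
        thr = thresholds[sample]
        tot = read_table.total[sample].to_numpy()
        var = read_table.variant[sample].to_numpy()
        calls[sample] = [
            call_genotype(int(v), int(t), rho, thr) for v, t in zip(var, tot)
        ]
    return MipGenotypeMatrix(calls=calls)


def filter_matrix(
    genotypes: MipGenotypeMatrix,
    normal_calls: MipGenotypeMatrix | None = None,
    max_variant_n_frac: float = 0.5,
    max_sample_n_frac: float = 0.5,
) -> MipGenotypeMatrix:
    """Matrix-level filters, in order: drop variants present in any normal;
    drop variants with > 50% N across samples; drop samples with > 50% N
    across the remaining variants."""
    calls = genotypes.calls.copy()
    if normal_calls is not None:
        in_normals = (normal_calls.calls == PRESENT).any(axis=1)
        drop = [p for p in calls.index if p in in_normals.index and in_normals[p]]
        calls = calls.drop(index=drop)
    if len(calls):
        n_frac = (calls == AMBIGUOUS).mean(axis=1)
        calls = calls.loc[n_frac <= max_variant_n_frac]
    if len(calls):
        n_frac = (calls == AMBIGUOUS).mean(axis=0)
        calls = calls.loc[:, n_frac <= max_sample_n_frac]
    return MipGenotypeMatrix(calls=calls)


def probe_rebalance(
    probe_medians: dict[str, float],
    overall_median: float,
    off_target_ratios: dict[str, float] | None = None,
    max_log10_fold: float = 1.5,
    max_off_target: float = 0.5,
) -> tuple[dict[str, float], list[str]]:
    """Per-probe rebalancing factors and a removal list.

    factor_p = sqrt(overall_median / probe_median). Probes more than
    ``max_log10_fold`` log10-fold above the overall median, probes with zero
    coverage, and probes with off-target ratio above ``max_off_target`` are
    listed for removal (with no factor).
    """
    if overall_median <= 0:
        raise ValueError("overall median must be positive")
    factors: dict[str, float] = {}
    removals: list[str] = []
    for probe, med in probe_medians.items():
        off = (off_target_ratios or {}).get(probe, 0.0)
        if med <= 0 or off > max_off_target:
            removals.append(probe)
            continue
        if math.log10(med / overall_median) > max_log10_fold:
            removals.append(probe)
            continue
        factors[probe] = math.sqrt(overall_median / med)
    return factors, removals


def expected_vaf(
    tumour_genotype: tuple[float, float],
    purity: float,
    host_genotype: tuple[float, float] = (2.0, 0.0),
) -> float:
    """Expected VAF of a mixture of host and tumour cells.

    ``(H_alt (1-p) + T_alt p) / (H_total (1-p) + T_total p)`` with genotypes
    given as (ref copies, alt copies).
    """
    h_ref, h_alt = host_genotype
    t_ref, t_alt = tumour_genotype
    denom = (h_ref + h_alt) * (1.0 - purity) + (t_ref + t_alt) * purity
    if denom <= 0:
        raise ValueError("undefined VAF: zero total copy number in mixture")
    return (h_alt * (1.0 - purity) + t_alt * purity) / denom


def best_fit_genotype(
    total_cn: float,
    observed_vaf: float,
    purity: float,
    host_genotype: tuple[float, float] = (2.0, 0.0),
) -> AllelicGenotype:
    """Half-integer allele-specific genotype minimising |expected - observed|
    VAF over the grid (total_cn - a | a), a in {0, 0.5, ..., total_cn}.
    Ties break toward the smaller alt copy number."""
    if total_cn < 0:
        raise ValueError("total copy number must be >= 0")
    n_steps = int(round(total_cn * 2))
    best: AllelicGenotype | None = None
    for step in range(n_steps + 1):
        alt = step / 2.0
        ref = total_cn - alt
        resid = abs(expected_vaf((ref, alt), purity, host_genotype) - observed_vaf)
        if best is None or resid < best.residual - 1e-15:
            best = AllelicGenotype(ref=ref, alt=alt, residual=resid)
    return best
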