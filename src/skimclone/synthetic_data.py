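"""Synthetic cohort generation.

Generates clone trees with clade structure, scatters ground-truth CNV /
whole-genome-duplication / cassette-loss events on branches, and renders
bin-count matrices (Poisson noise at skim coverage with host-cell dilution
by purity) and targeted-panel read tables (with cross-contamination), so
every downstream stage is testable without external data.

All stochastic operations take an explicit integer seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth_normalization import BinCountMatrix, GenomeLayout
from .mip_genotyping import MipReadTable

__all__ = [
    "CloneTree",
    "TruthEvent",
    "SampleTruth",
    "default_genome",
    "default_m5_cassette",
    "simulate_clone_tree",
    "scatter_events",
    "render_bin_counts",
    "render_mip_reads",
    "true_copy_number",
    "write_bin_counts_tsv",
    "read_bin_counts_tsv",
]

CNV_KINDS = ("gain", "loss", "back_mutation", "wgd", "m5_loss", "snv")


def default_genome(bin_size: int = 100_000) -> GenomeLayout:
    """Six ~9-Mb autosomes plus a 6-Mb X: 600 bins at the default bin size."""
    lengths = {str(i): 9_000_000 for i in range(1, 7)}
    lengths["X"] = 6_000_000
    return GenomeLayout(names=tuple(list(map(str, range(1, 7))) + ["X"]),
                        lengths=lengths, bin_size=bin_size)


def default_m5_cassette(genome: GenomeLayout) -> list[tuple[str, int, int]]:
    """Three fixed intervals lost together, one each on chromosomes 2, 5 and X
    (mirroring a derived chromosome assembled from three donor fragments)."""
    for chrom in ("2", "5", "X"):
        if chrom not in genome.lengths:
            raise ValueError("genome lacks the chromosomes needed for the cassette")
    return [
        ("2", 0, 1_000_000),
        ("5", 2_000_000, 3_000_000),
        ("X", 4_000_000, 5_000_000),
    ]


@dataclass(frozen=True)
class TruthEvent:
    """A ground-truth mutational event on a branch."""

    kind: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    delta: int = 0
    m5: bool = False

    def __post_init__(self) -> None:
        if self.kind not in CNV_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("gain", "loss", "back_mutation", "m5_loss"):
            if self.start is None or self.end is None or self.chrom is None:
                raise ValueError(f"{self.kind} events need an interval")
            if self.start >= self.end:
                raise ValueError("interval start must precede end")


@dataclass
class CloneTree:
    """Rooted clone phylogeny with per-branch events and clade-labelled tips."""

    parent: dict[str, str | None]
    tips: tuple[str, ...]
    clade_labels: dict[str, str]
    branch_events: dict[str, list[TruthEvent]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have a single root")
        for tip in self.tips:
            if tip not in self.parent:
                raise ValueError(f"tip {tip!r} not in tree")
        # acyclicity + reachability via the ancestor walk
        for tip in self.tips:
            seen = set()
            node = tip
            while node is not None:
                if node in seen:
                    raise ValueError("cycle detected in parent map")
                seen.add(node)
                node = self.parent[node]

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                ch[p].append(n)
        return ch

    def path_from_root(self, tip: str) -> list[str]:
        """Nodes from root down to (and including) ``tip``."""
        path = []
        node: str | None = tip
        while node is not None:
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def tips_below(self, node: str) -> set[str]:
        ch = self.children()
        stack, out = [node], set()
        while stack:
            n = stack.pop()
            if n in self.tips:
                out.add(n)
            stack.extend(ch[n])
        return out

    def branches(self) -> list[str]:
        """Non-root nodes; each identifies the branch from its parent."""
        return [n for n, p in self.parent.items() if p is not None]

    def to_newick(self) -> str:
        ch = self.children()

        def fmt(node: str) -> str:
            if not ch[node]:
                label = self.clade_labels.get(node, "")
                return f"{node}|{label}" if label else node
            return "(" + ",".join(fmt(c) for c in ch[node]) + ")" + node
        return fmt(self.root) + ";"


@dataclass
class SampleTruth:
    """Ground truth for one tip: purity, ploidy, per-bin copy number and
    panel-variant presence."""

    sample: str
    rho: float
    psi: int
    copy_number: np.ndarray
    mip_presence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("purity must be in (0, 1]")
        if (self.copy_number < 0).any():
            raise ValueError("copy numbers must be >= 0")


def _random_binary_tree(labels: list[str], prefix: str, rng: np.random.Generator,
                        parent: dict[str, str | None], counter: list[int]) -> str:
    """Join ``labels`` into a random binary subtree; returns its root id."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = f"{prefix}{counter[0]}"
        counter[0] += 1
        parent[nodes[i]] = new
        parent[nodes[j]] = new
        parent[new] = None
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    return nodes[0]


def simulate_clone_tree(n_tips: int, n_clades: int, seed: int) -> CloneTree:
    """Random rooted binary tree whose tips partition into ``n_clades``
    monophyletic, labelled groups. Deterministic for a fixed seed."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if n_clades > n_tips:
        raise ValueError("n_clades cannot exceed n_tips")
    if n_clades < 1:
        raise ValueError("n_clades must be >= 1")
    rng = np.random.default_rng(seed)
    tips = [f"S{i:03d}" for i in range(n_tips)]
    sizes = np.full(n_clades, n_tips // n_clades)
    sizes[: n_tips % n_clades] += 1
    parent: dict[str, str | None] = {t: None for t in tips}
    counter = [0]
    clade_roots = []
    clade_labels: dict[str, str] = {}
    pos = 0
    for c in range(n_clades):
        members = tips[pos: pos + sizes[c]]
        pos += sizes[c]
        label = f"clade{c + 1:02d}"
        for t in members:
            clade_labels[t] = label
        clade_roots.append(
            _random_binary_tree(members, "N", rng, parent, counter)
            if len(members) > 1 else members[0]
        )
    root = (
        _random_binary_tree(clade_roots, "B", rng, parent, counter)
        if len(clade_roots) > 1 else clade_roots[0]
    )
    parent[root] = None
    return CloneTree(parent=parent, tips=tuple(tips), clade_labels=clade_labels)


def _align(pos: int, bin_size: int) -> int:
    return (pos // bin_size) * bin_size


def scatter_events(
    tree: CloneTree,
    genome: GenomeLayout,
    cnv_rate: float,
    length_log_mean: float = 2_000_000,
    length_log_sd: float = 0.5,
    hotspot_positions: list[tuple[str, int]] | None = None,
    hotspot_weight: float = 0.0,
    m5_loss_rate: float = 0.0,
    wgd_probability: float = 0.0,
    seed: int = 0,
    min_length: int = 500_000,
    cassette: list[tuple[str, int, int]] | None = None,
) -> CloneTree:
    """Scatter ground-truth events on the branches of a clone tree.

    Per branch: CNV count ~ Poisson(``cnv_rate``); lengths log-normal with
    median ``length_log_mean`` truncated at ``min_length``; a
    ``hotspot_weight`` fraction of events reuse hotspot start positions;
    cassette losses occur with probability ``m5_loss_rate`` and place the
    fixed three-component cassette; whole-genome duplications occur with
    probability ``wgd_probability``. Returns a new tree with
    ``branch_events`` populated. Deterministic per seed.
    """
    if cnv_rate < 0 or m5_loss_rate < 0 or wgd_probability < 0:
        raise ValueError("rates must be >= 0")
    if genome.n_bins == 0:
        raise ValueError("genome has no bins")
    rng = np.random.default_rng(seed)
    bin_size = genome.bin_size
    cassette = cassette or default_m5_cassette(genome)
    chrom_lens = {c: genome.n_bins_of(c) * bin_size for c in genome.names}
    chroms = list(genome.names)
    weights = np.array([chrom_lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    events: dict[str, list[TruthEvent]] = {}
    for branch in tree.branches():
        evs: list[TruthEvent] = []
        for _ in range(rng.poisson(cnv_rate)):
            length = float(np.exp(np.log(length_log_mean)
                                  + length_log_sd * rng.standard_normal()))
            length = max(_align(int(length), bin_size), min_length)
            if hotspot_positions and rng.random() < hotspot_weight:
                chrom, start = hotspot_positions[rng.integers(len(hotspot_positions))]
                start = _align(start, bin_size)
            else:
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                max_start = chrom_lens[chrom] - min_length
                start = _align(int(rng.integers(0, max(max_start, bin_size))), bin_size)
            end = min(start + length, chrom_lens[chrom])
            if end - start < min_length:
                start = max(end - min_length, 0)
            kind = "gain" if rng.random() < 0.5 else "loss"
            evs.append(TruthEvent(kind=kind, chrom=chrom, start=int(start),
                                  end=int(end), delta=1 if kind == "gain" else -1))
        if rng.random() < m5_loss_rate:
            for chrom, lo, hi in cassette:
                evs.append(TruthEvent(kind="m5_loss", chrom=chrom, start=lo,
                                      end=hi, delta=-1, m5=True))
        if rng.random() < wgd_probability:
            evs.append(TruthEvent(kind="wgd"))
        events[branch] = evs
    return replace(tree, branch_events=events)


def true_copy_number(tree: CloneTree, genome: GenomeLayout, tip: str) -> tuple[np.ndarray, int]:
    """Per-bin true tumour copy number and baseline ploidy for one tip,
    accumulated along the root-to-tip path."""
    bins = genome.bins()
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    cn = np.full(genome.n_bins, 2, dtype=float)
    psi = 2
    for node in tree.path_from_root(tip):
        for ev in tree.branch_events.get(node, []):
            if ev.kind == "wgd":
                cn = cn * 2
                psi = 4
            elif ev.kind in ("gain", "loss", "back_mutation", "m5_loss"):
                hit = (chroms == ev.chrom) & (starts >= ev.start) & (starts < ev.end)
                cn[hit] = np.maximum(cn[hit] + ev.delta, 0)
    return cn, psi


def render_bin_counts(
    tree: CloneTree,
    genome: GenomeLayout,
    purity_map: dict[str, float],
    mean_reads_per_bin: float = 100.0,
    n_normals: int = 10,
    bias_dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[BinCountMatrix, BinCountMatrix, dict[str, SampleTruth]]:
    """Render tumour and normal bin-count matrices plus per-tip truth.

    A per-bin multiplicative bias b_j ~ Gamma(shape 1/d^2, mean 1) is shared
    across all samples (d = ``bias_dispersion``; d = 0 gives b_j = 1).
    Tumour counts in bin j are Poisson with mean
    ``mean_reads_per_bin * b_j * (2 (1 - rho) + rho CN_j) / psi_norm`` where
    ``psi_norm`` is the sample's autosomal median of the dilution factor, so
    each sample's autosomal median expectation equals ``mean_reads_per_bin``.
    Normals use CN_j = 2 and rho = 1.
    """
    if mean_reads_per_bin < 1:
        raise ValueError("mean_reads_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    n_bins = genome.n_bins
    if bias_dispersion > 0:
        shape = 1.0 / bias_dispersion**2
        bias = rng.gamma(shape, 1.0 / shape, size=n_bins)
    else:
        bias = np.ones(n_bins)
    autosomal = genome.autosome_mask()

    tumour_cols = {}
    truths: dict[str, SampleTruth] = {}
    for tip in tree.tips:
        rho = purity_map[tip]
        cn, psi = true_copy_number(tree, genome, tip)
        dilution = 2.0 * (1.0 - rho) + rho * cn
        psi_norm = float(np.median(dilution[autosomal]))
        lam = mean_reads_per_bin * bias * dilution / psi_norm
        tumour_cols[tip] = rng.poisson(lam)
        truths[tip] = SampleTruth(sample=tip, rho=rho, psi=psi, copy_number=cn)

    normal_cols = {
        f"H{i:03d}": rng.poisson(mean_reads_per_bin * bias)
        for i in range(n_normals)
    }
    mask = np.zeros(n_bins, dtype=bool)
    tumours = BinCountMatrix(genome=genome, counts=pd.DataFrame(tumour_cols),
                             mask=mask.copy())
    normals = BinCountMatrix(genome=genome, counts=pd.DataFrame(normal_cols),
                             mask=mask.copy())
    return tumours, normals, truths


def render_mip_reads(
    tree: CloneTree,
    n_probes: int,
    median_depth: float,
    purity_map: dict[str, float],
    contamination_rate: float = 0.0,
    seed: int = 0,
    depth_shape: float = 8.0,
    truths: dict[str, SampleTruth] | None = None,
) -> tuple[MipReadTable, pd.DataFrame]:
    """Render a panel read table with known variant placement.

    Each probe's variant is assigned to a uniformly random branch and is
    present in every tip below it. Total reads per probe are
    negative-binomial around ``median_depth``; variant reads are
    Binomial(total, rho/2) where present, Binomial(total,
    ``contamination_rate``) where absent. Returns the read table and the
    truth presence matrix (probes x samples, bool).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0 <= contamination_rate < 1:
        raise ValueError("contamination_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    branches = tree.branches()
    probes = [f"MIP{i:04d}" for i in range(n_probes)]
    presence = pd.DataFrame(False, index=probes, columns=list(tree.tips))
    for probe in probes:
        branch = branches[rng.integers(len(branches))]
        for tip in tree.tips_below(branch):
            presence.loc[probe, tip] = True

    total = pd.DataFrame(index=probes, columns=list(tree.tips), dtype=int)
    variant = pd.DataFrame(index=probes, columns=list(tree.tips), dtype=int)
    for tip in tree.tips:
        rho = purity_map[tip]
        # gamma-poisson mixture: NB with mean ~= median_depth
        lam = rng.gamma(depth_shape, median_depth / depth_shape, size=n_probes)
        tot = rng.poisson(lam)
        pres = presence[tip].to_numpy()
        p = np.where(pres, rho / 2.0, contamination_rate)
        var = rng.binomial(tot, p)
        total[tip] = tot
        variant[tip] = var
    if truths is not None:
        for tip in tree.tips:
            truths[tip].mip_presence = presence[tip].to_numpy()
    table = MipReadTable(total=total, variant=variant)
    return table, presence


def write_bin_counts_tsv(matrix: BinCountMatrix, path) -> None:
    """Bin-count matrix as TSV (0-based half-open coordinates)."""
    df = matrix.genome.bins()
    df = pd.concat([df, matrix.counts.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)


def read_bin_counts_tsv(path, genome: GenomeLayout) -> BinCountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    counts = df.drop(columns=["chrom", "start", "end"])
    return BinCountMatrix(genome=genome, counts=counts,
                          mask=np.zeros(len(df), dtype=bool))
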