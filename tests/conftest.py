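import numpy as np
import pytest

from skimclone.depth_normalization import GenomeLayout, LogRProfile
from skimclone.cnv_catalogue import CladeTree


@pytest.fixture
def small_genome() -> GenomeLayout:
    """Two chromosomes, 10 + 5 bins of 100 kb."""
    return GenomeLayout(names=("1", "2"), lengths={"1": 1_000_000, "2": 500_000})


@pytest.fixture
def flat_profile(small_genome) -> LogRProfile:
    return LogRProfile(
        sample="t1",
        genome=small_genome,
        values=np.zeros(small_genome.n_bins),
        mask=np.zeros(small_genome.n_bins, dtype=bool),
    )


def make_profile(genome, values, sample="t1", mask=None, counts=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(len(values), dtype=bool)
    return LogRProfile(sample=sample, genome=genome, values=values, mask=mask,
                       raw_counts=counts)


def called_states_per_bin(genome, segments):
    """Expand a sample's segments into a per-bin called-state vector."""
    states = np.full(genome.n_bins, np.nan)
    offsets = genome.chrom_offsets()
    for seg in segments:
        lo = offsets[seg.chrom] + seg.start // genome.bin_size
        hi = offsets[seg.chrom] + seg.end // genome.bin_size
        states[lo:hi] = seg.cn_state
    return states


def event_bins(genome, chrom, start, end):
    offset = genome.chrom_offsets()[chrom]
    return offset + start // genome.bin_size, offset + end // genome.bin_size


def recovered_event_fraction(tree, genome, truths, called, min_match=0.9):
    """Fraction of true clonal CNV events recovered with the correct state.

    An event is recovered for a carrier tip when >= ``min_match`` of its bins
    are called at the true copy number.
    """
    n_events = n_recovered = 0
    for tip in tree.tips:
        truth = truths[tip]
        states = called_states_per_bin(genome, called[tip])
        path = set(tree.path_from_root(tip))
        for node in path:
            for ev in tree.branch_events.get(node, []):
                if ev.kind not in ("gain", "loss"):
                    continue
                lo, hi = event_bins(genome, ev.chrom, ev.start, ev.end)
                true_cn = truth.copy_number[lo:hi]
                match = np.mean(states[lo:hi] == true_cn)
                n_events += 1
                n_recovered += match >= min_match
    return n_recovered / max(n_events, 1), n_events


@pytest.fixture
def cherry_clade_tree() -> CladeTree:
    """((A,B),(C,D)) over clades, one sample per clade."""
    return CladeTree(
        parent={"I0": None, "I1": "I0", "I2": "I0",
                "A": "I1", "B": "I1", "C": "I2", "D": "I2"},
        sample_clade={"sA": "A", "sB": "B", "sC": "C", "sD": "D"},
    )
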