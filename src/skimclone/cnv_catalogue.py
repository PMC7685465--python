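"""Cross-sample CNV catalogue.

Consolidates per-sample copy-number segments into cohort-level events with a
recurrence/back-mutation nomenclature (R / BM / PBM / G#CN# / L#CN#
suffixes), groups co-occurring events into linkage groups, detects losses of
a configured multi-component cassette, runs the opportunity-corrected
enrichment test, computes per-sample burdens and genome sizes with their
time regressions, and classifies multi-tumour hosts as single infection or
coinfection.

Phylogenetic independence of recurrent events is decided by parsimony on a
clade tree: a minimum-change binary labelling that, among equally
parsimonious labellings, has the fewest independent origins (ties resolve
toward a single origin).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CNVEvent",
    "CladeTree",
    "BurdenRecord",
    "min_origin_labelling",
    "consolidate_events",
    "link_events",
    "detect_m5_loss",
    "count_independent_m5_losses",
    "fisher_exact_2x2",
    "m5_enrichment_test",
    "burden_and_genome_size",
    "rate_regression",
    "coinfection_classify",
]


@dataclass
class CladeTree:
    """Rooted tree over clade-group labels plus a sample -> clade map."""

    parent: dict[str, str | None]
    sample_clade: dict[str, str]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("clade tree must have a single root")
        for sample, clade in self.sample_clade.items():
            if clade not in self.parent:
                raise ValueError(f"sample {sample!r} maps to unknown clade {clade!r}")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                ch[p].append(n)
        return ch

    def leaves(self) -> list[str]:
        ch = self.children()
        return [n for n, c in ch.items() if not c]

    def samples_in(self, clades: set[str]) -> set[str]:
        return {s for s, c in self.sample_clade.items() if c in clades}

    @classmethod
    def from_clone_tree(cls, tree) -> "CladeTree":
        """Collapse a clone tree with monophyletic clade labels into a tree
        over the clade labels."""
        ch = tree.children()

        def clades_below(node: str) -> set[str]:
            if node in tree.tips:
                return {tree.clade_labels[node]}
            out: set[str] = set()
            for c in ch[node]:
                out |= clades_below(c)
            return out

        parent: dict[str, str | None] = {}
        counter = itertools.count()

        def build(node: str, parent_label: str | None) -> str:
            below = clades_below(node)
            if len(below) == 1:
                label = next(iter(below))
                if label not in parent:
                    parent[label] = parent_label
                return label
            label = f"I{next(counter)}"
            parent[label] = parent_label
            for c in ch[node]:
                build(c, label)
            return label

        build(tree.root, None)
        sample_clade = dict(tree.clade_labels)
        return cls(parent=parent, sample_clade=sample_clade)


@dataclass
class CNVEvent:
    """A phylogenetically independent cross-sample copy-number event."""

    basic_id: str
    extended_id: str
    type: str               # gain | loss
    chrom: str
    start: int
    end: int
    carriers: dict[str, float]   # sample -> copy-number state
    clades: tuple[str, ...] = ()
    linkage_group: int | None = None
    cell_line_only: bool = False
    post_wgd: bool = False
    m5_component: bool = False
    subclonal: bool = False
    parent_id: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def carrier_set(self) -> frozenset[str]:
        return frozenset(self.carriers)


@dataclass
class BurdenRecord:
    sample: str
    burden: float
    genome_size: int
    date: float | None = None
    clade: str | None = None


# ---------------------------------------------------------------------------
# parsimony machinery

def min_origin_labelling(
    tree: CladeTree, carrier_clades: set[str]
) -> tuple[dict[str, int], int, list[str], list[str]]:
    """Minimum-change binary labelling with the fewest independent origins.

    Leaf state is 1 for clades in ``carrier_clades``, 0 otherwise. Among all
    labellings minimising the number of mutational events (state-change
    edges, plus one when the root itself is labelled 1), one minimising the
    number of 0 -> 1 transitions (origins) is chosen; remaining ties prefer
    ancestral absence. Returns (labelling, n_events, origin_nodes,
    loss_nodes) where origin/loss nodes are the child nodes of the 0 -> 1 and
    1 -> 0 edges (the root counts as an origin when labelled 1).
    """
    ch = tree.children()
    INF = (10**9, 10**9)
    cost: dict[str, list[tuple[int, int]]] = {}

    order: list[str] = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(ch[n])
    for node in reversed(order):
        if not ch[node]:
            state = 1 if node in carrier_clades else 0
            cost[node] = [(0, 0) if state == 0 else INF,
                          (0, 0) if state == 1 else INF]
        else:
            c0 = [0, 0]
            c1 = [0, 0]
            for child in ch[node]:
                k0, k1 = cost[child]
                # parent 0: child stays 0 (free) or gains (change + origin)
                stay0 = k0
                gain = (k1[0] + 1, k1[1] + 1)
                best0 = min(stay0, gain)
                c0[0] += best0[0]
                c0[1] += best0[1]
                # parent 1: child stays 1 (free) or reverts (change, no origin)
                stay1 = k1
                lose = (k0[0] + 1, k0[1])
                best1 = min(stay1, lose)
                c1[0] += best1[0]
                c1[1] += best1[1]
            cost[node] = [tuple(c0), tuple(c1)]

    r0, r1 = cost[tree.root]
    # a root labelled 1 is itself a mutational event and an origin
    root_as_origin = (r1[0] + 1, r1[1] + 1)
    root_state = 0 if r0 <= root_as_origin else 1

    labelling: dict[str, int] = {}
    origins: list[str] = []
    losses: list[str] = []

    def backtrace(node: str, state: int) -> None:
        labelling[node] = state
        for child in ch[node]:
            k0, k1 = cost[child]
            if state == 0:
                stay = k0
                switch = (k1[0] + 1, k1[1] + 1)
                child_state = 0 if stay <= switch else 1
                if child_state == 1:
                    origins.append(child)
            else:
                stay = k1
                switch = (k0[0] + 1, k0[1])
                child_state = 1 if stay <= switch else 0
                if child_state == 0:
                    losses.append(child)
            backtrace(child, child_state)

    if root_state == 1:
        origins.append(tree.root)
    backtrace(tree.root, root_state)
    n_events = r0[0] if root_state == 0 else r1[0] + 1
    return labelling, n_events, origins, losses


def _clades_below(tree: CladeTree, node: str) -> set[str]:
    ch = tree.children()
    out, stack = set(), [node]
    while stack:
        n = stack.pop()
        if not ch[n]:
            out.add(n)
        stack.extend(ch[n])
    return out


# ---------------------------------------------------------------------------
# consolidation

def _direction(state: float) -> str:
    return "gain" if state > 2 else "loss"


def consolidate_events(
    segments_by_sample: dict[str, list],
    clades: CladeTree,
    cell_line_samples: set[str] | None = None,
    wgd_samples: set[str] | None = None,
) -> list[CNVEvent]:
    """Consolidate final-state segments into independent cross-sample events.

    Segments sharing coordinates and direction are split into
    phylogenetically independent occurrences by parsimony on the clade tree;
    the second and later origins get R1, R2, ... suffixes. Back mutations
    implied by the parsimony labelling (a reversion edge inside a carrier
    subtree) are emitted as BM records of the parent event; an
    opposite-direction event strictly nested inside a parent event carried by
    a superset of clades is re-labelled as a PBM of that parent. States more
    than one step from baseline additionally produce per-step G#CN# / L#CN#
    records.
    """
    cell_line_samples = cell_line_samples or set()
    wgd_samples = wgd_samples or set()

    groups: dict[tuple, dict[str, float]] = {}
    subclonal_info: dict[tuple, set[str]] = {}
    for sample, segs in segments_by_sample.items():
        if sample not in clades.sample_clade:
            raise ValueError(f"carrier sample {sample!r} missing from clade map")
        for seg in segs:
            if seg.cn_state is None or seg.cn_state == 2:
                continue
            key = (seg.chrom, seg.start, seg.end, _direction(seg.cn_state))
            groups.setdefault(key, {})[sample] = seg.cn_state
            if seg.subclonal:
                subclonal_info.setdefault(key, set()).add(sample)

    events: list[CNVEvent] = []
    next_id = itertools.count(1)
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2], k[3])):
        chrom, start, end, direction = key
        carriers = groups[key]
        basic = f"CNV{next(next_id)}"
        carrier_clades = {clades.sample_clade[s] for s in carriers}
        labelling, _, origins, losses = min_origin_labelling(clades, carrier_clades)

        origin_records = []
        for origin in sorted(origins):
            below = _clades_below(clades, origin)
            members = below & carrier_clades
            samples = {
                s: st for s, st in carriers.items()
                if clades.sample_clade[s] in members
            }
            if samples:
                origin_records.append((origin, members, samples))

        for oi, (origin, members, samples) in enumerate(origin_records):
            suffix = "" if oi == 0 else f"R{oi}"
            ev = CNVEvent(
                basic_id=basic,
                extended_id=basic + suffix,
                type=direction,
                chrom=chrom,
                start=start,
                end=end,
                carriers=samples,
                clades=tuple(sorted(members)),
                cell_line_only=set(samples) <= cell_line_samples,
                post_wgd=bool(samples) and set(samples) <= wgd_samples,
                m5_component=False,
                subclonal=bool(subclonal_info.get(key, set()) & set(samples)),
            )
            events.append(ev)
            # back mutations inside this origin's subtree
            below_origin = _clades_below(clades, origin)
            my_losses = sorted({
                n for n in losses if _clades_below(clades, n) <= below_origin
            })
            for bi, loss_node in enumerate(my_losses):
                bm_clades = _clades_below(clades, loss_node)
                bm_samples = {
                    s: 2.0 for s, c in clades.sample_clade.items() if c in bm_clades
                }
                if not bm_samples:
                    continue
                events.append(CNVEvent(
                    basic_id=basic,
                    extended_id=f"{basic}{suffix}BM" + (str(bi) if bi else ""),
                    type="loss" if direction == "gain" else "gain",
                    chrom=chrom,
                    start=start,
                    end=end,
                    carriers=bm_samples,
                    clades=tuple(sorted(bm_clades)),
                    parent_id=basic + suffix,
                ))
            # amplitude steps beyond CN3 / below CN1
            extreme = {s: st for s, st in samples.items()
                       if (direction == "gain" and st > 3) or (direction == "loss" and st < 1)}
            if extreme:
                states = sorted({st for st in extreme.values()},
                                reverse=(direction == "loss"))
                for li, state in enumerate(states, start=1):
                    step_samples = {
                        s: st for s, st in extreme.items()
                        if (st >= state if direction == "gain" else st <= state)
                    }
                    tag = "G" if direction == "gain" else "L"
                    events.append(CNVEvent(
                        basic_id=basic,
                        extended_id=f"{basic}{suffix}{tag}{li}CN{state:g}",
                        type=direction,
                        chrom=chrom,
                        start=start,
                        end=end,
                        carriers=step_samples,
                        clades=tuple(sorted({clades.sample_clade[s] for s in step_samples})),
                        parent_id=basic + suffix,
                    ))

    _tag_partial_back_mutations(events, clades)
    return events


def _tag_partial_back_mutations(events: list[CNVEvent], clades: CladeTree) -> None:
    """Re-label opposite-direction events strictly nested inside a parent
    event whose carrier clades contain the child's as PBM of that parent."""
    for child in events:
        if child.parent_id is not None:
            continue
        for parent in events:
            if parent is child or parent.parent_id is not None:
                continue
            if parent.chrom != child.chrom or parent.type == child.type:
                continue
            nested = parent.start <= child.start and child.end <= parent.end \
                and child.length < parent.length
            if nested and set(child.clades) <= set(parent.clades):
                child.parent_id = parent.extended_id
                child.extended_id = parent.extended_id + "PBM"
                break


def link_events(events: list[CNVEvent]) -> list[CNVEvent]:
    """Assign linkage groups: events with identical carrier sets and the same
    direction share a group id."""
    keys: dict[tuple[frozenset, str], int] = {}
    for ev in events:
        key = (ev.carrier_set, ev.type)
        if key not in keys:
            keys[key] = len(keys) + 1
        ev.linkage_group = keys[key]
    return events


# ---------------------------------------------------------------------------
# M5 cassette

def detect_m5_loss(
    events: list[CNVEvent],
    mandatory: tuple[str, str],
    optional: tuple[str, ...],
) -> pd.DataFrame:
    """Per-sample cassette-loss status.

    A sample is cassette-lost iff it carries both mandatory component events
    and at least one optional component. A subclonal component state
    propagates a subclonal flag. Component ids match extended event ids.
    Matched component events are additionally tagged ``m5_component``.
    """
    if len(mandatory) != 2 or len(optional) < 1:
        raise ValueError("cassette config needs two mandatory components and >= 1 optional")
    by_id = {ev.extended_id: ev for ev in events}
    for cid in (*mandatory, *optional):
        if cid not in by_id:
            raise ValueError(f"cassette component {cid!r} not in event list")
    for cid in (*mandatory, *optional):
        by_id[cid].m5_component = True

    samples = sorted({s for ev in events for s in ev.carriers})
    rows = []
    for s in samples:
        has_mand = all(s in by_id[c].carriers for c in mandatory)
        opt_hits = [c for c in optional if s in by_id[c].carriers]
        lost = has_mand and bool(opt_hits)
        sub = lost and any(
            by_id[c].subclonal for c in (*mandatory, *opt_hits)
        )
        rows.append((s, lost, sub))
    return pd.DataFrame(rows, columns=["sample", "m5_lost", "subclonal"]).set_index("sample")


def count_independent_m5_losses(status: pd.DataFrame, clades: CladeTree) -> int:
    """Number of phylogenetically independent cassette losses, by parsimony
    on the lost/retained character over the clade tree."""
    lost_samples = set(status.index[status["m5_lost"]])
    lost_clades = {clades.sample_clade[s] for s in lost_samples
                   if s in clades.sample_clade}
    if not lost_clades:
        return 0
    _, _, origins, _ = min_origin_labelling(clades, lost_clades)
    return len(origins)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Returns (odds_ratio, p). p sums the probabilities of all tables with the
    observed margins that are at most as probable as the observed table
    (with a small relative tolerance, as in standard implementations).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = np.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c > 0 else np.nan
    )
    return odds, min(p, 1.0)


def m5_enrichment_test(
    losses_group1: int, opportunity_group1: int,
    losses_group2: int, opportunity_group2: int,
) -> dict[str, float]:
    """Opportunity-corrected enrichment of cassette losses between two groups.

    Opportunity is the summed per-lineage copy count of the cassette
    (1 diploid, 2 tetraploid); the test contrasts losses vs retained
    opportunity across the groups with a two-sided Fisher exact test.
    """
    for lo, op in ((losses_group1, opportunity_group1),
                   (losses_group2, opportunity_group2)):
        if op < 1:
            raise ValueError("each group needs opportunity >= 1")
        if lo > op:
            raise ValueError("losses cannot exceed opportunity")
    table = [
        [losses_group1, opportunity_group1 - losses_group1],
        [losses_group2, opportunity_group2 - losses_group2],
    ]
    odds, p = fisher_exact_2x2(table)
    return {"odds_ratio": odds, "p": p, "table": table}


# ---------------------------------------------------------------------------
# burdens and rates

def burden_and_genome_size(
    sample: str,
    events: list[CNVEvent],
    haploid_size: int,
    date: float | None = None,
    clade: str | None = None,
    clonal_only: bool = True,
) -> BurdenRecord:
    """Per-sample burden (linkage groups; post-WGD groups count half) and
    genome size (2 x haploid + gain widths - loss widths, clonal events)."""
    if haploid_size <= 0:
        raise ValueError("haploid_size must be positive")
    mine = [ev for ev in events if sample in ev.carriers]
    if clonal_only:
        mine = [ev for ev in mine if not ev.subclonal]
    groups: dict[int | None, bool] = {}
    for ev in mine:
        key = ev.linkage_group if ev.linkage_group is not None else id(ev)
        groups[key] = groups.get(key, True) and ev.post_wgd
    burden = sum(0.5 if post_wgd else 1.0 for post_wgd in groups.values())
    delta = sum(
        ev.length if ev.type == "gain" else -ev.length for ev in mine
    )
    return BurdenRecord(
        sample=sample,
        burden=burden,
        genome_size=2 * haploid_size + delta,
        date=date,
        clade=clade,
    )


def rate_regression(
    burdens: list[BurdenRecord],
    year_only: dict[str, int] | None = None,
    seed: int = 0,
) -> dict:
    """Time regressions over per-sample burden records.

    OLS slope and prediction intervals for burden ~ date; an F-test on the
    date x clade interaction; a Huber M-estimator slope for genome size ~
    date. Samples listed in ``year_only`` get a seeded uniform-random date
    within the recorded year.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(seed)
    rows = []
    for rec in burdens:
        date = rec.date
        if year_only and rec.sample in year_only:
            date = year_only[rec.sample] + rng.uniform(0, 1)
        if date is None:
            raise ValueError(f"sample {rec.sample!r} has no date")
        rows.append((rec.sample, rec.burden, rec.genome_size, date, rec.clade))
    df = pd.DataFrame(rows, columns=["sample", "burden", "genome_size", "date", "clade"])
    if df["date"].nunique() < 2:
        raise ValueError("degenerate design: need >= 2 distinct dates")
    if len(df) < 3:
        raise ValueError("need >= 3 records")

    ols = smf.ols("burden ~ date", data=df).fit()
    pred = ols.get_prediction(df).summary_frame(alpha=0.05)

    result = {
        "slope": float(ols.params["date"]),
        "intercept": float(ols.params["Intercept"]),
        "slope_p": float(ols.pvalues["date"]),
        "prediction_interval": pred[["obs_ci_lower", "obs_ci_upper"]],
        "interaction_p": None,
        "genome_size_slope": None,
    }
    if df["clade"].notna().all() and df["clade"].nunique() > 1:
        full = smf.ols("burden ~ date * C(clade)", data=df).fit()
        reduced = smf.ols("burden ~ date + C(clade)", data=df).fit()
        from statsmodels.stats.anova import anova_lm
        an = anova_lm(reduced, full)
        result["interaction_p"] = float(an["Pr(>F)"].iloc[1])
    # centred dates for conditioning; tight tolerance — the IRLS can stall at
    # a spurious fixed point with the default convergence criterion
    if df["genome_size"].nunique() == 1:
        result["genome_size_slope"] = 0.0
        return result
    centred = df["date"] - df["date"].mean()
    X = sm.add_constant(centred.to_numpy())
    rlm = sm.RLM(df["genome_size"].to_numpy(dtype=float), X,
                 M=sm.robust.norms.HuberT()).fit(maxiter=300, tol=1e-10)
    result["genome_size_slope"] = float(rlm.params[1])
    return result


# ---------------------------------------------------------------------------
# coinfection

def coinfection_classify(
    tumours_by_devil: dict[str, dict[str, dict[str, int]]],
) -> pd.DataFrame:
    """Classify multi-tumour hosts.

    ``tumours_by_devil`` maps devil -> tumour -> {variant: 0/1}. Identical
    genotype vectors give single_infection/identical; vectors differing only
    at variants carried by no other devil's tumours give
    single_infection/polymorphic_private; differences at variants also seen
    in other devils give coinfection/polymorphic_public. Devils with fewer
    than two tumours are skipped.
    """
    carriers: dict[str, set[str]] = {}
    for devil, tumours in tumours_by_devil.items():
        for genotype in tumours.values():
            for variant, present in genotype.items():
                if present:
                    carriers.setdefault(variant, set()).add(devil)

    rows = []
    for devil, tumours in tumours_by_devil.items():
        if len(tumours) < 2:
            continue
        genos = list(tumours.values())
        variants = sorted({v for g in genos for v in g})
        differing = [
            v for v in variants
            if len({g.get(v, 0) for g in genos}) > 1
        ]
        if not differing:
            label, sub = "single_infection", "identical"
        elif all(carriers.get(v, set()) <= {devil} for v in differing):
            label, sub = "single_infection", "polymorphic_private"
        else:
            label, sub = "coinfection", "polymorphic_public"
        rows.append((devil, len(tumours), label, sub))
    return pd.DataFrame(
        rows, columns=["devil", "n_tumours", "label", "sublabel"]
    ).set_index("devil")
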