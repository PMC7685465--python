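import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from skimclone.cnv_catalogue import (
    BurdenRecord,
    CladeTree,
    burden_and_genome_size,
    coinfection_classify,
    consolidate_events,
    count_independent_m5_losses,
    detect_m5_loss,
    fisher_exact_2x2,
    link_events,
    m5_enrichment_test,
    min_origin_labelling,
    rate_regression,
)
from skimclone.segmentation import Segment
from skimclone.synthetic_data import simulate_clone_tree


def seg(sample, chrom, start, end, state, subclonal=False):
    return Segment(sample, chrom, start, end, (end - start) // 100_000, 0.0,
                   cn_state=state, subclonal=subclonal)


def brute_force_min_origins(tree: CladeTree, carriers: set[str]):
    """Enumerate all internal labellings; min changes, then min origins."""
    ch = tree.children()
    leaves = tree.leaves()
    internal = [n for n in tree.parent if n not in leaves]
    best = None
    for assignment in itertools.product([0, 1], repeat=len(internal)):
        state = dict(zip(internal, assignment))
        for leaf in leaves:
            state[leaf] = 1 if leaf in carriers else 0
        changes = origins = 0
        for node, parent in tree.parent.items():
            if parent is None:
                if state[node] == 1:  # root presence is itself an event
                    origins += 1
                    changes += 1
                continue
            if state[node] != state[parent]:
                changes += 1
                if state[node] == 1:
                    origins += 1
        key = (changes, origins)
        if best is None or key < best:
            best = key
    return best


class TestMinOriginLabelling:
    def test_single_origin_sister_samples(self, cherry_clade_tree):
        _, changes, origins, losses = min_origin_labelling(
            cherry_clade_tree, {"A", "B"})
        assert len(origins) == 1 and changes == 1 and not losses

    def test_two_distant_origins(self, cherry_clade_tree):
        _, _, origins, _ = min_origin_labelling(cherry_clade_tree, {"A", "C"})
        assert len(origins) == 2

    def test_all_carriers_root_origin(self, cherry_clade_tree):
        lab, n_events, origins, _ = min_origin_labelling(
            cherry_clade_tree, {"A", "B", "C", "D"})
        assert origins == ["I0"] and n_events == 1

    def test_back_mutation_inferred(self):
        # carriers everywhere except one tip deep inside the carrier clade
        tree = CladeTree(
            parent={"R": None, "I1": "R", "A": "I1", "B": "I1", "C": "R",
                    "I2": "R", "D": "I2", "E": "I2"},
            sample_clade={},
        )
        _, changes, origins, losses = min_origin_labelling(
            tree, {"A", "B", "C", "D"})
        assert len(origins) == 1
        assert losses == ["E"]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 9))
        clone = simulate_clone_tree(n_tips, n_tips, seed)  # one clade per tip
        tree = CladeTree.from_clone_tree(clone)
        leaves = tree.leaves()
        carriers = {l for l in leaves if rng.random() < 0.45}
        if not carriers:
            carriers = {leaves[0]}
        _, changes, origins, _ = min_origin_labelling(tree, carriers)
        bf_changes, bf_origins = brute_force_min_origins(tree, carriers)
        assert changes == bf_changes
        assert len(origins) == bf_origins


class TestConsolidateEvents:
    def test_sister_samples_single_event(self, cherry_clade_tree):
        segs = {
            "sA": [seg("sA", "1", 0, 1_000_000, 1.0)],
            "sB": [seg("sB", "1", 0, 1_000_000, 1.0)],
        }
        events = consolidate_events(segs, cherry_clade_tree)
        assert len(events) == 1
        assert events[0].extended_id == events[0].basic_id
        assert events[0].carrier_set == frozenset({"sA", "sB"})

    def test_distant_clades_get_recurrence_suffix(self, cherry_clade_tree):
        segs = {
            "sA": [seg("sA", "1", 0, 1_000_000, 3.0)],
            "sC": [seg("sC", "1", 0, 1_000_000, 3.0)],
        }
        events = consolidate_events(segs, cherry_clade_tree)
        assert len(events) == 2
        ids = sorted(e.extended_id for e in events)
        assert ids[0] == events[0].basic_id
        assert ids[1].endswith("R1")

    def test_missing_clade_mapping_rejected(self, cherry_clade_tree):
        segs = {"sX": [seg("sX", "1", 0, 1_000_000, 1.0)]}
        with pytest.raises(ValueError):
            consolidate_events(segs, cherry_clade_tree)

    def test_cn2_segments_ignored(self, cherry_clade_tree):
        segs = {"sA": [seg("sA", "1", 0, 1_000_000, 2.0)]}
        assert consolidate_events(segs, cherry_clade_tree) == []

    def test_amplitude_steps_get_records(self, cherry_clade_tree):
        segs = {"sA": [seg("sA", "1", 0, 1_000_000, 4.0)]}
        events = consolidate_events(segs, cherry_clade_tree)
        ids = [e.extended_id for e in events]
        assert len(events) == 2  # base gain + G1CN4 step
        assert any("G1CN4" in i for i in ids)

    def test_nested_opposite_event_tagged_pbm(self, cherry_clade_tree):
        segs = {
            "sA": [seg("sA", "1", 0, 5_000_000, 3.0)],
            "sB": [seg("sB", "1", 0, 5_000_000, 3.0),
                   seg("sB", "1", 1_000_000, 2_000_000, 2.0)],
        }
        # the nested CN2 region inside sB's gain shows as a loss-direction
        # segment relative to the gain; model it as an explicit nested loss
        segs["sB"][1].cn_state = 1.9  # force non-CN2 nested opposite direction
        events = consolidate_events(segs, cherry_clade_tree)
        pbm = [e for e in events if "PBM" in e.extended_id]
        assert len(pbm) == 1
        assert pbm[0].parent_id is not None

    def test_origin_count_matches_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for rep in range(10):
            clone = simulate_clone_tree(8, 8, rep)
            tree = CladeTree.from_clone_tree(clone)
            tree.sample_clade.update({f"s{l}": l for l in tree.leaves()})
            carriers = {l for l in tree.leaves() if rng.random() < 0.5}
            if not carriers:
                continue
            segs = {
                f"s{l}": [seg(f"s{l}", "1", 0, 1_000_000, 1.0)] for l in carriers
            }
            events = consolidate_events(segs, tree)
            n_origins = len([e for e in events if e.parent_id is None])
            _, bf_origins = brute_force_min_origins(tree, carriers)
            assert n_origins == bf_origins


class TestLinkEvents:
    def _event(self, carriers, direction, chrom="1", start=0, end=1_000_000):
        from skimclone.cnv_catalogue import CNVEvent
        return CNVEvent(basic_id="x", extended_id="x", type=direction,
                        chrom=chrom, start=start, end=end,
                        carriers={c: 3.0 if direction == "gain" else 1.0
                                  for c in carriers})

    def test_same_carriers_same_direction_one_group(self):
        evs = [self._event({"a", "b"}, "loss"),
               self._event({"a", "b"}, "loss", chrom="2")]
        link_events(evs)
        assert evs[0].linkage_group == evs[1].linkage_group

    def test_direction_splits_groups(self):
        evs = [self._event({"a", "b"}, "loss"),
               self._event({"a", "b"}, "gain", chrom="2")]
        link_events(evs)
        assert evs[0].linkage_group != evs[1].linkage_group

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(1)
        samples = list("abcde")
        evs = []
        for i in range(5):
            carriers = {s for s in samples if rng.random() < 0.5} or {"a"}
            evs.append(self._event(carriers, rng.choice(["gain", "loss"]),
                                   chrom=str(i + 1)))
        link_events(evs)
        for x, y in itertools.combinations(evs, 2):
            same_group = x.linkage_group == y.linkage_group
            same_key = (x.carrier_set, x.type) == (y.carrier_set, y.type)
            assert same_group == same_key


class TestM5:
    def _events_with_cassette(self, cherry_clade_tree, carriers_by_component):
        from skimclone.cnv_catalogue import CNVEvent
        evs = []
        for cid, carriers in carriers_by_component.items():
            evs.append(CNVEvent(
                basic_id=cid, extended_id=cid, type="loss", chrom="1",
                start=0, end=1_000_000,
                carriers={c: 1.0 for c in carriers}))
        return evs

    def test_full_cassette_lost(self, cherry_clade_tree):
        evs = self._events_with_cassette(cherry_clade_tree, {
            "6BM": {"sA"}, "11BM": {"sA"}, "16R": {"sA"},
            "17R": set(), "18R": set(),
        })
        status = detect_m5_loss(evs, ("6BM", "11BM"), ("16R", "17R", "18R"))
        assert status.loc["sA", "m5_lost"]

    def test_mandatory_only_not_lost(self, cherry_clade_tree):
        evs = self._events_with_cassette(cherry_clade_tree, {
            "6BM": {"sA"}, "11BM": set(), "16R": set(), "17R": set(), "18R": set(),
        })
        status = detect_m5_loss(evs, ("6BM", "11BM"), ("16R", "17R", "18R"))
        assert not status.loc["sA", "m5_lost"]

    def test_missing_x_component_not_lost(self, cherry_clade_tree):
        evs = self._events_with_cassette(cherry_clade_tree, {
            "6BM": {"sA"}, "11BM": {"sA"}, "16R": set(), "17R": set(), "18R": set(),
        })
        status = detect_m5_loss(evs, ("6BM", "11BM"), ("16R", "17R", "18R"))
        assert not status.loc["sA", "m5_lost"]

    def test_components_tagged(self, cherry_clade_tree):
        evs = self._events_with_cassette(cherry_clade_tree, {
            "6BM": {"sA"}, "11BM": {"sA"}, "16R": {"sA"},
        })
        detect_m5_loss(evs, ("6BM", "11BM"), ("16R",))
        assert all(e.m5_component for e in evs)

    def test_independent_loss_count(self, cherry_clade_tree):
        evs = self._events_with_cassette(cherry_clade_tree, {
            "6BM": {"sA", "sC"}, "11BM": {"sA", "sC"}, "16R": {"sA", "sC"},
        })
        status = detect_m5_loss(evs, ("6BM", "11BM"), ("16R",))
        assert count_independent_m5_losses(status, cherry_clade_tree) == 2


class TestFisher:
    def test_equal_rates_p_one(self):
        odds, p = fisher_exact_2x2([[4, 6], [8, 12]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy(self):
        table = [[8, 2], [1, 9]]
        odds, p = fisher_exact_2x2(table)
        s_odds, s_p = sstats.fisher_exact(table)
        assert p == pytest.approx(s_p, rel=1e-9)
        assert odds == pytest.approx(s_odds)

    def test_matches_hand_enumeration(self):
        table = [[3, 1], [1, 3]]
        _, p = fisher_exact_2x2(table)
        # margins 4/4, col 4: a ranges 0..4, hypergeom pmfs
        pmfs = {a: sstats.hypergeom(8, 4, 4).pmf(a) for a in range(5)}
        p_obs = pmfs[3]
        expected = sum(v for v in pmfs.values() if v <= p_obs * (1 + 1e-7))
        assert p == pytest.approx(expected, rel=1e-12)

    def test_doubling_counts_decreases_p(self):
        _, p1 = fisher_exact_2x2([[8, 2], [1, 9]])
        _, p2 = fisher_exact_2x2([[16, 4], [2, 18]])
        assert p2 < p1

    def test_enrichment_wrapper(self):
        res = m5_enrichment_test(8, 10, 1, 10)
        assert res["p"] == pytest.approx(sstats.fisher_exact([[8, 2], [1, 9]])[1])

    def test_enrichment_validates(self):
        with pytest.raises(ValueError):
            m5_enrichment_test(2, 0, 1, 10)


class TestBurden:
    def _linked_events(self, spec_list):
        from skimclone.cnv_catalogue import CNVEvent
        evs = []
        for i, (carriers, typ, length, post_wgd, subclonal) in enumerate(spec_list):
            evs.append(CNVEvent(
                basic_id=f"e{i}", extended_id=f"e{i}", type=typ, chrom=str(i + 1),
                start=0, end=length, post_wgd=post_wgd, subclonal=subclonal,
                carriers={c: 3.0 if typ == "gain" else 1.0 for c in carriers}))
        return link_events(evs)

    def test_no_events_baseline_genome(self):
        rec = burden_and_genome_size("s1", [], haploid_size=2_625_758_988)
        assert rec.genome_size == 5_251_517_976
        assert rec.burden == 0

    def test_post_wgd_half_counts(self):
        evs = self._linked_events([
            ({"s1"}, "gain", 1_000_000, False, False),
            ({"s1"}, "loss", 1_000_000, False, False),
            ({"s1", "s2"}, "gain", 1_000_000, False, False),
            ({"s1"}, "gain", 2_000_000, True, False),
            ({"s1"}, "loss", 3_000_000, True, False),
        ])
        # chrom differs so linkage groups: {s1}gain x2 (one wgd one not) are
        # distinct? carriers {s1} gain appears twice -> same group
        rec = burden_and_genome_size("s1", evs, haploid_size=10_000_000)
        # groups: ({s1},gain) [mixed wgd -> not all post-wgd], ({s1},loss)
        # [mixed], ({s1,s2},gain)
        assert rec.burden == 3.0

    def test_pure_wgd_groups_half(self):
        evs = self._linked_events([
            ({"s1"}, "gain", 1_000_000, True, False),
            ({"s1"}, "loss", 1_000_000, True, False),
            ({"s1", "s2"}, "gain", 1_000_000, False, False),
        ])
        rec = burden_and_genome_size("s1", evs, haploid_size=10_000_000)
        assert rec.burden == 2.0  # 2 x 0.5 + 1

    def test_genome_size_change(self):
        evs = self._linked_events([
            ({"s1"}, "gain", 1_000_000, False, False),
            ({"s1"}, "loss", 3_000_000, False, False),
        ])
        rec = burden_and_genome_size("s1", evs, haploid_size=10_000_000)
        assert rec.genome_size == 2 * 10_000_000 + 1_000_000 - 3_000_000

    def test_burden_invariant_to_event_split(self):
        whole = self._linked_events([({"s1"}, "gain", 2_000_000, False, False)])
        split = self._linked_events([
            ({"s1"}, "gain", 1_000_000, False, False),
            ({"s1"}, "gain", 1_000_000, False, False),
        ])
        b1 = burden_and_genome_size("s1", whole, haploid_size=10_000_000).burden
        b2 = burden_and_genome_size("s1", split, haploid_size=10_000_000).burden
        assert b1 == b2 == 1.0


class TestRateRegression:
    def test_exact_linear_slope(self):
        recs = [BurdenRecord(f"s{i}", burden=2.5 * (2000 + i) - 4000,
                             genome_size=5_000_000, date=2000 + i)
                for i in range(10)]
        fits = rate_regression(recs)
        assert fits["slope"] == pytest.approx(2.5, abs=1e-9)

    def test_zero_burden_zero_slope(self):
        recs = [BurdenRecord(f"s{i}", burden=0.0, genome_size=5_000_000,
                             date=2000 + i) for i in range(5)]
        assert rate_regression(recs)["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_single_date_rejected(self):
        recs = [BurdenRecord(f"s{i}", 1.0, 5_000_000, date=2005) for i in range(5)]
        with pytest.raises(ValueError):
            rate_regression(recs)

    def test_interaction_power(self):
        """Clade slope difference 5 vs 10 detected at p<0.01 in >=95% of seeds."""
        detected = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            recs = []
            for i in range(100):
                clade = "A" if i % 2 == 0 else "B"
                slope = 5.0 if clade == "A" else 10.0
                date = 2000 + rng.uniform(0, 10)
                recs.append(BurdenRecord(
                    f"s{i}", burden=slope * (date - 2000) + rng.normal(0, 2),
                    genome_size=5_000_000, date=date, clade=clade))
            if rate_regression(recs)["interaction_p"] < 0.01:
                detected += 1
        assert detected >= 0.95 * n_seeds

    def test_year_only_dates_seeded(self):
        recs = [BurdenRecord(f"s{i}", float(i), 5_000_000,
                             date=None if i == 0 else 2000 + i)
                for i in range(5)]
        f1 = rate_regression(recs, year_only={"s0": 2000}, seed=4)
        f2 = rate_regression(recs, year_only={"s0": 2000}, seed=4)
        assert f1["slope"] == f2["slope"]

    def test_robust_genome_size_slope(self):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(40):
            date = 2000 + i / 4
            size = int(5_000_000 + 1000 * (date - 2000) + rng.normal(0, 50))
            recs.append(BurdenRecord(f"s{i}", 1.0, size, date=date))
        recs[0].genome_size += 10_000_000  # gross outlier
        fits = rate_regression(recs)
        assert fits["genome_size_slope"] == pytest.approx(1000, rel=0.1)


class TestCoinfection:
    def test_identical_single_infection(self):
        out = coinfection_classify({
            "d1": {"t1": {"v1": 1, "v2": 0}, "t2": {"v1": 1, "v2": 0}},
        })
        assert out.loc["d1", "label"] == "single_infection"
        assert out.loc["d1", "sublabel"] == "identical"

    def test_private_variation_single_infection(self):
        out = coinfection_classify({
            "d1": {"t1": {"v1": 1, "v2": 1}, "t2": {"v1": 1, "v2": 0}},
            "d2": {"t1": {"v1": 1, "v2": 0}, "t2": {"v1": 1, "v2": 0}},
        })
        # v2 only ever present in d1's tumours -> private
        assert out.loc["d1", "label"] == "single_infection"
        assert out.loc["d1", "sublabel"] == "polymorphic_private"

    def test_public_variation_coinfection(self):
        out = coinfection_classify({
            "d1": {"t1": {"v1": 1, "v2": 1}, "t2": {"v1": 1, "v2": 0}},
            "d2": {"t1": {"v1": 1, "v2": 1}, "t2": {"v1": 1, "v2": 1}},
        })
        assert out.loc["d1", "label"] == "coinfection"
        assert out.loc["d1", "sublabel"] == "polymorphic_public"

    def test_single_tumour_devils_skipped(self):
        out = coinfection_classify({"d1": {"t1": {"v1": 1}}})
        assert "d1" not in out.index
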