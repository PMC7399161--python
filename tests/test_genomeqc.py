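from math import ceil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eetscan.genomeqc import (SCG_UNIVERSE, PairSimilarity, SCGInventory,
                              bin_score, completeness_tier, dereplicate,
                              genome_similarity, n50, pair_passes,
                              tier_cutoff)
from eetscan.seqio import GenomeBin
from eetscan.synthcommunity import make_bin_inventory, make_genome_pair


class TestCompleteness:
    @pytest.mark.parametrize("domain,n,tier", [
        ("bacteria", 36, "draft"),          # 36/51 = 70.6%
        ("bacteria", 35, "below"),
        ("bacteria", 46, "near_complete"),  # ceil(0.9 * 51)
        ("bacteria", 45, "draft"),
        ("archaea", 27, "draft"),           # 27/38
        ("archaea", 26, "below"),
        ("archaea", 35, "near_complete"),
        ("archaea", 34, "draft"),
    ])
    def test_tier_boundaries(self, domain, n, tier):
        inv, _ = make_bin_inventory(domain, n, 0, (1000,), "b")
        assert completeness_tier(inv).tier == tier

    def test_integer_cutoffs_match_fraction_rule(self):
        for domain, universe in SCG_UNIVERSE.items():
            for frac in (0.70, 0.90):
                cutoff = tier_cutoff(domain, frac)
                assert cutoff == ceil(frac * universe)
                assert cutoff / universe >= frac
                assert (cutoff - 1) / universe < frac

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            SCGInventory("b", "virus")


class TestBinScore:
    @pytest.mark.parametrize("present,multi,expected", [
        (40, 3, 34), (51, 0, 51), (10, 10, -10), (51, 2, 47), (0, 0, 0),
    ])
    def test_formula(self, present, multi, expected):
        inv, _ = make_bin_inventory("bacteria", present, multi, (1,), "b")
        assert bin_score(inv) == expected


class TestN50:
    def test_examples(self):
        assert n50([10, 8, 5, 3]) == 8
        assert n50([7]) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10_000),
                    min_size=1, max_size=30),
           st.randoms())
    def test_matches_prefix_sum_oracle_and_order_invariance(self, lengths, rnd):
        desc = sorted(lengths, reverse=True)
        total = sum(desc)
        acc, expected = 0, None
        for l in desc:
            acc += l
            if acc >= total / 2:
                expected = l
                break
        assert n50(lengths) == expected
        shuffled = list(lengths)
        rnd.shuffle(shuffled)
        assert n50(shuffled) == expected


class TestGenomeSimilarity:
    def test_identical_bins(self):
        a, b, _ = make_genome_pair(20_000, 0.0, 1)
        sim = genome_similarity(a, b)
        assert sim.identity_pct == 100.0
        assert sim.aligned_fraction == pytest.approx(1.0)

    def test_substitution_rate_recovered(self):
        a, b, truth = make_genome_pair(50_000, 0.02, 2)
        sim = genome_similarity(a, b)
        assert abs(sim.identity_pct - truth.realized_identity_pct) < 0.2
        assert abs(sim.identity_pct - 98.0) < 0.5

    def test_unrelated_fraction_controls_coverage(self):
        a, b, _ = make_genome_pair(50_000, 0.01, 3, unrelated_fraction=0.4)
        sim = genome_similarity(a, b)
        assert sim.aligned_fraction == pytest.approx(0.6, abs=0.05)

    def test_unrelated_bins_do_not_align(self):
        rng = np.random.default_rng(4)
        nuc = np.array(list("ACGT"))
        a = GenomeBin("a", scaffolds=[("a0", "".join(nuc[rng.integers(0, 4, 30_000)]))])
        b = GenomeBin("b", scaffolds=[("b0", "".join(nuc[rng.integers(0, 4, 30_000)]))])
        assert genome_similarity(a, b).aligned_fraction < 0.10

    def test_sequence_free_bin_rejected(self):
        stub = GenomeBin("s", contig_lengths=[100])
        other = GenomeBin("o", scaffolds=[("o0", "ACGT" * 100)])
        with pytest.raises(ValueError, match="marker-only"):
            genome_similarity(stub, other)


class TestPairRule:
    def test_thresholds(self):
        hi = PairSimilarity(99.0, 0.85)
        lo_cov = PairSimilarity(98.5, 0.60)
        lo_id = PairSimilarity(95.0, 0.90)
        null = PairSimilarity(0.0, 0.0)
        assert pair_passes(hi, null)
        assert not pair_passes(lo_cov, null)
        assert not pair_passes(lo_id, null)

    def test_identity_compared_at_printed_precision(self):
        # a pair whose measured identity rounds to 98 meets "at least 98%"
        assert pair_passes(PairSimilarity(97.6, 0.9), PairSimilarity(0, 0))
        assert not pair_passes(PairSimilarity(97.4, 0.9), PairSimilarity(0, 0))
        # exact comparison available
        assert not pair_passes(PairSimilarity(97.6, 0.9), PairSimilarity(0, 0),
                               id_precision=0.0)

    def test_or_vs_and_semantics(self):
        good = PairSimilarity(99.0, 0.9)
        bad = PairSimilarity(99.0, 0.5)
        assert pair_passes(good, bad, semantics="or")
        assert not pair_passes(good, bad, semantics="and")


def _inventory_for(bin_id, present, multi=0, lengths=(10_000,)):
    inv, stub = make_bin_inventory("bacteria", present, multi, lengths, bin_id)
    return inv, stub


class TestDereplicate:
    def _run(self, sims, specs):
        """specs: bin_id -> (present, multi, contig_lengths)."""
        bins, invs = [], {}
        for bin_id, (present, multi, lengths) in specs.items():
            inv, stub = _inventory_for(bin_id, present, multi, lengths)
            bins.append(stub)
            invs[bin_id] = inv
        return dereplicate(bins, invs, similarities=sims)

    def test_cluster_and_singletons(self):
        sims = {
            ("a", "b"): PairSimilarity(99.0, 0.85),
            ("b", "a"): PairSimilarity(99.0, 0.83),
            ("a", "c"): PairSimilarity(80.0, 0.1),
            ("c", "a"): PairSimilarity(80.0, 0.1),
            ("b", "c"): PairSimilarity(80.0, 0.1),
            ("c", "b"): PairSimilarity(80.0, 0.1),
        }
        specs = {"a": (40, 0, (10_000,)), "b": (38, 0, (9_000,)),
                 "c": (45, 0, (8_000,))}
        clusters = self._run(sims, specs)
        parts = sorted(tuple(c.members) for c in clusters)
        assert parts == [("a", "b"), ("c",)]

    def test_coverage_failure_keeps_separate(self):
        sims = {("a", "b"): PairSimilarity(98.5, 0.60),
                ("b", "a"): PairSimilarity(98.5, 0.58)}
        specs = {"a": (40, 0, (10_000,)), "b": (38, 0, (9_000,))}
        clusters = self._run(sims, specs)
        assert sorted(tuple(c.members) for c in clusters) == [("a",), ("b",)]

    def test_representative_priority_chain(self):
        sims = {}
        for x in "abc":
            for y in "abc":
                if x != y:
                    sims[(x, y)] = PairSimilarity(99.5, 0.95)
        # a: score 40; b: score 42 -> wins on score
        specs = {"a": (40, 0, (12_000,)), "b": (42, 0, (5_000,)),
                 "c": (40, 0, (9_000,))}
        clusters = self._run(sims, specs)
        assert clusters[0].representative == "b"
        # tie on score: N50 12 kb beats 9 kb
        specs = {"a": (40, 0, (12_000,)), "c": (40, 0, (9_000,))}
        sims2 = {k: v for k, v in sims.items() if "b" not in k[0] + k[1]}
        clusters = self._run(sims2, specs)
        assert clusters[0].representative == "a"
        # tie on score and N50: total size decides
        specs = {"a": (40, 0, (9_000, 2_000)), "c": (40, 0, (9_000,))}
        clusters = self._run(sims2, specs)
        assert clusters[0].representative == "a"
        # full tie: lexicographically smallest id
        specs = {"a": (40, 0, (9_000,)), "c": (40, 0, (9_000,))}
        clusters = self._run(sims2, specs)
        assert clusters[0].representative == "a"

    def test_partition_property_and_order_invariance(self):
        sims = {}
        ids = ["a", "b", "c", "d"]
        def link(x, y):
            sims[(x, y)] = PairSimilarity(99.0, 0.9)
            sims[(y, x)] = PairSimilarity(99.0, 0.9)
        for x in ids:
            for y in ids:
                if x != y and (x, y) not in sims:
                    sims[(x, y)] = PairSimilarity(50.0, 0.2)
        link("a", "b")
        link("b", "d")  # transitive: a-b-d single-linkage
        specs = {i: (40, 0, (10_000,)) for i in ids}
        clusters = self._run(sims, specs)
        parts = sorted(tuple(c.members) for c in clusters)
        assert parts == [("a", "b", "d"), ("c",)]
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(ids)  # partition

    def test_missing_inventory_rejected(self):
        stub = GenomeBin("a", contig_lengths=[100])
        with pytest.raises(ValueError, match="inventory"):
            dereplicate([stub], {})


class TestEndToEndPairs:
    def test_rule_clusters_close_pairs_and_splits_distant(self):
        """Pairs simulated below/at 2% divergence fall into one cluster;
        5% pairs stay separate."""
        bins, invs, sims = [], {}, None
        a, b, _ = make_genome_pair(30_000, 0.01, 11, bin_ids=("p1a", "p1b"))
        c, d, _ = make_genome_pair(30_000, 0.05, 12, bin_ids=("p2a", "p2b"))
        for i, g in enumerate((a, b, c, d)):
            inv, _ = make_bin_inventory("bacteria", 40, 0,
                                        [len(g.scaffolds[0][1])], g.bin_id)
            invs[g.bin_id] = inv
            bins.append(g)
        clusters = dereplicate(bins, invs)
        parts = sorted(tuple(c.members) for c in clusters)
        assert parts == [("p1a", "p1b"), ("p2a",), ("p2b",)]
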