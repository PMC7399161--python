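import numpy as np
import pytest

from eetscan.hemescan import MHCProfile
from eetscan.pcc import (PORIN_FAMILIES, PorinCandidate, build_profile,
                         call_pcc, estimate_tm_strands, load_seed_alignment,
                         local_profile_score, search)
from eetscan.seqio import GeneCall, ProteinRecord
from eetscan.synthcommunity import (family_ancestor, make_barrel,
                                    make_filler_protein, make_pcc_operon,
                                    make_porin_seed_alignment, mutate_protein)


@pytest.fixture(scope="module")
def mtrb_profile():
    return build_profile("MtrB", load_seed_alignment("MtrB"))


class TestBuildProfile:
    def test_identical_seeds_saturate_self_scores(self):
        seeds = [ProteinRecord(f"s{i}", "MKTAYIAKQR") for i in range(2)]
        prof = build_profile("MtrB", seeds)
        assert prof.seed_self_scores[0] == pytest.approx(prof.max_score)
        assert prof.seed_self_scores[1] == pytest.approx(prof.max_score)

    def test_conserved_column_log_odds_sign(self):
        seeds = [ProteinRecord(f"s{i}", "AAAAAAAAAA") for i in range(4)]
        prof = build_profile("MtrB", seeds)
        a, w = 0, 18  # indices of A and W in the residue order
        assert (prof.pssm[:, a] > prof.pssm[:, w]).all()

    def test_ragged_seeds_rejected(self):
        seeds = [ProteinRecord("s0", "MKTAYI"), ProteinRecord("s1", "MKT")]
        with pytest.raises(ValueError, match="aligned"):
            build_profile("MtrB", seeds)

    def test_single_seed_rejected(self):
        with pytest.raises(ValueError, match="2"):
            build_profile("MtrB", [ProteinRecord("s0", "MKTAYI")])

    def test_held_out_family_member_scores_high(self, mtrb_profile):
        """A held-out relative of the seed family clears the z = 6 bar by a
        wide margin."""
        rng = np.random.default_rng(77)
        member = ProteinRecord(
            "held_out", mutate_protein(family_ancestor("MtrB"), 0.25, rng))
        cands = search(mtrb_profile, [member], n_shuffles=50, rng_seed=3)
        assert len(cands) == 1
        assert cands[0].shuffle_z > 6


class TestSearch:
    def test_seed_self_hit(self, mtrb_profile):
        seed = load_seed_alignment("MtrB")[0]
        cands = search(mtrb_profile, [seed], n_shuffles=50, rng_seed=0)
        assert [c.protein_id for c in cands] == [seed.id]

    def test_random_sequences_rejected(self, mtrb_profile):
        prots = [make_filler_protein(300, 9000 + i, f"r{i}") for i in range(20)]
        cands = search(mtrb_profile, prots, n_shuffles=50, rng_seed=1)
        assert cands == []

    def test_empty_input(self, mtrb_profile):
        assert search(mtrb_profile, [], rng_seed=0) == []

    def test_deterministic_and_monotone_in_z(self, mtrb_profile):
        rng = np.random.default_rng(5)
        prots = [ProteinRecord("m", mutate_protein(family_ancestor("MtrB"),
                                                   0.3, rng)),
                 make_filler_protein(250, 11, "r0")]
        a = search(mtrb_profile, prots, n_shuffles=30, z_min=-99, rng_seed=9)
        b = search(mtrb_profile, prots, n_shuffles=30, z_min=-99, rng_seed=9)
        assert [(c.protein_id, c.score, c.shuffle_z) for c in a] == \
               [(c.protein_id, c.score, c.shuffle_z) for c in b]
        ids = lambda zmin: {c.protein_id for c in search(
            mtrb_profile, prots, n_shuffles=30, z_min=zmin, rng_seed=9)}
        low, mid, high = ids(-99), ids(6), ids(1e9)
        assert high <= mid <= low

    def test_n_shuffles_floor(self, mtrb_profile):
        with pytest.raises(ValueError):
            search(mtrb_profile, [], n_shuffles=5, rng_seed=0)

    def test_tm_override_wins(self, mtrb_profile):
        seed = load_seed_alignment("MtrB")[0]
        cands = search(mtrb_profile, [seed], n_shuffles=50, rng_seed=0,
                       tm_overrides={seed.id: 20})
        assert cands[0].tm_strands == 20
        assert cands[0].tm_from_override


class TestEstimateTMStrands:
    def test_planted_barrel_counted_exactly(self):
        rng = np.random.default_rng(42)
        for n in (12, 16):
            seq = make_barrel(n, rng)
            assert estimate_tm_strands(ProteinRecord("b", seq)).n_strands == n

    def test_poly_g_has_no_signal(self):
        assert estimate_tm_strands(ProteinRecord("g", "G" * 200)).n_strands == 0

    def test_too_short_flagged(self):
        pred = estimate_tm_strands(ProteinRecord("s", "MKL" * 10))
        assert pred.n_strands == 0 and pred.too_short

    def test_reversal_invariance(self):
        rng = np.random.default_rng(7)
        seq = make_barrel(16, rng)
        fwd = estimate_tm_strands(ProteinRecord("f", seq)).n_strands
        rev = estimate_tm_strands(ProteinRecord("r", seq[::-1])).n_strands
        assert fwd == rev


def _gene(pid, scaffold, ordinal):
    return GeneCall(pid, scaffold, 1000 * ordinal + 1, 1000 * ordinal + 900,
                    "+", ordinal, ProteinRecord(pid, "MKL"))


def _cand(pid, tm=16):
    return PorinCandidate(pid, "MtrB", 500.0, 50.0, tm)


class TestCallPCC:
    def test_adjacent_porin_and_mhc(self):
        genes = [_gene("porin", "s1", 0), _gene("mhc", "s1", 1)]
        profiles = [MHCProfile("mhc", 5, 100), MHCProfile("porin", 0, 300)]
        clusters = call_pcc(genes, [_cand("porin")], profiles)
        assert len(clusters) == 1
        assert clusters[0].max_gene_gap == 0
        assert [g.gene_id for g, _ in clusters[0].mhcs] == ["mhc"]

    def test_low_tm_porin_rejected(self):
        genes = [_gene("porin", "s1", 0), _gene("mhc", "s1", 1)]
        profiles = [MHCProfile("mhc", 5, 100)]
        assert call_pcc(genes, [_cand("porin", tm=12)], profiles) == []

    def test_tm_threshold_is_14(self):
        genes = [_gene("porin", "s1", 0), _gene("mhc", "s1", 1)]
        profiles = [MHCProfile("mhc", 5, 100)]
        assert len(call_pcc(genes, [_cand("porin", tm=14)], profiles)) == 1

    def test_window_contract(self):
        genes = [_gene("porin", "s1", 0), _gene("f1", "s1", 1),
                 _gene("f2", "s1", 2), _gene("f3", "s1", 3),
                 _gene("mhc", "s1", 4)]
        profiles = [MHCProfile("mhc", 5, 100)]
        assert call_pcc(genes, [_cand("porin")], profiles,
                        max_intervening=2) == []
        got = call_pcc(genes, [_cand("porin")], profiles, max_intervening=3)
        assert len(got) == 1 and got[0].max_gene_gap == 3

    def test_different_scaffold_not_clustered(self):
        genes = [_gene("porin", "s1", 0), _gene("mhc", "s2", 0)]
        profiles = [MHCProfile("mhc", 5, 100)]
        assert call_pcc(genes, [_cand("porin")], profiles) == []

    def test_collects_all_mhcs_in_window(self):
        genes = [_gene("m1", "s1", 0), _gene("porin", "s1", 1),
                 _gene("m2", "s1", 2), _gene("m3", "s1", 3)]
        profiles = [MHCProfile(m, 4, 80) for m in ("m1", "m2", "m3")]
        got = call_pcc(genes, [_cand("porin")], profiles)
        assert [g.gene_id for g, _ in got[0].mhcs] == ["m1", "m2", "m3"]

    def test_two_motif_neighbour_not_an_mhc(self):
        genes = [_gene("porin", "s1", 0), _gene("near", "s1", 1)]
        profiles = [MHCProfile("near", 2, 100)]
        assert call_pcc(genes, [_cand("porin")], profiles) == []


class TestOperonRoundTrip:
    def test_planted_layouts_recovered(self):
        """Planted operons are recovered exactly; negatives (wide gap, thin
        barrel) are rejected — precision and recall 1 over random layouts."""
        fam_cycle = PORIN_FAMILIES
        n_called = n_expected = 0
        for trial in range(12):
            fam = fam_cycle[trial % 4]
            gap = trial % 4
            tm = 12 if trial % 5 == 0 else 16
            genes, truth = make_pcc_operon(fam, n_mhc=1, tm_strands=tm,
                                           gene_gap=gap, rng_seed=600 + trial)
            prof = build_profile(fam, load_seed_alignment(fam))
            prots = [g.protein for g in genes]
            cands = search(prof, prots, n_shuffles=30, rng_seed=trial,
                           tm_overrides={truth.porin_id: truth.tm_strands})
            assert truth.porin_id in {c.protein_id for c in cands}
            from eetscan.hemescan import classify

            profiles = [classify(p) for p in prots]
            clusters = call_pcc(genes, cands, profiles, max_intervening=2)
            called = {c.porin.protein_id for c in clusters}
            if truth.expect_cluster:
                n_expected += 1
                assert called == {truth.porin_id}
                assert set(m.gene_id for g in clusters for m, _ in g.mhcs) == \
                    set(truth.mhc_ids)
            else:
                assert called == set()
            n_called += len(called)
        assert n_called == n_expected  # no false positives anywhere


class TestSeedFixtures:
    @pytest.mark.parametrize("family", PORIN_FAMILIES)
    def test_fixtures_load_and_are_synthetic(self, family):
        seeds = load_seed_alignment(family)
        assert len(seeds) >= 2
        assert all(len(s) == len(seeds[0]) for s in seeds)
        assert all("synthetic" in s.description for s in seeds)

    def test_families_distinct(self):
        a = load_seed_alignment("MtrB")[0]
        b = load_seed_alignment("OmbB")[0]
        assert a.residues != b.residues

    def test_regeneration_is_deterministic(self):
        s1 = make_porin_seed_alignment("MtrB", rng_seed=1000)
        s2 = make_porin_seed_alignment("MtrB", rng_seed=1000)
        assert [x.residues for x in s1] == [x.residues for x in s2]
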