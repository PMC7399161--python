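"""Synthetic community generator with planted ground truth.

Every feature the screening pipeline looks for can be planted at known
parameters, and each generator returns the truth alongside the records so
that round-trip tests can demand exact recovery:

* proteins with an exact number of C-x(2,4)-C-H heme-binding motifs,
  on a background alphabet that excludes C and H so no spurious motif can
  arise (the construction guarantees the non-overlapping maximum equals
  the planted count, and a validation scan asserts it);
* prepilin+mature pilin sequences that pass or fail each strict e-pilin
  criterion (key positions, density, gap) independently;
* porin-cytochrome operons: a porin derived from a family seed ancestor
  with an alternating-hydropathy beta-barrel region, placed a controlled
  number of genes away from planted multiheme cytochromes;
* genome pairs at a controlled per-site substitution rate, optionally
  with an unrelated tail to control the alignable fraction;
* single-copy-gene inventories with controlled presence/multiplicity.

Backgrounds are uniform over the permitted alphabet — no codon or GC
realism — which is sufficient for the recovery properties the tests
assert and is documented as a limitation.  All outputs are bit
reproducible given ``rng_seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hemescan, nanowire, pcc
from .seqio import GeneCall, GenomeBin, ProteinRecord, assign_ordinals
from .genomeqc import SCGInventory, marker_ids

# 18 residues: everything except C and H, so backgrounds can never complete
# a heme-binding motif.
MOTIF_FREE_ALPHABET = "ADEFGIKLMNPQRSTVWY"
# Mature-pilin background: additionally no aromatics (F, W, Y, H), no G
# (protects the prepilin-junction scan) and no C.
PILIN_BACKGROUND = "ADIKLMNPQRSTV"
AROMATIC_CHOICES = "FWY"

PREPILIN_LEADER = "MKKLQG"
NO_LEADER_PREFIX = "MKKLQD"
# Pilins form a homologous family: mature backgrounds are drawn from a
# fixed consensus with 20% per-site variation, so planted pilins are
# mutually alignable (like real PilA relatives) while staying distinct
# from unrelated background proteins.
_CONSENSUS_RNG = np.random.default_rng(777)
MATURE_CONSENSUS = "".join(
    PILIN_BACKGROUND[i] for i in _CONSENSUS_RNG.integers(0, 13, 90))
CONSENSUS_FIDELITY = 0.8

STRAND_HYDROPHOBIC = "IVLF"
STRAND_POLAR = "DNKE"
LOOP_RESIDUES = "GS"
STRAND_LEN = 13
LOOP_LEN = 8

NUC = np.array(list("ACGT"))


def _choice(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------------------
# Multiheme cytochrome proteins


@dataclass(frozen=True)
class MHCTruth:
    protein_id: str
    n_motifs: int
    motif_starts: tuple[int, ...]  # 1-based


def make_mhc_protein(n_motifs: int, length: int, rng_seed: int,
                     protein_id: str = "mhc") -> tuple[ProteinRecord, MHCTruth]:
    """Generate a protein with exactly ``n_motifs`` planted heme motifs.

    Motif spans are drawn from {5, 6, 7} (2-4 variable residues) and
    placed at random non-overlapping positions; the remaining residues
    come from the C/H-free background.  A post-generation scan asserts
    the planted count is recovered exactly.
    """
    rng = np.random.default_rng(rng_seed)
    if length < 7 * n_motifs:
        raise ValueError(
            f"length {length} cannot hold {n_motifs} motifs (needs >= {7 * n_motifs})")
    spans = rng.integers(5, 8, n_motifs) if n_motifs else np.array([], dtype=int)
    slack = length - int(spans.sum())
    gaps = rng.multinomial(slack, np.full(n_motifs + 1, 1.0 / (n_motifs + 1)))
    parts: list[str] = []
    starts: list[int] = []
    pos = 0
    for k in range(n_motifs):
        bg = _choice(rng, MOTIF_FREE_ALPHABET, int(gaps[k]))
        parts.append(bg)
        pos += len(bg)
        starts.append(pos + 1)
        nx = int(spans[k]) - 3
        motif = "C" + _choice(rng, MOTIF_FREE_ALPHABET, nx) + "CH"
        parts.append(motif)
        pos += len(motif)
    parts.append(_choice(rng, MOTIF_FREE_ALPHABET, int(gaps[n_motifs])))
    seq = "".join(parts)
    record = ProteinRecord(protein_id, seq)
    found = hemescan.find_heme_motifs(record)
    if len(found) != n_motifs:
        raise AssertionError(
            f"planted {n_motifs} motifs but scan found {len(found)}")
    return record, MHCTruth(protein_id, n_motifs, tuple(starts))


def make_filler_protein(length: int, rng_seed: int,
                        protein_id: str = "filler") -> ProteinRecord:
    """A background protein with no heme motifs (C/H-free alphabet)."""
    rng = np.random.default_rng(rng_seed)
    return ProteinRecord(protein_id, _choice(rng, MOTIF_FREE_ALPHABET, length))


# ---------------------------------------------------------------------------
# Pilins


@dataclass(frozen=True)
class PilinToggles:
    """Independent pass/fail switches for the strict e-pilin criteria.

    ``relaxed`` controls whether a non-strict pilin still clears the 8%
    whole-mature density for the relaxed tier.  With ``density=True`` the
    planted aromatics always exceed 8%, so ``relaxed=False`` requires
    ``density=False`` (enforced).
    """

    leader: bool = True
    positions: bool = True
    density: bool = True
    gap: bool = True
    relaxed: bool = True

    @property
    def expected_tier(self) -> str | None:
        if not self.leader:
            return None
        if self.positions and self.density and self.gap:
            return "strict"
        return "relaxed" if (self.density or self.relaxed) else "none"


@dataclass(frozen=True)
class PilinTruth:
    protein_id: str
    cleavage_pos: int | None
    tier: str | None
    aromatic_positions: tuple[int, ...]


# Aromatic placements (1-based mature positions) per (positions, density,
# gap, relaxed) pass/fail combination, with the mature length they need.
# Key positions are 1, 24, 27, 50/51 and 32/57; the 1->24 spacing of 22
# intervening residues sits exactly at the gap bound, and a 27->51 jump
# (23 intervening) just breaks it.  Five aromatics on a 61-mer give 8.2%
# full-length density (relaxed) but only 8.5% over the 59-residue window
# (below the 9.8% strict bound); stretching the tail to 70 residues drops
# the full-length figure under 8% for the "none" combinations.
_PLACEMENTS = {
    (True, True, True, True): ((1, 24, 27, 32, 50, 57), 61),
    (True, True, False, True): ((1, 10, 24, 27, 51, 57), 61),
    (False, True, True, True): ((2, 10, 24, 27, 32, 50, 57), 61),
    (False, True, False, True): ((2, 10, 24, 27, 51, 57), 61),
    (True, False, True, True): ((1, 24, 27, 50, 57), 61),
    (True, False, False, True): ((1, 24, 27, 51, 57), 61),
    (False, False, True, True): ((2, 24, 27, 50, 57), 61),
    (False, False, False, True): ((2, 10, 24, 27, 51), 61),
    (True, False, True, False): ((1, 24, 27, 50, 57), 70),
    (True, False, False, False): ((1, 24, 27, 51, 57), 70),
    (False, False, True, False): ((20, 40), 61),
    (False, False, False, False): ((20, 44), 61),
}


def make_pilin(toggles: PilinToggles, rng_seed: int,
               protein_id: str = "pilin") -> tuple[ProteinRecord, PilinTruth]:
    """Generate a prepilin whose mature region passes or fails each
    strict criterion per ``toggles``; the planted design is re-verified
    through the classifier before returning."""
    rng = np.random.default_rng(rng_seed)
    if toggles.density and not toggles.relaxed:
        raise ValueError("density=True forces the relaxed criterion; "
                         "set density=False to plant a 'none'-tier pilin")
    key = (toggles.positions, toggles.density, toggles.gap, toggles.relaxed)
    aromatics, mature_length = _PLACEMENTS[key]
    mature = [""] * mature_length
    for p in range(1, mature_length + 1):
        if rng.random() < CONSENSUS_FIDELITY:
            mature[p - 1] = MATURE_CONSENSUS[p - 1]
        else:
            mature[p - 1] = PILIN_BACKGROUND[rng.integers(0, len(PILIN_BACKGROUND))]
    mature[4] = "E"  # E5, read by the cleavage heuristic
    for p in aromatics:
        mature[p - 1] = "F" if p == 1 else AROMATIC_CHOICES[
            rng.integers(0, len(AROMATIC_CHOICES))]
    if 1 not in aromatics:
        mature[0] = "A"  # keep the post-cleavage residue hydrophobic
    leader = PREPILIN_LEADER if toggles.leader else NO_LEADER_PREFIX
    seq = leader + "".join(mature)
    record = ProteinRecord(protein_id, seq)

    cleavage = nanowire.detect_prepilin(record)
    if toggles.leader:
        assert cleavage == len(PREPILIN_LEADER), "leader not detectable"
        cand = nanowire.find_epilins([record])[0]
        m = cand.metrics
        checks = {
            "positions": all(cand.position_flags) == toggles.positions,
            "density": (m.aromatic_pct >= nanowire.STRICT_PCT_MIN) == toggles.density,
            "gap": (m.max_gap <= nanowire.MAX_AROMATIC_GAP) == toggles.gap,
            "relaxed": (m.full_length_pct >= nanowire.RELAXED_PCT_MIN)
                       == (toggles.density or toggles.relaxed),
            "tier": cand.tier == toggles.expected_tier,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise AssertionError(f"planted pilin violates design: {bad}")
    else:
        assert cleavage is None, "planted leader-free pilin is detectable"
    return record, PilinTruth(protein_id, cleavage, toggles.expected_tier,
                              aromatics)


# ---------------------------------------------------------------------------
# Porins and operons


def _family_rng(family: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(family.encode()) & 0x7FFFFFFF)


def make_barrel(n_strands: int, rng: np.random.Generator,
                strand_len: int = STRAND_LEN, loop_len: int = LOOP_LEN) -> str:
    """An alternating-hydropathy beta-barrel region: ``n_strands`` strands
    of alternating hydrophobic/polar residues separated by short
    glycine/serine loops, built to saturate the strand-count heuristic."""
    parts = [_choice(rng, LOOP_RESIDUES, loop_len)]
    for _ in range(n_strands):
        strand = []
        for k in range(strand_len):
            pool = STRAND_HYDROPHOBIC if k % 2 == 0 else STRAND_POLAR
            strand.append(pool[rng.integers(0, len(pool))])
        parts.append("".join(strand))
        parts.append(_choice(rng, LOOP_RESIDUES, loop_len))
    return "".join(parts)


def family_ancestor(family: str, n_strands: int = 16) -> str:
    """Deterministic ancestral porin for one family: a family-specific
    N-terminal region, a 16-strand barrel and a short tail."""
    rng = _family_rng(family)
    nterm = _choice(rng, MOTIF_FREE_ALPHABET, 60)
    barrel = make_barrel(16, rng)
    tail = _choice(rng, MOTIF_FREE_ALPHABET, 20)
    seq = nterm + barrel + tail
    if n_strands < 16:
        # overwrite the last strands with loop-like sequence
        per = STRAND_LEN + LOOP_LEN
        kill = (16 - n_strands) * per
        core_end = len(nterm) + len(barrel)
        seq = (seq[:core_end - kill - LOOP_LEN]
               + _choice(rng, LOOP_RESIDUES, kill + LOOP_LEN)
               + seq[core_end:])
    return seq


def mutate_protein(seq: str, rate: float, rng: np.random.Generator,
                   alphabet: str = MOTIF_FREE_ALPHABET) -> str:
    """Substitute each position with probability ``rate`` by a different
    residue from ``alphabet`` (C/H-free by default, so mutation can never
    plant a heme motif)."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def make_porin_seed_alignment(family: str, n_seeds: int = 8,
                              divergence: float = 0.15,
                              rng_seed: int = 0) -> list[ProteinRecord]:
    """Synthetic seed set for one family: the ancestor plus mutated
    copies, all equal length (substitution-only, hence trivially
    aligned)."""
    rng = np.random.default_rng(rng_seed)
    ancestor = family_ancestor(family)
    tag = family.replace("/", "")
    seeds = [ProteinRecord(
        f"{tag}_seed_00", ancestor,
        f"synthetic {family}-family porin seed (simulated, not a database accession)")]
    for k in range(1, n_seeds):
        seeds.append(ProteinRecord(
            f"{tag}_seed_{k:02d}", mutate_protein(ancestor, divergence, rng),
            f"synthetic {family}-family porin seed (simulated, not a database accession)"))
    return seeds


@dataclass(frozen=True)
class OperonTruth:
    scaffold_id: str
    porin_id: str
    mhc_ids: tuple[str, ...]
    family: str
    tm_strands: int
    gene_gap: int
    expect_cluster: bool  # under the default window (2) and TM rule (>= 14)


def make_pcc_operon(family: str, n_mhc: int = 1, tm_strands: int = 16,
                    gene_gap: int = 0, rng_seed: int = 0,
                    scaffold_id: str = "operon_scaffold",
                    mutation_rate: float = 0.05, n_flanking: int = 2,
                    max_intervening: int = 2
                    ) -> tuple[list[GeneCall], OperonTruth]:
    """Plant a porin-cytochrome operon on one scaffold.

    Layout: ``n_flanking`` filler genes, the porin (a family-ancestor
    derivative with ``tm_strands`` barrel strands, mutated at
    ``mutation_rate``), ``gene_gap`` intervening fillers, ``n_mhc``
    multiheme cytochrome genes, then ``n_flanking`` more fillers.  The
    truth records the planted transmembrane count (the recommended
    override for the strand heuristic) and whether the default calling
    rule should produce a cluster.
    """
    rng = np.random.default_rng(rng_seed)
    porin_seq = mutate_protein(family_ancestor(family, n_strands=tm_strands),
                               mutation_rate, rng)
    proteins: list[ProteinRecord] = []
    for k in range(n_flanking):
        proteins.append(make_filler_protein(
            int(rng.integers(120, 200)), int(rng.integers(0, 2**31)),
            f"{scaffold_id}_f{k}"))
    porin_id = f"{scaffold_id}_porin"
    proteins.append(ProteinRecord(porin_id, porin_seq))
    for k in range(gene_gap):
        proteins.append(make_filler_protein(
            int(rng.integers(120, 200)), int(rng.integers(0, 2**31)),
            f"{scaffold_id}_g{k}"))
    mhc_ids = []
    for k in range(n_mhc):
        pid = f"{scaffold_id}_mhc{k}"
        n_motifs = int(rng.integers(3, 12))
        rec, _ = make_mhc_protein(n_motifs, max(7 * n_motifs + 40, 150),
                                  int(rng.integers(0, 2**31)), pid)
        proteins.append(rec)
        mhc_ids.append(pid)
    for k in range(n_flanking):
        proteins.append(make_filler_protein(
            int(rng.integers(120, 200)), int(rng.integers(0, 2**31)),
            f"{scaffold_id}_t{k}"))

    genes: list[GeneCall] = []
    pos = 1
    for prot in proteins:
        end = pos + 3 * len(prot) + 2
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneCall(prot.id, scaffold_id, pos, end, strand,
                              ordinal=-1, protein=prot))
        pos = end + int(rng.integers(20, 120))
    genes = assign_ordinals(genes)
    truth = OperonTruth(
        scaffold_id=scaffold_id, porin_id=porin_id, mhc_ids=tuple(mhc_ids),
        family=family, tm_strands=tm_strands, gene_gap=gene_gap,
        expect_cluster=(tm_strands >= pcc.TM_MIN_STRANDS
                        and gene_gap <= max_intervening and n_mhc > 0))
    return genes, truth


# ---------------------------------------------------------------------------
# Genome pairs


@dataclass(frozen=True)
class PairTruth:
    bin_a: str
    bin_b: str
    substitution_rate: float
    realized_identity_pct: float   # over the related region
    unrelated_fraction: float


def make_genome_pair(length: int, d: float, rng_seed: int,
                     unrelated_fraction: float = 0.0,
                     bin_ids: tuple[str, str] = ("binA", "binB")
                     ) -> tuple[GenomeBin, GenomeBin, PairTruth]:
    """Generate two genome bins from a common ancestor.

    The second genome differs from the first by independent per-site
    substitutions at rate ``d`` (always to a different base); optionally
    its trailing ``unrelated_fraction`` is replaced by fresh random
    sequence to control the alignable fraction.  The truth carries the
    realized identity of the related region.
    """
    rng = np.random.default_rng(rng_seed)
    a = rng.integers(0, 4, length)
    mask = rng.random(length) < d
    shift = rng.integers(1, 4, length)
    b = np.where(mask, (a + shift) % 4, a)
    n_unrelated = int(round(unrelated_fraction * length))
    related_len = length - n_unrelated
    if n_unrelated:
        b[related_len:] = rng.integers(0, 4, n_unrelated)
    n_mut = int(mask[:related_len].sum())
    seq_a = "".join(NUC[a])
    seq_b = "".join(NUC[b])
    bin_a = GenomeBin(bin_ids[0], scaffolds=[(f"{bin_ids[0]}_s0", seq_a)])
    bin_b = GenomeBin(bin_ids[1], scaffolds=[(f"{bin_ids[1]}_s0", seq_b)])
    truth = PairTruth(bin_ids[0], bin_ids[1], d,
                      100.0 * (1 - n_mut / related_len), unrelated_fraction)
    return bin_a, bin_b, truth


# ---------------------------------------------------------------------------
# SCG inventories


def make_bin_inventory(domain: str, present: int | Sequence[str],
                       multi: int | Sequence[str] = 0,
                       contig_lengths: Sequence[int] = (100_000,),
                       bin_id: str = "bin") -> tuple[SCGInventory, GenomeBin]:
    """Build an SCG inventory (and a sequence-free bin stub) with
    controlled marker presence and multiplicity.  ``present``/``multi``
    may be counts (the first k markers of the domain universe) or
    explicit marker-id lists."""
    universe = marker_ids(domain)
    if isinstance(present, int):
        present_ids = set(universe[:present])
    else:
        present_ids = set(present)
    if isinstance(multi, int):
        multi_ids = set(sorted(present_ids)[:multi])
    else:
        multi_ids = set(multi)
    multiplicity = {m: 2 for m in multi_ids}
    inv = SCGInventory(bin_id=bin_id, domain=domain, present=present_ids,
                       multiplicity=multiplicity)
    stub = GenomeBin(bin_id, contig_lengths=list(contig_lengths))
    return inv, stub
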