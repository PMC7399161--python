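"""Genome-bin quality scoring and de-replication.

Completeness is estimated from a universal single-copy-gene (SCG)
inventory: 51 markers for bacteria, 38 for archaea.  A bin is draft
quality when at least 70% of the markers are present (36 of 51 for
bacteria, 27 of 38 for archaea) and near-complete at >= 90% (46 and 35).
Bins are ranked by the score

    score = (number of non-redundant SCGs) - 2 x (number of multi-copy SCGs)

which penalises likely contamination twice as hard as it rewards
completeness.

Bins recovered from related samples are de-replicated: pairs that are at
least 98% identical across 70% or more of a bin's total length are
single-linkage clustered, and each cluster's representative is the member
with the highest score, breaking ties by largest N50, then largest total
size, then lexicographically smallest bin id.

Pairwise similarity is fragment-based: the query bin's scaffolds are cut
into 1-kb fragments, each fragment is anchored in the subject by shared
15-mers (diagonal voting) and aligned within a +/-50 bp band (edlib);
identity is the aligned-length-weighted mean over fragments that align
over >= 60% of their length at >= 70% identity, and the aligned fraction
is aligned bases over the query's total length.  Because the similarity
threshold is printed at whole-percent precision, the identity comparison
is applied at that precision (a pair at 97.6% identity meets a 98%
threshold); set ``id_precision=0`` for exact comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import edlib

from .seqio import GenomeBin

SCG_UNIVERSE = {"bacteria": 51, "archaea": 38}
DRAFT_FRACTION = 0.70
NEAR_COMPLETE_FRACTION = 0.90
DEREP_ID_MIN = 98.0
DEREP_COV_MIN = 0.70

FRAG_LEN = 1000
KMER = 15
BAND = 50
FRAG_MIN_COVERAGE = 0.60
FRAG_MIN_IDENTITY = 70.0


def marker_ids(domain: str) -> list[str]:
    """Synthetic marker-id universe for one domain (scg_b_01.., scg_a_01..)."""
    n = SCG_UNIVERSE[domain]
    tag = domain[0]
    return [f"scg_{tag}_{i:02d}" for i in range(1, n + 1)]


@dataclass
class SCGInventory:
    bin_id: str
    domain: str
    present: set[str] = field(default_factory=set)
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in SCG_UNIVERSE:
            raise ValueError(f"unknown domain {self.domain!r}")
        if len(self.present) > SCG_UNIVERSE[self.domain]:
            raise ValueError(
                f"bin {self.bin_id!r}: more markers than the "
                f"{self.domain} universe of {SCG_UNIVERSE[self.domain]}")
        bad = set(self.multiplicity) - self.present
        if bad:
            raise ValueError(
                f"bin {self.bin_id!r}: multiplicity for absent markers {sorted(bad)}")

    @property
    def universe(self) -> int:
        return SCG_UNIVERSE[self.domain]

    @property
    def n_multi(self) -> int:
        return sum(1 for c in self.multiplicity.values() if c >= 2)


@dataclass(frozen=True)
class QualityCall:
    completeness: float
    tier: str  # near_complete | draft | below


@dataclass(frozen=True)
class PairSimilarity:
    identity_pct: float
    aligned_fraction: float


@dataclass(frozen=True)
class DerepCluster:
    cluster_id: int
    members: tuple[str, ...]
    representative: str
    pairwise: Mapping[tuple[str, str], PairSimilarity]


def completeness_tier(inv: SCGInventory) -> QualityCall:
    """Tier a bin by SCG completeness with 70% / 90% thresholds.

    Equivalently, the integer cutoffs are the smallest marker counts
    meeting each fraction: 36 and 46 for bacteria, 27 and 35 for archaea.
    """
    completeness = len(inv.present) / inv.universe
    if completeness >= NEAR_COMPLETE_FRACTION:
        tier = "near_complete"
    elif completeness >= DRAFT_FRACTION:
        tier = "draft"
    else:
        tier = "below"
    return QualityCall(completeness=completeness, tier=tier)


def tier_cutoff(domain: str, fraction: float) -> int:
    """Smallest integer marker count whose completeness meets ``fraction``."""
    return ceil(fraction * SCG_UNIVERSE[domain])


def bin_score(inv: SCGInventory) -> int:
    """(non-redundant SCGs) - 2 x (multi-copy SCGs); may be negative."""
    return len(inv.present) - 2 * inv.n_multi


def n50(contig_lengths: Sequence[int]) -> int:
    """Smallest contig length at which the descending running sum first
    reaches half the total assembly length."""
    if not contig_lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return int(l)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Fragment-based genome similarity

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _concat(bin_: GenomeBin) -> str:
    if not bin_.scaffolds:
        raise ValueError(
            f"bin {bin_.bin_id!r} has no nucleotide scaffolds; sequence "
            "similarity needs sequences (use marker-only QC otherwise)")
    return ("N" * KMER).join(seq for _, seq in bin_.scaffolds)


def _kmer_index(seq: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(0, len(seq) - KMER + 1):
        kmer = seq[i:i + KMER]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _best_diagonal(frag: str, index: Mapping[str, list[int]],
                   stride: int = 25) -> int | None:
    votes: dict[int, int] = {}
    for q in range(0, len(frag) - KMER + 1, stride):
        for t in index.get(frag[q:q + KMER], ()):
            bucket = (t - q) // BAND
            votes[bucket] = votes.get(bucket, 0) + 1
    if not votes:
        return None
    best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    if best[1] < 2:
        return None
    return best[0] * BAND


def _align_fragment(frag: str, target: str, diag: int
                    ) -> tuple[int, float] | None:
    """Banded alignment of a fragment at an anchored diagonal; returns
    (aligned query bases, identity%) or None when the hit fails the
    per-fragment coverage/identity filters."""
    lo = max(0, diag - BAND)
    hi = min(len(target), diag + len(frag) + BAND)
    window = target[lo:hi]
    if len(window) < KMER:
        return None
    res = edlib.align(frag, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    matches = cols = qbases = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        cols += n
        if op == "=":
            matches += n
            qbases += n
        elif op in ("X", "M"):
            qbases += n
        elif op == "I":  # edlib: I consumes the target in HW query-vs-target
            pass
        elif op == "D":
            qbases += n
    # edlib cigar orientation: verify query consumption adds up; fall back
    # to fragment length (HW aligns the full query).
    if qbases != len(frag):
        qbases = len(frag)
    identity = 100.0 * matches / cols if cols else 0.0
    if identity < FRAG_MIN_IDENTITY:
        return None
    if qbases / len(frag) < FRAG_MIN_COVERAGE:
        return None
    return qbases, identity


def genome_similarity(bin_a: GenomeBin, bin_b: GenomeBin,
                      frag_len: int = FRAG_LEN) -> PairSimilarity:
    """Directional similarity of bin A against bin B.

    A's scaffolds are cut into ``frag_len`` pieces, each anchored and
    aligned in B; identity is the aligned-length-weighted mean over
    aligned fragments and the aligned fraction is aligned bases over A's
    total length.
    """
    if not bin_a.scaffolds:
        raise ValueError(
            f"bin {bin_a.bin_id!r} has no nucleotide scaffolds; sequence "
            "similarity needs sequences (use marker-only QC otherwise)")
    target = _concat(bin_b)
    index = _kmer_index(target)
    total = sum(len(seq) for _, seq in bin_a.scaffolds)
    aligned_bases = 0
    weighted_identity = 0.0
    for _, seq in bin_a.scaffolds:
        for off in range(0, len(seq), frag_len):
            frag = seq[off:off + frag_len]
            if len(frag) < KMER:
                continue
            diag = _best_diagonal(frag, index)
            if diag is None:
                continue
            hit = _align_fragment(frag, target, diag)
            if hit is None:
                continue
            qbases, identity = hit
            aligned_bases += qbases
            weighted_identity += qbases * identity
    if aligned_bases == 0:
        return PairSimilarity(identity_pct=0.0, aligned_fraction=0.0)
    return PairSimilarity(identity_pct=weighted_identity / aligned_bases,
                          aligned_fraction=aligned_bases / total)


# ---------------------------------------------------------------------------
# De-replication


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pair_passes(sim_ab: PairSimilarity, sim_ba: PairSimilarity,
                id_min: float = DEREP_ID_MIN, cov_min: float = DEREP_COV_MIN,
                id_precision: float = 1.0, semantics: str = "or") -> bool:
    """Whether a bin pair meets the similarity rule.

    The identity threshold is applied at its printed precision
    (``id_min - id_precision/2``); the coverage threshold is exact.  With
    "or" semantics (default) the pair passes if either direction passes;
    "and" requires both.
    """
    id_cut = id_min - id_precision / 2.0
    ok_ab = sim_ab.identity_pct >= id_cut and sim_ab.aligned_fraction >= cov_min
    ok_ba = sim_ba.identity_pct >= id_cut and sim_ba.aligned_fraction >= cov_min
    return (ok_ab or ok_ba) if semantics == "or" else (ok_ab and ok_ba)


def dereplicate(bins: Sequence[GenomeBin],
                inventories: Mapping[str, SCGInventory],
                id_min: float = DEREP_ID_MIN, cov_min: float = DEREP_COV_MIN,
                id_precision: float = 1.0, semantics: str = "or",
                similarities: Mapping[tuple[str, str], PairSimilarity] | None = None,
                ) -> list[DerepCluster]:
    """Single-linkage de-replication with representative selection.

    Pairs passing the 98%/70% rule (see :func:`pair_passes`) are linked;
    each cluster's representative maximises bin score, then N50, then
    total size, with the lexicographically smallest bin id as the final
    deterministic tie-break.  Pass ``similarities`` to reuse precomputed
    directional pairs (keyed (query, subject)); otherwise they are
    computed here.
    """
    by_id = {b.bin_id: b for b in bins}
    for bid in by_id:
        if bid not in inventories:
            raise ValueError(f"bin {bid!r} has no SCG inventory")
    ids = sorted(by_id)
    sims: dict[tuple[str, str], PairSimilarity] = dict(similarities or {})
    uf = _UnionFind(ids)
    pair_stats: dict[tuple[str, str], PairSimilarity] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if (a, b) not in sims:
                sims[(a, b)] = genome_similarity(by_id[a], by_id[b])
            if (b, a) not in sims:
                sims[(b, a)] = genome_similarity(by_id[b], by_id[a])
            if pair_passes(sims[(a, b)], sims[(b, a)], id_min, cov_min,
                           id_precision, semantics):
                uf.union(a, b)
                pair_stats[(a, b)] = sims[(a, b)]
                pair_stats[(b, a)] = sims[(b, a)]

    groups: dict[str, list[str]] = {}
    for bid in ids:
        groups.setdefault(uf.find(bid), []).append(bid)

    clusters: list[DerepCluster] = []
    for k, root in enumerate(sorted(groups)):
        members = sorted(groups[root])

        def rank(bid: str):
            inv = inventories[bid]
            b = by_id[bid]
            return (-bin_score(inv), -n50(b.contig_lengths), -b.total_size, bid)

        rep = min(members, key=rank)
        pairs = {pr: s for pr, s in pair_stats.items()
                 if pr[0] in members and pr[1] in members}
        clusters.append(DerepCluster(cluster_id=k, members=tuple(members),
                                     representative=rep, pairwise=pairs))
    return clusters
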