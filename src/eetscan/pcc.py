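"""Porin-cytochrome complex (PCC) calling.

In Gram-negative electroactive bacteria, electrons reach the cell exterior
through trans-outer-membrane conduits built from a beta-barrel porin and
one or more multiheme cytochromes encoded next to it.  This module finds
candidate porins by scoring proteins against four reference porin families
(MtrB, OmbB, ExtB/E, ExtI), requires a minimum number of predicted
transmembrane beta strands, and calls a PCC wherever a passing porin gene
sits within a small number of genes of a multiheme cytochrome on the same
scaffold.

Homology scoring is a position-specific scoring matrix (PSSM) built from a
seed alignment per family, combined with affine-gap local alignment
(Smith-Waterman, gap open 10 / extend 1) and a within-sequence shuffle
null: a protein is a candidate when its score sits ``z_min`` standard
deviations above the mean of its own shuffles.  Transmembrane strand
counts come from an alternating-hydropathy heuristic, and an externally
supplied count table always overrides the heuristic.

The dynamic programme is vectorised over profile columns with the
standard running-maximum trick for the horizontal (profile-gap) state,
which is exact because re-opening a gap from a cell that itself ends in
a horizontal gap can never beat extending (open >= extend).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .hemescan import MHCProfile
from .seqio import GeneCall, ProteinRecord, read_fasta

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
PORIN_FAMILIES = ("MtrB", "OmbB", "ExtB/E", "ExtI")

GAP_OPEN = 10.0
GAP_EXTEND = 1.0
TM_MIN_STRANDS = 14
DEFAULT_Z_MIN = 6.0
DEFAULT_N_SHUFFLES = 200

# Kyte-Doolittle hydropathy, z-normalised over the 20 standard residues so
# that the alternating-strand statistic is scale-free; X scores 0.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_KD_MEAN = sum(_KD.values()) / 20.0
_KD_SD = math.sqrt(sum((v - _KD_MEAN) ** 2 for v in _KD.values()) / 20.0)
HYDROPATHY_Z = {aa: (v - _KD_MEAN) / _KD_SD for aa, v in _KD.items()}

TM_WINDOW = 9
TM_AMPLITUDE_MIN = 0.6
TM_MIN_RUN = 5
TM_MERGE_GAP = 3
TM_MIN_LENGTH = 50


@dataclass(frozen=True)
class PorinProfile:
    """Log-odds profile over the columns of one family's seed alignment."""

    family: str
    pssm: np.ndarray  # (n_columns, 21): 20 residues + neutral X row
    seed_self_scores: tuple[float, ...]

    @property
    def n_columns(self) -> int:
        return self.pssm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pssm[:, :20].max(axis=1).sum())


@dataclass(frozen=True)
class PorinCandidate:
    protein_id: str
    family: str
    score: float
    shuffle_z: float
    tm_strands: int
    tm_too_short: bool = False
    tm_from_override: bool = False

    @property
    def passes_tm(self) -> bool:
        return self.tm_strands >= TM_MIN_STRANDS


@dataclass(frozen=True)
class PCCCluster:
    """A porin candidate plus the multiheme cytochromes in its gene
    neighbourhood on one scaffold."""

    scaffold_id: str
    porin: PorinCandidate
    porin_gene: GeneCall
    mhcs: tuple[tuple[GeneCall, MHCProfile], ...]
    max_gene_gap: int
    family: str


# ---------------------------------------------------------------------------
# Profile construction


def build_profile(family: str, seed_alignment: Sequence[ProteinRecord],
                  max_gap_fraction: float = 0.5) -> PorinProfile:
    """Build a log-odds PSSM from an aligned seed set.

    Columns with more than ``max_gap_fraction`` gap characters are
    dropped.  The background q mixes the seed-set mean composition 50/50
    with the uniform distribution; per-column frequencies use one
    background-proportional pseudocount, f_a = (c_a + q_a) / (n + 1), and
    scores are log2(f_a / q_a).  (A flat per-residue pseudocount would let
    a strongly skewed seed composition invert the log-odds sign at fully
    conserved columns.)
    """
    if len(seed_alignment) < 2:
        raise ValueError(f"family {family}: need at least 2 aligned seeds")
    rows = [p.residues for p in seed_alignment]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"family {family}: seed sequences are not aligned "
                         "(ragged lengths)")
    mat = np.array([[ch for ch in r] for r in rows])
    keep = (mat == "-").mean(axis=0) <= max_gap_fraction
    mat = mat[:, keep]

    counts = np.zeros((mat.shape[1], 20))
    for j in range(mat.shape[1]):
        for ch in mat[:, j]:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[j, idx] += 1
    comp = counts.sum(axis=0)
    comp = comp / comp.sum() if comp.sum() else np.full(20, 0.05)
    background = 0.5 * comp + 0.5 / 20.0
    freqs = ((counts + background[None, :])
             / (counts.sum(axis=1, keepdims=True) + 1.0))
    pssm20 = np.log2(freqs / background[None, :])
    pssm = np.hstack([pssm20, np.zeros((pssm20.shape[0], 1))])

    prof = PorinProfile(family=family, pssm=pssm, seed_self_scores=())
    selfs = tuple(
        local_profile_score(prof, p.residues.replace("-", "")) for p in seed_alignment
    )
    return replace(prof, seed_self_scores=selfs)


def encode(seq: str) -> np.ndarray:
    """Map residues to PSSM row indices; anything non-standard -> the
    neutral X row (index 20)."""
    return np.fromiter((AA_INDEX.get(ch, 20) for ch in seq), dtype=np.intp,
                       count=len(seq))


def _align_batch(pssm: np.ndarray, seqs: np.ndarray) -> np.ndarray:
    """Best local affine-gap alignment score of each row of ``seqs``
    (encoded residue indices, shape (B, L)) against the profile."""
    ncol = pssm.shape[0]
    B, L = seqs.shape
    scores_by_col = pssm.T  # (21, ncol)
    H = np.zeros((B, ncol))
    F = np.full((B, ncol), -np.inf)
    best = np.zeros(B)
    jix = np.arange(ncol)
    for i in range(L):
        S = scores_by_col[seqs[:, i]]  # (B, ncol)
        diag = np.empty_like(H)
        diag[:, 0] = S[:, 0]
        diag[:, 1:] = H[:, :-1] + S[:, 1:]
        F = np.maximum(H - GAP_OPEN, F - GAP_EXTEND)
        G = np.maximum(np.maximum(diag, F), 0.0)
        # E[j] = max_{j'<j} G[j'] - open - (j-1-j')*extend, via running max
        T = np.maximum.accumulate(G + GAP_EXTEND * jix, axis=1)
        E = np.full_like(G, -np.inf)
        E[:, 1:] = T[:, :-1] - GAP_OPEN - GAP_EXTEND * (jix[1:] - 1)
        H = np.maximum(G, E)
        best = np.maximum(best, H.max(axis=1))
    return best


def local_profile_score(profile: PorinProfile, seq: str) -> float:
    return float(_align_batch(profile.pssm, encode(seq)[None, :])[0])


# ---------------------------------------------------------------------------
# Transmembrane beta-strand heuristic


@dataclass(frozen=True)
class TMPrediction:
    n_strands: int
    too_short: bool = False


def estimate_tm_strands(protein: ProteinRecord) -> TMPrediction:
    """Estimate the number of transmembrane beta strands.

    Membrane beta strands alternate lipid-facing hydrophobic and
    lumen-facing polar residues.  The statistic A(i) is the mean over a
    centred 9-residue window of z-normalised hydropathy multiplied by
    (-1)^offset; positions with |A(i)| >= 0.6 mark strand cores.  Maximal
    qualifying runs of length >= 5 are counted as strands, merging runs
    separated by fewer than 3 positions.  This is a deliberately simple
    stand-in for a dedicated beta-barrel topology predictor: supply a
    count table to ``search``/``annotate_tm`` to override it on real data.
    """
    seq = protein.residues
    n = len(seq)
    if n < TM_MIN_LENGTH:
        return TMPrediction(0, too_short=True)
    h = np.array([HYDROPATHY_Z.get(ch, 0.0) for ch in seq])
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    alt = h * signs
    kernel = np.ones(TM_WINDOW) / TM_WINDOW
    amp = np.abs(np.convolve(alt, kernel, mode="valid"))  # centre i = idx+half
    qualifying = amp >= TM_AMPLITUDE_MIN

    runs: list[tuple[int, int]] = []
    start = None
    for i, q in enumerate(qualifying):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(qualifying) - 1))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < TM_MERGE_GAP:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    n_strands = sum(1 for s, e in merged if e - s + 1 >= TM_MIN_RUN)
    return TMPrediction(n_strands)


# ---------------------------------------------------------------------------
# Candidate search


def search(profile: PorinProfile, proteins: Sequence[ProteinRecord],
           n_shuffles: int = DEFAULT_N_SHUFFLES, z_min: float = DEFAULT_Z_MIN,
           rng_seed: int = 0,
           tm_overrides: Mapping[str, int] | None = None
           ) -> list[PorinCandidate]:
    """Score proteins against a family profile with a shuffle null.

    Each protein's best local alignment score is compared with the scores
    of ``n_shuffles`` within-sequence residue shuffles; candidates are the
    proteins with z >= ``z_min``.  Deterministic given ``rng_seed``.
    Transmembrane strand counts come from ``tm_overrides`` where present,
    else the alternating-hydropathy heuristic.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    rng = np.random.default_rng(rng_seed)
    out: list[PorinCandidate] = []
    for prot in proteins:
        enc = encode(prot.residues)
        score = float(_align_batch(profile.pssm, enc[None, :])[0])
        shuffles = np.stack([rng.permutation(enc) for _ in range(n_shuffles)])
        null = _align_batch(profile.pssm, shuffles)
        sd = float(null.std())
        z = (score - float(null.mean())) / max(sd, 1e-9)
        if z >= z_min:
            if tm_overrides is not None and prot.id in tm_overrides:
                tm, too_short, overridden = int(tm_overrides[prot.id]), False, True
            else:
                pred = estimate_tm_strands(prot)
                tm, too_short, overridden = pred.n_strands, pred.too_short, False
            out.append(PorinCandidate(
                protein_id=prot.id, family=profile.family, score=score,
                shuffle_z=z, tm_strands=tm, tm_too_short=too_short,
                tm_from_override=overridden))
    return out


# ---------------------------------------------------------------------------
# Gene-neighbourhood PCC calling


def call_pcc(genes: Sequence[GeneCall],
             porin_candidates: Sequence[PorinCandidate],
             mhc_profiles: Sequence[MHCProfile],
             max_intervening: int = 2) -> list[PCCCluster]:
    """Call porin-cytochrome complexes from gene neighbourhoods.

    One cluster per porin candidate that passes the transmembrane-strand
    minimum and has at least one multiheme cytochrome (>= 3 motifs) within
    ``max_intervening`` intervening genes on the same scaffold; the
    cluster collects every MHC inside the window.  Strand agreement is not
    required.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    profile_by_id = {p.protein_id: p for p in mhc_profiles}
    by_scaffold: dict[str, dict[int, GeneCall]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, {})[g.ordinal] = g

    clusters: list[PCCCluster] = []
    for cand in porin_candidates:
        if not cand.passes_tm:
            continue
        gene = gene_by_id.get(cand.protein_id)
        if gene is None:
            continue
        neighbours = by_scaffold[gene.scaffold_id]
        hits: list[tuple[GeneCall, MHCProfile]] = []
        best_gap: int | None = None
        for delta in range(-(max_intervening + 1), max_intervening + 2):
            if delta == 0:
                continue
            other = neighbours.get(gene.ordinal + delta)
            if other is None:
                continue
            prof = profile_by_id.get(other.gene_id)
            if prof is None or not prof.is_mhc:
                continue
            gap = abs(delta) - 1
            hits.append((other, prof))
            best_gap = gap if best_gap is None else min(best_gap, gap)
        if hits:
            hits.sort(key=lambda t: t[0].ordinal)
            clusters.append(PCCCluster(
                scaffold_id=gene.scaffold_id, porin=cand, porin_gene=gene,
                mhcs=tuple(hits), max_gene_gap=best_gap, family=cand.family))
    return clusters


# ---------------------------------------------------------------------------
# Fixtures

_FIXTURE_NAMES = {
    "MtrB": "synthetic_porin_seed_MtrB.fasta",
    "OmbB": "synthetic_porin_seed_OmbB.fasta",
    "ExtB/E": "synthetic_porin_seed_ExtBE.fasta",
    "ExtI": "synthetic_porin_seed_ExtI.fasta",
}


def load_seed_alignment(family: str) -> list[ProteinRecord]:
    """Load the packaged synthetic seed alignment for one porin family.

    These seeds are synthetic stand-ins generated by the community
    simulator (see the fixture headers), not database sequences.
    """
    if family not in _FIXTURE_NAMES:
        raise ValueError(f"unknown porin family {family!r}; "
                         f"expected one of {PORIN_FAMILIES}")
    ref = resources.files("eetscan.fixtures") / _FIXTURE_NAMES[family]
    with resources.as_file(ref) as path:
        return read_fasta(path, alphabet="protein")


def load_all_profiles() -> dict[str, PorinProfile]:
    return {fam: build_profile(fam, load_seed_alignment(fam))
            for fam in PORIN_FAMILIES}
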