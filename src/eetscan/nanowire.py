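"""Electrically conductive "nanowire" candidates: e-pilins and OmcS.

Two filament types are screened.  Type-IV pili become candidate "e-pili"
when the mature pilin is dense in aromatic residues (F, W, Y, H), whose
stacked side chains are thought to support electron delocalisation along
the filament.  Separately, OmcS-like hexaheme cytochromes polymerise into
conductive filaments and are found by sequence similarity to a query
cytochrome with a length cutoff.

Pilin processing: a class-III signal peptidase cleaves the prepilin
leader immediately before the mature N-terminal phenylalanine; the
heuristic here looks for the canonical G|[hydrophobic] junction with a
glutamate five residues into the mature sequence (E5).  A supplied
cleavage-position table always overrides the heuristic.

The strict e-pilin tier requires, over the mature sequence:

* aromatic density >= 9.8% within the assessment window (residues 1-59
  when the mature sequence is that long, otherwise the whole sequence);
* no stretch of more than 22 consecutive non-aromatic residues between
  successive aromatics (terminal flanks excluded);
* aromatic residues at mature positions 1, 24, 27, 50 and/or 51, and
  32 and/or 57 — positions shown to be essential for conductivity.

Failing strict, a candidate is "relaxed" when its whole-mature aromatic
fraction is at least 8%, else "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .hemescan import find_heme_motifs
from .seqio import ProteinRecord, read_fasta

AROMATIC = frozenset("FWYH")
LEADER_HYDROPHOBIC = frozenset("FMLIVAST")
LEADER_MIN_POS = 6
LEADER_MAX_POS = 40
STRICT_PCT_MIN = 9.8
RELAXED_PCT_MIN = 8.0
MAX_AROMATIC_GAP = 22
DENSITY_WINDOW = 59
KEY_POSITIONS = (("1", (1,)), ("24", (24,)), ("27", (27,)),
                 ("50/51", (50, 51)), ("32/57", (32, 57)))
OMCS_LEN_MAX = 500
OMCS_IDENTITY_MIN = 25.0


@dataclass(frozen=True)
class AromaticMetrics:
    aromatic_count: int
    mature_length: int
    aromatic_pct: float      # over the assessment window (residues 1-59)
    full_length_pct: float   # over the whole mature sequence
    max_gap: int


@dataclass(frozen=True)
class PilinCandidate:
    protein_id: str
    cleavage_pos: int         # last pre-pilin residue; mature starts next
    mature: str
    metrics: AromaticMetrics
    position_flags: tuple[bool, ...]  # parallel to KEY_POSITIONS
    tier: str                 # strict | relaxed | none


@dataclass(frozen=True)
class OmcSHit:
    protein_id: str
    identity_pct: float
    length: int
    n_cxxch: int
    coverage: float = 1.0  # aligned columns / reference length

    @property
    def passes_length(self) -> bool:
        return self.length <= OMCS_LEN_MAX


def detect_prepilin(protein: ProteinRecord,
                    require_e5: bool = True) -> int | None:
    """Locate the prepilin cleavage site, or None.

    Returns the 1-based position i of the leader's final glycine — the
    leftmost i with 6 <= i <= 40 where residue i is G, residue i+1 is
    hydrophobic/small (F, M, L, I, V, A, S or T) and residue i+5 is E.
    ``require_e5=False`` gives the relaxed mode that drops the glutamate
    condition.
    """
    seq = protein.residues
    if len(seq) < 30:
        return None
    hi = min(LEADER_MAX_POS, len(seq) - 5)
    for i in range(LEADER_MIN_POS, hi + 1):
        if seq[i - 1] != "G" or seq[i] not in LEADER_HYDROPHOBIC:
            continue
        if require_e5 and seq[i + 4] != "E":
            continue
        return i
    return None


def aromatic_metrics(mature: str) -> AromaticMetrics:
    """Aromatic content of a mature pilin.

    The density percentage is computed over mature residues 1-59 when the
    sequence is at least 59 long, otherwise over the whole sequence; the
    count is over the whole sequence.  ``max_gap`` is the largest number
    of consecutive non-aromatic residues strictly between successive
    aromatics — flanks before the first and after the last aromatic are
    excluded; a sequence with fewer than two aromatics has max_gap 0,
    except the degenerate aromatic-free case where max_gap is defined as
    the mature length.
    """
    if not mature:
        raise ValueError("empty mature sequence")
    positions = [i for i, ch in enumerate(mature, start=1) if ch in AROMATIC]
    count = len(positions)
    window = min(DENSITY_WINDOW, len(mature))
    in_window = sum(1 for p in positions if p <= window)
    pct = 100.0 * in_window / window
    full_pct = 100.0 * count / len(mature)
    if count == 0:
        max_gap = len(mature)
    else:
        max_gap = max(
            (b - a - 1 for a, b in zip(positions, positions[1:])), default=0
        )
    return AromaticMetrics(aromatic_count=count, mature_length=len(mature),
                           aromatic_pct=pct, full_length_pct=full_pct,
                           max_gap=max_gap)


def position_flags(mature: str) -> tuple[bool, ...]:
    """Aromatic presence at the key mature positions (1, 24, 27, 50 or
    51, 32 or 57); positions beyond the sequence count as absent."""
    def at(p: int) -> bool:
        return p <= len(mature) and mature[p - 1] in AROMATIC

    return tuple(any(at(p) for p in group) for _, group in KEY_POSITIONS)


def classify_epilin(metrics: AromaticMetrics,
                    flags: Sequence[bool]) -> str:
    """Assign the e-pilin tier: strict, relaxed or none."""
    if (metrics.aromatic_pct >= STRICT_PCT_MIN
            and metrics.max_gap <= MAX_AROMATIC_GAP
            and all(flags)):
        return "strict"
    if metrics.full_length_pct >= RELAXED_PCT_MIN:
        return "relaxed"
    return "none"


def find_epilins(proteins: Sequence[ProteinRecord],
                 cleavage_overrides: Mapping[str, int] | None = None,
                 require_e5: bool = True,
                 reference: ProteinRecord | None = None,
                 ref_identity_min: float = 35.0,
                 ref_coverage_min: float = 0.5) -> list[PilinCandidate]:
    """Run prepilin detection, aromatic metrics and tier classification.

    Proteins without a detectable (or supplied) cleavage site are not
    candidates and are omitted.  When a ``reference`` pilin is given,
    candidates must additionally align to it at ``ref_identity_min``
    percent identity over ``ref_coverage_min`` of its length — the
    similarity pre-screen that restricts the aromatic criteria to actual
    pilin homologs rather than any protein with a pilin-like junction.
    """
    out: list[PilinCandidate] = []
    for prot in proteins:
        if reference is not None:
            ident, cov = local_identity(reference.residues, prot.residues)
            if ident < ref_identity_min or cov < ref_coverage_min:
                continue
        if cleavage_overrides is not None and prot.id in cleavage_overrides:
            pos = int(cleavage_overrides[prot.id])
            if not 1 <= pos < len(prot.residues):
                raise ValueError(
                    f"cleavage override for {prot.id!r} out of range: {pos}")
        else:
            if len(prot.residues) < 30:
                continue
            pos = detect_prepilin(prot, require_e5=require_e5)
        if pos is None:
            continue
        mature = prot.residues[pos:]
        metrics = aromatic_metrics(mature)
        flags = position_flags(mature)
        out.append(PilinCandidate(
            protein_id=prot.id, cleavage_pos=pos, mature=mature,
            metrics=metrics, position_flags=flags,
            tier=classify_epilin(metrics, flags)))
    return out


# ---------------------------------------------------------------------------
# OmcS homologs

_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _ALIGNER = a
    return _ALIGNER


def local_identity(query: str, target: str) -> tuple[float, float]:
    """Percent identity over the best local alignment (matched columns /
    aligned columns, gaps in the denominator) and the fraction of the
    query covered by the alignment."""
    q = query.replace("X", "A").replace("*", "")
    t = target.replace("X", "A").replace("*", "")
    aln = _aligner().align(q, t)
    if len(aln) == 0:
        return 0.0, 0.0
    best = aln[0]
    counts = best.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return 0.0, 0.0
    return 100.0 * counts.identities / cols, cols / len(q)


def find_omcs(proteins: Sequence[ProteinRecord],
              reference: ProteinRecord,
              identity_min: float = OMCS_IDENTITY_MIN,
              len_max: int = OMCS_LEN_MAX,
              coverage_min: float = 0.5) -> list[OmcSHit]:
    """Find OmcS-like cytochromes by local-alignment identity.

    Returns every protein whose best local alignment to the reference
    reaches ``identity_min`` percent identity over at least
    ``coverage_min`` of the reference length (the coverage requirement
    stands in for search significance: a short high-identity window in an
    unrelated protein is not homology).  ``passes_length`` flags the
    length cutoff (<= len_max, which removes large unrelated multiheme
    cytochromes that merely share motif-rich segments); ``n_cxxch``
    counts strict CxxCH motifs so reports can flag hexaheme homologs.
    """
    out: list[OmcSHit] = []
    for prot in proteins:
        ident, cov = local_identity(reference.residues, prot.residues)
        if ident < identity_min or cov < coverage_min:
            continue
        n_cxxch = len(find_heme_motifs(prot, min_x=2, max_x=2))
        out.append(OmcSHit(protein_id=prot.id, identity_pct=ident,
                           length=len(prot), n_cxxch=n_cxxch, coverage=cov))
    return out


def load_reference(name: str) -> ProteinRecord:
    """Load a packaged synthetic reference ("omcs" or "pilin").

    The packaged references are synthetic stand-ins generated by the
    community simulator, not database accessions.
    """
    fname = {"omcs": "synthetic_omcs_reference.fasta",
             "pilin": "synthetic_pilin_reference.fasta"}[name]
    ref = resources.files("eetscan.fixtures") / fname
    with resources.as_file(ref) as path:
        return read_fasta(path, alphabet="protein")[0]
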