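"""Sequence and annotation I/O plus the scaffold -> ordered-gene model.

Every downstream stage (motif scanning, porin-cytochrome calling, pilin
classification, bin QC) consumes the containers defined here:

* :class:`ProteinRecord` — a translated gene product.
* :class:`GeneCall` — a protein in its scaffold context, with 1-based
  inclusive nucleotide coordinates and a 0-based ordinal giving the gene's
  rank along its scaffold (sorted by start coordinate).  Gene-neighbourhood
  logic such as "porin within two genes of a multiheme cytochrome" is
  expressed in ordinal space.
* :class:`GenomeBin` — a genome bin: scaffold sequences, gene calls and
  contig lengths, as used by completeness scoring and de-replication.

Gene calls are accepted in three dialects: GFF3 (CDS features), a TSV gene
table (gene_id, scaffold_id, start, end, strand) and Prodigal-style protein
FASTA headers ("id # start # end # strand # ...").
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class SeqFormatError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A translated gene with a non-empty upper-case residue string.

    Residues are restricted to the 20 standard amino acids plus the
    ambiguity code ``X``; a single trailing stop symbol ``*`` is stripped
    on load.  ``X`` never matches C or H in downstream motif scans.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqFormatError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET or (ch == "*" and pos != len(self.residues)):
                raise SeqFormatError(
                    f"protein {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqFormatError(f"sequence {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise SeqFormatError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCall:
    """A protein-coding gene placed on a scaffold.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates
    (GFF3 convention); ``ordinal`` is the 0-based rank of the gene along
    its scaffold after sorting by start coordinate.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    ordinal: int
    protein: ProteinRecord

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SeqFormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise SeqFormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class GenomeBin:
    """A genome bin: scaffolds, gene calls and contig lengths."""

    bin_id: str
    scaffolds: list[tuple[str, str]] = field(default_factory=list)
    genes: list[GeneCall] = field(default_factory=list)
    contig_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scaffolds and not self.contig_lengths:
            self.contig_lengths = [len(seq) for _, seq in self.scaffolds]
        if self.scaffolds:
            lens = [len(seq) for _, seq in self.scaffolds]
            if lens != list(self.contig_lengths):
                raise SeqFormatError(
                    f"bin {self.bin_id!r}: contig_lengths disagree with scaffold sequences"
                )
            known = {sid for sid, _ in self.scaffolds}
            for g in self.genes:
                if g.scaffold_id not in known:
                    raise SeqFormatError(
                        f"bin {self.bin_id!r}: gene {g.gene_id!r} on unknown scaffold "
                        f"{g.scaffold_id!r}"
                    )
        if any(l <= 0 for l in self.contig_lengths):
            raise SeqFormatError(f"bin {self.bin_id!r}: non-positive contig length")

    @property
    def total_size(self) -> int:
        return int(sum(self.contig_lengths))


@dataclass
class LoadReport:
    """Bookkeeping for a gene-call load: skipped records are never silent."""

    n_loaded: int = 0
    n_skipped_no_protein: int = 0
    skipped_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a FASTA file into ProteinRecord or NucleotideRecord objects.

    Order is preserved and residues are upper-cased.  Duplicate ids and
    characters outside the alphabet are hard errors.  A single trailing
    ``*`` on a protein sequence is stripped.
    """
    if alphabet not in {"protein", "nucleotide"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if alphabet == "protein":
            if seq.endswith("*"):
                seq = seq[:-1]
            records.append(ProteinRecord(rec.id, seq, desc))
        else:
            records.append(NucleotideRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[ProteinRecord | NucleotideRecord],
                path: str | Path, width: int = 60) -> None:
    seqs = []
    for r in records:
        seq = r.residues if isinstance(r, ProteinRecord) else r.sequence
        seqs.append(SeqRecord(Seq(seq), id=r.id, description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Gene calls

_PRODIGAL_RE = re.compile(
    r"^\s*#?\s*(?P<start>\d+)\s*#\s*(?P<end>\d+)\s*#\s*(?P<strand>-?1|[+-])"
)


def assign_ordinals(genes: Sequence[GeneCall]) -> list[GeneCall]:
    """Re-rank genes per scaffold by ascending start coordinate.

    Ordinals are a pure function of coordinates: permuting the input order
    never changes the result.  Ties on start are broken by end, then id,
    for determinism.
    """
    out: list[GeneCall] = []
    by_scaffold: dict[str, list[GeneCall]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for sid in sorted(by_scaffold):
        ranked = sorted(by_scaffold[sid], key=lambda g: (g.start, g.end, g.gene_id))
        out.extend(replace(g, ordinal=i) for i, g in enumerate(ranked))
    return out


def _pair_proteins(rows, proteins: Mapping[str, ProteinRecord],
                   report: LoadReport) -> list[GeneCall]:
    calls = []
    for gene_id, scaffold_id, start, end, strand in rows:
        prot = proteins.get(gene_id)
        if prot is None:
            report.n_skipped_no_protein += 1
            report.skipped_ids.append(gene_id)
            warnings.warn(f"gene {gene_id!r}: no matching protein record; skipped")
            continue
        calls.append(GeneCall(gene_id, scaffold_id, int(start), int(end),
                              strand, ordinal=-1, protein=prot))
        report.n_loaded += 1
    return assign_ordinals(calls)


def read_gene_calls(path: str | Path, proteins: Sequence[ProteinRecord],
                    dialect: str = "auto") -> tuple[list[GeneCall], LoadReport]:
    """Load gene calls and pair them with protein records.

    dialect: "gff3", "table" (TSV with gene_id, scaffold_id, start, end,
    strand), "prodigal" (coordinates parsed from the protein FASTA header
    descriptions) or "auto" (sniffed from the file).  CDS features without
    a matching protein are skipped with a warning and counted in the
    returned LoadReport; start > end is a hard error.
    """
    prot_map = {p.id: p for p in proteins}
    if len(prot_map) != len(proteins):
        raise SeqFormatError("duplicate protein ids in gene-call pairing")
    report = LoadReport()
    path = Path(path)
    if dialect == "auto":
        head = path.read_text()[:2048] if path.exists() else ""
        if head.startswith("##gff") or "\tCDS\t" in head:
            dialect = "gff3"
        else:
            dialect = "table"
    if dialect == "gff3":
        rows = _iter_gff3_cds(path)
    elif dialect == "table":
        rows = _iter_gene_table(path)
    elif dialect == "prodigal":
        rows = _iter_prodigal(proteins)
    else:
        raise ValueError(f"unknown gene-call dialect {dialect!r}")
    return _pair_proteins(rows, prot_map, report), report


def _iter_gff3_cds(path: Path):
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.start > feat.end:
            raise SeqFormatError(f"gene {gene_id!r}: start {feat.start} > end {feat.end}")
        yield gene_id, feat.seqid, feat.start, feat.end, feat.strand


def _iter_gene_table(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold_id": str})
    required = ["gene_id", "scaffold_id", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SeqFormatError(f"gene table {path}: missing columns {missing}")
    for row in df.itertuples(index=False):
        if row.start > row.end:
            raise SeqFormatError(f"gene {row.gene_id!r}: start {row.start} > end {row.end}")
        yield row.gene_id, row.scaffold_id, int(row.start), int(row.end), row.strand


def _iter_prodigal(proteins: Sequence[ProteinRecord]):
    """Prodigal protein headers: ``>id_N # start # end # strand # ...``.

    The scaffold id is the protein id with the trailing ``_N`` gene number
    removed, as Prodigal writes it.
    """
    for p in proteins:
        m = _PRODIGAL_RE.match(p.description)
        if m is None:
            raise SeqFormatError(
                f"protein {p.id!r}: description is not a Prodigal coordinate header"
            )
        strand = m.group("strand")
        strand = {"1": "+", "-1": "-"}.get(strand, strand)
        scaffold_id = p.id.rsplit("_", 1)[0]
        yield p.id, scaffold_id, int(m.group("start")), int(m.group("end")), strand


def write_gene_table(genes: Sequence[GeneCall], path: str | Path) -> None:
    rows = [
        {"gene_id": g.gene_id, "scaffold_id": g.scaffold_id, "start": g.start,
         "end": g.end, "strand": g.strand}
        for g in genes
    ]
    schema = {"gene_id": "s", "scaffold_id": "s", "start": "d", "end": "d",
              "strand": "s"}
    write_table(rows, path, schema)


# ---------------------------------------------------------------------------
# TSV tables


def write_table(rows: Sequence[Mapping], path: str | Path,
                schema: Mapping[str, str]) -> None:
    """Write rows as a TSV with a header line and fixed float precision.

    ``schema`` maps column name to a format code: "s" (string), "d"
    (integer) or ".Nf" (float with N decimal places).  Rows must carry
    exactly the schema's columns; a violation is a hard error naming the
    offending column.
    """
    cols = list(schema)
    lines = ["\t".join(cols)]
    for i, row in enumerate(rows):
        cells = []
        for col in cols:
            if col not in row:
                raise SeqFormatError(f"row {i}: missing column {col!r}")
            val = row[col]
            fmt = schema[col]
            if val is None or (isinstance(val, float) and val != val):
                cells.append("NA")
            elif fmt == "s":
                cells.append(str(val))
            elif fmt == "d":
                if isinstance(val, bool) or (isinstance(val, float) and not float(val).is_integer()):
                    raise SeqFormatError(f"row {i}: column {col!r} is not an integer: {val!r}")
                cells.append(str(int(val)))
            elif fmt.startswith(".") and fmt.endswith("f"):
                cells.append(f"{float(val):{fmt}}")
            else:
                raise SeqFormatError(f"schema: unknown format {fmt!r} for column {col!r}")
        extra = set(row) - set(cols)
        if extra:
            raise SeqFormatError(f"row {i}: unexpected column {sorted(extra)[0]!r}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold_id": str,
                                              "protein_id": str, "bin_id": str})
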