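"""Multiheme c-type cytochrome detection and localization summaries.

Heme c attaches covalently to the apoprotein at C-x(2,4)-C-H motifs
(cysteine, 2-4 variable residues, cysteine, histidine).  A protein with
three or more such motifs is classified as a multiheme cytochrome (MHC);
those with >= 10 motifs are flagged as large.  The scanner reports the
maximum number of mutually non-overlapping motif occurrences: it walks
left to right, at each candidate cysteine tries the shortest extension
first (2 variable residues before 3 before 4) and resumes after the
matched histidine.  Earliest-end greedy selection is optimal for
non-overlapping interval scheduling, and a brute-force oracle verifies
this in the test suite.

The ambiguity code X never matches C or H.

Per-protein profiles carry the heme-density statistic length/h (residues
per heme — densely packed "molecular wire" cytochromes sit near 22-25),
a size class over the heme-count strata used in reporting (3-14, 15-27,
30-53 motifs), and optional subcellular-localization and signal-peptide
labels merged from external predictor tables.  Summaries pivot these into
a localization count/percentage matrix and signal-peptide fractions for
small (3-20 motifs) versus large (>20) cytochromes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import ProteinRecord, SeqFormatError

MHC_MIN_MOTIFS = 3
LARGE_MHC_MIN_MOTIFS = 10
SIZE_CLASSES = (("3–14", 3, 14), ("15–27", 15, 27), ("30–53", 30, 53))
LOCALIZATION_COLUMNS = (
    "Cytoplasm", "Cytoplasmic membrane", "Extracellular", "Periplasm", "Unknown",
)
CYTO_LABELS = frozenset({"Cytoplasm", "Cytoplasmic membrane"})


@dataclass(frozen=True)
class HemeMotifHit:
    """One C-x(2,4)-C-H occurrence: start is the 1-based position of the
    leading cysteine, span the full matched length (5-7)."""

    start: int
    span: int

    @property
    def n_x(self) -> int:
        return self.span - 3

    @property
    def end(self) -> int:
        """1-based position of the matched histidine."""
        return self.start + self.span - 1


@dataclass(frozen=True)
class MHCProfile:
    protein_id: str
    n_motifs: int
    length: int
    localization: str | None = None
    has_signal_peptide: bool | None = None

    @property
    def is_mhc(self) -> bool:
        return self.n_motifs >= MHC_MIN_MOTIFS

    @property
    def is_large(self) -> bool:
        return self.n_motifs >= LARGE_MHC_MIN_MOTIFS

    @property
    def residues_per_heme(self) -> float | None:
        """Protein length over heme-motif count, rounded to 1 decimal;
        undefined (None) for proteins without motifs."""
        if self.n_motifs == 0:
            return None
        return round(self.length / self.n_motifs, 1)

    @property
    def size_class(self) -> str:
        for label, lo, hi in SIZE_CLASSES:
            if lo <= self.n_motifs <= hi:
                return label
        return "other"


def find_heme_motifs(protein: ProteinRecord,
                     min_x: int = 2, max_x: int = 4) -> list[HemeMotifHit]:
    """Scan a protein for non-overlapping C-x(2,4)-C-H heme-binding motifs.

    Returns the leftmost-start, shortest-extension-first greedy matching,
    whose size equals the maximum number of mutually non-overlapping
    occurrences.  X (and every non-C residue) never serves as a motif
    cysteine; x positions may be any residue including C, H or X.
    """
    seq = protein.residues
    n = len(seq)
    hits: list[HemeMotifHit] = []
    i = 0
    while i < n:
        if seq[i] == "C":
            matched = False
            for nx in range(min_x, max_x + 1):
                c2 = i + 1 + nx
                h = c2 + 1
                if h < n and seq[c2] == "C" and seq[h] == "H":
                    hits.append(HemeMotifHit(start=i + 1, span=nx + 3))
                    i = h + 1
                    matched = True
                    break
            if not matched:
                i += 1
        else:
            i += 1
    return hits


def classify(protein: ProteinRecord,
             hits: Sequence[HemeMotifHit] | None = None) -> MHCProfile:
    """Build the per-protein MHC profile from a motif scan."""
    if hits is None:
        hits = find_heme_motifs(protein)
    return MHCProfile(protein_id=protein.id, n_motifs=len(hits),
                      length=len(protein))


def _read_two_column(path_or_df, value_col: str) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns or value_col not in df.columns:
        raise SeqFormatError(
            f"annotation table needs columns protein_id, {value_col}"
        )
    bad = df[df[value_col].isna() | df["protein_id"].isna()]
    if len(bad):
        raise SeqFormatError(
            f"annotation table: malformed row at line {int(bad.index[0]) + 2}"
        )
    dup = df[df.duplicated("protein_id", keep=False)]
    if len(dup):
        groups = dup.groupby("protein_id")[value_col].nunique()
        conflicting = groups[groups > 1]
        if len(conflicting):
            raise SeqFormatError(
                f"annotation table: conflicting rows for protein "
                f"{conflicting.index[0]!r}"
            )
        df = df.drop_duplicates("protein_id")
    return df


def merge_annotations(profiles: Sequence[MHCProfile],
                      localization_table=None,
                      signal_table=None) -> tuple[list[MHCProfile], int]:
    """Attach localization and signal-peptide labels to profiles.

    Tables are TSVs (or DataFrames) keyed by protein_id; proteins absent
    from a table get localization "Unknown" / signal None.  Returns the
    annotated profiles and the count of table ids that matched no profile
    (ignored with a warning count, never an error).
    """
    loc: Mapping[str, str] = {}
    sig: Mapping[str, bool] = {}
    if localization_table is not None:
        df = _read_two_column(localization_table, "localization")
        loc = dict(zip(df["protein_id"], df["localization"]))
    if signal_table is not None:
        df = _read_two_column(signal_table, "signal")
        sig = {pid: bool(int(v)) for pid, v in zip(df["protein_id"], df["signal"])}
    known = {p.protein_id for p in profiles}
    n_unknown_ids = len((set(loc) | set(sig)) - known)
    out = [
        replace(p, localization=loc.get(p.protein_id, "Unknown"),
                has_signal_peptide=sig.get(p.protein_id))
        for p in profiles
    ]
    return out, n_unknown_ids


@dataclass
class LocalizationMatrix:
    """Counts and row percentages of MHC localizations, one row per group
    plus one row per heme-count stratum; mirrors a five-column
    Gram-negative predictor vocabulary, with an extra "Outer membrane"
    column only when such labels occur."""

    columns: tuple[str, ...]
    counts: pd.DataFrame = field(default=None)  # rows x columns, ints
    percentages: pd.DataFrame = field(default=None)  # integer percents
    row_totals: pd.Series = field(default=None)
    noncyto_fraction: pd.Series = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        out = self.percentages.copy().astype(object)
        for col in out.columns:
            out[col] = [
                "–" if self.row_totals[r] == 0 else f"{out.at[r, col]}%"
                for r in out.index
            ]
        out["Total num."] = self.row_totals
        return out


def localization_summary(profiles: Sequence[MHCProfile],
                         grouping: Mapping[str, str] | None = None
                         ) -> LocalizationMatrix:
    """Pivot MHC profiles into a localization count/percentage matrix.

    ``grouping`` maps protein_id -> group label; ungrouped proteins fall
    into "All".  Heme-count stratum rows (3-14, 15-27, 30-53 motifs) are
    always appended.  Percentages are rounded to integers; each row also
    carries the fraction of proteins whose predicted localization is
    neither cytoplasm nor cytoplasmic membrane (export-competent signal).
    """
    mhcs = [p for p in profiles if p.is_mhc]
    columns = list(LOCALIZATION_COLUMNS)
    labels = {p.localization or "Unknown" for p in mhcs}
    if labels - set(columns):
        extra = sorted(labels - set(columns))
        if extra != ["Outer membrane"]:
            unknown = [l for l in extra if l != "Outer membrane"]
            raise SeqFormatError(f"unknown localization labels: {unknown}")
        columns = columns[:-1] + ["Outer membrane", "Unknown"]

    def row_label(p: MHCProfile) -> str:
        if grouping is None:
            return "All"
        return grouping.get(p.protein_id, "All")

    groups: dict[str, list[MHCProfile]] = {}
    for p in mhcs:
        groups.setdefault(row_label(p), []).append(p)
    for label, lo, hi in SIZE_CLASSES:
        groups[f"MHCs with {label} hemes"] = [
            p for p in mhcs if lo <= p.n_motifs <= hi
        ]

    index = list(groups)
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for name, members in groups.items():
        for p in members:
            counts.at[name, p.localization or "Unknown"] += 1
    totals = counts.sum(axis=1)
    pct = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    noncyto = pd.Series(float("nan"), index=index)
    for name in index:
        t = totals[name]
        if t > 0:
            pct.loc[name] = [int(round(100 * c / t)) for c in counts.loc[name]]
            noncyto[name] = sum(
                c for col, c in counts.loc[name].items() if col not in CYTO_LABELS
            ) / t
    return LocalizationMatrix(columns=tuple(columns), counts=counts,
                              percentages=pct, row_totals=totals,
                              noncyto_fraction=noncyto)


@dataclass(frozen=True)
class SignalStrata:
    """Signal-peptide fractions for MHCs with 3-20 motifs vs > 20 motifs."""

    fraction_3_20: float | None
    fraction_gt20: float | None
    overall_fraction: float | None
    n_3_20: int
    n_gt20: int
    n_unknown: int


def signal_strata(profiles: Iterable[MHCProfile],
                  split: int = 20) -> SignalStrata:
    """Fraction of MHCs carrying a signal peptide, split at `split` motifs.

    Proteins with unknown signal status are excluded from denominators and
    counted in ``n_unknown``.  Fractions are None when a stratum is empty.
    """
    small = large = small_pos = large_pos = unknown = 0
    for p in profiles:
        if not p.is_mhc:
            continue
        if p.has_signal_peptide is None:
            unknown += 1
            continue
        if p.n_motifs <= split:
            small += 1
            small_pos += p.has_signal_peptide
        else:
            large += 1
            large_pos += p.has_signal_peptide
    total = small + large
    return SignalStrata(
        fraction_3_20=small_pos / small if small else None,
        fraction_gt20=large_pos / large if large else None,
        overall_fraction=(small_pos + large_pos) / total if total else None,
        n_3_20=small, n_gt20=large, n_unknown=unknown,
    )


def profiles_to_rows(profiles: Sequence[MHCProfile]) -> list[dict]:
    return [
        {
            "protein_id": p.protein_id,
            "n_motifs": p.n_motifs,
            "length": p.length,
            "residues_per_heme": p.residues_per_heme,
            "is_mhc": int(p.is_mhc),
            "is_large": int(p.is_large),
            "size_class": p.size_class,
            "localization": p.localization or "Unknown",
            "signal": "NA" if p.has_signal_peptide is None else int(p.has_signal_peptide),
        }
        for p in profiles
    ]


MHC_TABLE_SCHEMA = {
    "protein_id": "s", "n_motifs": "d", "length": "d",
    "residues_per_heme": ".1f", "is_mhc": "d", "is_large": "d",
    "size_class": "s", "localization": "s", "signal": "s",
}
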