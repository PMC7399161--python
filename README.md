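# eetscan

Genomic screening for **extracellular electron transfer (EET) potential** in
bacterial and archaeal genome bins, plus the bin quality scoring and
de-replication needed to build a non-redundant genome set first.

Some microorganisms respire by moving electrons across the cell envelope to
external acceptors — iron minerals, other cells, or a poised electrode.
Genomes from such organisms carry a characteristic toolkit, and `eetscan`
flags each of its parts:

* **Multiheme *c*-type cytochromes (MHCs).** Heme *c* attaches at
  C-x(2,4)-C-H motifs (cysteine, 2–4 variable residues, cysteine,
  histidine). A protein with ≥ 3 motifs is an MHC; ≥ 10 flags a large MHC.
  The scanner reports the maximum number of non-overlapping motif
  occurrences together with the heme-packing density, length/*h* residues
  per heme (densely packed "molecular wire" cytochromes sit near 22–25),
  and merges external subcellular-localization and signal-peptide
  predictions into summary matrices.
* **Porin–cytochrome complexes (PCCs).** Trans-outer-membrane conduits
  made of a β-barrel porin encoded next to MHCs. Candidate porins are
  scored against four reference porin families (MtrB, OmbB, ExtB/E, ExtI)
  with a PSSM + affine-gap local alignment and a within-sequence shuffle
  null (z ≥ 6), must have ≥ 14 predicted transmembrane β-strands, and must
  sit within a small number of genes of an MHC on the same scaffold.
* **e-pilins.** Type-IV pilins whose mature sequence is dense in aromatic
  residues (F, W, Y, H). Strict candidates need ≥ 9.8 % aromatics over
  mature residues 1–59, no gap of more than 22 consecutive non-aromatics
  between aromatics, and aromatics at mature positions 1, 24, 27, 50/51
  and 32/57; failing that, ≥ 8 % over the whole mature sequence gives the
  relaxed tier.
* **OmcS-like filament cytochromes.** Hexaheme cytochromes found by
  local-alignment identity to a query sequence with a 500-residue length
  cutoff.
* **Bin QC and de-replication.** Completeness tiers from universal
  single-copy genes (draft ≥ 70 %, near-complete ≥ 90 %; 36/51 markers for
  bacteria, 27/38 for archaea), the bin score
  `(non-redundant SCGs) − 2 × (multi-copy SCGs)`, N50, and single-linkage
  de-replication of bins that are ≥ 98 % identical across ≥ 70 % of their
  length, with representative selection by score → N50 → total size.

A synthetic community generator (`eetscan.synthcommunity`) plants every one
of these features at known parameters and returns the ground truth, so the
whole pipeline is testable end to end. Packaged reference fixtures
(porin seed alignments, OmcS and pilin queries) are synthetic stand-ins
generated by that module — see `docs/methods.md`.

## Worked example

Run the pipeline on a two-genome synthetic community:

```bash
eetscan run --seed 11 --n-genomes 2 --outdir demo/
cat demo/roster.tsv
```

```
bin_id           n_mhc  max_hemes  n_large_mhc  frac_noncyto  pcc_MtrB  pcc_OmbB  pcc_ExtB/E  pcc_ExtI  pilin_strict  pilin_relaxed  pilin_none  n_omcs  abundance
synth_genome_00  5      23         2            1.000         1         0         0           0         1             0              0           1       NA
synth_genome_01  5      29         2            1.000         0         1         0           0         0             1              0           1       NA
```

Each row is one genome: five MHCs each (the largest with 23 and 29 heme
motifs; two per genome with ≥ 10), one PCC in the planted family (MtrB for
the first genome, OmbB for the second), one e-pilin (strict in genome 00,
relaxed in genome 01 — its pilin lacks the position-1 aromatic, flag string
`01111`), and one OmcS-like homolog. `frac_noncyto` is the fraction of MHCs
whose predicted localization is neither cytoplasm nor cytoplasmic membrane
(all `Unknown` here, since no localization table was supplied).

The per-protein detail behind the roster lands next to it, e.g.
`demo/pilins.tsv`:

```
protein_id             cleavage_pos  mature_length  aromatic_count  aromatic_pct  max_gap  position_flags  tier
synth_genome_00_pilin  6             61             6               10.2          22       11111           strict
```

— a prepilin cleaved after residue 6, with 6 aromatics in a 61-residue
mature sequence (10.2 % over the 59-residue window, maximal spacing exactly
22) and all five key-position flags set: a strict e-pilin candidate.

Stage subcommands (`scan-mhc`, `find-pcc`, `find-epilin`, `find-omcs`,
`qc`, `derep`, `simulate`) expose each step separately on FASTA/GFF3/TSV
inputs; `eetscan COMMAND --help` shows the options.

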