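# Methods

This note documents the models and procedures implemented in `eetscan`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Heme-motif scanning

Heme *c* attaches at C-x(2,4)-C-H motifs. `find_heme_motifs` reports the
**maximum number of mutually non-overlapping occurrences**: it scans left
to right, at each cysteine tries the shortest extension first (2 variable
residues before 3 before 4) and resumes after the matched histidine. This
is earliest-end greedy interval scheduling, which is optimal for
maximising non-overlapping matches; the test suite checks it against an
exact dynamic-programming oracle (itself validated by subset enumeration
on tiny instances). Whether overlapping motifs should be counted at all
was an open choice; the non-overlapping maximum is the documented one.
The ambiguity code X never matches C or H; variable positions may be any
residue.

Thresholds: ≥ 3 motifs → MHC; ≥ 10 → large MHC. The density statistic
residues-per-heme divides the **full stored protein length** by the motif
count (signal peptides are not removed; the choice of length basis is an
open question for densities quoted elsewhere, so the value is reported,
not compared against external references). Heme-count strata for
summaries are 3–14, 15–27 and 30–53; counts in the gaps (28–29, > 53) go
to class "other" rather than being silently merged.

Localization and signal-peptide labels are consumed from external
predictor tables, never recomputed. Percentages in the localization
matrix are rounded to integers, so rows sum to 100 ± rounding; the
"fraction non-cytoplasmic" statistic counts every label outside
{Cytoplasm, Cytoplasmic membrane}, including Unknown — an MHC of unknown
localization is treated as potentially exported, which matches how such
summaries are conventionally read. An "Outer membrane" column appears
only when such labels occur.

## Porin–cytochrome complex calling

Porin homology is scored with a position-specific scoring matrix (PSSM)
per reference family (MtrB, OmbB, ExtB/E, ExtI) rather than a profile
HMM: the PSSM is transparent, dependency-free and calibratable at desk
scale. Columns with > 50 % gaps are dropped. The background distribution
mixes the seed-set mean composition 50/50 with uniform; per-column
frequencies use one background-proportional pseudocount,
f_a = (c_a + q_a)/(n + 1), and scores are log2(f_a / q_a). A flat
per-residue pseudocount was rejected because a strongly skewed seed
composition can then invert the log-odds sign at fully conserved columns.

Candidates are found by local (Smith–Waterman) alignment against the
profile with affine gaps (open 10, extend 1). Significance is a
**within-sequence shuffle null**: the score of each protein is compared
with `n_shuffles` (default 200) residue shuffles of itself, and a
candidate needs z ≥ 6. This controls for length and composition; on 100
random composition-matched sequences the observed null z never exceeded
~3. The dynamic programme is vectorised over profile columns; the
horizontal gap state uses the running-maximum identity
E[j] = max_{j'<j}(G[j'] − open − (j−1−j')·extend), exact because
re-opening a gap from a cell that already ends in a horizontal gap can
never beat extending when open ≥ extend.

Transmembrane β-strands: membrane strands alternate lipid-facing
hydrophobic and lumen-facing polar residues. The statistic A(i) is the
mean over a centred 9-residue window of z-normalised Kyte–Doolittle
hydropathy × (−1)^offset; positions with |A| ≥ 0.6 mark strand cores,
maximal runs ≥ 5 long count as strands, and runs separated by < 3
positions merge. Sequences shorter than 50 residues return 0 with a
too-short flag. This heuristic is a deliberately simple stand-in for a
dedicated β-barrel topology predictor: **an externally supplied count
table always overrides it**, and that is the recommended path on real
data. The acceptance threshold of ≥ 14 predicted strands is fixed.

A PCC is called when a passing porin has ≥ 1 MHC within
`max_intervening` (default 2) intervening genes on the same scaffold,
collecting every MHC in the window. Proximity in the source protocol was
assessed visually; the 2-gene window is this package's quantification,
and strand agreement is not required (configurable). Because the four
family profiles describe structurally similar barrels, one porin can
clear the z-threshold for several families; the pipeline assigns each
candidate to its best-scoring family before clustering.

## e-pilins and OmcS

Prepilin cleavage: the class-III signal peptidase motif is approximated
by the leftmost position i ∈ [6, 40] with G at i, a hydrophobic/small
residue (F, M, L, I, V, A, S, T) at i+1 and E at i+5 (the conserved
mature-E5); an "E5-relaxed" mode drops the glutamate condition, and a
supplied cleavage table overrides the heuristic.

Aromatic metrics on the mature sequence: count of F/W/Y/H; density over
the assessment window (residues 1–59 when the mature sequence is ≥ 59
long, else the whole sequence); and the maximal gap, defined as
**intervening non-aromatic residues between successive aromatics**
(pos₂ − pos₁ − 1), terminal flanks excluded. With this definition the
canonical 1→24 aromatic spacing equals exactly the printed bound of 22,
which anchors the convention. A sequence without aromatics reports
max_gap = mature length (degenerate convention). Strict tier: window
density ≥ 9.8 % AND max_gap ≤ 22 AND aromatics at mature positions 1,
24, 27, 50-or-51 and 32-or-57, evaluated on unaligned mature positions
(an offset map can re-map them when an alignment says otherwise).
Relaxed tier: whole-mature density ≥ 8 %. Tier assignment is monotone in
adding aromatics for pilin-scale sequences (property-tested on 61-mers);
for much longer matures a C-terminal aromatic can in principle create a
new > 22 gap, which is why the property is asserted at generator scale
rather than universally.

OmcS-like cytochromes: local-alignment identity (BLOSUM62, gap −11/−1)
to a query sequence, requiring identity ≥ 25 % over ≥ 50 % of the
reference length. The coverage requirement stands in for search
significance — without it, short high-identity windows in unrelated
proteins clear the identity floor. The 500-residue length cutoff is
applied as an upper bound. Local-alignment identity is slightly
upward-biased for deeply diverged homologs (~2–5 points at 30 %
identity); tests assert the mean over seeds within ±5 points.

The pipeline pre-screens pilin candidates by similarity to the pilin
query (identity ≥ 35 % over ≥ 50 % of the query) before applying the
aromatic criteria, mirroring the homology-search-then-filter design of
the original protocol; `find_epilins` applies no pre-screen unless a
reference is passed.

## Bin quality and de-replication

Completeness uses universal single-copy-gene inventories: 51 markers for
bacteria, 38 for archaea. Draft ≥ 70 % (36 and 27 markers), near-complete
≥ 90 % (46 and 35); the integer cutoffs are exactly ⌈fraction ×
universe⌉. The bin score is (non-redundant SCGs) − 2 × (multi-copy SCGs)
and may be negative. N50 is the smallest contig length at which the
descending running sum first reaches half the total.

Pairwise similarity is fragment-based: the query bin is cut into 1-kb
fragments; each fragment is anchored in the subject by shared 15-mers
(diagonal voting, ≥ 2 votes) and aligned with edlib in a ±50 bp band;
fragments count as aligned at ≥ 60 % query coverage and ≥ 70 % identity.
Identity is the aligned-length-weighted mean over aligned fragments;
aligned fraction is aligned bases over the query's total length. The
fragment/seed parameters (1000 bp, k = 15, band 50, 60 %/70 % filters)
are calibration choices validated by a recovery property: across
substitution rates 0.5–5 % on 100-kb pairs the mean estimated identity
is within 0.5 percentage points of 100(1−d), and in practice within a
few hundredths of the realized Hamming identity.

De-replication links pairs passing identity ≥ 98 % and aligned fraction
≥ 70 %, evaluated in both directions with OR semantics (configurable to
AND), then takes single-linkage clusters. **The identity threshold is
applied at its printed precision**: a threshold stated as a whole
percentage admits pairs whose measured identity rounds to it (cut-off
98 − 0.5). This matters because a pair generated at exactly 2 %
divergence has realized identity binomially distributed around 98.0, so
an exact ≥ 98.0 comparison would accept or reject such borderline pairs
on sampling noise; `id_precision=0` restores the exact comparison.
Coverage is compared exactly. Whether "98 % similar" means identity
within aligned blocks (assumed here) or a whole-genome average including
unaligned regions is an interpretation; the aligned-blocks reading is
implemented. Representatives maximise bin score, then N50, then total
size; a final lexicographic tie-break on bin id (an invention) makes the
choice deterministic.

## Synthetic community generator

The generator plants each feature the pipeline detects and returns the
ground truth:

* MHC proteins: motifs with 2–4 variable residues at random
  non-overlapping positions on a background drawn from the 18 residues
  excluding C and H, so the background can never complete a motif; a
  validation scan asserts the planted count. Feasibility requires
  length ≥ 7 × n_motifs.
* Pilins: a fixed leader (MKKLQG) plus a 61-residue (70 for below-relaxed
  designs) mature region whose aromatics are placed to pass or fail the
  key-position, density and gap criteria independently; backgrounds are
  drawn from a fixed consensus with 20 % per-site variation so that
  planted pilins form a mutually alignable family, as real pilin
  relatives do. Each construct is re-verified through the classifier at
  generation time. Not every toggle combination is feasible — with all
  key positions aromatic, the five aromatics alone give ≥ 8 % on a
  61-mer, so "none"-tier designs use a longer mature region; the
  generator enforces the feasible set.
* Porin operons: a family-ancestor porin (an alternating-hydropathy
  barrel of 13-residue strands alternating I/V/L/F and D/N/K/E with 8-mer
  G/S loops, flanked by family-specific regions) mutated at 5 %, placed
  `gene_gap` genes from planted MHCs with filler genes around; the truth
  carries the planted strand count as the recommended TM override. The
  barrel construction saturates the strand heuristic (the planted count
  is read back exactly), and mutation draws from the C/H-free alphabet so
  a porin can never become an MHC.
* Genome pairs: a uniform-ACGT ancestor, per-site substitution at rate d
  (always to a different base), optionally an unrelated tail replacing a
  fraction of the second genome; truth records the realized identity.
  Indels are not simulated — recovery tolerances are asserted for the
  substitution-only regime.
* SCG inventories with controlled presence and multiplicity, against
  synthetic marker universes of 51 (bacteria) and 38 (archaea) ids.

Backgrounds are uniform over the permitted alphabets: no codon structure,
GC bias, repeat content or phylogenetic covariance. Passing round-trip
tests therefore demonstrates internal correctness of the detection logic
and thresholds, not performance on real metagenomes, where gene
prediction errors, fragmented scaffolds, compositional bias and true
biological ambiguity (e.g. pseudo-pilins, non-barrel porin-like scores)
all add noise that the generator deliberately omits.

The packaged reference fixtures (four porin seed alignments, the OmcS
query, the pilin query) are synthetic stand-ins produced by this module
with fixed seeds — their filenames and FASTA headers say so — because the
package carries no database sequences. On real data, users should supply
their own reference FASTA files in their place.

## Pipeline, determinism and problem sizes

The driver runs stages in dependency order, derives per-genome seeds from
the run seed, and writes TSVs plus a JSON manifest of parameters and
versions; timings go to the stderr log only, so a re-run with the same
seed is byte-identical. All thresholds live in one config dictionary
(YAML/JSON overrides, CLI flags on top): MHC ≥ 3 and large ≥ 10 motifs,
TM ≥ 14, pilin 9.8 %/8 %/22, OmcS 500 and 25 %, completeness 0.70/0.90,
de-replication 98 %/70 %, proximity window 2.

Default problem sizes were chosen to keep the full test suite near a
minute and the acceptance script near half a minute: demo communities of
2–4 genomes, 30–50 shuffles for the porin null in bulk runs (z margins
for true family members are two orders of magnitude above the threshold,
so the reduced null costs no sensitivity), 100-kb genome pairs, and
40–100 replicates per planted-feature class.

## Known limitations

* The TM-strand heuristic is a screening stand-in; topology predictors
  or experimental annotations should override it on real data.
* Shuffle-null z-scores are not E-values; they are comparable within a
  run but not across databases.
* Key-position flags are evaluated on unaligned mature coordinates;
  insertions upstream of position 57 shift them (use the offset map).
* Fragment-based similarity underestimates coverage for highly
  rearranged or indel-rich genome pairs (substitution-only calibration).
* The localization vocabulary is the Gram-negative predictor label set;
  monoderm organisms will legitimately lack several categories.
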