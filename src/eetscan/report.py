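"""Pipeline driver and summary products.

``run_pipeline`` executes the stages in dependency order — heme-motif
scanning, porin search and PCC calling, e-pilin and OmcS screening — over
a set of genomes (either user-supplied files or a synthetic community
with planted truth) and emits:

* a per-genome roster of EET-relevant features (total MHCs, largest heme
  count, large-MHC count, fraction of MHCs predicted outside the
  cytoplasm/cytoplasmic membrane, PCC counts per porin family, e-pilin
  tier counts, OmcS hit count, optional abundance);
* per-protein detail tables for every stage;
* a localization matrix and signal-peptide strata;
* a JSON run manifest recording versions, parameters, seeds and warning
  counts.  Timings go to the stderr log only, so re-running with one seed
  reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from scipy import stats

from . import __version__, hemescan, nanowire, pcc, synthcommunity
from .config import DEFAULTS, load_config
from .seqio import GeneCall, ProteinRecord, write_table

log = logging.getLogger("eetscan")

ROSTER_SCHEMA = {
    "bin_id": "s", "n_mhc": "d", "max_hemes": "d", "n_large_mhc": "d",
    "frac_noncyto": ".3f", "pcc_MtrB": "d", "pcc_OmbB": "d",
    "pcc_ExtB/E": "d", "pcc_ExtI": "d", "pilin_strict": "d",
    "pilin_relaxed": "d", "pilin_none": "d", "n_omcs": "d",
    "abundance": ".4f",
}


@dataclass
class GenomeInput:
    bin_id: str
    proteins: list[ProteinRecord]
    genes: list[GeneCall]
    tm_overrides: dict[str, int] = field(default_factory=dict)
    abundance: float | None = None
    truth: dict | None = None


@dataclass
class RosterRow:
    bin_id: str
    n_mhc: int = 0
    max_hemes: int = 0
    n_large_mhc: int = 0
    frac_noncyto: float = 0.0
    pcc_by_family: dict = field(default_factory=dict)
    pilin_tiers: dict = field(default_factory=dict)
    n_omcs: int = 0
    abundance: float | None = None


@dataclass
class PipelineResult:
    roster: list[RosterRow]
    profiles: dict[str, list]          # bin_id -> MHCProfile list
    clusters: dict[str, list]          # bin_id -> PCCCluster list
    pilins: dict[str, list]            # bin_id -> PilinCandidate list
    omcs: dict[str, list]              # bin_id -> passing OmcSHit list
    manifest: dict


def simulate_community(sim_cfg: Mapping, rng_seed: int) -> list[GenomeInput]:
    """Generate a synthetic community for an end-to-end run.

    Each genome gets planted MHC proteins, cycling e-pilin scenarios, an
    optional PCC operon (families cycling) and an optional OmcS homolog
    built by mutating the packaged synthetic reference.  The per-genome
    truth dict summarises what the pipeline should recover.
    """
    n_genomes = int(sim_cfg.get("n_genomes", 2))
    n_mhc = int(sim_cfg.get("mhc_per_genome", 3))
    with_pcc = bool(sim_cfg.get("with_pcc", True))
    with_pilin = bool(sim_cfg.get("with_pilin", True))
    with_omcs = bool(sim_cfg.get("with_omcs", True))
    genomes: list[GenomeInput] = []
    pilin_cases = [
        synthcommunity.PilinToggles(),
        synthcommunity.PilinToggles(positions=False),
        synthcommunity.PilinToggles(density=False),
    ]
    omcs_ref = nanowire.load_reference("omcs")
    for gi in range(n_genomes):
        seed = (rng_seed * 1_000_003 + 7919 * gi) % (2**31)
        bin_id = f"synth_genome_{gi:02d}"
        proteins: list[ProteinRecord] = []
        genes: list[GeneCall] = []
        tm_overrides: dict[str, int] = {}
        truth = {"n_mhc": 0, "max_hemes": 0, "n_large": 0,
                 "pcc_families": [], "pilin_tiers": {}, "n_omcs": 0}
        pos = 1
        scaffold = f"{bin_id}_s0"

        def add_gene(prot: ProteinRecord) -> None:
            nonlocal pos
            end = pos + 3 * len(prot) + 2
            genes.append(GeneCall(prot.id, scaffold, pos, end, "+",
                                  ordinal=-1, protein=prot))
            pos = end + 73
            proteins.append(prot)

        for k in range(n_mhc):
            h = 3 + (seed + 11 * k) % 28
            rec, t = synthcommunity.make_mhc_protein(
                h, max(7 * h + 60, 160), (seed + k) % (2**31),
                f"{bin_id}_mhc{k}")
            add_gene(rec)
            truth["n_mhc"] += 1
            truth["max_hemes"] = max(truth["max_hemes"], t.n_motifs)
            truth["n_large"] += t.n_motifs >= hemescan.LARGE_MHC_MIN_MOTIFS
        for k in range(2):
            add_gene(synthcommunity.make_filler_protein(
                150, (seed + 97 * k) % (2**31), f"{bin_id}_fill{k}"))
        if with_pcc:
            family = pcc.PORIN_FAMILIES[gi % len(pcc.PORIN_FAMILIES)]
            op_genes, op_truth = synthcommunity.make_pcc_operon(
                family, n_mhc=1, tm_strands=16, gene_gap=0,
                rng_seed=(seed + 13) % (2**31),
                scaffold_id=f"{bin_id}_s1")
            for g in op_genes:
                proteins.append(g.protein)
            genes.extend(op_genes)
            tm_overrides[op_truth.porin_id] = op_truth.tm_strands
            truth["pcc_families"].append(family)
            truth["n_mhc"] += len(op_truth.mhc_ids)
        if with_pilin:
            case = pilin_cases[gi % len(pilin_cases)]
            rec, t = synthcommunity.make_pilin(
                case, (seed + 29) % (2**31), f"{bin_id}_pilin")
            add_gene(rec)
            truth["pilin_tiers"][t.tier] = truth["pilin_tiers"].get(t.tier, 0) + 1
        if with_omcs:
            import numpy as np

            rng = np.random.default_rng((seed + 41) % (2**31))
            hom = ProteinRecord(
                f"{bin_id}_omcs",
                synthcommunity.mutate_protein(omcs_ref.residues, 0.10, rng))
            add_gene(hom)
            truth["n_omcs"] += 1
            # mutation may strike motif residues; score the homolog as the
            # scanner will see it
            h = len(hemescan.find_heme_motifs(hom))
            truth["n_mhc"] += h >= hemescan.MHC_MIN_MOTIFS
            truth["max_hemes"] = max(truth["max_hemes"], h)
            truth["n_large"] += h >= hemescan.LARGE_MHC_MIN_MOTIFS
        from .seqio import assign_ordinals

        genes = assign_ordinals(genes)
        genomes.append(GenomeInput(bin_id=bin_id, proteins=proteins,
                                   genes=genes, tm_overrides=tm_overrides,
                                   abundance=None, truth=truth))
    return genomes


def run_pipeline(config: Mapping | None = None,
                 genomes: Sequence[GenomeInput] | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage over the configured genomes and write all outputs.

    ``genomes`` may be passed directly; otherwise ``config['simulate']``
    must describe a synthetic community (requiring ``rng_seed``).  An
    empty genome list is valid and yields an empty roster.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    if genomes is None:
        sim = cfg.get("simulate")
        if sim is None:
            genomes = []
        else:
            if cfg.get("rng_seed") is None:
                raise ValueError("rng_seed is required when simulation is requested")
            genomes = simulate_community(sim, int(cfg["rng_seed"]))

    t0 = time.perf_counter()
    porin_profiles = pcc.load_all_profiles()
    omcs_ref = nanowire.load_reference("omcs")
    pilin_ref = nanowire.load_reference("pilin")
    log.info("loaded %d porin profiles in %.2fs", len(porin_profiles),
             time.perf_counter() - t0)

    roster: list[RosterRow] = []
    all_profiles: dict[str, list] = {}
    all_clusters: dict[str, list] = {}
    all_pilins: dict[str, list] = {}
    all_omcs: dict[str, list] = {}
    n_warnings = 0

    for genome in genomes:
        t0 = time.perf_counter()
        profiles = [hemescan.classify(
            p, hemescan.find_heme_motifs(p, cfg["motif_min_x"], cfg["motif_max_x"]))
            for p in genome.proteins]
        profiles, _ = hemescan.merge_annotations(profiles)
        mhcs = [p for p in profiles if p.is_mhc]

        # structurally similar beta-barrels cross-hit several family
        # profiles; keep only the best-scoring family per protein
        best_by_protein: dict[str, pcc.PorinCandidate] = {}
        seed = int(cfg.get("rng_seed") or 0)
        for family in pcc.PORIN_FAMILIES:
            for cand in pcc.search(
                    porin_profiles[family], genome.proteins,
                    n_shuffles=int(cfg["porin_n_shuffles"]),
                    z_min=float(cfg["porin_z_min"]),
                    rng_seed=seed, tm_overrides=genome.tm_overrides):
                prev = best_by_protein.get(cand.protein_id)
                if prev is None or cand.score > prev.score:
                    best_by_protein[cand.protein_id] = cand
        candidates = [best_by_protein[k] for k in sorted(best_by_protein)]
        clusters = pcc.call_pcc(genome.genes, candidates, profiles,
                                max_intervening=int(cfg["pcc_max_intervening"]))

        pilins = nanowire.find_epilins(genome.proteins,
                                       require_e5=bool(cfg["pilin_require_e5"]),
                                       reference=pilin_ref)
        omcs_all = nanowire.find_omcs(genome.proteins, omcs_ref,
                                      identity_min=float(cfg["omcs_identity_min"]),
                                      len_max=int(cfg["omcs_len_max"]))
        omcs_pass = [h for h in omcs_all if h.passes_length]

        noncyto = [p for p in mhcs
                   if (p.localization or "Unknown") not in hemescan.CYTO_LABELS]
        tier_counts: dict[str, int] = {}
        for cand in pilins:
            tier_counts[cand.tier] = tier_counts.get(cand.tier, 0) + 1
        fam_counts: dict[str, int] = {f: 0 for f in pcc.PORIN_FAMILIES}
        for cl in clusters:
            fam_counts[cl.family] += 1
        roster.append(RosterRow(
            bin_id=genome.bin_id,
            n_mhc=len(mhcs),
            max_hemes=max((p.n_motifs for p in mhcs), default=0),
            n_large_mhc=sum(p.is_large for p in mhcs),
            frac_noncyto=len(noncyto) / len(mhcs) if mhcs else 0.0,
            pcc_by_family=fam_counts,
            pilin_tiers=tier_counts,
            n_omcs=len(omcs_pass),
            abundance=genome.abundance,
        ))
        all_profiles[genome.bin_id] = profiles
        all_clusters[genome.bin_id] = clusters
        all_pilins[genome.bin_id] = pilins
        all_omcs[genome.bin_id] = omcs_pass
        log.info("genome %s: %d MHCs, %d PCCs, %d pilins in %.2fs",
                 genome.bin_id, len(mhcs), len(clusters), len(pilins),
                 time.perf_counter() - t0)

    manifest = {
        "eetscan_version": __version__,
        "parameters": {k: cfg[k] for k in sorted(DEFAULTS)},
        "n_genomes": len(genomes),
        "n_warnings": n_warnings,
    }
    result = PipelineResult(roster=roster, profiles=all_profiles,
                            clusters=all_clusters, pilins=all_pilins,
                            omcs=all_omcs, manifest=manifest)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in result.roster:
        row = {"bin_id": r.bin_id, "n_mhc": r.n_mhc, "max_hemes": r.max_hemes,
               "n_large_mhc": r.n_large_mhc, "frac_noncyto": r.frac_noncyto,
               "pilin_strict": r.pilin_tiers.get("strict", 0),
               "pilin_relaxed": r.pilin_tiers.get("relaxed", 0),
               "pilin_none": r.pilin_tiers.get("none", 0),
               "n_omcs": r.n_omcs,
               "abundance": r.abundance}
        for fam in pcc.PORIN_FAMILIES:
            row[f"pcc_{fam}"] = r.pcc_by_family.get(fam, 0)
        rows.append(row)
    write_table(rows, outdir / "roster.tsv", ROSTER_SCHEMA)

    prof_rows = []
    for bin_id in sorted(result.profiles):
        for row in hemescan.profiles_to_rows(result.profiles[bin_id]):
            prof_rows.append({"bin_id": bin_id, **row})
    write_table(prof_rows, outdir / "mhc_profiles.tsv",
                {"bin_id": "s", **hemescan.MHC_TABLE_SCHEMA})

    pcc_rows = []
    for bin_id in sorted(result.clusters):
        for cl in result.clusters[bin_id]:
            pcc_rows.append({
                "bin_id": bin_id, "scaffold_id": cl.scaffold_id,
                "porin_id": cl.porin.protein_id, "family": cl.family,
                "score": cl.porin.score, "shuffle_z": cl.porin.shuffle_z,
                "tm_strands": cl.porin.tm_strands,
                "mhc_ids": ",".join(g.gene_id for g, _ in cl.mhcs),
                "heme_counts": ",".join(str(p.n_motifs) for _, p in cl.mhcs),
                "gene_gap": cl.max_gene_gap,
            })
    write_table(pcc_rows, outdir / "pcc.tsv",
                {"bin_id": "s", "scaffold_id": "s", "porin_id": "s",
                 "family": "s", "score": ".1f", "shuffle_z": ".2f",
                 "tm_strands": "d", "mhc_ids": "s", "heme_counts": "s",
                 "gene_gap": "d"})

    pilin_rows = []
    for bin_id in sorted(result.pilins):
        for cand in result.pilins[bin_id]:
            m = cand.metrics
            pilin_rows.append({
                "bin_id": bin_id, "protein_id": cand.protein_id,
                "cleavage_pos": cand.cleavage_pos,
                "mature_length": m.mature_length,
                "aromatic_count": m.aromatic_count,
                "aromatic_pct": m.aromatic_pct,
                "full_length_pct": m.full_length_pct,
                "max_gap": m.max_gap,
                "position_flags": "".join("1" if f else "0"
                                          for f in cand.position_flags),
                "tier": cand.tier,
            })
    write_table(pilin_rows, outdir / "pilins.tsv",
                {"bin_id": "s", "protein_id": "s", "cleavage_pos": "d",
                 "mature_length": "d", "aromatic_count": "d",
                 "aromatic_pct": ".1f", "full_length_pct": ".1f",
                 "max_gap": "d", "position_flags": "s", "tier": "s"})

    omcs_rows = []
    for bin_id in sorted(result.omcs):
        for hit in result.omcs[bin_id]:
            omcs_rows.append({"bin_id": bin_id, "protein_id": hit.protein_id,
                              "identity_pct": hit.identity_pct,
                              "length": hit.length, "n_cxxch": hit.n_cxxch})
    write_table(omcs_rows, outdir / "omcs.tsv",
                {"bin_id": "s", "protein_id": "s", "identity_pct": ".1f",
                 "length": "d", "n_cxxch": "d"})

    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")


def mhc_abundance_correlation(roster: Sequence[RosterRow],
                              abundance: Mapping[str, float] | None = None
                              ) -> tuple[float | None, int]:
    """Spearman rank correlation (average-rank ties) between per-genome
    MHC counts and abundance; (None, n) when fewer than 3 genomes have
    abundance values."""
    pairs = []
    for r in roster:
        value = abundance.get(r.bin_id) if abundance is not None else r.abundance
        if value is not None:
            pairs.append((r.n_mhc, float(value)))
    if len(pairs) < 3:
        return None, len(pairs)
    x, y = zip(*pairs)
    rho = stats.spearmanr(x, y).statistic
    return float(rho), len(pairs)
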