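"""Regenerate the packaged synthetic reference fixtures.

All fixtures are synthetic stand-ins produced by the community simulator
with fixed seeds — none is a database sequence.  Run from the repository
root:

    python scripts/make_fixtures.py
"""

from pathlib import Path

import numpy as np

from eetscan import synthcommunity
from eetscan.seqio import ProteinRecord, write_fasta

FIXTURES = Path(__file__).resolve().parent.parent / "src" / "eetscan" / "fixtures"


def main() -> None:
    FIXTURES.mkdir(parents=True, exist_ok=True)
    for i, family in enumerate(["MtrB", "OmbB", "ExtB/E", "ExtI"]):
        seeds = synthcommunity.make_porin_seed_alignment(
            family, n_seeds=8, divergence=0.15, rng_seed=1000 + i)
        tag = family.replace("/", "")
        write_fasta(seeds, FIXTURES / f"synthetic_porin_seed_{tag}.fasta")

    # OmcS-like stand-in: ~430 aa hexaheme cytochrome with exactly six
    # strict CxxCH motifs
    rec, truth = synthcommunity.make_mhc_protein(
        6, 430, rng_seed=2024, protein_id="synthetic_omcs_ref")
    rng = np.random.default_rng(2024)
    # force strict CxxCH spacing (n_x = 2) by regenerating until all spans
    # are minimal; simpler: rebuild with spans pinned via direct construction
    parts = []
    slack = 430 - 6 * 5
    gaps = rng.multinomial(slack, np.full(7, 1 / 7))
    for k in range(6):
        parts.append(synthcommunity._choice(rng, synthcommunity.MOTIF_FREE_ALPHABET,
                                            int(gaps[k])))
        parts.append("C" + synthcommunity._choice(
            rng, synthcommunity.MOTIF_FREE_ALPHABET, 2) + "CH")
    parts.append(synthcommunity._choice(rng, synthcommunity.MOTIF_FREE_ALPHABET,
                                        int(gaps[6])))
    omcs = ProteinRecord(
        "synthetic_omcs_ref", "".join(parts),
        "synthetic hexaheme OmcS-like reference (simulated, not a database accession)")
    write_fasta([omcs], FIXTURES / "synthetic_omcs_reference.fasta")

    pilin, _ = synthcommunity.make_pilin(
        synthcommunity.PilinToggles(), rng_seed=2025,
        protein_id="synthetic_pilin_ref")
    pilin = ProteinRecord(
        pilin.id, pilin.residues,
        "synthetic strict e-pilin reference (simulated, not a database accession)")
    write_fasta([pilin], FIXTURES / "synthetic_pilin_reference.fasta")
    print(f"wrote fixtures to {FIXTURES}")


if __name__ == "__main__":
    main()
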