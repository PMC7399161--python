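"""Run configuration: every named threshold with its default.

A YAML or JSON file overrides any subset; CLI flags override the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "rng_seed": None,              # mandatory whenever simulation is requested
    # multiheme cytochromes
    "mhc_min_motifs": 3,           # motifs to call an MHC
    "large_mhc_min_motifs": 10,    # motifs to flag a large MHC
    "motif_min_x": 2,              # variable residues in C-x(2,4)-C-H
    "motif_max_x": 4,
    "signal_split_motifs": 20,     # small/large split for signal-peptide strata
    # porin-cytochrome complexes
    "tm_min_strands": 14,          # minimum predicted transmembrane strands
    "porin_z_min": 6.0,            # shuffle-null z to accept a porin hit
    "porin_n_shuffles": 200,
    "pcc_max_intervening": 2,      # gene-neighbourhood window
    "pcc_same_strand": False,      # porin and MHC strand agreement not required
    # e-pilins
    "pilin_strict_pct": 9.8,       # aromatic % over mature 1-59
    "pilin_relaxed_pct": 8.0,      # aromatic % over the whole mature sequence
    "pilin_max_gap": 22,           # max consecutive non-aromatics between aromatics
    "pilin_require_e5": True,
    # OmcS
    "omcs_len_max": 500,
    "omcs_identity_min": 25.0,
    # bin quality and de-replication
    "draft_completeness": 0.70,
    "near_complete_completeness": 0.90,
    "derep_id_min": 98.0,
    "derep_cov_min": 0.70,
    "derep_id_precision": 1.0,     # identity compared at printed precision
    "derep_semantics": "or",
    "frag_len": 1000,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """DEFAULTS, updated by a YAML/JSON file, updated by keyword
    overrides.  Unknown keys are a hard error."""
    cfg = dict(DEFAULTS)
    layers = []
    if path is not None:
        text = Path(path).read_text()
        layers.append(json.loads(text) if str(path).endswith(".json")
                      else (yaml.safe_load(text) or {}))
    layers.append(overrides)
    for layer in layers:
        unknown = set(layer) - set(DEFAULTS) - {"genomes", "outdir", "simulate"}
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(layer)
    return cfg
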