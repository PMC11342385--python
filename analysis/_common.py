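"""Shared study configuration for the analysis drivers.

The study library is one regime-faithful simulated reference collection
(60 species, 1-5 sequences each, indels, one full mitochondrial
introgression and one cross-species identical haplotype), fixed by a single
seed so every driver reproduces the same library independently.
"""

from pathlib import Path

import barcode_eval as be
from barcode_eval.simulate import scenario_regime, simulate_library

STUDY_SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"


def study_config():
    return scenario_regime(seed=STUDY_SEED, n_species=60)


def study_library():
    cfg = study_config()
    records, truth, meta = simulate_library(cfg)
    return cfg, records, truth, meta


def trimmed_library(cfg, records):
    """Subregion dataset: primer excision with anchor-trim fallback."""
    pair = cfg.primer_pair()
    anchor = None
    trimmed, failed = [], []
    for rec in records:
        try:
            out = be.extract_subregion(rec, pair)
            anchor = anchor or out
            trimmed.append(out)
        except ValueError:
            if anchor is not None:
                trimmed.append(be.anchor_trim(rec, anchor))
            else:
                failed.append(rec.accession)
    return trimmed, failed
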