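"""Generate the study's synthetic 12S reference library and describe it.

Writes the library (FASTA, metadata, ground truth, true species tree) under
scratch/ and a composition table under results/.
"""

from collections import Counter

import pandas as pd

from _common import RESULTS, SCRATCH, study_library
from barcode_eval.simulate import write_library


def main():
    cfg, records, truth, meta = study_library()
    outdir = SCRATCH / "library"
    write_library(records, truth, meta, outdir)

    counts = Counter(r.species for r in records)
    lengths = [len(r) for r in records]
    comp = pd.DataFrame(
        {
            "quantity": [
                "n_sequences", "n_species", "species_with_multiple",
                "min_length_nt", "max_length_nt",
                "n_expected_failures",
            ],
            "value": [
                len(records), len(counts), sum(1 for c in counts.values() if c > 1),
                min(lengths), max(lengths),
                int((truth.species.expected_judgement == "failure").sum()),
            ],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    comp.to_csv(RESULTS / "01_library_composition.tsv", sep="\t", index=False)
    print(f"library written to {outdir}")
    print(comp.to_string(index=False))
    failures = truth.species[truth.species.expected_judgement == "failure"]
    print("\nplanted failures (ground truth):")
    print(failures.to_string(index=False))


if __name__ == "__main__":
    main()
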