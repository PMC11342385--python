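"""Which species lose diagnosability when the region is shortened?

Diffs the per-species judgements between the longer-region run and the
subregion run over the same species universe and writes the delta table.
"""

import json

from _common import RESULTS, study_library, trimmed_library
from barcode_eval.pipeline import RunConfig, compare_regions, run_pipeline


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg, records, truth, _ = study_library()
    trimmed, _ = trimmed_library(cfg, records)
    _, long_assess, _ = run_pipeline(records, RunConfig(metric="p", tree_metric="tn93"))
    _, short_assess, _ = run_pipeline(trimmed, RunConfig(metric="p", tree_metric="tn93"))
    delta = compare_regions(long_assess, short_assess)
    with open(RESULTS / "05_region_delta.json", "w") as fh:
        json.dump(delta, fh, indent=2)
    print(
        f"{delta['n_common']} species compared: {delta['n_degraded']} degraded, "
        f"{delta['n_improved']} improved when shortening to the subregion"
    )
    for entry in delta["degraded"]:
        print(f"  {entry['species']}: {entry['long']} -> {entry['short']}")


if __name__ == "__main__":
    main()
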