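"""End-to-end orchestration: assemble -> distances -> tree -> classify -> report.

``run_pipeline`` executes the whole evaluation for one dataset and writes
the standard artifacts (PHYLIP matrix, long-format distances, newick tree,
per-species assessments, a summary in JSON and TSV, and a grouped caution
report). ``compare_regions`` diffs two runs over the same species universe
— the question of interest being which species lose (or, rarely, gain)
diagnosability when the analysis region is shortened.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from barcode_eval.classify import (
    ClassifierConfig,
    SpeciesAssessment,
    assessments_frame,
    caution_report,
    classify_species,
    discriminability,
)
from barcode_eval.distances import (
    AlignmentParams,
    DistanceMatrix,
    distance_matrices,
    interspecific_summary,
    intraspecific_summary,
)
from barcode_eval.njtree import BootstrapConfig, bootstrap_support, nj_build, write_newick
from barcode_eval.records import SequenceRecord

log = logging.getLogger("barcode_eval")


@dataclass
class RunConfig:
    dataset: str = "D1_longer"
    metric: str = "p"  # distance used for thresholding and the matrix artifact
    tree_metric: str = "tn93"  # distance used to build the NJ tree
    aligned: bool = False  # True: inputs are positionally homologous (no pairwise alignment)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    bootstrap_replicates: int = 0  # 0 disables bootstrap
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunSummary:
    dataset: str
    n_seqs: int
    n_species: int
    species_with_multiple: int
    category_counts: dict
    n_single_merge: int
    n_caution: int
    n_failures: int
    pct_unique: float
    conspecific_mean_subst: float
    conspecific_max_subst: int
    conspecific_mean_dist: float
    conspecific_max_dist: float
    pct_multi_species_below_threshold: float
    per_genus: list

    def check_consistency(self) -> None:
        cats = sum(self.category_counts.values())
        if cats != self.n_species:
            raise AssertionError("category counts do not sum to species count")
        failures = (
            self.category_counts.get("Split", 0)
            + self.category_counts.get("Merge", 0)
            + self.category_counts.get("Mixture", 0)
            + self.n_single_merge
        )
        if failures != self.n_failures:
            raise AssertionError("failure count inconsistent with categories")
        expect_pct = round(100 * (self.n_species - self.n_failures) / self.n_species, 1)
        if abs(expect_pct - self.pct_unique) > 1e-9:
            raise AssertionError("pct_unique inconsistent")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    assessments: list[SpeciesAssessment],
    dm: DistanceMatrix,
    species_labels: list[str],
    genus_labels: list[str],
    config: RunConfig,
) -> RunSummary:
    intra_df, intra_overall = intraspecific_summary(dm, species_labels)
    inter_df = interspecific_summary(dm, species_labels, genus_labels)
    cats = {"Match": 0, "Split": 0, "Merge": 0, "Mixture": 0, "NA_single": 0}
    for a in assessments:
        cats[a.category] += 1
    disc = discriminability(assessments)
    multi = intra_df[intra_df.n_seqs > 1]
    thr = config.classifier.caution_threshold
    pct_below = round(100 * float((multi.max_dist < thr).mean()), 1) if len(multi) else float("nan")
    summary = RunSummary(
        dataset=config.dataset,
        n_seqs=len(dm),
        n_species=disc["n_species"],
        species_with_multiple=int((intra_df.n_seqs > 1).sum()),
        category_counts=cats,
        n_single_merge=sum(1 for a in assessments if a.single_specimen_merge),
        n_caution=sum(1 for a in assessments if a.judgement == "caution"),
        n_failures=disc["n_failures"],
        pct_unique=disc["pct_unique"],
        conspecific_mean_subst=intra_overall["mean_subst_count"],
        conspecific_max_subst=intra_overall["max_subst_count"],
        conspecific_mean_dist=intra_overall["mean_dist"],
        conspecific_max_dist=intra_overall["max_dist"],
        pct_multi_species_below_threshold=pct_below,
        per_genus=inter_df.to_dict(orient="records"),
    )
    summary.check_consistency()
    return summary


def run_pipeline(records: list[SequenceRecord], config: RunConfig) -> tuple[RunSummary, list[SpeciesAssessment], dict]:
    """Run the evaluation over assembled records; optionally write artifacts.

    Returns ``(summary, assessments, artifacts)`` where artifacts maps names
    to in-memory objects (and to paths when ``config.outdir`` is set).
    """
    species_labels = [r.species for r in records]
    genus_labels = [r.genus for r in records]
    log.info("dataset %s: %d sequences, %d species", config.dataset, len(records), len(set(species_labels)))

    metrics = tuple(dict.fromkeys((config.metric, config.tree_metric, "p")))
    matrices = distance_matrices(records, metrics, params=config.alignment, aligned=config.aligned)
    dm = matrices[config.metric]
    tree_dm = matrices[config.tree_metric]
    if np.isnan(tree_dm.values).any():
        log.warning(
            "%d undefined %s distances; tree falls back to p-distance",
            tree_dm.n_undefined, config.tree_metric,
        )
        tree_dm = matrices["p"]
    tree = nj_build(tree_dm)

    boot = None
    if config.bootstrap_replicates:
        if not config.aligned:
            from barcode_eval.msa import progressive_msa

            msa = progressive_msa(records, config.alignment)
        else:
            msa = [(r.accession, r.seq) for r in records]
        tree, boot = bootstrap_support(
            msa, BootstrapConfig(config.bootstrap_replicates, config.seed, config.tree_metric)
        )

    assessments = classify_species(tree, dm, species_labels, config.classifier)
    summary = summarize(assessments, dm, species_labels, genus_labels, config)

    artifacts: dict = {"matrix": dm, "tree": tree, "bootstrap": boot}
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        dm.to_phylip(out / "matrix.phylip")
        dm.to_long_tsv(out / "distances.tsv")
        write_newick(tree, out / "tree.nwk")
        assessments_frame(assessments).to_csv(out / "assessments.tsv", sep="\t", index=False, float_format="%.6f")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        pd.json_normalize(summary.to_dict()).drop(columns=["per_genus"]).T.to_csv(out / "summary.tsv", sep="\t", header=False)
        with open(out / "report.txt", "w") as fh:
            fh.write(caution_report(assessments, config.classifier))
        with open(out / "run_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True, default=str)
        artifacts["outdir"] = str(out)
    return summary, assessments, artifacts


_ORDER = {"success": 0, "caution": 1, "failure": 2}


def compare_regions(
    assessments_long: list[SpeciesAssessment], assessments_short: list[SpeciesAssessment]
) -> dict:
    """Per-species judgement delta between a longer-region run and a
    shorter-region run over (the intersection of) the same species."""
    a = {x.species: x for x in assessments_long}
    b = {x.species: x for x in assessments_short}
    common = sorted(set(a) & set(b))
    if set(a) != set(b):
        log.warning(
            "species universes differ (%d vs %d); restricting to %d common species",
            len(a), len(b), len(common),
        )
    degraded, improved = [], []
    for sp in common:
        ja, jb = _ORDER[a[sp].judgement], _ORDER[b[sp].judgement]
        entry = {"species": sp, "long": a[sp].judgement, "short": b[sp].judgement}
        if jb > ja:
            degraded.append(entry)
        elif jb < ja:
            improved.append(entry)
    return {
        "n_common": len(common),
        "n_degraded": len(degraded),
        "n_improved": len(improved),
        "degraded": degraded,
        "improved": improved,
        "new_failures": sorted(
            sp for sp in common if b[sp].judgement == "failure" and a[sp].judgement != "failure"
        ),
    }
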