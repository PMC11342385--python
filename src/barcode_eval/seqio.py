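"""Sequence and metadata I/O, taxonomic-name revisions, dataset assembly.

The FASTA header dialect is pipe-delimited ``accession|Species_name|voucher``
(underscores in the species token become spaces). Plain NCBI-style headers
are accepted with ``header="plain"``, in which case the metadata table is the
authoritative source of species labels: INSD headers are unreliable, and a
curated library typically relabels a fraction of retrieved sequences.
"""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from barcode_eval.records import (
    DATASET_LENGTH_RANGES,
    DatasetSpec,
    NameRevision,
    SequenceRecord,
    normalize_species,
)

METADATA_COLUMNS = [
    "accession",
    "species",
    "genus",
    "voucher",
    "source",
    "d1_flag",
    "d2_flag",
    "d3_flag",
    "original_insd_name",
    "morphotype",
]

_TRUTHY = {"1", "true", "yes", "y", "〇", "o"}  # 〇 is the circle mark 〇


def read_fasta(path, header: str = "pipe", region: str = "longer12S") -> list[SequenceRecord]:
    """Read sequence records from a FASTA file.

    With ``header="pipe"`` each description must be
    ``accession|Species_with_underscores[|voucher]``; with ``header="plain"``
    the accession is the first whitespace token and the species is left empty
    ("unassigned unassigned") pending metadata join.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        desc = entry.description
        if header == "pipe":
            parts = desc.split("|")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"FASTA entry {desc!r}: no species token (expected accession|species|voucher)")
            accession = parts[0].strip()
            species = parts[1].strip().replace("_", " ")
            voucher = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        elif header == "plain":
            accession = desc.split()[0]
            species, voucher = "Unassigned unassigned", None
        else:
            raise ValueError(f"unknown header dialect {header!r}")
        records.append(
            SequenceRecord(accession=accession, species=species, seq=str(entry.seq), voucher=voucher, region=region)
        )
    if not records:
        raise ValueError(f"{path}: empty or non-FASTA file")
    _check_unique([r.accession for r in records])
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write records with pipe-delimited headers (round-trips with read_fasta)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in records:
            voucher = f"|{r.voucher}" if r.voucher else ""
            fh.write(f">{r.accession}|{r.species.replace(' ', '_')}{voucher}\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i : i + 70] + "\n")


def _check_unique(accessions: list[str]) -> None:
    dup = [a for a, c in Counter(accessions).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate accessions: {sorted(dup)}")


def read_metadata(path) -> pd.DataFrame:
    """Read the metadata TSV (accession, species, genus, voucher, source, dataset flags...)."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"accession", "species"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = ""
    meta["species"] = meta["species"].map(normalize_species)
    meta.loc[meta["genus"] == "", "genus"] = meta["species"].str.split().str[0]
    _check_unique(list(meta["accession"]))
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False)


def read_revisions(path) -> list[NameRevision]:
    """Read a two-column TSV of taxonomic-name revisions (original_name, revised_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [NameRevision(o, r) for o, r in zip(df["original_name"], df["revised_name"])]


def apply_name_revisions(
    records: list[SequenceRecord], revisions: list[NameRevision]
) -> tuple[list[SequenceRecord], int, list[NameRevision]]:
    """Relabel species according to a revision table.

    Returns ``(records, n_replaced, unmatched_revisions)``. Records are
    modified in place and also returned. Two revisions sharing an original
    name but disagreeing on the revised name are rejected.
    """
    mapping: dict[str, str] = {}
    for rev in revisions:
        orig = normalize_species(rev.original_name)
        new = normalize_species(rev.revised_name)
        if orig in mapping and mapping[orig] != new:
            raise ValueError(f"conflicting revisions for {orig!r}: {mapping[orig]!r} vs {new!r}")
        mapping[orig] = new
    n_replaced = 0
    hit: set[str] = set()
    for rec in records:
        if rec.species in mapping:
            hit.add(rec.species)
            rec.species = mapping[rec.species]
            rec.genus = rec.species.split()[0]
            n_replaced += 1
    unmatched = [rev for rev in revisions if normalize_species(rev.original_name) not in hit]
    return records, n_replaced, unmatched


def is_flagged(value: str) -> bool:
    return str(value).strip().lower() in _TRUTHY


def assemble_dataset(
    records: list[SequenceRecord], meta: pd.DataFrame, dataset_name: str
) -> tuple[DatasetSpec, list[SequenceRecord], dict]:
    """Select the records flagged for one dataset and report its composition.

    Species labels from the metadata table override the FASTA headers.
    Members whose length falls outside the dataset's expected window are
    retained with a warning — exclusion is a curation decision
    (:func:`barcode_eval.classify.curation_screen`), not an I/O side effect.
    """
    spec = DatasetSpec(dataset_name, DATASET_LENGTH_RANGES[dataset_name])
    flagged = meta[meta[spec.flag_column].map(is_flagged)]
    by_acc = {r.accession: r for r in records}
    missing = [a for a in flagged["accession"] if a not in by_acc]
    if missing:
        raise ValueError(f"{dataset_name}: flagged accessions with no sequence: {sorted(missing)}")

    members: list[SequenceRecord] = []
    lo, hi = spec.expected_length_range
    out_of_range: list[str] = []
    for row in flagged.itertuples(index=False):
        rec = by_acc[row.accession]
        if row.species:
            rec.species = row.species
            rec.genus = row.genus or rec.species.split()[0]
        if getattr(row, "voucher", ""):
            rec.voucher = row.voucher
        if getattr(row, "source", "") in ("determined", "retrieved"):
            rec.source = row.source
        if not (lo <= len(rec) <= hi):
            out_of_range.append(rec.accession)
        members.append(rec)
    if out_of_range:
        warnings.warn(
            f"{dataset_name}: {len(out_of_range)} member(s) outside expected length "
            f"{lo}-{hi} nt (retained): {out_of_range[:10]}"
        )

    species = [r.species for r in members]
    counts = Counter(species)
    report = {
        "dataset": dataset_name,
        "n_seqs": len(members),
        "n_species": len(counts),
        "species_with_multiple": sum(1 for c in counts.values() if c > 1),
        "out_of_range": out_of_range,
    }
    spec.members = frozenset(r.accession for r in members)
    return spec, members, report
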