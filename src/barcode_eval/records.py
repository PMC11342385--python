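"""Core record types shared across the package."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: IUPAC nucleotide one-letter codes mapped to the set of bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

_AUTHOR_TAIL = re.compile(r"\s*\(?[A-Z][a-zA-Zü\-&.\s]*,?\s*\d{4}\)?\s*$")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase, map U to T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return s


def normalize_species(name: str) -> str:
    """Normalize a binomial: collapse whitespace/underscores, strip author/year.

    "sp." epithets are kept verbatim (e.g. "Pomacentrus sp. minamiiso"), so
    undescribed species map to a stable species key.
    """
    s = re.sub(r"[\s_]+", " ", name).strip()
    # strip a trailing author-year citation, but never from a "sp." epithet
    if " sp." not in s:
        s = _AUTHOR_TAIL.sub("", s).strip()
    return s


@dataclass
class SequenceRecord:
    """One accessioned sequence with its species label and dataset flags."""

    accession: str
    species: str
    seq: str
    genus: str = ""
    voucher: str | None = None
    source: str = "retrieved"  # {"determined", "retrieved"}
    region: str = "longer12S"  # {"longer12S", "mifish"}

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.accession}: empty sequence")
        self.seq = normalize_seq(self.seq)
        self.species = normalize_species(self.species)
        if not self.genus:
            self.genus = self.species.split()[0]
        elif self.genus != self.species.split()[0]:
            raise ValueError(
                f"{self.accession}: genus {self.genus!r} does not match species {self.species!r}"
            )
        if self.source not in ("determined", "retrieved"):
            raise ValueError(f"{self.accession}: bad source {self.source!r}")
        if self.region not in ("longer12S", "mifish"):
            raise ValueError(f"{self.accession}: bad region {self.region!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NameRevision:
    """A taxonomic relabelling applied to the library (original -> revised)."""

    original_name: str
    revised_name: str

    def __post_init__(self) -> None:
        if normalize_species(self.original_name) == normalize_species(self.revised_name):
            raise ValueError(f"revision maps {self.original_name!r} to itself")


#: Expected sequence-length windows (nt) per dataset.
DATASET_LENGTH_RANGES = {
    "D1_longer": (725, 773),
    "D2_mifish_same": (166, 199),
    "D3_mifish_extended": (166, 199),
}

_DATASET_FLAGS = {"D1_longer": "d1_flag", "D2_mifish_same": "d2_flag", "D3_mifish_extended": "d3_flag"}


@dataclass
class DatasetSpec:
    """Membership and length expectations for one of the three analysis datasets."""

    name: str
    expected_length_range: tuple[int, int]
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.name not in DATASET_LENGTH_RANGES:
            raise ValueError(f"unknown dataset {self.name!r}; expected one of {sorted(DATASET_LENGTH_RANGES)}")

    @property
    def flag_column(self) -> str:
        return _DATASET_FLAGS[self.name]
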