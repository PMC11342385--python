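"""In-silico excision of an amplicon subregion by degenerate primer matching.

Reference libraries of the longer 12S fragment are trimmed down to the
hypervariable window they contain by locating the flanking primer sites and
cutting them (and everything outside them) away — the computational analogue
of building a short-amplicon dataset from longer deposited sequences. The
window is delimited by a primer pair given 5'->3' on each strand; the
reverse primer is reverse-complemented before matching the sense strand, and
the primers themselves are excluded from the excised insert, consistent with
reported MiFish insert lengths (~166-199 nt, averaging ~172 nt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from barcode_eval.records import IUPAC_CODES, SequenceRecord, revcomp

#: Outer amplicon primers bracketing the first half of the 12S gene.
L709 = "TACACATGCAAGTCTCCGCA"
H1552 = "ACTTACCGTGTTACGACTTGCCTC"

#: Expected insert length window (nt) for the hypervariable subregion.
MIFISH_LENGTH_RANGE = (166, 199)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair; both given 5'->3' on their own strand."""

    fwd: str
    rev: str
    max_mismatch: int = 3
    search_windows: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            if len(p) < 10:
                raise ValueError(f"primer {p!r} shorter than 10 nt")
            bad = set(p.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"primer {p!r}: non-IUPAC symbols {sorted(bad)}")
        limit = min(len(self.fwd), len(self.rev)) // 4
        if self.max_mismatch > limit:
            raise ValueError(f"max_mismatch {self.max_mismatch} exceeds floor(primer length / 4) = {limit}")


@dataclass(frozen=True)
class PrimerHit:
    start: int
    end: int  # 0-based half-open on the target
    mismatches: int
    strand: str = "+"


def _iupac_match(primer_sym: str, target_sym: str) -> bool:
    # degenerate primer symbol matches when the target base is in its set
    return target_sym in IUPAC_CODES.get(primer_sym, frozenset())


def match_primer(
    target: str, primer: str, max_mismatch: int = 3, window: tuple[int, int] | None = None
) -> PrimerHit | None:
    """Best ungapped placement of a degenerate primer on the sense strand.

    Scans every offset (optionally restricted to ``window``), counting a site
    as matched when the target base belongs to the IUPAC set of the primer
    symbol. Returns the hit with fewest mismatches (ties -> smallest start),
    or None if no placement is within ``max_mismatch``.
    """
    target = target.upper()
    primer = primer.upper()
    k = len(primer)
    lo, hi = window if window is not None else (0, len(target))
    if not (0 <= lo <= hi <= len(target)):
        raise ValueError(f"window {(lo, hi)} outside target bounds (len {len(target)})")
    best: PrimerHit | None = None
    for start in range(lo, hi - k + 1):
        mm = 0
        for ps, ts in zip(primer, target[start : start + k]):
            if not _iupac_match(ps, ts):
                mm += 1
                if mm > max_mismatch or (best is not None and mm >= best.mismatches):
                    break
        else:
            if best is None or mm < best.mismatches:
                best = PrimerHit(start, start + k, mm)
    return best


def extract_subregion(record: SequenceRecord, primers: PrimerPair) -> SequenceRecord:
    """Excise the insert between a primer pair from a longer-region record.

    The returned record carries the exact substring between the forward hit's
    end and the (reverse-complemented) reverse hit's start; the primers are
    excluded. A warning is emitted when the insert length falls outside the
    expected hypervariable window.
    """
    if record.region != "longer12S":
        raise ValueError(f"{record.accession}: expected a longer-region record, got {record.region}")
    wf, wr = primers.search_windows if primers.search_windows else (None, None)
    fwd_hit = match_primer(record.seq, primers.fwd, primers.max_mismatch, wf)
    if fwd_hit is None:
        raise ValueError(f"{record.accession}: forward primer not found within {primers.max_mismatch} mismatches")
    rev_site = revcomp(primers.rev)
    rev_hit = match_primer(record.seq, rev_site, primers.max_mismatch, wr)
    if rev_hit is None:
        raise ValueError(f"{record.accession}: reverse primer not found within {primers.max_mismatch} mismatches")
    if rev_hit.start <= fwd_hit.end:
        raise ValueError(
            f"{record.accession}: reverse primer site at {rev_hit.start} does not follow forward site end {fwd_hit.end}"
        )
    insert = record.seq[fwd_hit.end : rev_hit.start]
    lo, hi = MIFISH_LENGTH_RANGE
    if not (lo <= len(insert) <= hi):
        warnings.warn(f"{record.accession}: excised insert length {len(insert)} outside {lo}-{hi} nt")
    return SequenceRecord(
        accession=record.accession,
        species=record.species,
        seq=insert,
        genus=record.genus,
        voucher=record.voucher,
        source=record.source,
        region="mifish",
    )


def anchor_trim(record: SequenceRecord, reference: SequenceRecord, params=None, min_coverage: float = 0.8) -> SequenceRecord:
    """Trim by global alignment to a trusted subregion exemplar.

    Fallback for deposited fragments that lack the primer sites: the record
    is aligned to the reference and the columns spanning the reference's
    aligned extent are returned, gaps removed.
    """
    from barcode_eval.distances import AlignmentParams

    if reference.region != "mifish":
        raise ValueError("anchor reference must be a trimmed subregion exemplar")
    params = params or AlignmentParams()
    aligner = params.aligner()
    # semi-global: the short reference floats freely inside the record
    aligner.end_deletion_score = 0.0
    best = aligner.align(record.seq, reference.seq)[0]
    ga, gb = str(best[0]), str(best[1])
    # columns where the reference is present
    ref_cols = [i for i, c in enumerate(gb) if c != "-"]
    lo, hi = ref_cols[0], ref_cols[-1] + 1
    segment = ga[lo:hi].replace("-", "")
    matched = sum(1 for i in ref_cols if ga[i] != "-" and ga[i] == gb[i])
    coverage = matched / len(reference.seq)
    if coverage < min_coverage:
        raise ValueError(
            f"{record.accession}: aligned identity to anchor covers {coverage:.0%} of reference (< {min_coverage:.0%})"
        )
    return SequenceRecord(
        accession=record.accession,
        species=record.species,
        seq=segment,
        genus=record.genus,
        voucher=record.voucher,
        source=record.source,
        region="mifish",
    )
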