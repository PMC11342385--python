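"""Pairwise alignment, site-pattern counting, p and TN93 distances, summaries.

Distances follow the two estimators standard in barcode-gap work: the
uncorrected p-distance (proportion of differing sites among compared sites)
and the Tamura-Nei (TN93) distance, which corrects for multiple hits while
distinguishing purine transitions, pyrimidine transitions and transversions
under unequal base frequencies. Columns containing a gap or a non-ACGT
symbol are excluded pair by pair (pairwise deletion); base frequencies are
estimated from the compared sites of both sequences pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes A=0 C=1 G=2 T=3, other/gap=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring: positive penalties, a gap run of length k costs
    gap_open + (k-1)*gap_extend."""

    match: float = 2.0
    mismatch: float = 1.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.match <= -self.mismatch:
            raise ValueError("match score must exceed the (negated) mismatch penalty")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = -self.mismatch
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a


def nw_align(a: str, b: str, params: AlignmentParams | None = None) -> tuple[str, str, float]:
    """Global (Needleman-Wunsch) alignment with affine gaps.

    Returns ``(gapped_a, gapped_b, score)``; the score is optimal for the
    scoring scheme and the traceback is the aligner's canonical first path,
    so results are deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignmentParams()
    aln = params.aligner().align(a.upper(), b.upper())
    best = aln[0]
    return str(best[0]), str(best[1]), float(best.score)


@dataclass(frozen=True)
class SiteComparison:
    """Site-pattern summary of one aligned pair under pairwise deletion.

    P1/P2/Q are the proportions (of the L compared sites) of purine
    transitions (A<->G), pyrimidine transitions (C<->T) and transversions;
    gA..gT are base frequencies pooled over both sequences' compared sites.
    """

    L: int
    P1: float
    P2: float
    Q: float
    gA: float
    gC: float
    gG: float
    gT: float
    n_ts1: int = 0
    n_ts2: int = 0
    n_tv: int = 0

    @property
    def n_diff(self) -> int:
        return self.n_ts1 + self.n_ts2 + self.n_tv


def count_site_patterns(gapped_a: str, gapped_b: str, deletion_policy: str = "pairwise") -> SiteComparison:
    """Count transition/transversion site patterns for one aligned pair.

    Sites where either symbol is a gap or a non-ACGT code are excluded from
    L; an all-excluded pair is an error (no comparable sites).
    """
    if deletion_policy != "pairwise":
        raise ValueError("only pairwise deletion is supported per pair")
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings differ in length")
    a, b = encode(gapped_a), encode(gapped_b)
    valid = (a < 4) & (b < 4)
    L = int(valid.sum())
    if L == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    av, bv = a[valid], b[valid]
    ts1 = int((((av == 0) & (bv == 2)) | ((av == 2) & (bv == 0))).sum())
    ts2 = int((((av == 1) & (bv == 3)) | ((av == 3) & (bv == 1))).sum())
    diff = int((av != bv).sum())
    tv = diff - ts1 - ts2
    counts = np.bincount(av, minlength=4) + np.bincount(bv, minlength=4)
    g = counts / (2 * L)
    return SiteComparison(
        L=L, P1=ts1 / L, P2=ts2 / L, Q=tv / L,
        gA=float(g[0]), gC=float(g[1]), gG=float(g[2]), gT=float(g[3]),
        n_ts1=ts1, n_ts2=ts2, n_tv=tv,
    )


def p_distance(sc: SiteComparison) -> float:
    """Uncorrected proportion of differing sites among compared sites."""
    return sc.P1 + sc.P2 + sc.Q


def tn93_distance(sc: SiteComparison) -> float:
    """Tamura-Nei (1993) distance; ``nan`` when the correction is undefined.

    d = -k1 ln(1 - P1/k1 - Q/(2 gR)) - k2 ln(1 - P2/k2 - Q/(2 gY))
        - 2 (gR gY - gA gG gY/gR - gT gC gR/gY) ln(1 - Q/(2 gR gY))
    with k1 = 2 gA gG / gR, k2 = 2 gT gC / gY, gR = gA+gG, gY = gC+gT.

    A log argument <= 0 (saturation) yields nan, a sentinel that downstream
    consumers must reject or replace; a zero base frequency is an error.
    """
    gA, gC, gG, gT = sc.gA, sc.gC, sc.gG, sc.gT
    if min(gA, gC, gG, gT) <= 0:
        raise ValueError("TN93 undefined: a base frequency is zero among compared sites")
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    w1 = 1 - sc.P1 / k1 - sc.Q / (2 * gR)
    w2 = 1 - sc.P2 / k2 - sc.Q / (2 * gY)
    w3 = 1 - sc.Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return float("nan")
    c3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    d = -k1 * math.log(w1) - k2 * math.log(w2) - c3 * math.log(w3)
    return max(d, 0.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with companion substitution/site counts.

    ``values`` are substitutions/site (nan marks an undefined corrected
    distance); ``subst`` holds the raw integer mismatch counts, which are
    authoritative when a "bp" count is reported; ``sites`` the compared-site
    counts (pairwise deletion).
    """

    labels: list[str]
    values: np.ndarray
    metric: str  # {"p", "tn93"}
    subst: np.ndarray
    sites: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0), np.where(finite & finite.T, self.values.T, 0.0), atol=1e-12
        ):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum() // 2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + " ".join(f"{v:.6f}" for v in row) + "\n")

    def to_long_tsv(self, path) -> None:
        rows = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                rows.append(
                    (a, self.labels[j], self.metric, self.values[i, j], int(self.subst[i, j]), int(self.sites[i, j]))
                )
        pd.DataFrame(rows, columns=["acc1", "acc2", "metric", "distance", "substitutions", "sites"]).to_csv(
            path, sep="\t", index=False, float_format="%.8f"
        )


def matrix_from_codes(codes: np.ndarray, labels: list[str], metric: str = "p") -> DistanceMatrix:
    """Distance matrix from an (n, L) code array of positionally homologous rows.

    Vectorised pairwise-deletion counting; used for already-aligned inputs
    (multiple alignments, bootstrap resamples, substitution-only simulations).
    """
    n, L = codes.shape
    values = np.zeros((n, n))
    subst = np.zeros((n, n), dtype=int)
    sites = np.zeros((n, n), dtype=int)
    isbase = codes < 4
    for i in range(n - 1):
        A = codes[i]
        B = codes[i + 1 :]
        valid = isbase[i] & isbase[i + 1 :]
        Ls = valid.sum(axis=1)
        if np.any(Ls == 0):
            j = i + 1 + int(np.argmax(Ls == 0))
            raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
        diff = (valid & (A != B)).sum(axis=1)
        if metric == "p":
            d = diff / Ls
        elif metric == "tn93":
            ts1 = (valid & (((A == 0) & (B == 2)) | ((A == 2) & (B == 0)))).sum(axis=1)
            ts2 = (valid & (((A == 1) & (B == 3)) | ((A == 3) & (B == 1)))).sum(axis=1)
            tv = diff - ts1 - ts2
            counts = np.stack(
                [((A == b) & valid).sum(axis=1) + ((B == b) & valid).sum(axis=1) for b in range(4)], axis=1
            )
            g = counts / (2 * Ls)[:, None]
            if np.any(g <= 0):
                j = i + 1 + int(np.argmax(np.any(g <= 0, axis=1)))
                raise ValueError(f"TN93 undefined for pair ({labels[i]}, {labels[j]}): zero base frequency")
            d = _tn93_vec(ts1 / Ls, ts2 / Ls, tv / Ls, g)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        subst[i, i + 1 :] = subst[i + 1 :, i] = diff
        sites[i, i + 1 :] = sites[i + 1 :, i] = Ls
    return DistanceMatrix(list(labels), values, metric, subst, sites)


def _tn93_vec(P1, P2, Q, g) -> np.ndarray:
    gA, gC, gG, gT = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    c3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            (w1 > 0) & (w2 > 0) & (w3 > 0),
            -k1 * np.log(np.clip(w1, 1e-300, None))
            - k2 * np.log(np.clip(w2, 1e-300, None))
            - c3 * np.log(np.clip(w3, 1e-300, None)),
            np.nan,
        )
    return np.where(np.isnan(d), np.nan, np.maximum(d, 0.0))


def distance_matrices(
    records, metrics=("p",), params: AlignmentParams | None = None, aligned: bool = False
) -> dict[str, DistanceMatrix]:
    """All-pairs distance matrices, one per metric, from a single pass.

    With ``aligned=False`` every pair goes through one global alignment and
    one site-pattern count, from which every requested metric is derived.
    ``aligned=True`` treats equal-length inputs as positionally homologous
    (a multiple alignment, or simulated sequences without indels) and uses
    the vectorised counting path.
    """
    labels = [r.accession for r in records]
    seqs = [r.seq for r in records]
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records")
    for m in metrics:
        if m not in ("p", "tn93"):
            raise ValueError(f"unknown metric {m!r}")
    if aligned:
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("aligned=True requires equal-length sequences")
        codes = np.stack([encode(s) for s in seqs])
        return {m: matrix_from_codes(codes, labels, m) for m in metrics}
    params = params or AlignmentParams()
    values = {m: np.zeros((n, n)) for m in metrics}
    subst = np.zeros((n, n), dtype=int)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        for j in range(i + 1, n):
            try:
                ga, gb, _ = nw_align(seqs[i], seqs[j], params)
                sc = count_site_patterns(ga, gb)
                for m in metrics:
                    d = p_distance(sc) if m == "p" else tn93_distance(sc)
                    values[m][i, j] = values[m][j, i] = d
            except ValueError as err:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {err}") from err
            subst[i, j] = subst[j, i] = sc.n_diff
            sites[i, j] = sites[j, i] = sc.L
    return {m: DistanceMatrix(labels, values[m], m, subst, sites) for m in metrics}


def distance_matrix(
    records, metric: str = "p", params: AlignmentParams | None = None, aligned: bool = False
) -> DistanceMatrix:
    """All-pairs distance matrix over sequence records (see distance_matrices)."""
    return distance_matrices(records, (metric,), params=params, aligned=aligned)[metric]


# ---------------------------------------------------------------------------
# intra/interspecific summaries

def _pairs_index(dm: DistanceMatrix):
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    return iu


def intraspecific_summary(dm: DistanceMatrix, species_labels: list[str]) -> tuple[pd.DataFrame, dict]:
    """Per-species conspecific distance summary, plus the overall means.

    Species represented by one sequence appear with null distances. The
    overall dict reports the mean/max substitution count and distance over
    every conspecific pair — the quantities quoted when a library's
    within-species variation is summarised in "bp" and distance units.
    """
    sp = np.asarray(species_labels)
    if len(sp) != len(dm):
        raise ValueError("species labels do not align with matrix")
    rows = []
    all_d, all_s = [], []
    for species in sorted(set(species_labels)):
        idx = np.flatnonzero(sp == species)
        if len(idx) == 1:
            rows.append((species, 1, None, None, None))
            continue
        sub = dm.values[np.ix_(idx, idx)]
        ss = dm.subst[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        d, s = sub[iu], ss[iu]
        rows.append((species, len(idx), float(np.nanmax(d)), float(np.nanmean(d)), int(s.max())))
        all_d.extend(d.tolist())
        all_s.extend(s.tolist())
    df = pd.DataFrame(rows, columns=["species", "n_seqs", "max_dist", "mean_dist", "max_subst_count"])
    overall = {
        "n_conspecific_pairs": len(all_d),
        "mean_subst_count": float(np.mean(all_s)) if all_s else float("nan"),
        "max_subst_count": int(max(all_s)) if all_s else 0,
        "mean_dist": float(np.nanmean(all_d)) if all_d else float("nan"),
        "max_dist": float(np.nanmax(all_d)) if all_d else float("nan"),
    }
    return df, overall


def interspecific_summary(
    dm: DistanceMatrix, species_labels: list[str], genus_labels: list[str]
) -> pd.DataFrame:
    """Per-genus summary of between-species, within-genus distances.

    Only genera with >= 2 species appear; conspecific pairs are excluded.
    """
    sp = np.asarray(species_labels)
    gn = np.asarray(genus_labels)
    rows = []
    for genus in sorted(set(genus_labels)):
        idx = np.flatnonzero(gn == genus)
        if len(set(sp[idx])) < 2:
            continue
        d_list, s_list = [], []
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if sp[i] != sp[j]:
                    d_list.append(dm.values[i, j])
                    s_list.append(dm.subst[i, j])
        d = np.asarray(d_list)
        s = np.asarray(s_list, dtype=int)
        rows.append(
            (genus, len(set(sp[idx])), len(d), float(np.nanmean(d)), float(np.nanmin(d)), float(np.nanmax(d)),
             float(s.mean()), int(s.min()), int(s.max()))
        )
    return pd.DataFrame(
        rows,
        columns=["genus", "n_species", "n_pairs", "mean_dist", "min_dist", "max_dist", "mean_subst", "min_subst", "max_subst"],
    )


def nearest_heterospecific(dm: DistanceMatrix, species_labels: list[str], species: str) -> dict:
    """Minimum distance from any focal sequence to any heterospecific one.

    Ties (within 1e-12) report every tied species. This is the quantity the
    0.01 caution threshold is applied to.
    """
    sp = np.asarray(species_labels)
    focal = np.flatnonzero(sp == species)
    other = np.flatnonzero(sp != species)
    if len(focal) == 0:
        raise ValueError(f"species {species!r} not present")
    if len(other) == 0:
        raise ValueError("no heterospecific sequences present")
    sub = dm.values[np.ix_(focal, other)]
    if np.all(np.isnan(sub)):
        raise ValueError(f"all heterospecific distances undefined for {species!r}")
    dmin = float(np.nanmin(sub))
    ties = np.argwhere(np.abs(sub - dmin) <= 1e-12)
    tied_species = sorted({sp[other[j]] for _, j in ties})
    fi, oj = ties[0]
    return {
        "distance": dmin,
        "species": tied_species,
        "witness": (dm.labels[focal[fi]], dm.labels[other[oj]]),
    }
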