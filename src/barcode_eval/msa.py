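"""Progressive multiple alignment (guide tree + profile-profile merging).

Needed only where a column structure is required (bootstrap resampling,
planted-indel inspection): a p-distance NJ guide tree orders profile merges,
and profiles are aligned with the same affine scheme as the pairwise
aligner, scoring column pairs by average symbol-pair score (gap symbols
contribute zero). Deterministic: traceback prefers substitution, then a gap
in the second profile, then a gap in the first.
"""

from __future__ import annotations

import numpy as np

from barcode_eval.distances import AlignmentParams, count_site_patterns, nw_align, p_distance, DistanceMatrix


class _Profile:
    __slots__ = ("labels", "rows", "counts")

    def __init__(self, labels: list[str], rows: list[str]):
        self.labels = labels
        self.rows = rows
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.zeros((len(rows[0]), 4))
        for row in rows:
            for i, ch in enumerate(row):
                k = idx.get(ch)
                if k is not None:
                    counts[i, k] += 1
        self.counts = counts


def _column_scores(pa: _Profile, pb: _Profile, params: AlignmentParams) -> np.ndarray:
    na, nb = len(pa.rows), len(pb.rows)
    # sum over base pairs: match*same + (-mismatch)*different
    same = pa.counts @ pb.counts.T
    tot = pa.counts.sum(axis=1)[:, None] * pb.counts.sum(axis=1)[None, :]
    s = (params.match * same - params.mismatch * (tot - same)) / (na * nb)
    return s


def _merge(pa: _Profile, pb: _Profile, params: AlignmentParams) -> _Profile:
    la, lb = len(pa.rows[0]), len(pb.rows[0])
    S = _column_scores(pa, pb, params)
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # consume a column of A (gap in B)
    Y = np.full((la + 1, lb + 1), NEG)  # consume a column of B (gap in A)
    # traceback pointers: predecessor state index 0=M, 1=X, 2=Y
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -params.gap_open - (i - 1) * params.gap_extend
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Y[0, j] = -params.gap_open - (j - 1) * params.gap_extend
        ptrY[0, j] = 0 if j == 1 else 2
    go, ge = params.gap_open, params.gap_extend
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            # substitution: prefer M, then X, then Y on ties
            best, who = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, who = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, who = Yi1[j - 1], 2
            Mi[j] = Si[j - 1] + best
            ptrM[i, j] = who
            if Mi1[j] - go >= Xi1[j] - ge:
                Xi[j], ptrX[i, j] = Mi1[j] - go, 0
            else:
                Xi[j], ptrX[i, j] = Xi1[j] - ge, 1
            if Mi[j - 1] - go >= Yi[j - 1] - ge:
                Yi[j], ptrY[i, j] = Mi[j - 1] - go, 0
            else:
                Yi[j], ptrY[i, j] = Yi[j - 1] - ge, 2
    i, j = la, lb
    state, best = 0, M[i, j]
    if X[i, j] > best:
        state, best = 1, X[i, j]
    if Y[i, j] > best:
        state, best = 2, Y[i, j]
    cols: list[str] = []  # 'D' diag, 'A' A-column vs gap, 'B' gap vs B-column
    while i > 0 or j > 0:
        if state == 0:
            cols.append("D")
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append("A")
            state = int(ptrX[i, j])
            i -= 1
        else:
            cols.append("B")
            state = int(ptrY[i, j])
            j -= 1
    cols.reverse()
    new_a = ["".join(row[ia] if c != "B" else "-" for c, ia in _walk(cols, "B")) for row in pa.rows]
    new_b = ["".join(row[ib] if c != "A" else "-" for c, ib in _walk(cols, "A")) for row in pb.rows]
    return _Profile(pa.labels + pb.labels, new_a + new_b)


def _walk(cols: list[str], gap_for: str):
    """Yield (col_type, source_index) pairs; index advances except on gap columns."""
    k = 0
    for c in cols:
        yield c, k
        if c != gap_for:
            k += 1


def progressive_msa(records, params: AlignmentParams | None = None) -> list[tuple[str, str]]:
    """Multiple alignment of records; returns (label, gapped_seq) in input order.

    Guide tree is NJ on pairwise p-distances (from global alignments);
    profiles are merged child-by-child in postorder. Deterministic given the
    input order; no randomness is involved.
    """
    params = params or AlignmentParams()
    items = [(r.accession, r.seq) if not isinstance(r, tuple) else r for r in records]
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    seqs = dict(items)
    if len(items) == 1:
        return items
    if len(items) == 2:
        (la, sa), (lb, sb) = items
        ga, gb, _ = nw_align(sa, sb, params)
        return [(la, ga), (lb, gb)]

    n = len(items)
    dvals = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            ga, gb, _ = nw_align(items[i][1], items[j][1], params)
            dvals[i, j] = dvals[j, i] = p_distance(count_site_patterns(ga, gb))
    dm = DistanceMatrix(labels, dvals, "p", np.zeros((n, n), dtype=int), np.zeros((n, n), dtype=int))
    from barcode_eval.njtree import nj_build

    guide = nj_build(dm)

    def build(node) -> _Profile:
        if node.is_leaf():
            lab = node.taxon.label
            return _Profile([lab], [seqs[lab]])
        profiles = [build(ch) for ch in node.child_nodes()]
        acc = profiles[0]
        for p in profiles[1:]:
            acc = _merge(acc, p, params)
        return acc

    final = build(guide.seed_node)
    by_label = dict(zip(final.labels, final.rows))
    return [(lab, by_label[lab]) for lab in labels]
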