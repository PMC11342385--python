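"""Neighbour-joining trees, bootstrap support, newick I/O.

Classic Saitou-Nei agglomeration: at each step join the pair minimising
Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), with branch lengths from
the standard formulas. Ties are broken by the lexicographically smallest
label pair so runs are reproducible; negative branch lengths (finite-sample
artifacts) are clamped to zero with the deficit moved to the sibling branch,
preserving the path length between the joined clusters. Trees are dendropy
objects (unrooted, trifurcating seed node), so newick I/O and bipartition
encoding come from dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from barcode_eval.distances import DistanceMatrix, encode, matrix_from_codes


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0
    metric: str = "tn93"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.metric not in ("p", "tn93"):
            raise ValueError(f"unknown metric {self.metric!r}")


def nj_build(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Unrooted neighbour-joining tree from a finite distance matrix."""
    n = len(dm)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    bad = np.argwhere(~np.isfinite(dm.values))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"non-finite distance for pair ({dm.labels[i]}, {dm.labels[j]})")

    tns = taxon_namespace or dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        taxon = tns.get_taxon(lab)
        if taxon is None:
            taxon = tns.new_taxon(lab)
        nodes.append(dendropy.Node(taxon=taxon))
    # tie-break key: lexicographically smallest leaf label in each cluster
    keys = list(dm.labels)
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - (R[:, None] + R[None, :])  # grouped so Q is exactly symmetric
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i, j = min(
            ((int(a), int(b)) for a, b in ties if a < b),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        d_ij = D[i, j]
        li = d_ij / 2 + (R[i] - R[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final trifurcation: closed-form three-taxon lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2]
    central = dendropy.Node()
    for node, ln in zip(nodes, lens):
        central.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=central)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # clamp a negative branch to 0, moving the deficit to the sibling so the
    # leaf-to-leaf path through the new node is preserved
    total = li + lj
    if li < 0:
        return 0.0, max(total, 0.0)
    if lj < 0:
        return max(total, 0.0), 0.0
    return li, lj


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def bipartition_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side;
    ties resolved lexicographically), independent of rooting."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        out.add(pick)
    return out


def _msa_codes(msa) -> tuple[list[str], np.ndarray]:
    labels, rows = [], []
    for item in msa:
        if isinstance(item, tuple):
            lab, seq = item
        else:
            lab, seq = item.accession, item.seq
        labels.append(lab)
        rows.append(encode(seq))
    if len({r.size for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    return labels, np.stack(rows)


def bootstrap_support(msa, config: BootstrapConfig) -> tuple[dendropy.Tree, dict]:
    """Nonparametric bootstrap on alignment columns.

    The reference tree is NJ on the unresampled alignment; each replicate
    resamples columns with replacement (seeded), recomputes the distance
    matrix and NJ, and the support of each internal edge of the reference
    tree is the percentage of retained replicates containing the same
    bipartition. Replicates with an undefined distance are dropped; more
    than 10% dropped is an error. Supports are written as internal node
    labels (0-100).
    """
    labels, codes = _msa_codes(msa)
    if len(labels) < 4:
        raise ValueError("bootstrap needs at least 4 aligned sequences")
    ref_dm = matrix_from_codes(codes, labels, config.metric)
    if np.isnan(ref_dm.values).any():
        raise ValueError("reference matrix contains undefined distances")
    tns = dendropy.TaxonNamespace(labels)
    ref_tree = nj_build(ref_dm, taxon_namespace=tns)
    ref_bips = bipartition_sets(ref_tree)

    rng = np.random.default_rng(config.seed)
    n_cols = codes.shape[1]
    counts: dict[frozenset[str], int] = {b: 0 for b in ref_bips}
    dropped = 0
    for _ in range(config.n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_dm = matrix_from_codes(codes[:, cols], labels, config.metric)
        except ValueError:
            dropped += 1
            continue
        if np.isnan(rep_dm.values).any():
            dropped += 1
            continue
        rep_bips = bipartition_sets(nj_build(rep_dm, taxon_namespace=tns))
        for b in ref_bips & rep_bips:
            counts[b] += 1
    if dropped > 0.1 * config.n_replicates:
        raise ValueError(f"{dropped}/{config.n_replicates} bootstrap replicates dropped (undefined distances)")
    kept = config.n_replicates - dropped
    supports = {b: int(round(100 * c / kept)) for b, c in counts.items()}

    leaves_all = frozenset(labels)
    for node in ref_tree.preorder_node_iter():
        if node is ref_tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves_all - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        node.label = str(supports[pick])
    return ref_tree, {"supports": supports, "n_dropped": dropped, "n_replicates": config.n_replicates}


# ---------------------------------------------------------------------------
# newick I/O (dendropy-backed)

def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise with branch lengths to 6 decimals and supports as internal
    node labels; returns the newick string (and writes it when given a path)."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(source: str) -> dendropy.Tree:
    """Parse a newick string (or read a path-like) into an unrooted tree."""
    import os

    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    try:
        if os.path.exists(str(source)):
            tree = dendropy.Tree.get(path=str(source), **kwargs)
        else:
            tree = dendropy.Tree.get(data=str(source), **kwargs)
    except Exception as err:  # dendropy raises schema-specific errors with positions
        raise ValueError(f"malformed newick: {err}") from err
    tree.is_rooted = False
    return tree
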