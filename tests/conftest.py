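import numpy as np
import pytest

import barcode_eval as be
from barcode_eval.simulate import scenario_clean


@pytest.fixture(scope="session")
def clean_library():
    """Well-separated 30-species library, 3 sequences each, substitution-only."""
    cfg = scenario_clean(seed=7)
    records, truth, meta = be.simulate_library(cfg)
    return cfg, records, truth, meta


@pytest.fixture(scope="session")
def clean_run(clean_library):
    """Distance matrix, NJ tree and assessments over the clean library."""
    cfg, records, truth, meta = clean_library
    dm = be.distance_matrix(records, metric="p", aligned=True)
    tree = be.nj_build(dm)
    species = [r.species for r in records]
    assessments = be.classify_species(tree, dm, species)
    return dm, tree, species, assessments


def random_binary_tree(labels, rng, min_len=0.1, max_len=1.0):
    """Random unrooted binary tree over the given leaf labels (test helper:
    built by random joins, independent of the package's tree code)."""
    import dendropy

    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(nodes[k])
            nodes[k].edge.length = float(rng.uniform(min_len, max_len))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for n in nodes:
        root.add_child(n)
        n.edge.length = float(rng.uniform(min_len, max_len))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_path_distances(tree):
    """Leaf-to-leaf path lengths by BFS over the node graph (test oracle,
    independent of any library distance code)."""
    adj = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            adj.setdefault(id(node), []).append((id(ch), ch.edge.length))
            adj.setdefault(id(ch), []).append((id(node), ch.edge.length))
    leaves = {id(lf): lf.taxon.label for lf in tree.leaf_node_iter()}
    out = {}
    for start, lab in leaves.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other, olab in leaves.items():
            if olab != lab:
                out[(lab, olab)] = dist[other]
    return out
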