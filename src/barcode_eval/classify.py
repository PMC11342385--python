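"""Species-level discrimination assessment on an NJ tree and distance matrix.

Each species with two or more sequences receives one of four categories,
scored against the reference tree and the pairwise distances:

* **Match** — all sequences form a single exclusive cluster: barcoding works.
* **Split** — the sequences fall into several clusters, none shared with
  another species: a failure (a query could land in either cluster).
* **Merge** — a single cluster shared with another species: a failure.
* **Mixture** — several clusters, at least one shared: a failure.

"Cluster" (OTU) is operationalised deterministically: two leaves belong to
the same OTU iff their distance is at or below ``identity_epsilon``, or they
lie in a clade of the tree with no intervening heterospecific leaf. Species
with a single sequence cannot be placed this way; they fail only when their
sequence is shared verbatim by another species (equivalent to Merge), and
are otherwise judged by the distance to their closest heterospecific
sequence. A species that passes but sits within ``caution_threshold``
(default 0.01 substitutions/site, inclusive) of its nearest heterospecific
neighbour is marked *caution*: diagnosable in the present library but too
close for confident field identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from barcode_eval.distances import DistanceMatrix, nearest_heterospecific


@dataclass(frozen=True)
class ClassifierConfig:
    caution_threshold: float = 0.01
    identity_epsilon: float = 0.0
    metric: str = "p"

    def __post_init__(self) -> None:
        if not (0 <= self.identity_epsilon < self.caution_threshold):
            raise ValueError("require 0 <= identity_epsilon < caution_threshold")


@dataclass
class SpeciesAssessment:
    species: str
    n_seqs: int
    category: str  # {"Match", "Split", "Merge", "Mixture", "NA_single"}
    k: int  # number of pure clusters (1 for single-specimen species)
    single_specimen_merge: bool
    max_intra: float | None
    nn_hetero: float
    nn_species: list[str]
    judgement: str  # {"success", "caution", "failure"}

    def __post_init__(self) -> None:
        multi = self.category in ("Match", "Split", "Merge", "Mixture")
        if multi != (self.n_seqs >= 2):
            raise ValueError(f"{self.species}: category {self.category} inconsistent with n_seqs {self.n_seqs}")


def _species_leaves(tree: dendropy.Tree, species_labels: dict[str, str], species: str) -> list:
    return [lf for lf in tree.leaf_node_iter() if species_labels[lf.taxon.label] == species]


def pure_clusters(
    tree: dendropy.Tree,
    species_labels: dict[str, str],
    species: str,
    matrix: DistanceMatrix | None = None,
    epsilon: float = 0.0,
) -> tuple[int, list[list[str]]]:
    """Partition a species' leaves into maximal conspecific-only clades.

    Unrooted-safe: a "clade" is either side of any edge. The maximal sides
    containing only leaves of the focal species form a laminar family and
    hence partition the species' leaves; ``k`` is the number of parts. When
    a distance matrix is supplied, parts whose members lie within
    ``epsilon`` of each other are merged (identical haplotypes scattered by
    tie-breaking should not inflate the cluster count).
    """
    leaves = list(tree.leaf_node_iter())
    focal = [lf for lf in leaves if species_labels[lf.taxon.label] == species]
    if not focal:
        raise ValueError(f"species {species!r} absent from tree")
    if len(focal) == len(leaves):
        parts = [[lf.taxon.label for lf in focal]]
        return 1, parts

    # root the traversal at a heterospecific leaf so every pure side is a
    # subtree "below" some node
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * len(leaves) + 1000))
    outside = next(lf for lf in leaves if species_labels[lf.taxon.label] != species)
    adj: dict[int, list] = {}
    node_of: dict[int, dendropy.Node] = {}

    def nid(n):
        node_of[id(n)] = n
        return id(n)

    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            adj.setdefault(nid(node), []).append(nid(ch))
            adj.setdefault(nid(ch), []).append(nid(node))

    focal_ids = {id(lf) for lf in focal}
    parts: list[list[str]] = []

    def explore(u: int, parent: int) -> tuple[bool, list[int]]:
        """Return (pure, focal-leaf ids) for the component below u; append
        maximal pure subtrees hanging off impure nodes as parts."""
        node = node_of[u]
        children = [v for v in adj[u] if v != parent]
        if not children:
            return (u in focal_ids), [u] if u in focal_ids else []
        results = [explore(v, u) for v in children]
        if all(p for p, _ in results):
            return True, [x for _, xs in results for x in xs]
        for pure, xs in results:
            if pure and xs:
                parts.append([node_of[x].taxon.label for x in xs])
        return False, []

    root_id = id(outside)
    pure, xs = explore(next(v for v in adj[root_id]), root_id)
    if pure and xs:
        parts.append([node_of[x].taxon.label for x in xs])

    if matrix is not None and len(parts) > 1:
        parts = _merge_close_parts(parts, matrix, epsilon)
    parts = sorted((sorted(p) for p in parts), key=lambda p: p[0])
    return len(parts), parts


def _merge_close_parts(parts: list[list[str]], matrix: DistanceMatrix, epsilon: float) -> list[list[str]]:
    parent = list(range(len(parts)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(parts) - 1):
        for j in range(i + 1, len(parts)):
            dmin = min(matrix.loc(a, b) for a in parts[i] for b in parts[j])
            if dmin <= epsilon:
                parent[find(j)] = find(i)
    merged: dict[int, list[str]] = {}
    for i, part in enumerate(parts):
        merged.setdefault(find(i), []).extend(part)
    return list(merged.values())


def shares_identity(
    dm: DistanceMatrix, species_labels: list[str], species: str, epsilon: float = 0.0
) -> tuple[bool, list[tuple[str, str, str, float]]]:
    """Does any heterospecific sequence sit within ``epsilon`` of the species?

    Returns the flag and witness pairs (focal_acc, other_acc, other_species,
    distance)."""
    sp = np.asarray(species_labels)
    focal = np.flatnonzero(sp == species)
    other = np.flatnonzero(sp != species)
    if len(focal) == 0:
        raise ValueError(f"species {species!r} not present")
    witnesses = []
    for i in focal:
        for j in other:
            d = dm.values[i, j]
            if np.isfinite(d) and d <= epsilon:
                witnesses.append((dm.labels[i], dm.labels[j], sp[j], float(d)))
    return bool(witnesses), witnesses


def classify_species(
    tree: dendropy.Tree,
    dm: DistanceMatrix,
    species_labels: list[str],
    config: ClassifierConfig | None = None,
) -> list[SpeciesAssessment]:
    """Assess every species in the library (sorted by species name)."""
    config = config or ClassifierConfig()
    if len(species_labels) != len(dm):
        raise ValueError("species labels do not align with matrix")
    label_map = dict(zip(dm.labels, species_labels))
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_leaves != set(dm.labels):
        raise ValueError("tree and matrix cover different accessions")

    sp = np.asarray(species_labels)
    out: list[SpeciesAssessment] = []
    for species in sorted(set(species_labels)):
        idx = np.flatnonzero(sp == species)
        n = len(idx)
        shared, _wit = shares_identity(dm, species_labels, species, config.identity_epsilon)
        nn = nearest_heterospecific(dm, species_labels, species)
        if n == 1:
            category, k, max_intra = "NA_single", 1, None
            single_merge = shared
            failure = shared
        else:
            k, _parts = pure_clusters(tree, label_map, species, matrix=dm, epsilon=config.identity_epsilon)
            single_merge = False
            if k == 1:
                category = "Merge" if shared else "Match"
            else:
                category = "Mixture" if shared else "Split"
            failure = category != "Match"
            sub = dm.values[np.ix_(idx, idx)]
            max_intra = float(np.nanmax(sub[np.triu_indices(n, k=1)]))
        if failure:
            judgement = "failure"
        elif 0 < nn["distance"] <= config.caution_threshold:
            judgement = "caution"
        else:
            judgement = "success"
        out.append(
            SpeciesAssessment(
                species=species,
                n_seqs=n,
                category=category,
                k=k,
                single_specimen_merge=single_merge,
                max_intra=max_intra,
                nn_hetero=nn["distance"],
                nn_species=nn["species"],
                judgement=judgement,
            )
        )
    return out


def assessments_frame(assessments: list[SpeciesAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": a.species,
                "n_seqs": a.n_seqs,
                "category": a.category,
                "k": a.k,
                "single_specimen_merge": a.single_specimen_merge,
                "max_intra": a.max_intra,
                "nn_hetero": a.nn_hetero,
                "nn_species": ";".join(a.nn_species),
                "judgement": a.judgement,
            }
            for a in assessments
        ]
    )


def caution_report(assessments: list[SpeciesAssessment], config: ClassifierConfig | None = None) -> str:
    """Text report of every species not judged a clean success, grouped by
    genus, with the category in parentheses and near-threshold species
    flagged as Cautions."""
    config = config or ClassifierConfig()
    lines: list[str] = []
    by_genus: dict[str, list[SpeciesAssessment]] = {}
    for a in assessments:
        if a.judgement == "success":
            continue
        by_genus.setdefault(a.species.split()[0], []).append(a)
    for genus in sorted(by_genus):
        lines.append(genus)
        for a in by_genus[genus]:
            cat = "Merge" if a.single_specimen_merge else a.category
            tag = " [Caution]" if a.judgement == "caution" else ""
            nn = ", ".join(a.nn_species)
            lines.append(f"  {a.species} ({cat}){tag}  nn={a.nn_hetero:.4f} to {nn}")
    return "\n".join(lines) + ("\n" if lines else "")


def discriminability(assessments: list[SpeciesAssessment]) -> dict:
    """Library-level discrimination summary.

    ``n_unique`` counts species whose sequences are not confused with any
    other species (judgement != failure); ``pct_unique`` is reported to one
    decimal, the conventional precision for these percentages.
    """
    n_species = len(assessments)
    n_failures = sum(1 for a in assessments if a.judgement == "failure")
    n_unique = n_species - n_failures
    pct = round(100 * n_unique / n_species, 1) if n_species else float("nan")
    return {"n_species": n_species, "n_failures": n_failures, "n_unique": n_unique, "pct_unique": pct}


def curation_screen(
    dm: DistanceMatrix,
    tree: dendropy.Tree | None,
    species_labels: list[str],
    genus_labels: list[str] | None = None,
    max_conspecific_dist: float = 0.05,
    require_genus_neighbor: bool = True,
) -> list[dict]:
    """Flag sequences that deserve a second look before analysis.

    A sequence is flagged (never auto-excluded) when its nearest conspecific
    is further than ``max_conspecific_dist``, or when its overall nearest
    neighbour belongs to a different genus while conspecific sequences exist
    elsewhere — both signatures of mislabelled or otherwise anomalous
    deposits. Exclusion is left to the curator.
    """
    sp = np.asarray(species_labels)
    gn = np.asarray(genus_labels if genus_labels is not None else [s.split()[0] for s in species_labels])
    flags: list[dict] = []
    n = len(dm)
    vals = dm.values.copy()
    np.fill_diagonal(vals, np.inf)
    for i in range(n):
        consp = np.flatnonzero((sp == sp[i]) & (np.arange(n) != i))
        if len(consp) == 0:
            continue
        d_consp = float(np.nanmin(vals[i, consp]))
        if d_consp > max_conspecific_dist:
            flags.append(
                {
                    "accession": dm.labels[i],
                    "species": sp[i],
                    "reason": "distant_conspecific",
                    "detail": f"nearest conspecific at {d_consp:.4f} > {max_conspecific_dist}",
                }
            )
        if require_genus_neighbor:
            j = int(np.nanargmin(vals[i]))
            if gn[j] != gn[i] and vals[i, j] < d_consp:
                flags.append(
                    {
                        "accession": dm.labels[i],
                        "species": sp[i],
                        "reason": "heterogeneric_neighbor",
                        "detail": f"nearest neighbour {dm.labels[j]} ({sp[j]}) at {vals[i, j]:.4f} "
                        f"is another genus; nearest conspecific at {d_consp:.4f}",
                    }
                )
    return flags
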