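import itertools

import numpy as np
import pytest

import barcode_eval as be
from barcode_eval.classify import ClassifierConfig, pure_clusters, shares_identity
from barcode_eval.distances import DistanceMatrix
from barcode_eval.njtree import read_newick
from barcode_eval.records import SequenceRecord
from conftest import random_binary_tree


def brute_force_pure_k(tree, species_labels, species):
    """Oracle: enumerate both sides of every edge; count maximal sides whose
    leaves all belong to the focal species."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    focal = frozenset(l for l in leaves if species_labels[l] == species)
    if focal == leaves:
        return 1  # the whole tree is one conspecific cluster
    sides = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(below)
        sides.add(leaves - below)
    pure = [s for s in sides if s and s <= focal]
    maximal = [s for s in pure if not any(s < t for t in pure)]
    return len(maximal)


class TestPureClusters:
    def test_monophyletic_species(self):
        tree = read_newick("((A1:1,A2:1):1,(B1:1,B2:1):1,C1:2);")
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C"}
        k, parts = pure_clusters(tree, labels, "A")
        assert k == 1 and parts == [["A1", "A2"]]

    def test_paraphyletic_species_split_in_two(self):
        tree = read_newick("((A1:1,(B1:1,A2:1):1):1,B2:1,OUT:1);")
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "OUT": "O"}
        k, parts = pure_clusters(tree, labels, "A")
        assert k == 2
        assert parts == [["A1"], ["A2"]]

    def test_agrees_with_exhaustive_clade_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            labels = [f"L{k}" for k in range(n)]
            tree = random_binary_tree(labels, rng)
            species_of = {lab: f"S{rng.integers(1, 4)}" for lab in labels}
            present = set(species_of.values())
            for sp in present:
                k, parts = pure_clusters(tree, species_of, sp)
                assert k == brute_force_pure_k(tree, species_of, sp)
                # parts partition the focal leaves
                flat = sorted(itertools.chain.from_iterable(parts))
                assert flat == sorted(l for l in labels if species_of[l] == sp)

    def test_epsilon_merges_identical_haplotype_clusters(self):
        # A1 and A2 identical (d=0) but separated in the tree by B1 at d=0
        tree = read_newick("((A1:0,B1:0):1,A2:0,C1:2);")
        labels = {"A1": "A", "A2": "A", "B1": "B", "C1": "C"}
        vals = np.array(
            [
                [0, 0.0, 0.0, 0.3],
                [0.0, 0, 0.0, 0.3],
                [0.0, 0.0, 0, 0.3],
                [0.3, 0.3, 0.3, 0],
            ]
        )
        dm = DistanceMatrix(["A1", "A2", "B1", "C1"], vals, "p", np.zeros((4, 4), int), np.zeros((4, 4), int))
        k_tree, _ = pure_clusters(tree, labels, "A")
        assert k_tree == 2
        k_eps, _ = pure_clusters(tree, labels, "A", matrix=dm, epsilon=0.0)
        assert k_eps == 1

    def test_absent_species_is_error(self):
        tree = read_newick("(A1:1,B1:1,C1:1);")
        with pytest.raises(ValueError, match="absent"):
            pure_clusters(tree, {"A1": "A", "B1": "B", "C1": "C"}, "Z")


def toy_matrix(labels, pairs, default=0.1):
    n = len(labels)
    vals = np.full((n, n), default)
    np.fill_diagonal(vals, 0)
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), d in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = d
    return DistanceMatrix(labels, vals, "p", np.zeros((n, n), int), np.zeros((n, n), int))


class TestSharesIdentity:
    def test_identical_cross_species_pair(self):
        dm = toy_matrix(["A1", "B1", "C1"], {("A1", "B1"): 0.0})
        shared, wit = shares_identity(dm, ["A", "B", "C"], "A", epsilon=0.0)
        assert shared and wit[0][:2] == ("A1", "B1")

    def test_small_but_nonzero_distance_not_shared(self):
        dm = toy_matrix(["A1", "B1"], {("A1", "B1"): 0.004})
        shared, wit = shares_identity(dm, ["A", "B"], "A", epsilon=0.0)
        assert not shared and wit == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(71)
        labels = [f"X{i}" for i in range(8)]
        species = [f"S{i % 3}" for i in range(8)]
        vals = rng.random((8, 8)) * 0.02
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix(labels, vals, "p", np.zeros((8, 8), int), np.zeros((8, 8), int))
        eps = 0.005
        for sp in set(species):
            brute = any(
                vals[i, j] <= eps
                for i in range(8)
                for j in range(8)
                if species[i] == sp and species[j] != sp
            )
            assert shares_identity(dm, species, sp, eps)[0] == brute


def two_species_setup(d_inter=0.05):
    newick = "((A1:0.001,A2:0.001):0.02,(B1:0.001,B2:0.001):0.02,OUT:0.2);"
    tree = read_newick(newick)
    labels = ["A1", "A2", "B1", "B2", "OUT"]
    species = ["Alpha a", "Alpha a", "Alpha b", "Alpha b", "Out x"]
    pairs = {("A1", "A2"): 0.002, ("B1", "B2"): 0.002}
    for a in ("A1", "A2"):
        for b in ("B1", "B2"):
            pairs[(a, b)] = d_inter
    dm = toy_matrix(labels, pairs, default=0.3)
    return tree, dm, species


class TestClassifySpecies:
    def test_reciprocal_monophyly_is_match_success(self):
        tree, dm, species = two_species_setup()
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].category == "Match" and out["Alpha a"].judgement == "success"
        assert out["Alpha b"].category == "Match" and out["Alpha b"].judgement == "success"

    def test_caution_when_within_threshold(self):
        tree, dm, species = two_species_setup(d_inter=0.008)
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].judgement == "caution"

    def test_boundary_exactly_at_threshold_is_caution(self):
        tree, dm, species = two_species_setup(d_inter=0.01)
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].judgement == "caution"
        tree, dm, species = two_species_setup(d_inter=0.0100001)
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].judgement == "success"

    def test_mixture_for_intermixed_shared_species(self):
        # A's sequences identical to B's and interleaved in the tree
        tree = read_newick("((A1:0,B1:0):0.01,(A2:0,B2:0):0.01,OUT:0.2);")
        labels = ["A1", "A2", "B1", "B2", "OUT"]
        species = ["Alpha a", "Alpha a", "Alpha b", "Alpha b", "Out x"]
        pairs = {
            ("A1", "B1"): 0.0, ("A2", "B2"): 0.0,
            ("A1", "A2"): 0.02, ("B1", "B2"): 0.02,
            ("A1", "B2"): 0.02, ("A2", "B1"): 0.02,
        }
        dm = toy_matrix(labels, pairs, default=0.3)
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].category == "Mixture"
        assert out["Alpha b"].category == "Mixture"
        assert out["Alpha a"].judgement == "failure"

    def test_merge_when_single_cluster_shared(self):
        tree = read_newick("((A1:0,A2:0,B1:0):0.02,C1:0.1,OUT:0.2);")
        labels = ["A1", "A2", "B1", "C1", "OUT"]
        species = ["Alpha a", "Alpha a", "Alpha b", "Gamma c", "Out x"]
        pairs = {("A1", "A2"): 0.0, ("A1", "B1"): 0.0, ("A2", "B1"): 0.0}
        dm = toy_matrix(labels, pairs, default=0.3)
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Alpha a"].category == "Merge"
        assert out["Alpha b"].single_specimen_merge
        assert out["Alpha b"].judgement == "failure"

    def test_single_specimen_without_sharing_judged_by_distance(self):
        tree, dm, species = two_species_setup()
        out = {a.species: a for a in be.classify_species(tree, dm, species)}
        assert out["Out x"].category == "NA_single"
        assert not out["Out x"].single_specimen_merge
        assert out["Out x"].judgement == "success"

    def test_category_partition_holds(self, clean_run):
        _, _, _, assessments = clean_run
        for a in assessments:
            if a.n_seqs >= 2:
                assert a.category in {"Match", "Split", "Merge", "Mixture"}
            else:
                assert a.category == "NA_single"

    def test_raising_threshold_never_creates_success(self, clean_run):
        dm, tree, species, _ = clean_run
        lo = be.classify_species(tree, dm, species, ClassifierConfig(caution_threshold=0.01))
        hi = be.classify_species(tree, dm, species, ClassifierConfig(caution_threshold=0.03))
        for a, b in zip(lo, hi):
            assert a.species == b.species
            if b.judgement == "success":
                assert a.judgement == "success"


class TestReportsAndCounts:
    def test_discriminability_arithmetic(self):
        tree, dm, species = two_species_setup(d_inter=0.008)
        assessments = be.classify_species(tree, dm, species)
        d = be.discriminability(assessments)
        assert d["n_species"] == 3 and d["n_failures"] == 0
        assert d["pct_unique"] == 100.0

    def test_caution_report_contents(self):
        tree, dm, species = two_species_setup(d_inter=0.008)
        assessments = be.classify_species(tree, dm, species)
        text = be.caution_report(assessments)
        assert "Alpha a" in text and "[Caution]" in text
        assert "Out x" not in text  # success species omitted

    def test_success_species_absent_from_report(self):
        tree, dm, species = two_species_setup(d_inter=0.05)
        assessments = be.classify_species(tree, dm, species)
        assert be.caution_report(assessments) == ""


class TestCurationScreen:
    def _records(self):
        rng = np.random.default_rng(81)
        base_a = rng.choice(list("ACGT"), 200)
        base_b = np.where(rng.random(200) < 0.15, rng.choice(list("ACGT"), 200), base_a)
        recs, species = [], []
        for i in range(3):
            s = np.where(rng.random(200) < 0.005, rng.choice(list("ACGT"), 200), base_a)
            recs.append(SequenceRecord(f"A{i}", "Alpha one", "".join(s)))
            species.append("Alpha one")
        for i in range(3):
            s = np.where(rng.random(200) < 0.005, rng.choice(list("ACGT"), 200), base_b)
            recs.append(SequenceRecord(f"B{i}", "Beta two", "".join(s)))
            species.append("Beta two")
        return recs, species

    def test_clean_library_unflagged(self):
        recs, species = self._records()
        dm = be.distance_matrix(recs, metric="p")
        assert be.curation_screen(dm, None, species) == []

    def test_mislabelled_sequence_flagged(self):
        # one sequence generated inside the Beta cluster but deposited under
        # an Alpha label: exactly that sequence should be flagged
        recs, species = self._records()
        rng = np.random.default_rng(99)
        beta_seq = np.array(list(recs[3].seq))
        drift = np.where(rng.random(200) < 0.02, rng.choice(list("ACGT"), 200), beta_seq)
        recs.append(SequenceRecord("M0", "Alpha one", "".join(drift)))
        species.append("Alpha one")
        dm = be.distance_matrix(recs, metric="p")
        flagged = {f["accession"] for f in be.curation_screen(dm, None, species)}
        assert flagged == {"M0"}

    def test_deep_split_threshold_sensitivity(self):
        # a genuine deep intraspecific split at 0.026 flags at the 0.02
        # default-style threshold but passes at 0.03
        labels = ["X1", "X2", "Y1"]
        species = ["Xu xi", "Xu xi", "Yo yi"]
        pairs = {("X1", "X2"): 0.026, ("X1", "Y1"): 0.15, ("X2", "Y1"): 0.15}
        dm = toy_matrix(labels, pairs, default=0.15)
        assert be.curation_screen(dm, None, species, max_conspecific_dist=0.02) != []
        assert be.curation_screen(dm, None, species, max_conspecific_dist=0.03) == []


def test_config_epsilon_must_stay_below_threshold():
    with pytest.raises(ValueError):
        ClassifierConfig(caution_threshold=0.01, identity_epsilon=0.02)
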