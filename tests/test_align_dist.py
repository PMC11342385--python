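import math

import numpy as np
import pytest

import barcode_eval as be
from barcode_eval.distances import (
    AlignmentParams,
    SiteComparison,
    count_site_patterns,
    matrix_from_codes,
    encode,
    nw_align,
    p_distance,
    tn93_distance,
)
from barcode_eval.records import SequenceRecord


def exhaustive_best_score(a, b, p: AlignmentParams):
    """Independent oracle: enumerate every global alignment path, scoring
    affine gap runs directly (first gap residue costs gap_open, later ones
    gap_extend). Exponential — only for short strings."""
    best = -math.inf

    def rec(i, j, last, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] else -p.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "X", score - (p.gap_extend if last == "X" else p.gap_open))
        if j < len(b):
            rec(i, j + 1, "Y", score - (p.gap_extend if last == "Y" else p.gap_open))

    rec(0, 0, "M", 0.0)
    return best


class TestNwAlign:
    def test_identity(self):
        ga, gb, score = nw_align("ACGT", "ACGT")
        assert ga == gb == "ACGT"
        assert score == 4 * AlignmentParams().match

    def test_single_gap_placed(self):
        ga, gb, _ = nw_align("ACGT", "ACGGT")
        assert len(ga) == len(gb) == 5
        assert ga.count("-") == 1 and gb.count("-") == 0
        assert ga.replace("-", "") == "ACGT"

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 40))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 40))))
            ga, gb, _ = nw_align(a, b)
            assert ga.replace("-", "") == a
            assert gb.replace("-", "") == b

    def test_score_is_optimal_for_short_pairs(self):
        """Alignment score equals the exhaustive-search optimum (length <= 8)."""
        rng = np.random.default_rng(4)
        params = AlignmentParams()
        for _ in range(30):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            _, _, score = nw_align(a, b, params)
            assert score == pytest.approx(exhaustive_best_score(a, b, params))
        for _ in range(3):
            a = "".join(rng.choice(list("ACGT"), 8))
            b = "".join(rng.choice(list("ACGT"), 8))
            _, _, score = nw_align(a, b, params)
            assert score == pytest.approx(exhaustive_best_score(a, b, params))


class TestSitePatterns:
    def test_purine_transition(self):
        sc = count_site_patterns("ACGT", "GCGT")
        assert (sc.L, sc.P1, sc.P2, sc.Q) == (4, 0.25, 0.0, 0.0)

    def test_gap_column_dropped(self):
        assert count_site_patterns("AC-T", "ACGT").L == 3

    def test_ambiguity_dropped(self):
        assert count_site_patterns("ANGT", "ACGT").L == 3

    def test_all_gapped_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            count_site_patterns("---", "AC-")

    def test_frequencies_pooled_and_sum_to_one(self):
        sc = count_site_patterns("AACC", "AGCC")
        assert sc.gA + sc.gC + sc.gG + sc.gT == pytest.approx(1.0, abs=1e-12)
        assert sc.gA == pytest.approx(3 / 8)


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance(count_site_patterns("ACGT" * 10, "ACGT" * 10)) == 0.0

    def test_three_over_750(self):
        a = "ACGT" * 188  # 752 nt; use first 750
        a = a[:750]
        b = a[:100] + "T" + a[101:200] + "G" + a[201:300] + "C" + a[301:]
        sc = count_site_patterns(a, b)
        assert p_distance(sc) == pytest.approx(3 / 750)
        assert sc.n_diff == 3

    def test_matches_mismatch_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            L = int(rng.integers(10, 200))
            a = "".join(rng.choice(list("ACGT"), L))
            b = "".join(rng.choice(list("ACGT"), L))
            sc = count_site_patterns(a, b)
            brute = sum(x != y for x, y in zip(a, b)) / L
            assert p_distance(sc) == pytest.approx(brute)


def k2p_distance(P, Q):
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestTn93:
    def test_zero_on_identical(self):
        sc = SiteComparison(L=100, P1=0, P2=0, Q=0, gA=0.25, gC=0.25, gG=0.25, gT=0.25)
        assert tn93_distance(sc) == 0.0

    @pytest.mark.parametrize("P,Q", [(0.01, 0.005), (0.04, 0.02), (0.1, 0.06)])
    def test_equals_k2p_under_equal_frequencies(self, P, Q):
        sc = SiteComparison(L=1000, P1=P / 2, P2=P / 2, Q=Q, gA=0.25, gC=0.25, gG=0.25, gT=0.25)
        assert tn93_distance(sc) == pytest.approx(k2p_distance(P, Q), rel=1e-10)

    def test_at_least_p_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            L = 400
            a = "".join(rng.choice(list("ACGT"), L))
            b = "".join(np.where(rng.random(L) < 0.08, rng.choice(list("ACGT"), L), list(a)))
            sc = count_site_patterns(a, b)
            d = tn93_distance(sc)
            if not math.isnan(d):
                assert d >= p_distance(sc) - 1e-12

    def test_saturation_flagged_nan(self):
        sc = SiteComparison(L=100, P1=0.4, P2=0.1, Q=0.3, gA=0.25, gC=0.25, gG=0.25, gT=0.25)
        assert math.isnan(tn93_distance(sc))

    def test_zero_frequency_is_error(self):
        sc = SiteComparison(L=100, P1=0.01, P2=0, Q=0, gA=0.5, gC=0.5, gG=0.0, gT=0.0)
        with pytest.raises(ValueError, match="frequency"):
            tn93_distance(sc)


class TestDistanceMatrix:
    def test_identical_records_zero_matrix(self):
        recs = [SequenceRecord(f"A{i}", "X y", "ACGTACGTACGT") for i in range(3)]
        dm = be.distance_matrix(recs, metric="p")
        assert np.all(dm.values == 0)

    def test_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(12)
        recs = [
            SequenceRecord(f"A{i}", "X y", "".join(rng.choice(list("ACGT"), 80))) for i in range(5)
        ]
        dm = be.distance_matrix(recs, metric="p")
        assert np.allclose(dm.values, dm.values.T)
        dm_rev = be.distance_matrix(recs[::-1], metric="p")
        for a in dm.labels:
            for b in dm.labels:
                assert dm.loc(a, b) == pytest.approx(dm_rev.loc(a, b))

    def test_hand_computed_values(self):
        # equal-length, no indels: distances are direct mismatch proportions
        seqs = {
            "A1": "ACGTACGTAC",
            "A2": "ACGTACGTAC",
            "A3": "ACGAACGTAC",  # 1 diff vs A1
            "A4": "TCGAACGTAC",  # 2 diffs vs A1
            "A5": "ACGTACGTGG",  # 2 diffs vs A1
        }
        recs = [SequenceRecord(k, "X y", v) for k, v in seqs.items()]
        dm = be.distance_matrix(recs, metric="p")
        assert dm.loc("A1", "A2") == 0.0
        assert dm.loc("A1", "A3") == pytest.approx(0.1, abs=1e-12)
        assert dm.loc("A1", "A4") == pytest.approx(0.2, abs=1e-12)
        assert dm.loc("A3", "A4") == pytest.approx(0.1, abs=1e-12)
        assert dm.loc("A4", "A5") == pytest.approx(0.4, abs=1e-12)

    def test_aligned_fast_path_matches_pairwise(self):
        rng = np.random.default_rng(5)
        base = rng.choice(list("ACGT"), 300)
        recs = []
        for i in range(6):
            s = np.where(rng.random(300) < 0.03, rng.choice(list("ACGT"), 300), base)
            recs.append(SequenceRecord(f"A{i}", "X y", "".join(s)))
        slow = be.distance_matrix(recs, metric="tn93", aligned=False)
        fast = be.distance_matrix(recs, metric="tn93", aligned=True)
        assert np.allclose(slow.values, fast.values, atol=1e-12, equal_nan=True)
        assert np.array_equal(slow.subst, fast.subst)


class TestSummaries:
    @pytest.fixture()
    def toy(self):
        # two species x two seqs, plus one singleton; equal length
        seqs = {
            "A1": "ACGTACGTACGTACGTACGT",
            "A2": "ACGTACGTACGTACGTACGA",  # 1 diff from A1
            "B1": "ACGTACGTACGTTTTTACGT",  # 4 diffs from A1
            "B2": "ACGTACGTACGTTTTAACGT",
            "C1": "GGGTACGTACGTTTTTACGT",
        }
        species = ["Alpha one", "Alpha one", "Alpha two", "Alpha two", "Beta one"]
        recs = [SequenceRecord(k, sp, v) for (k, v), sp in zip(seqs.items(), species)]
        dm = be.distance_matrix(recs, metric="p")
        return dm, species, [s.split()[0] for s in species]

    def test_intraspecific(self, toy):
        dm, species, _ = toy
        df, overall = be.intraspecific_summary(dm, species)
        alpha1 = df[df.species == "Alpha one"].iloc[0]
        assert alpha1.max_dist == pytest.approx(0.05)
        assert alpha1.max_subst_count == 1
        single = df[df.species == "Beta one"].iloc[0]
        assert single.max_dist is None or np.isnan(single.max_dist)
        assert overall["n_conspecific_pairs"] == 2

    def test_intraspecific_max_over_pairs(self):
        recs = [
            SequenceRecord("A1", "X y", "A" * 100),
            SequenceRecord("A2", "X y", "A" * 99 + "C"),
            SequenceRecord("A3", "X y", "C" * 2 + "A" * 98),
        ]
        dm = be.distance_matrix(recs, metric="p")
        df, _ = be.intraspecific_summary(dm, ["X y"] * 3)
        assert df.iloc[0].max_dist == pytest.approx(0.03)

    def test_interspecific_within_genus_only(self, toy):
        dm, species, genus = toy
        df = be.interspecific_summary(dm, species, genus)
        assert list(df.genus) == ["Alpha"]  # Beta has one species
        row = df.iloc[0]
        # brute force over the 4 Alpha-one x Alpha-two pairs
        pairs = [("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2")]
        vals = [dm.loc(a, b) for a, b in pairs]
        assert row.mean_dist == pytest.approx(np.mean(vals))
        assert row.min_dist == pytest.approx(min(vals))
        assert row.max_dist == pytest.approx(max(vals))

    def test_nearest_heterospecific(self, toy):
        dm, species, _ = toy
        nn = be.nearest_heterospecific(dm, species, "Beta one")
        brute = min(dm.loc("C1", x) for x in ["A1", "A2", "B1", "B2"])
        assert nn["distance"] == pytest.approx(brute)

    def test_nearest_heterospecific_zero_on_shared(self):
        recs = [
            SequenceRecord("A1", "X y", "ACGT" * 10),
            SequenceRecord("B1", "X z", "ACGT" * 10),
            SequenceRecord("C1", "W v", "TTTT" * 10),
        ]
        dm = be.distance_matrix(recs, metric="p")
        nn = be.nearest_heterospecific(dm, ["X y", "X z", "W v"], "X y")
        assert nn["distance"] == 0.0
        assert nn["species"] == ["X z"]

    def test_no_heterospecific_is_error(self):
        recs = [SequenceRecord("A1", "X y", "ACGT"), SequenceRecord("A2", "X y", "ACGT")]
        dm = be.distance_matrix(recs, metric="p")
        with pytest.raises(ValueError, match="heterospecific"):
            be.nearest_heterospecific(dm, ["X y", "X y"], "X y")


class TestProgressiveMsa:
    def test_identical_records_no_gaps(self):
        recs = [SequenceRecord(f"A{i}", "X y", "ACGTACGTACGTACGT") for i in range(4)]
        msa = be.progressive_msa(recs)
        assert all(s == "ACGTACGTACGTACGT" for _, s in msa)

    def test_substitution_only_is_trivial_stacking(self):
        rng = np.random.default_rng(6)
        base = rng.choice(list("ACGT"), 60)
        recs = []
        for i in range(5):
            s = np.where(rng.random(60) < 0.05, rng.choice(list("ACGT"), 60), base)
            recs.append(SequenceRecord(f"A{i}", "X y", "".join(s)))
        msa = be.progressive_msa(recs)
        assert all("-" not in s for _, s in msa)
        assert [s for _, s in msa] == [r.seq for r in recs]

    def test_rows_degap_to_inputs_and_planted_deletion_is_one_gap_run(self):
        rng = np.random.default_rng(7)
        anc = "".join(rng.choice(list("ACGT"), 90))
        recs = []
        for i in range(6):
            s = list(anc)
            for pos in rng.choice(90, size=2, replace=False):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            s = "".join(s)
            if i < 2:  # carriers of a 3 nt deletion at a fixed ancestral position
                s = s[:40] + s[43:]
            recs.append(SequenceRecord(f"A{i}", "X y", s))
        msa = be.progressive_msa(recs)
        for (_, g), r in zip(msa, recs):
            assert g.replace("-", "") == r.seq
        for (_, g), r in zip(msa, recs):
            if len(r.seq) == 87:
                assert "---" in g and g.count("-") == 3
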