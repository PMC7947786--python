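"""Guide trees, progressive alignment, weights and conservation grading."""

import random

import numpy as np
import pytest
from skbio import DistanceMatrix

from divcons.alignment_conservation import (
    ConservationProfile,
    FamilyAlignment,
    align_family,
    background_vector,
    column_conservation,
    conservation_profile,
    grade_conservation,
    henikoff_weights,
    jensen_shannon,
    kmer_distance_matrix,
    neighbor_joining,
    progressive_align,
    read_alignment,
    write_alignment,
)
from divcons.sequence_families import DivconsError, SequenceRecord
from divcons.synthetic_data import SimulationConfig, simulate_families

from oracles import jsd_direct, nw_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestKmerDistance:
    def test_extremes(self):
        a = SequenceRecord("a", "MKVLAWG")
        b = SequenceRecord("b", "MKVLAWG")
        c = SequenceRecord("c", "PPPPPPP")
        dm = kmer_distance_matrix([a, b, c], k=3)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_matches_set_intersection_oracle(self):
        rng = random.Random(3)
        k = 3
        for _ in range(50):
            s1 = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
            s2 = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
            dm = kmer_distance_matrix(
                [SequenceRecord("x", s1), SequenceRecord("y", s2)], k=k
            )
            k1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
            k2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
            expected = 1.0 - len(k1 & k2) / min(len(k1), len(k2))
            assert dm["x", "y"] == pytest.approx(expected)

    def test_short_sequence_raises_with_id(self):
        with pytest.raises(DivconsError, match="'tiny'"):
            kmer_distance_matrix([SequenceRecord("tiny", "MK")], k=5)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_topology(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        dist = DistanceMatrix(
            np.array(
                [
                    [0, 3, 5, 6],
                    [3, 0, 6, 7],
                    [5, 6, 0, 7],
                    [6, 7, 7, 0],
                ],
                dtype=float,
            ),
            ids=list("abcd"),
        )
        tree = neighbor_joining(dist)
        # the recovered unrooted topology must contain the ab|cd split
        # (Robinson-Foulds distance 0 to the generating tree)
        splits = set()
        leaves = frozenset("abcd")
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if min(len(side), len(leaves - side)) >= 2:  # non-trivial splits only
                splits.add(min(side, leaves - side, key=len))
        assert splits <= {frozenset("ab"), frozenset("cd")}
        assert splits & {frozenset("ab"), frozenset("cd")}

    def test_closest_pair_joined_first_in_three_taxon_case(self):
        dist = DistanceMatrix(
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float), ids=list("abc")
        )
        tree = neighbor_joining(dist)
        assert {t.name for t in tree.lca(["a", "b"]).tips()} == {"a", "b"}

    def test_topology_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(0)
        n = 8
        base = rng.uniform(1, 10, size=(n, n))
        dist = (base + base.T) / 2
        np.fill_diagonal(dist, 0.0)
        ids = [f"t{i}" for i in range(n)]
        reference = neighbor_joining(DistanceMatrix(dist, ids=ids))
        for _ in range(10):
            perm = rng.permutation(n)
            dm = DistanceMatrix(dist[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
            shuffled = neighbor_joining(dm)
            assert reference.compare_rfd(shuffled) == 0.0

    def test_two_taxon_star(self):
        dist = DistanceMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), ids=["a", "b"])
        tree = neighbor_joining(dist)
        assert {t.name for t in tree.tips()} == {"a", "b"}
        assert all(t.length == pytest.approx(2.0) for t in tree.tips())

    def test_branch_lengths_clamped_nonnegative(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.1, 1.0, size=(6, 6))
        dist = (base + base.T) / 2
        np.fill_diagonal(dist, 0.0)
        tree = neighbor_joining(DistanceMatrix(dist, ids=[f"x{i}" for i in range(6)]))
        assert all(node.length >= 0 for node in tree.traverse() if node.length is not None)


class TestProgressiveAlign:
    def test_identical_pair_aligns_gap_free(self):
        records = [SequenceRecord("a", "MKVLAWGHEE"), SequenceRecord("b", "MKVLAWGHEE")]
        aln = align_family(records)
        assert aln.n_columns == 10
        assert all("-" not in seq for _, seq in aln.rows)

    def test_single_indel_pair_matches_global_oracle(self, matrix_scorer):
        records = [SequenceRecord("a", "MKVLA"), SequenceRecord("b", "MKLA")]
        aln = align_family(records)
        assert aln.n_columns == 5
        assert aln.ungapped("a") == "MKVLA"
        assert aln.ungapped("b") == "MKLA"
        # score of the produced alignment equals the optimal global DP score
        row_a, row_b = aln.row("a"), aln.row("b")
        produced = 0.0
        state = None
        for x, y in zip(row_a, row_b):
            if x == "-" or y == "-":
                gap = "a" if x == "-" else "b"
                produced -= 11 if state != gap else 1
                state = gap
            else:
                produced += matrix_scorer(x, y)
                state = None
        assert produced == pytest.approx(nw_score("MKVLA", "MKLA", matrix_scorer, 11, 1))

    def test_indel_free_family_aligns_without_gaps(self):
        for seed in (2, 4, 6):
            bundle = simulate_families(SimulationConfig(seed=seed, n_sequences=30))
            aln = align_family(bundle.records_a, reference_id=bundle.reference_a)
            assert aln.n_columns == bundle.config.length
            for record in bundle.records_a:
                assert aln.ungapped(record.id) == record.residues

    def test_mismatched_leaf_set_raises(self):
        records = [SequenceRecord("a", "MKVLA"), SequenceRecord("b", "MKLA")]
        tree = neighbor_joining(
            DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "z"])
        )
        with pytest.raises(DivconsError, match="differ"):
            progressive_align(records, tree)


class TestAlignmentIO:
    def test_roundtrip_identity(self, tmp_path):
        rows = [("a", "MKV-LA"), ("b", "MKVQLA"), ("c", "M--QLA")]
        aln = FamilyAlignment(rows=rows, reference_id="a", weights=np.full(3, 1 / 3))
        path = tmp_path / "aln.fasta"
        write_alignment(aln, path)
        back = read_alignment(path, reference_id="a")
        assert back.rows == rows
        assert back.n_columns == 6

    def test_ragged_rows_rejected_with_ids(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nMKVLAWGHEE\n>b\nMKVLAWGHE\n")
        with pytest.raises(DivconsError, match="a:10, b:9"):
            read_alignment(path)


class TestHenikoffWeights:
    def test_identical_rows_weighted_equally(self):
        aln = FamilyAlignment(
            rows=[("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")],
            reference_id="a",
            weights=np.full(3, 1 / 3),
        )
        assert henikoff_weights(aln) == pytest.approx([1 / 3] * 3)

    def test_minority_row_gets_largest_weight(self):
        # hand-computed: each column has symbols {A:2, C:1}, r=2 types, so
        # each A row collects 4 * 1/(2*2) = 1 and the C row 4 * 1/(2*1) = 2;
        # normalised weights (0.25, 0.25, 0.5)
        aln = FamilyAlignment(
            rows=[("a", "AAAA"), ("b", "AAAA"), ("c", "CCCC")],
            reference_id="a",
            weights=np.full(3, 1 / 3),
        )
        assert henikoff_weights(aln) == pytest.approx([0.25, 0.25, 0.5])

    def test_invariant_under_row_reordering(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"s{i}", "".join(rng.choice(list(AA), size=12))) for i in range(6)
        ]
        aln = FamilyAlignment(rows=rows, reference_id="s0", weights=np.full(6, 1 / 6))
        weights = dict(zip(aln.ids, henikoff_weights(aln)))
        shuffled_rows = rows[::-1]
        aln2 = FamilyAlignment(
            rows=shuffled_rows, reference_id="s0", weights=np.full(6, 1 / 6)
        )
        weights2 = dict(zip(aln2.ids, henikoff_weights(aln2)))
        for key in weights:
            assert weights[key] == pytest.approx(weights2[key])
        assert sum(weights.values()) == pytest.approx(1.0)


def _single_column_alignment(letters: list[str]) -> FamilyAlignment:
    rows = [(f"s{i}", ch) for i, ch in enumerate(letters)]
    return FamilyAlignment(
        rows=rows, reference_id="s0", weights=np.full(len(rows), 1 / len(rows))
    )


class TestColumnConservation:
    def test_point_mass_column_scores_one_under_uniform_background(self):
        for letter in ("W", "A", "L"):
            profile = column_conservation(
                _single_column_alignment([letter] * 5), background="uniform"
            )
            assert profile.scores[0] == pytest.approx(1.0, abs=1e-9)
            assert profile.consensus[0] == letter

    def test_background_matching_column_scores_zero(self):
        profile = column_conservation(
            _single_column_alignment(list(AA)), background="uniform"
        )
        assert profile.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_scores_zero_with_dash_consensus(self):
        aln = FamilyAlignment(
            rows=[("a", "-K"), ("b", "-K")], reference_id="a", weights=np.array([0.5, 0.5])
        )
        profile = column_conservation(aln, background="uniform")
        assert profile.scores[0] == 0.0
        assert profile.consensus[0] == "-"
        assert profile.gap_fractions[0] == 1.0

    def test_background_validation(self):
        aln = _single_column_alignment(["A", "A"])
        bad = np.zeros(20)
        bad[0] = 1.0
        with pytest.raises(DivconsError, match="positive"):
            column_conservation(aln, background=bad)

    def test_scores_match_direct_jsd_oracle_on_random_columns(self, bundle):
        rng = np.random.default_rng(9)
        aln = align_family(bundle.records_b, reference_id=bundle.reference_b)
        profile = column_conservation(aln, background="uniform")
        uniform = [1 / 20] * 20
        d_max = jsd_direct([1.0] + [0.0] * 19, uniform)
        aa_index = {ch: i for i, ch in enumerate(AA)}
        for col in rng.choice(profile.n_columns, size=100, replace=False):
            freq = [0.0] * 20
            for weight, (_, row) in zip(aln.weights, aln.rows):
                ch = row[col]
                if ch in aa_index:
                    freq[aa_index[ch]] += weight
            total = sum(freq)
            expected = (total) * jsd_direct([f / total for f in freq], uniform) / d_max
            assert profile.scores[col] == pytest.approx(expected, abs=1e-10)

    def test_score_monotone_under_concentration(self):
        # moving mass from a minority entry onto the majority entry
        # (majorization) never lowers the JSD against a uniform background
        rng = np.random.default_rng(4)
        uniform = np.full(20, 1 / 20)
        for _ in range(50):
            p = rng.dirichlet(np.ones(20))
            q = p.copy()
            lo, hi = int(np.argmin(q)), int(np.argmax(q))
            delta = q[lo] * rng.uniform(0, 1)
            q[lo] -= delta
            q[hi] += delta
            assert jensen_shannon(q, uniform) >= jensen_shannon(p, uniform) - 1e-12


def _profile_from_scores(scores, gap_fractions=None) -> ConservationProfile:
    n = len(scores)
    return ConservationProfile(
        reference_id="ref",
        scores=np.asarray(scores, dtype=float),
        gap_fractions=np.zeros(n) if gap_fractions is None else np.asarray(gap_fractions),
        consensus=["A"] * n,
        reference_positions=list(range(1, n + 1)),
    )


class TestGrading:
    def test_unique_invariant_column_tops_the_ranking(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.1, 0.8, size=50)
        scores[17] = 1.0
        graded = grade_conservation(_profile_from_scores(scores))
        assert graded.grades[17] == 9

    def test_uniform_scores_share_one_grade(self):
        graded = grade_conservation(_profile_from_scores([0.5] * 30))
        assert set(graded.grades) == {9}

    def test_equal_frequency_bins_balanced_for_tie_free_scores(self):
        rng = np.random.default_rng(8)
        n = 90
        scores = rng.permutation(np.linspace(0.01, 0.99, n))
        graded = grade_conservation(_profile_from_scores(scores))
        counts = np.bincount(graded.grades, minlength=10)[1:]
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == n

    def test_gappy_columns_pinned_to_grade_one(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        gaps = [0.0, 0.9, 0.0, 0.0]
        graded = grade_conservation(_profile_from_scores(scores, gaps))
        assert graded.grades[1] == 1

    def test_fewer_than_nine_columns_ranked_with_ties_sharing_high_grade(self):
        graded = grade_conservation(_profile_from_scores([0.9, 0.9, 0.1]))
        assert graded.grades[0] == graded.grades[1] == 9
        assert graded.grades[2] < 9

    def test_planted_constrained_sites_reach_maximal_grade(self):
        hits = total = 0
        for seed in range(8):
            bundle = simulate_families(SimulationConfig(seed=300 + seed))
            for records, reference, side in (
                (bundle.records_a, bundle.reference_a, "target_a"),
                (bundle.records_b, bundle.reference_b, "target_b"),
            ):
                aln = align_family(records, reference_id=reference)
                profile = conservation_profile(aln)
                for constraint in bundle.constraints:
                    if getattr(constraint, side) is None:
                        continue
                    pos = (
                        bundle.position_a_of_ancestral(constraint.site)
                        if side == "target_a"
                        else constraint.site
                    )
                    col = profile.column_of_reference_position(pos)
                    total += 1
                    hits += int(profile.grades[col] == 9)
        assert hits / total >= 0.9
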