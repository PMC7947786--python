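"""Mutation units, the edit engine, libraries and reversion series."""

import random

import pytest

from divcons.differential_analysis import (
    PositionClassRecord,
    load_library_memberships,
    load_position_table,
)
from divcons.mutant_design import (
    MutantDefinition,
    MutationUnit,
    Segment,
    apply_mutations,
    dop_anchor_letters,
    enumerate_library,
    invert_definition,
    reciprocal_units,
    reversion_series,
    synthetic_base_sequence,
    units_from_position_table,
    write_mutants,
)
from divcons.sequence_families import DivconsError, SequenceRecord, read_fasta

from oracles import apply_units_left_to_right

AA = "ACDEFGHIKLMNPQRSTVWY"


def _matched_record(pos, base_letter, counterpart, selected=True):
    return PositionClassRecord(
        column_a=pos - 1,
        column_b=pos - 1,
        ref_residue_a=(pos, base_letter),
        ref_residue_b=(pos, counterpart),
        grade_a=9,
        grade_b=2,
        consensus_a=base_letter,
        consensus_b=counterpart,
        position_class="unique_A",
        selected=selected,
    )


class TestReciprocalUnits:
    def test_substitution_named_by_convention(self):
        base = SequenceRecord("base", "MKVLAWGHEEMKVLAWGHEEMKVLAWS")
        records = [_matched_record(27, "S", "A")]
        units = reciprocal_units(records, base)
        assert [u.name for u in units] == ["S27A"]
        assert units[0].kind == "substitution"

    def test_noop_mutation_rejected(self):
        base = SequenceRecord("base", "MKVLA")
        with pytest.raises(DivconsError, match="not a candidate"):
            reciprocal_units([_matched_record(3, "V", "V")], base)

    def test_coordinate_drift_guard(self):
        base = SequenceRecord("base", "MKVLA")
        with pytest.raises(DivconsError, match="drift"):
            reciprocal_units([_matched_record(3, "W", "A")], base)


class TestApplyMutations:
    def test_single_substitution(self):
        base = SequenceRecord("base", "MKVLA")
        mutant = MutantDefinition(
            name="m",
            base_id="base",
            units=(
                MutationUnit(name="V3F", kind="substitution", start=3, end=3,
                             replacement="F", expected="V"),
            ),
        )
        assert apply_mutations(base, mutant).residues == "MKFLA"

    def test_loop_deletion_removes_37_residues(self):
        table = load_position_table()
        base = synthetic_base_sequence(dop_anchor_letters(table), length=475, seed=0)
        deletion = units_from_position_table(table)["dop_loop_deletion"]
        mutant = MutantDefinition(name="del", base_id=base.id, units=(deletion,))
        assert len(base) - len(apply_mutations(base, mutant)) == 37

    def test_overlap_and_bounds_errors(self):
        base = SequenceRecord("base", "MKVLA")
        u1 = MutationUnit(name="del2-4", kind="deletion", start=2, end=4)
        u2 = MutationUnit(name="V3F", kind="substitution", start=3, end=3,
                          replacement="F", expected="V")
        with pytest.raises(DivconsError, match="overlap"):
            MutantDefinition(name="m", base_id="base", units=(u1, u2))
        far = MutationUnit(name="A9S", kind="substitution", start=9, end=9,
                           replacement="S", expected="A")
        with pytest.raises(DivconsError, match="out of bounds"):
            apply_mutations(base, MutantDefinition(name="m", base_id="base", units=(far,)))

    @staticmethod
    def _random_units(rng, base):
        """Random disjoint unit set over a base sequence."""
        n = len(base)
        positions = sorted(rng.sample(range(1, n - 4), rng.randint(1, 6)))
        units = []
        previous_end = 0
        for pos in positions:
            if pos <= previous_end:
                continue
            kind = rng.choice(["substitution", "insertion", "deletion", "segment_swap"])
            if kind == "substitution":
                new = rng.choice([c for c in AA if c != base[pos - 1]])
                units.append(MutationUnit(name=f"{base[pos-1]}{pos}{new}", kind=kind,
                                          start=pos, end=pos, replacement=new,
                                          expected=base[pos - 1]))
                previous_end = pos
            elif kind == "insertion":
                ins = "".join(rng.choice(AA) for _ in range(rng.randint(1, 4)))
                units.append(MutationUnit(name=f"ins{pos}{ins}", kind=kind,
                                          start=pos, end=pos, replacement=ins))
                previous_end = pos
            else:
                end = min(pos + rng.randint(0, 3), n)
                replacement = (
                    "" if kind == "deletion"
                    else "".join(rng.choice(AA) for _ in range(rng.randint(1, 5)))
                )
                units.append(MutationUnit(name=f"{kind}{pos}-{end}", kind=kind,
                                          start=pos, end=end, replacement=replacement,
                                          expected=base[pos - 1 : end]))
                previous_end = end
        return tuple(units)

    def test_apply_then_invert_restores_base(self):
        rng = random.Random(17)
        for _ in range(100):
            base_seq = "".join(rng.choice(AA) for _ in range(rng.randint(20, 60)))
            base = SequenceRecord("base", base_seq)
            units = self._random_units(rng, base_seq)
            mutant = MutantDefinition(name="m", base_id="base", units=units)
            mutated = apply_mutations(base, mutant)
            inverse = invert_definition(mutant, base)
            restored = apply_mutations(mutated, inverse)
            assert restored.residues == base_seq

    def test_descending_application_matches_left_to_right_oracle(self):
        rng = random.Random(29)
        for _ in range(50):
            base_seq = "".join(rng.choice(AA) for _ in range(rng.randint(20, 60)))
            base = SequenceRecord("base", base_seq)
            units = self._random_units(rng, base_seq)
            mutant = MutantDefinition(name="m", base_id="base", units=units)
            assert apply_mutations(base, mutant).residues == apply_units_left_to_right(
                base_seq, units
            )


class TestLibrary:
    @staticmethod
    def _segments(k):
        return [
            Segment(
                label=f"seg{i}",
                units=(
                    MutationUnit(name=f"A{10 * (i + 1)}S", kind="substitution",
                                 start=10 * (i + 1), end=10 * (i + 1),
                                 replacement="S", expected="A"),
                ),
            )
            for i in range(k)
        ]

    @pytest.mark.parametrize("k", range(0, 13))
    def test_library_size_is_two_to_the_k(self, k):
        assert len(enumerate_library(self._segments(k))) == 2**k

    def test_backbone_and_full_variant_present(self):
        library = enumerate_library(self._segments(3))
        assert library[0].units == ()
        assert len(library[-1].units) == 3

    def test_members_are_pairwise_distinct_sequences(self):
        base = SequenceRecord("base", "A" * 70)
        library = enumerate_library(self._segments(5))
        sequences = {apply_mutations(base, d).residues for d in library}
        assert len(sequences) == 32

    def test_segment_guard(self):
        with pytest.raises(DivconsError, match="too large"):
            enumerate_library(self._segments(21))


class TestReversionSeries:
    def test_each_reversion_drops_exactly_one_unit(self):
        segments = TestLibrary._segments(3)
        full = MutantDefinition(
            name="full", base_id="base", units=tuple(u for s in segments for u in s.units)
        )
        series = reversion_series(full)
        assert len(series) == 3
        for member in series:
            assert len(member.units) == 2
            assert set(member.units) < set(full.units)

    def test_grouped_units_revert_together(self):
        table = load_position_table()
        info = units_from_position_table(table)
        full = MutantDefinition(name="full", base_id="dop", units=info["all_units"])
        series = reversion_series(full)
        # 9 alpha-loop + 7 supporting groups (the 4-unit block counts once)
        # + 1 loop deletion = 17 single reversions... plus segment blocks:
        groups = {u.group for u in info["all_units"]}
        assert len(series) == len(groups) == 18
        block = [m for m in series if "segment3" in m.name]
        assert len(block) == 1
        assert len(full.units) - len(block[0].units) == 4


class TestPublishedLibrary:
    def test_segment_units_match_published_naming(self):
        info = units_from_position_table(load_position_table())
        by_label = {s.label: [u.name for u in s.units] for s in info["segments"]}
        assert by_label == {
            "segment1": ["S27A", "V31F"],
            "segment2": ["I85F"],
            "segment3": ["V94L", "ins95V", "H96G", "A97S"],
            "segment4": ["S102A", "A103T", "P104A"],
            "segment5": ["S450D"],
        }
        assert [u.name for u in info["alpha_units"]] == [
            "Y209H", "E211W", "V212E", "E213G", "G215S", "L216S", "E217A", "L220R", "K221S",
        ]

    def test_reciprocal_position_count_is_twenty(self):
        info = units_from_position_table(load_position_table())
        assert len(info["all_units"]) - 1 == 20  # all edits minus the loop deletion

    def test_published_32_member_combinations_reproduced(self):
        info = units_from_position_table(load_position_table())
        ours = {
            tuple((mask >> i) & 1 for i in range(5))
            for mask in range(2 ** len(info["segments"]))
        }
        memberships = load_library_memberships()
        published = {
            tuple(int(row[f"segment{i}"]) for i in range(1, 6))
            for _, row in memberships.iterrows()
        }
        assert len(memberships) == 32
        assert ours == published

    def test_supporting_positions_span_2048_combinations(self):
        info = units_from_position_table(load_position_table())
        singletons = [
            Segment(label=u.name, units=(u,)) for s in info["segments"] for u in s.units
        ]
        assert len(singletons) == 11
        assert len(enumerate_library(singletons)) == 2048


class TestWriteMutants:
    def test_library_fasta_roundtrip(self, tmp_path):
        table = load_position_table()
        info = units_from_position_table(table)
        base = synthetic_base_sequence(dop_anchor_letters(table), length=475, seed=0)
        library = enumerate_library(
            info["segments"], base_id=base.id, always_on=tuple(info["alpha_units"])
        )
        path = tmp_path / "library.fasta"
        written = write_mutants(library, base, path)
        back = read_fasta(path)
        assert len(back) == 32
        assert [r.residues for r in back] == [r.residues for r in written]
        # backbone member: only the always-on alpha substitutions applied
        backbone = back[0].residues
        expected = apply_mutations(
            base, MutantDefinition(name="bb", base_id=base.id,
                                   units=tuple(info["alpha_units"]))
        ).residues
        assert backbone == expected
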