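"""Mutant construction: reciprocal substitutions, indel units, combinatorial
segment libraries and single-reversion series.

Conventions
-----------
* Anchors are 1-based positions on the wild-type (base) sequence.
* Insertions are placed AFTER the anchor position; deletions and segment
  swaps cover inclusive ranges.
* Units within a mutant are disjoint in base coordinates and are applied in
  canonical descending-coordinate order, so earlier anchors never shift.
* Unit names follow the field's ``X<pos>Y`` convention (``S27A``), with
  ``del<start>-<end>`` and ``ins<pos><seq>`` for indels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_conservation import background_vector
from .sequence_families import AMINO_ACIDS, DivconsError, SequenceRecord, write_fasta

MAX_SEGMENTS = 20  # 2^20 library members is already beyond any bench use

KINDS = ("substitution", "insertion", "deletion", "segment_swap")


@dataclass(frozen=True)
class MutationUnit:
    """One atomic edit of the base sequence.

    ``expected`` is the base-sequence content at the anchor (a drift guard:
    application fails loudly if the base does not carry it).  ``group`` ties
    units that must revert together; it defaults to the unit name.
    """

    name: str
    kind: str
    start: int
    end: int
    replacement: str = ""
    expected: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DivconsError(f"unknown mutation kind {self.kind!r}")
        min_start = 0 if self.kind == "insertion" else 1  # anchor 0: insert at front
        if self.start < min_start or self.end < self.start:
            raise DivconsError(f"unit {self.name!r}: invalid anchor range {self.start}-{self.end}")
        if self.kind == "substitution":
            if self.start != self.end or len(self.replacement) != 1:
                raise DivconsError(f"substitution {self.name!r} must replace a single residue")
            if self.expected and self.replacement == self.expected:
                raise DivconsError(f"unit {self.name!r} is a no-op (not a candidate)")
        if self.kind == "deletion" and self.replacement:
            raise DivconsError(f"deletion {self.name!r} must have an empty replacement")
        if self.kind == "insertion":
            if self.start != self.end:
                raise DivconsError(f"insertion {self.name!r} takes a single anchor")
            if not self.replacement:
                raise DivconsError(f"insertion {self.name!r} must insert at least one residue")
        if not self.group:
            object.__setattr__(self, "group", self.name)

    @property
    def span(self) -> tuple[float, float]:
        """Occupied interval in base coordinates; insertions occupy the gap
        after their anchor."""
        if self.kind == "insertion":
            return (self.start + 0.5, self.start + 0.5)
        return (float(self.start), float(self.end))

    @property
    def length_change(self) -> int:
        if self.kind == "insertion":
            return len(self.replacement)
        if self.kind == "deletion":
            return -(self.end - self.start + 1)
        if self.kind == "segment_swap":
            return len(self.replacement) - (self.end - self.start + 1)
        return 0


@dataclass(frozen=True)
class Segment:
    """A named group of mutation units toggled together in a library."""

    label: str
    units: tuple[MutationUnit, ...]

    def __post_init__(self) -> None:
        if not self.units:
            raise DivconsError(f"segment {self.label!r} has no units")
        _check_disjoint(self.units)


@dataclass(frozen=True)
class MutantDefinition:
    """An ordered, disjoint set of units applied to one base sequence."""

    name: str
    base_id: str
    units: tuple[MutationUnit, ...]

    def __post_init__(self) -> None:
        _check_disjoint(self.units)


def _check_disjoint(units: Sequence[MutationUnit]) -> None:
    spans = sorted((u.span, u.name) for u in units)
    for ((_, end1), name1), ((start2, _), name2) in zip(spans, spans[1:]):
        if start2 <= end1:
            raise DivconsError(f"units {name1!r} and {name2!r} overlap in base coordinates")


# ---------------------------------------------------------------------------
# Reciprocal units from classification records
# ---------------------------------------------------------------------------


def reciprocal_units(selected_records, base: SequenceRecord) -> list[MutationUnit]:
    """Turn selected position records into family-A -> family-B edits.

    Matched records become substitutions of the base (family A) residue by
    the family-B consensus; runs of selected unmatched family-A columns
    become one deletion unit; runs of selected unmatched family-B columns
    become one insertion unit anchored after the nearest preceding matched
    family-A residue.
    """
    units: list[MutationUnit] = []
    matched = [r for r in selected_records if r.column_a is not None and r.column_b is not None]
    for rec in matched:
        if not rec.selected:
            continue
        pos, base_letter = rec.ref_residue_a
        target = rec.consensus_b
        if pos > len(base.residues):
            raise DivconsError(f"anchor {pos} beyond base sequence length {len(base.residues)}")
        if base.residues[pos - 1] != base_letter:
            raise DivconsError(
                f"coordinate drift: base has {base.residues[pos - 1]!r} at {pos}, "
                f"record expects {base_letter!r}"
            )
        if target == base_letter:
            raise DivconsError(f"position {pos} is not a candidate: both residues are {target!r}")
        units.append(
            MutationUnit(
                name=f"{base_letter}{pos}{target}",
                kind="substitution",
                start=pos,
                end=pos,
                replacement=target,
                expected=base_letter,
            )
        )
    # Family-A-only runs -> deletions
    del_positions = sorted(
        rec.ref_residue_a[0]
        for rec in selected_records
        if rec.selected and rec.column_b is None and rec.ref_residue_a is not None
    )
    for run_start, run_end in _runs(del_positions):
        units.append(
            MutationUnit(
                name=f"del{run_start}-{run_end}",
                kind="deletion",
                start=run_start,
                end=run_end,
                expected=base.residues[run_start - 1 : run_end],
            )
        )
    # Family-B-only runs -> insertions, anchored on the closest preceding
    # matched family-A residue.
    ins_records = sorted(
        (r for r in selected_records if r.selected and r.column_a is None and r.ref_residue_b),
        key=lambda r: r.column_b,
    )
    if ins_records:
        anchors = sorted(
            (r.column_b, r.ref_residue_a[0])
            for r in matched
            if r.ref_residue_a is not None
        )
        for rec in ins_records:
            preceding = [pos for col_b, pos in anchors if col_b < rec.column_b]
            if not preceding:
                raise DivconsError(
                    f"no matched family-A residue precedes inserted column {rec.column_b}"
                )
            anchor = max(preceding)
            units.append(
                MutationUnit(
                    name=f"ins{anchor}{rec.consensus_b}",
                    kind="insertion",
                    start=anchor,
                    end=anchor,
                    replacement=rec.consensus_b,
                )
            )
    return sorted(units, key=lambda u: u.span)


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    if not positions:
        return []
    runs = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        runs.append((start, prev))
        start = prev = p
    runs.append((start, prev))
    return runs


# ---------------------------------------------------------------------------
# Edit engine
# ---------------------------------------------------------------------------


def apply_mutations(base: SequenceRecord, mutant: MutantDefinition) -> SequenceRecord:
    """Apply a mutant definition to its base sequence.

    Units are applied in descending base-coordinate order so earlier anchors
    stay valid.  The drift guard rejects any unit whose ``expected`` content
    disagrees with the base sequence.
    """
    seq = base.residues
    for unit in mutant.units:
        if unit.end > len(seq) + (1 if unit.kind == "insertion" else 0):
            raise DivconsError(f"unit {unit.name!r} is out of bounds for base of length {len(seq)}")
    for unit in sorted(mutant.units, key=lambda u: u.span, reverse=True):
        if unit.kind == "insertion":
            seq = seq[: unit.start] + unit.replacement + seq[unit.start :]
            continue
        found = seq[unit.start - 1 : unit.end]
        if unit.expected and found != unit.expected:
            raise DivconsError(
                f"coordinate drift applying {unit.name!r}: base carries {found!r} "
                f"at {unit.start}-{unit.end}, expected {unit.expected!r}"
            )
        seq = seq[: unit.start - 1] + unit.replacement + seq[unit.end :]
    return SequenceRecord(
        id=mutant.name,
        residues=seq,
        description=f"{mutant.name} base={base.id} units={','.join(u.name for u in mutant.units) or 'none'}",
    )


def invert_definition(mutant: MutantDefinition, base: SequenceRecord) -> MutantDefinition:
    """Build the inverse mutant (applies to the mutated sequence, restores the
    base): replacements and expectations swap and anchors are re-computed
    through the cumulative length changes of preceding units."""
    inverse_units: list[MutationUnit] = []
    offset = 0
    for unit in sorted(mutant.units, key=lambda u: u.span):
        if unit.kind == "substitution":
            expected = unit.expected or base.residues[unit.start - 1]
            inverse_units.append(
                MutationUnit(
                    name=f"{unit.replacement}{unit.start + offset}{expected}",
                    kind="substitution",
                    start=unit.start + offset,
                    end=unit.start + offset,
                    replacement=expected,
                    expected=unit.replacement,
                )
            )
        elif unit.kind == "deletion":
            deleted = base.residues[unit.start - 1 : unit.end]
            anchor = unit.start - 1 + offset  # 0 means re-insert at the front
            inverse_units.append(
                MutationUnit(
                    name=f"ins{anchor}{deleted}",
                    kind="insertion",
                    start=anchor,
                    end=anchor,
                    replacement=deleted,
                )
            )
        elif unit.kind == "insertion":
            start = unit.start + offset + 1
            inverse_units.append(
                MutationUnit(
                    name=f"del{start}-{start + len(unit.replacement) - 1}",
                    kind="deletion",
                    start=start,
                    end=start + len(unit.replacement) - 1,
                    expected=unit.replacement,
                )
            )
        else:  # segment_swap
            original = base.residues[unit.start - 1 : unit.end]
            start = unit.start + offset
            inverse_units.append(
                MutationUnit(
                    name=f"swap{start}-{start + len(unit.replacement) - 1}",
                    kind="segment_swap",
                    start=start,
                    end=start + len(unit.replacement) - 1,
                    replacement=original,
                    expected=unit.replacement,
                )
            )
        offset += unit.length_change
    # Adjacent deletions invert to insertions at one shared anchor; merge
    # them (in processing order) into a single insertion unit.
    merged: list[MutationUnit] = []
    for unit in inverse_units:
        if (
            merged
            and unit.kind == "insertion"
            and merged[-1].kind == "insertion"
            and merged[-1].start == unit.start
        ):
            previous = merged.pop()
            unit = MutationUnit(
                name=f"ins{unit.start}{previous.replacement + unit.replacement}",
                kind="insertion",
                start=unit.start,
                end=unit.end,
                replacement=previous.replacement + unit.replacement,
            )
        merged.append(unit)
    return MutantDefinition(
        name=f"revert({mutant.name})", base_id=mutant.name, units=tuple(merged)
    )


# ---------------------------------------------------------------------------
# Libraries and reversion series
# ---------------------------------------------------------------------------


def enumerate_library(
    segments: Sequence[Segment],
    base_id: str = "backbone",
    always_on: Sequence[MutationUnit] = (),
    name_prefix: str = "lib",
) -> list[MutantDefinition]:
    """All 2^k on/off combinations of k segments, in binary counting order.

    Bit *i* of the combination index toggles segment *i* (segment order as
    given); index 0 is the backbone (only ``always_on`` units applied) and
    index 2^k - 1 the fully-on variant.
    """
    if len(segments) > MAX_SEGMENTS:
        raise DivconsError(
            f"library too large: {len(segments)} segments imply 2^{len(segments)} members"
        )
    labels = [s.label for s in segments]
    if len(set(labels)) != len(labels):
        raise DivconsError("segment labels must be unique")
    _check_disjoint(tuple(always_on) + tuple(u for s in segments for u in s.units))
    definitions = []
    k = len(segments)
    for mask in range(2 ** k):
        units = list(always_on)
        on_labels = []
        for i, segment in enumerate(segments):
            if mask >> i & 1:
                units.extend(segment.units)
                on_labels.append(segment.label)
        definitions.append(
            MutantDefinition(
                name=f"{name_prefix}_{mask + 1:03d}" + (f"[{'+'.join(on_labels)}]" if on_labels else "[backbone]"),
                base_id=base_id,
                units=tuple(sorted(units, key=lambda u: u.span)),
            )
        )
    return definitions


def reversion_series(full_mutant: MutantDefinition) -> list[MutantDefinition]:
    """Single-reversion variants of a multi-unit mutant.

    One definition per unit group, each omitting exactly that group (units
    sharing a ``group`` label revert together).
    """
    if not full_mutant.units:
        raise DivconsError("full mutant has no units to revert")
    groups: list[str] = []
    for unit in full_mutant.units:
        if unit.group not in groups:
            groups.append(unit.group)
    series = []
    for group in groups:
        kept = tuple(u for u in full_mutant.units if u.group != group)
        series.append(
            MutantDefinition(
                name=f"{full_mutant.name}_rev_{group}",
                base_id=full_mutant.base_id,
                units=kept,
            )
        )
    return series


def write_mutants(
    definitions: Sequence[MutantDefinition],
    base: SequenceRecord,
    path: str | Path,
) -> list[SequenceRecord]:
    """Apply every definition and write one FASTA entry per mutant."""
    records = [apply_mutations(base, d) for d in definitions]
    write_fasta(records, path)
    return records


# ---------------------------------------------------------------------------
# The published Dop -> PafA mutant set (from the shipped position table)
# ---------------------------------------------------------------------------


def units_from_position_table(table: pd.DataFrame) -> dict:
    """Build mutation units from the shipped reciprocal-position table.

    Returns a dict with: ``alpha_units`` (the alpha-loop substitutions),
    ``segments`` (the five supporting-mutation segments of the combinatorial
    library), ``dop_loop_deletion`` and ``all_units`` (the full
    depupylase-to-ligase mutant, loop deletion included).  Positions flagged
    ``deletion_covered`` are carried by the loop deletion and never emitted
    as standalone substitutions.
    """
    alpha_units: list[MutationUnit] = []
    per_segment: dict[int, list[MutationUnit]] = {}
    deletion_unit: MutationUnit | None = None
    for _, row in table.iterrows():
        kind = row["kind"]
        if kind == "deletion_covered":
            continue
        if kind == "deletion":
            start = int(row["dop_msm_pos"])
            end = int(row["dop_ref_pos"])  # range endpoints live in the two columns
            deletion_unit = MutationUnit(
                name=f"del{start}-{end}", kind="deletion", start=start, end=end,
                group="dop_loop",
            )
            continue
        if kind == "insertion":
            anchor = int(row["dop_msm_pos"])
            unit = MutationUnit(
                name=f"ins{anchor}{row['pafa_msm_res']}",
                kind="insertion",
                start=anchor,
                end=anchor,
                replacement=row["pafa_msm_res"],
            )
        else:
            pos = int(row["dop_msm_pos"])
            unit = MutationUnit(
                name=f"{row['dop_msm_res']}{pos}{row['pafa_msm_res']}",
                kind="substitution",
                start=pos,
                end=pos,
                replacement=row["pafa_msm_res"],
                expected=row["dop_msm_res"],
            )
        if row["region"] == "alpha_loop":
            alpha_units.append(unit)
        else:
            seg = int(row["segment"])
            per_segment.setdefault(seg, []).append(unit)
    segments = [
        Segment(label=f"segment{idx}", units=tuple(units))
        for idx, units in sorted(per_segment.items())
    ]
    if deletion_unit is None:
        raise DivconsError("position table lacks the loop-deletion row")
    # In the reversion series the four segment-3 edits revert as one block.
    grouped_segments = []
    for seg in segments:
        if len(seg.units) > 1 and seg.label == "segment3":
            grouped = tuple(replace(u, group=seg.label) for u in seg.units)
            grouped_segments.append(Segment(label=seg.label, units=grouped))
        else:
            grouped_segments.append(seg)
    all_units = tuple(
        sorted(
            list(alpha_units)
            + [u for s in grouped_segments for u in s.units]
            + [deletion_unit],
            key=lambda u: u.span,
        )
    )
    return {
        "alpha_units": tuple(alpha_units),
        "segments": grouped_segments,
        "dop_loop_deletion": deletion_unit,
        "all_units": all_units,
    }


def synthetic_base_sequence(
    anchors: dict[int, str],
    length: int,
    seed: int = 0,
    record_id: str = "synthetic_base",
) -> SequenceRecord:
    """A synthetic stand-in base sequence: background-frequency residues with
    the given wild-type letters pinned at their anchor positions.

    Used wherever the real wild-type protein is not needed beyond carrying
    the anchored residues (count, length and naming computations).
    """
    rng = np.random.default_rng(seed)
    bg = background_vector("blosum62")
    letters = list(rng.choice(list(AMINO_ACIDS), size=length, p=bg))
    for pos, letter in anchors.items():
        if not 1 <= pos <= length:
            raise DivconsError(f"anchor {pos} outside synthetic base of length {length}")
        letters[pos - 1] = letter
    return SequenceRecord(
        id=record_id,
        residues="".join(letters),
        description=f"{record_id} synthetic stand-in base sequence",
    )


def dop_anchor_letters(table: pd.DataFrame) -> dict[int, str]:
    """Wild-type Dop residues at every anchored position of the table."""
    anchors: dict[int, str] = {}
    for _, row in table.iterrows():
        if row["kind"] == "deletion":
            anchors[int(row["dop_msm_pos"])] = row["dop_msm_res"]
            anchors[int(row["dop_ref_pos"])] = row["dop_ref_res"]
        elif row["kind"] == "insertion":
            continue
        else:
            anchors[int(row["dop_msm_pos"])] = row["dop_msm_res"]
    return anchors
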