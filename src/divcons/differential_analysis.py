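"""Differential-conservation classification and active-site distance filter.

Mapped column pairs are classified from the two families' conservation
grades (9 = maximal):

* ``shared_identical``     - grade 9 in both families, same consensus residue;
* ``differently_conserved`` - grade 9 in both, different consensus residues;
* ``unique_A`` / ``unique_B`` - grade 9 in one family while the other family's
  grade is below ``low_cutoff`` (or the column is unmatched on that side);
* ``indel``                - an unmatched column that is maximally conserved
  on its own side (family-specific insertions such as the Dop-loop);
* ``unconserved``          - everything else.

Candidate classes (unique/differently/indel) are then filtered by the
minimum CA-CA distance to a user-supplied active-site residue set: positions
farther than the threshold (default 20 A) are dropped, reflecting that
specificity-determining residues act at or near the catalytic site.

``low_cutoff`` defaults to 9, i.e. a uniquely conserved call requires the
position NOT to be maximally conserved (grade <= 8) in the other family.
Published reciprocal-mutagenesis sets for the Dop/PafA pair include
positions graded 7-8 on the non-conserved side, which this default mirrors;
stricter behaviour is available by lowering ``low_cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_conservation import ConservationProfile
from .sequence_families import DivconsError
from .structure_mapping import CrossFamilyMap, StructureModel

DEFAULT_LOW_CUTOFF = 9
DEFAULT_DISTANCE_THRESHOLD = 20.0  # Angstrom
MAX_GRADE = 9

CANDIDATE_CLASSES = ("unique_A", "unique_B", "differently_conserved", "indel")


@dataclass(frozen=True)
class ActiveSiteSpec:
    """Active-site residues, given as residue numbers on one structure."""

    side: str  # "A" or "B"
    residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.side not in ("A", "B"):
            raise DivconsError("active-site side must be 'A' or 'B'")
        if not self.residue_numbers:
            raise DivconsError("active-site residue list must be non-empty")

    def validate_against(self, model: StructureModel) -> None:
        present = {r.residue_number for r in model.residues}
        missing = [n for n in self.residue_numbers if n not in present]
        if missing:
            raise DivconsError(f"active-site residues absent from structure: {missing}")


@dataclass
class PositionClassRecord:
    """Classification of one mapped (or unmatched) alignment position."""

    column_a: int | None
    column_b: int | None
    ref_residue_a: tuple[int, str] | None
    ref_residue_b: tuple[int, str] | None
    grade_a: int | None
    grade_b: int | None
    consensus_a: str | None
    consensus_b: str | None
    position_class: str
    min_distance_to_active_site: float | None = None
    selected: bool = False


def _reference_residue(profile: ConservationProfile, column: int) -> tuple[int, str] | None:
    pos = profile.reference_positions[column]
    if pos is None:
        return None
    return (pos, profile.consensus[column])


def classify_positions(
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    mapping: CrossFamilyMap,
    low_cutoff: int = DEFAULT_LOW_CUTOFF,
) -> list[PositionClassRecord]:
    """Classify every mapped column pair and every unmatched column."""
    if profile_a.grades is None or profile_b.grades is None:
        raise DivconsError("profiles must be graded before classification")
    if not 1 <= low_cutoff <= MAX_GRADE:
        raise DivconsError(f"low_cutoff must be in 1..{MAX_GRADE}")
    records: list[PositionClassRecord] = []
    for col_a, col_b in mapping.matched:
        ga = int(profile_a.grades[col_a])
        gb = int(profile_b.grades[col_b])
        ca = profile_a.consensus[col_a]
        cb = profile_b.consensus[col_b]
        if ga == MAX_GRADE and gb == MAX_GRADE:
            cls = "shared_identical" if ca == cb else "differently_conserved"
        elif ga == MAX_GRADE and gb < low_cutoff:
            cls = "unique_A"
        elif gb == MAX_GRADE and ga < low_cutoff:
            cls = "unique_B"
        else:
            cls = "unconserved"
        records.append(
            PositionClassRecord(
                column_a=col_a,
                column_b=col_b,
                ref_residue_a=_reference_residue(profile_a, col_a),
                ref_residue_b=_reference_residue(profile_b, col_b),
                grade_a=ga,
                grade_b=gb,
                consensus_a=ca,
                consensus_b=cb,
                position_class=cls,
            )
        )
    # Unmatched (insertion-region) columns yield a record only when they are
    # maximally conserved on their own side: those are the indel candidates
    # (e.g. the Dop-loop); unconserved insertion columns carry no signal and
    # are reported in the cross-family map, not here.  Records therefore
    # number exactly: matched columns + indel records.
    for col_a in mapping.unmatched_a:
        ga = int(profile_a.grades[col_a])
        if ga != MAX_GRADE:
            continue
        records.append(
            PositionClassRecord(
                column_a=col_a,
                column_b=None,
                ref_residue_a=_reference_residue(profile_a, col_a),
                ref_residue_b=None,
                grade_a=ga,
                grade_b=None,
                consensus_a=profile_a.consensus[col_a],
                consensus_b=None,
                position_class="indel",
            )
        )
    for col_b in mapping.unmatched_b:
        gb = int(profile_b.grades[col_b])
        if gb != MAX_GRADE:
            continue
        records.append(
            PositionClassRecord(
                column_a=None,
                column_b=col_b,
                ref_residue_a=None,
                ref_residue_b=_reference_residue(profile_b, col_b),
                grade_a=None,
                grade_b=gb,
                consensus_a=None,
                consensus_b=profile_b.consensus[col_b],
                position_class="indel",
            )
        )
    return records


def distance_to_active_site(
    record: PositionClassRecord,
    structure: StructureModel,
    active_site: ActiveSiteSpec,
) -> float:
    """Minimum CA-CA distance from the record's reference residue on the
    active-site structure's side to any active-site residue."""
    active_site.validate_against(structure)
    ref = record.ref_residue_a if active_site.side == "A" else record.ref_residue_b
    if ref is None:
        raise DivconsError(
            "record has no reference residue on the active-site structure's side"
        )
    target = np.array(structure.residue_by_number(ref[0]).ca)
    best = np.inf
    for number in active_site.residue_numbers:
        site = np.array(structure.residue_by_number(number).ca)
        best = min(best, float(np.linalg.norm(target - site)))
    return best


def annotate_distances(
    records: Iterable[PositionClassRecord],
    structure: StructureModel,
    active_site: ActiveSiteSpec,
) -> None:
    """Fill ``min_distance_to_active_site`` for every record that has a
    reference residue on the active-site side (others keep None)."""
    active_site.validate_against(structure)
    for record in records:
        ref = record.ref_residue_a if active_site.side == "A" else record.ref_residue_b
        if ref is None:
            continue
        record.min_distance_to_active_site = distance_to_active_site(
            record, structure, active_site
        )


def select_candidates(
    records: Sequence[PositionClassRecord],
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> dict:
    """Flag candidate positions within the distance threshold as selected.

    A record is selected iff its class is a candidate class (unique in either
    family, differently conserved, or indel) AND its minimum distance to the
    active site is <= ``distance_threshold``.  ``inf`` disables the filter
    (records lacking a distance are then selected too).  Returns summary
    counts per class before/after filtering.
    """
    before: dict[str, int] = {}
    after: dict[str, int] = {}
    for record in records:
        cls = record.position_class
        before[cls] = before.get(cls, 0) + 1
        if cls not in CANDIDATE_CLASSES:
            record.selected = False
            continue
        dist = record.min_distance_to_active_site
        if dist is None:
            record.selected = bool(np.isinf(distance_threshold))
        else:
            record.selected = dist <= distance_threshold
        if record.selected:
            after[cls] = after.get(cls, 0) + 1
    n_candidates = sum(before.get(c, 0) for c in CANDIDATE_CLASSES)
    n_selected = sum(after.values())
    assert n_selected <= n_candidates <= len(records)
    return {
        "counts_before_filter": before,
        "counts_after_filter": after,
        "n_candidates": n_candidates,
        "n_selected": n_selected,
        "distance_threshold": distance_threshold,
    }


def candidate_report(
    records: Sequence[PositionClassRecord],
    name_a: str = "A",
    name_b: str = "B",
) -> pd.DataFrame:
    """Deterministic candidate table, sorted by family-A reference residue
    number (records without one sort after, by family-B residue number)."""

    def sort_key(rec: PositionClassRecord):
        ra = rec.ref_residue_a[0] if rec.ref_residue_a else None
        rb = rec.ref_residue_b[0] if rec.ref_residue_b else None
        return (ra is None, ra if ra is not None else 0, rb if rb is not None else 0)

    rows = []
    for rec in sorted(records, key=sort_key):
        rows.append(
            {
                f"column_{name_a}": rec.column_a,
                f"column_{name_b}": rec.column_b,
                f"residue_{name_a}": (
                    f"{rec.ref_residue_a[1]}{rec.ref_residue_a[0]}" if rec.ref_residue_a else ""
                ),
                f"residue_{name_b}": (
                    f"{rec.ref_residue_b[1]}{rec.ref_residue_b[0]}" if rec.ref_residue_b else ""
                ),
                f"grade_{name_a}": rec.grade_a,
                f"grade_{name_b}": rec.grade_b,
                f"consensus_{name_a}": rec.consensus_a or "",
                f"consensus_{name_b}": rec.consensus_b or "",
                "class": rec.position_class,
                "distance_to_active_site": rec.min_distance_to_active_site,
                "selected": rec.selected,
            }
        )
    columns = [
        f"column_{name_a}", f"column_{name_b}", f"residue_{name_a}", f"residue_{name_b}",
        f"grade_{name_a}", f"grade_{name_b}", f"consensus_{name_a}", f"consensus_{name_b}",
        "class", "distance_to_active_site", "selected",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Published Dop/PafA reciprocal-mutagenesis position table
# ---------------------------------------------------------------------------


def load_position_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the transcribed Dop/PafA reciprocal-mutagenesis position table.

    The default table ships with the package; it records, for each selected
    alignment position, the wild-type residues and conservation grades in
    both families, the mutation kind, and the combinatorial-library segment.
    """
    if path is None:
        source = resources.files("divcons.data") / "dop_pafa_positions.tsv"
        with resources.as_file(source) as p:
            return pd.read_csv(p, sep="\t", comment="#", dtype={"no": str, "segment": "Int64"})
    return pd.read_csv(path, sep="\t", comment="#", dtype={"no": str, "segment": "Int64"})


def load_library_memberships(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published 32-member combinatorial library segment memberships."""
    if path is None:
        source = resources.files("divcons.data") / "dop_library_memberships.tsv"
        with resources.as_file(source) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")
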