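"""Structure superposition and cross-family column mapping.

The two family alignments live in unrelated column coordinate systems.  The
bridge between them is built from the two reference structures: a seed
sequence alignment of the structures' residues is refined by iterating
{Kabsch superposition on the current residue pairs; colinear re-pairing on
the inter-CA distance matrix} until the pair set is stable.  The final
residue pairs are lifted to alignment columns through each family's
reference row, yielding a strictly colinear column<->column map whose
unmatched stretches are the family-specific insertions (e.g. the Dop-loop,
present in depupylases but absent from Pup-ligases).

Only CA atoms are used: the downstream analysis needs residue-level
correspondence and CA-CA distances, not full-atom detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

from .alignment_conservation import ConservationProfile
from .sequence_families import DivconsError, load_matrix

DEFAULT_CUTOFF = 5.0  # Angstrom, re-pairing distance cutoff
DEFAULT_MAX_ITER = 20

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    residue_number: int  # 1-based sequential index within the chain
    amino_acid: str
    ca: tuple[float, float, float]
    original_label: str = ""  # author residue number + insertion code


@dataclass
class StructureModel:
    """CA-only model of one chain; residue numbers strictly increasing."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        numbers = [r.residue_number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise DivconsError("residue numbers must be strictly increasing")
        for res in self.residues:
            if not all(np.isfinite(res.ca)):
                raise DivconsError(f"non-finite CA coordinate at residue {res.residue_number}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def residue_by_number(self, number: int) -> Residue:
        for res in self.residues:
            if res.residue_number == number:
                return res
        raise DivconsError(f"residue {number} not present in chain {self.chain_id!r}")


@dataclass
class Superposition:
    """Proper rigid transform (rotation then translation) mapping B onto A."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise DivconsError("rotation must be a proper (det=+1) 3x3 matrix")
        self.rotation = r
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CrossFamilyMap:
    """Colinear column<->column correspondence between two family alignments."""

    matched: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    provenance: str = "structural"

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.matched, self.matched[1:]):
            if a2 <= a1 or b2 <= b1:
                raise DivconsError("matched column pairs must be strictly increasing")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------


def read_structure(path: str | Path, chain: str) -> StructureModel:
    """Read the CA trace of one chain from a PDB-format file.

    Only the first MODEL is used; HETATM entries are ignored; for altloc
    duplicates the blank/'A' location is preferred.  Residues lacking a CA
    atom are omitted with a warning.  Insertion-coded residues are kept in
    file order and renumbered sequentially (the author label is preserved in
    ``original_label``).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = next(iter(structure))
    chains = [c.id for c in model]
    if chain not in chains:
        raise DivconsError(f"chain {chain!r} not in {path} (available: {chains})")
    residues: list[Residue] = []
    number = 0
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        if "CA" not in res:
            warnings.warn(
                f"residue {resseq}{icode.strip()} in chain {chain!r} has no CA atom; omitted"
            )
            continue
        atom = res["CA"]
        if atom.is_disordered():
            preferred = None
            for alt in atom.disordered_get_id_list():
                if alt in (" ", "A"):
                    preferred = alt
                    break
            atom = atom.disordered_get(preferred or atom.disordered_get_id_list()[0])
        aa = _THREE_TO_ONE.get(res.get_resname().upper(), "X")
        number += 1
        residues.append(
            Residue(
                residue_number=number,
                amino_acid=aa,
                ca=tuple(float(x) for x in atom.coord),
                original_label=f"{resseq}{icode.strip()}",
            )
        )
    if not residues:
        raise DivconsError(f"no CA atoms found for chain {chain!r} in {path}")
    return StructureModel(chain_id=chain, residues=residues)


def write_structure(model: StructureModel, path: str | Path, chain: str | None = None) -> None:
    """Write a CA-only PDB file (one ATOM record per residue)."""
    one_to_three = {v: k.upper() for k, v in protein_letters_3to1.items()}
    chain_id = (chain or model.chain_id or "A")[:1]
    with open(path, "w") as fh:
        for i, res in enumerate(model.residues, start=1):
            resname = one_to_three.get(res.amino_acid, "UNK")
            x, y, z = res.ca
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:<3s} {chain_id}{res.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rigid superposition of B onto A (Kabsch/SVD).

    Reflections are forbidden: if the optimal orthogonal transform would be
    improper, the smallest singular direction is flipped, so the returned
    rotation always has determinant +1.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DivconsError("coordinate arrays must both be n x 3")
    n = a.shape[0]
    if n < 3:
        raise DivconsError("at least 3 point pairs are required")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    if min(np.linalg.matrix_rank(aa, tol=1e-8), np.linalg.matrix_rank(bb, tol=1e-8)) < 2:
        raise DivconsError("rank-deficient point set (collinear); superposition is not unique")
    h = bb.T @ aa
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = cen_a - rotation @ cen_b
    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - a) ** 2).sum() / n))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd, pairs=[(i + 1, i + 1) for i in range(n)])


# ---------------------------------------------------------------------------
# Residue pairing
# ---------------------------------------------------------------------------


def seed_pairs(
    model_a: StructureModel,
    model_b: StructureModel,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> list[tuple[int, int]]:
    """Initial residue correspondence from a global sequence alignment of the
    two structures' amino-acid strings (aligned non-gap pairs)."""
    if not model_a.residues or not model_b.residues:
        raise DivconsError("both structures must be non-empty")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(model_a.sequence, model_b.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, _eb) in zip(aln.aligned[0], aln.aligned[1]):
        for offset in range(ea - sa):
            pairs.append(
                (
                    model_a.residues[sa + offset].residue_number,
                    model_b.residues[sb + offset].residue_number,
                )
            )
    return pairs


def _colinear_repair(dist: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Monotone (sequence-alignment-shaped) matching on a distance matrix.

    Dynamic programme maximising the number of matched pairs with distance
    <= cutoff, breaking ties by minimising the total matched distance.
    Returns 0-based index pairs, strictly increasing in both coordinates.
    """
    na, nb = dist.shape
    # Count dominates; the distance bonus per match is < 1/(total matches+1).
    bonus = (cutoff - np.minimum(dist, cutoff)) / (cutoff * (min(na, nb) + 1.0) + 1e-12)
    gain = np.where(dist <= cutoff, 1.0 + bonus, -np.inf)
    d = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        cand = np.maximum(d[i - 1, 1:], d[i - 1, :-1] + gain[i - 1])
        d[i, 1:] = np.maximum.accumulate(np.maximum(cand, d[i, 0]))
    pairs: list[tuple[int, int]] = []
    i, j = na, nb
    while i > 0 and j > 0:
        if d[i, j] == d[i - 1, j]:
            i -= 1
        elif d[i, j] == d[i, j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs


def iterative_structural_align(
    model_a: StructureModel,
    model_b: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    max_iter: int = DEFAULT_MAX_ITER,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> tuple[Superposition, list[tuple[int, int]]]:
    """Superpose two structures and derive a colinear residue correspondence.

    Starting from sequence-seeded pairs, alternate Kabsch superposition on
    the current pairs with colinear re-pairing of residues whose transformed
    CA-CA distance is within ``cutoff``, until the pair set is stable or
    ``max_iter`` is reached.  Deterministic: no randomness anywhere.
    """
    if cutoff <= 0:
        raise DivconsError("cutoff must be positive")
    num_a = {r.residue_number: i for i, r in enumerate(model_a.residues)}
    num_b = {r.residue_number: i for i, r in enumerate(model_b.residues)}
    pairs = seed_pairs(model_a, model_b, matrix, gap_open, gap_extend)
    coords_a = model_a.coords
    coords_b = model_b.coords
    superposition: Superposition | None = None
    for _ in range(max_iter):
        if len(pairs) < 3:
            raise DivconsError(
                f"fewer than 3 residue pairs survive at cutoff {cutoff} A; "
                "structures too divergent"
            )
        idx_a = [num_a[a] for a, _ in pairs]
        idx_b = [num_b[b] for _, b in pairs]
        superposition = kabsch(coords_a[idx_a], coords_b[idx_b])
        moved_b = superposition.apply(coords_b)
        dist = np.sqrt(((coords_a[:, None, :] - moved_b[None, :, :]) ** 2).sum(axis=2))
        new_idx_pairs = _colinear_repair(dist, cutoff)
        new_pairs = [
            (model_a.residues[i].residue_number, model_b.residues[j].residue_number)
            for i, j in new_idx_pairs
        ]
        if new_pairs == pairs:
            break
        pairs = new_pairs
    if len(pairs) < 3:
        raise DivconsError(
            f"fewer than 3 residue pairs survive at cutoff {cutoff} A; structures too divergent"
        )
    idx_a = [num_a[a] for a, _ in pairs]
    idx_b = [num_b[b] for _, b in pairs]
    superposition = kabsch(coords_a[idx_a], coords_b[idx_b])
    superposition.pairs = list(pairs)
    return superposition, pairs


# ---------------------------------------------------------------------------
# Lifting residue pairs to alignment columns
# ---------------------------------------------------------------------------


def _residue_to_column(
    model: StructureModel, profile: ConservationProfile
) -> dict[int, int]:
    """Map structure residue numbers (sequential, 1-based) to alignment
    columns via the reference row's ungapped positions."""
    position_to_column = {
        pos: col for col, pos in enumerate(profile.reference_positions) if pos is not None
    }
    mapping: dict[int, int] = {}
    for res in model.residues:
        if res.residue_number not in position_to_column:
            raise DivconsError(
                f"structure residue {res.residue_number} has no counterpart in the "
                f"reference row of {profile.reference_id!r} "
                f"(alignment covers {len(position_to_column)} positions)"
            )
        mapping[res.residue_number] = position_to_column[res.residue_number]
    return mapping


def lift_to_columns(
    pairs: Sequence[tuple[int, int]],
    model_a: StructureModel,
    model_b: StructureModel,
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    provenance: str = "structural",
) -> CrossFamilyMap:
    """Convert structural residue pairs to a column<->column map.

    Columns of either family alignment with no structural partner are listed
    as unmatched; these cover both reference-gap columns and genuine
    insertion regions.
    """
    col_a = _residue_to_column(model_a, profile_a)
    col_b = _residue_to_column(model_b, profile_b)
    matched = [(col_a[a], col_b[b]) for a, b in pairs]
    matched.sort()
    matched_a = {a for a, _ in matched}
    matched_b = {b for _, b in matched}
    unmatched_a = [c for c in range(profile_a.n_columns) if c not in matched_a]
    unmatched_b = [c for c in range(profile_b.n_columns) if c not in matched_b]
    return CrossFamilyMap(
        matched=matched, unmatched_a=unmatched_a, unmatched_b=unmatched_b, provenance=provenance
    )


def write_map(
    mapping: CrossFamilyMap,
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("column_a\tcolumn_b\tref_residue_a\tref_residue_b\n")
        for a, b in mapping.matched:
            ra = profile_a.reference_positions[a]
            rb = profile_b.reference_positions[b]
            fh.write(f"{a}\t{b}\t{'' if ra is None else ra}\t{'' if rb is None else rb}\n")
        for a in mapping.unmatched_a:
            ra = profile_a.reference_positions[a]
            fh.write(f"{a}\t\t{'' if ra is None else ra}\t\n")
        for b in mapping.unmatched_b:
            rb = profile_b.reference_positions[b]
            fh.write(f"\t{b}\t\t{'' if rb is None else rb}\n")


def write_superposition(superposition: Superposition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rmsd_angstrom\t{superposition.rmsd:.4f}\n")
        fh.write("residue_a\tresidue_b\n")
        for a, b in superposition.pairs:
            fh.write(f"{a}\t{b}\n")
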