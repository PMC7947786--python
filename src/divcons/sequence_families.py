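"""Sequence-similarity-network construction and family partitioning.

Paralogous enzyme families (here the motivating case: the Pup-ligase PafA
versus the depupylase Dop) are separated by building a sequence similarity
network (SSN): every pair of input sequences is scored with a Smith-Waterman
local alignment, scores are converted to bits, edges below a threshold are
dropped, and the connected components of the remaining graph are the family
clusters.  This mirrors the EFI-EST / Cytoscape workflow used for curated
family harvests, scaled to desk-sized inputs (hundreds of sequences).

Scoring conventions
-------------------
* Default matrix BLOSUM62 with affine gaps, ``gap_open=11``, ``gap_extend=1``.
  A gap of length *k* costs ``gap_open + (k - 1) * gap_extend``.
* ``X`` (unknown residue) scores 0 against everything.
* Raw Smith-Waterman scores are converted to bit scores with the standard
  Karlin-Altschul constants ``bits = (lambda * S - ln K) / ln 2``.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

#: Karlin-Altschul (lambda, K) for gapped protein searches, keyed by
#: (matrix, gap_open, gap_extend); values as distributed with BLAST+.
GAPPED_KA_CONSTANTS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", 10, 1): (0.243, 0.024),
    ("BLOSUM50", 13, 2): (0.232, 0.112),
}

#: Ungapped (lambda, K) fallbacks per matrix (used when the exact gapped
#: combination is not tabulated; bit scores then are conservative).
UNGAPPED_KA_CONSTANTS = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM50": (0.232, 0.112),
    "BLOSUM80": (0.343, 0.177),
    "PAM250": (0.229, 0.090),
}

#: Default cap on the number of pairwise alignments a single SSN build may
#: perform; all-vs-all scoring is O(n^2 L^2) and this artifact targets
#: desk-scale inputs.
DEFAULT_MAX_PAIRS = 500_000


class DivconsError(ValueError):
    """Base class for user-facing errors raised by this package."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One homolog protein sequence.

    ``residues`` is an upper-case string over the 20 amino-acid letters plus
    ``X`` (unknown), with no gap characters.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DivconsError("sequence id must be non-empty")
        if not self.residues:
            raise DivconsError(f"sequence {self.id!r} has no residues")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise DivconsError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairScore:
    """Smith-Waterman local alignment summary for one unordered pair."""

    id_a: str
    id_b: str
    score_raw: float
    score_bits: float
    percent_identity: float
    percent_similarity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.percent_similarity < self.percent_identity - 1e-9:
            raise DivconsError("percent_similarity cannot be below percent_identity")


@dataclass
class SimilarityNetwork:
    """Thresholded SSN: nodes are sequence ids, edge weights are bit scores."""

    graph: nx.Graph
    threshold: float

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["score_bits"]) for a, b, d in self.graph.edges(data=True)]


@dataclass(frozen=True)
class FamilyBundle:
    """A family cluster tied to its structure-bearing reference sequence."""

    members: frozenset[str]
    reference_id: str

    def __post_init__(self) -> None:
        if self.reference_id not in self.members:
            raise DivconsError(
                f"reference {self.reference_id!r} is not a member of the cluster "
                f"{sorted(self.members)}"
            )


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences from a FASTA file (plain or gzip).

    Residues are upper-cased and trailing ``*`` stop characters stripped.
    Raises on an empty file, duplicate ids, or non-amino-acid characters.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise DivconsError(f"duplicate sequence id {entry.id!r} in {path}")
            seen.add(entry.id)
            residues = str(entry.seq).upper().rstrip("*")
            records.append(
                SequenceRecord(id=entry.id, residues=residues, description=entry.description)
            )
    if not records:
        raise DivconsError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            handle.write(f">{header}\n")
            seq = rec.residues
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Pairwise scoring
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def load_matrix(name: str):
    """Load a substitution matrix restricted to the 20 AAs + neutral X."""
    try:
        full = substitution_matrices.load(name)
    except Exception as exc:  # Bio raises FileNotFoundError for unknown names
        raise DivconsError(f"unknown substitution matrix {name!r}") from exc
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            mat[a, b] = full[a, b]
    # X is a neutral unknown: scores 0 against everything (including itself).
    for a in ALPHABET:
        mat["X", a] = 0.0
        mat[a, "X"] = 0.0
    return mat


def karlin_altschul_constants(
    matrix: str, gap_open: float, gap_extend: float
) -> tuple[float, float]:
    key = (matrix, int(gap_open), int(gap_extend))
    if key in GAPPED_KA_CONSTANTS:
        return GAPPED_KA_CONSTANTS[key]
    if matrix in UNGAPPED_KA_CONSTANTS:
        return UNGAPPED_KA_CONSTANTS[matrix]
    raise DivconsError(f"no Karlin-Altschul constants available for matrix {matrix!r}")


def raw_to_bits(score: float, matrix: str, gap_open: float, gap_extend: float) -> float:
    lam, k = karlin_altschul_constants(matrix, gap_open, gap_extend)
    return (lam * score - math.log(k)) / math.log(2.0)


def _check_gap_params(gap_open: float, gap_extend: float) -> None:
    if gap_open < gap_extend:
        raise DivconsError(
            f"gap_open ({gap_open}) must be >= gap_extend ({gap_extend}); "
            "a cheaper opening than extension is nonsensical"
        )


@lru_cache(maxsize=16)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(matrix)
    # A gap of length k costs gap_open + (k - 1) * gap_extend.
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def local_score(
    a: str, b: str, matrix: str = "BLOSUM62", gap_open: float = 11, gap_extend: float = 1
) -> float:
    """Raw Smith-Waterman score only (no traceback; used for SSN builds)."""
    _check_gap_params(gap_open, gap_extend)
    return _aligner(matrix, float(gap_open), float(gap_extend), "local").score(a, b)


def pairwise_local_score(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> PairScore:
    """Smith-Waterman local alignment of two sequences with affine gaps.

    ``percent_identity`` is identical pairs over aligned columns (gap columns
    included); ``percent_similarity`` additionally counts residue pairs with a
    positive substitution score.
    """
    _check_gap_params(gap_open, gap_extend)
    aligner = _aligner(matrix, float(gap_open), float(gap_extend), "local")
    mat = load_matrix(matrix)
    alignments = aligner.align(a.residues, b.residues)
    aln = alignments[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n_cols = len(row_a)
    if n_cols == 0:
        return PairScore(a.id, b.id, aln.score, raw_to_bits(aln.score, matrix, gap_open, gap_extend), 0.0, 0.0, 0)
    ident = sim = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            sim += 1
        elif mat[ca, cb] > 0:
            sim += 1
    return PairScore(
        id_a=a.id,
        id_b=b.id,
        score_raw=aln.score,
        score_bits=raw_to_bits(aln.score, matrix, gap_open, gap_extend),
        percent_identity=100.0 * ident / n_cols,
        percent_similarity=100.0 * sim / n_cols,
        aligned_length=n_cols,
    )


# ---------------------------------------------------------------------------
# SSN construction and clustering
# ---------------------------------------------------------------------------


def build_ssn(
    records: Sequence[SequenceRecord],
    threshold: float,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
    max_pairs: int = DEFAULT_MAX_PAIRS,
) -> SimilarityNetwork:
    """Score all sequence pairs and keep edges with bit score >= threshold."""
    if len(records) < 2:
        raise DivconsError("an SSN needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DivconsError(f"duplicate sequence ids: {dup}")
    n = len(records)
    n_pairs = n * (n - 1) // 2
    if n_pairs > max_pairs:
        raise DivconsError(
            f"{n} sequences imply {n_pairs} pairwise alignments, above the cap "
            f"of {max_pairs}; raise max_pairs explicitly for larger inputs"
        )
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            raw = local_score(records[i].residues, records[j].residues, matrix, gap_open, gap_extend)
            bits = raw_to_bits(raw, matrix, gap_open, gap_extend)
            if bits >= threshold:
                graph.add_edge(ids[i], ids[j], score_bits=bits)
    return SimilarityNetwork(graph=graph, threshold=float(threshold))


def cluster_families(network: SimilarityNetwork) -> list[set[str]]:
    """Connected components of the thresholded SSN.

    Deterministic order: by size descending, ties broken by the
    lexicographically smallest member id.
    """
    components = [set(c) for c in nx.connected_components(network.graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return components


def assign_reference(cluster: set[str], reference_id: str) -> FamilyBundle:
    """Tie a cluster to its structure-bearing reference sequence."""
    if reference_id not in cluster:
        raise DivconsError(
            f"reference {reference_id!r} is not in cluster {sorted(cluster)}"
        )
    return FamilyBundle(members=frozenset(cluster), reference_id=reference_id)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_edge_list(network: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore_bits\n")
        for a, b, bits in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{bits:.3f}\n")


def write_clusters(
    clusters: Sequence[set[str]], path: str | Path, references: dict[int, str] | None = None
) -> None:
    references = references or {}
    with open(path, "w") as fh:
        fh.write("id\tcluster_index\tis_reference\n")
        for idx, cluster in enumerate(clusters):
            for member in sorted(cluster):
                is_ref = int(references.get(idx) == member)
                fh.write(f"{member}\t{idx}\t{is_ref}\n")
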