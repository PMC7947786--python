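"""Synthetic two-family benchmark generator with planted ground truth.

The generator emulates the statistical structure the differential-
conservation analysis assumes: one ancestral protein is duplicated, the two
copies each found a family that diversifies along its own random pure-birth
tree, and a chosen set of sites is constrained:

* ``shared_identical``     - same residue enforced in both families;
* ``differently_conserved`` - a different residue enforced in each family;
* ``unique_A`` / ``unique_B`` - a residue enforced in one family only;
* ``free``                 - unconstrained everywhere.

Constraints are enforced at the leaves: each leaf shows its family's target
residue with probability 1 - epsilon and an explicitly non-target background
draw otherwise, so the per-site violation frequency is exactly epsilon and
directly verifiable.  Constrained sites are planted near a designated
active-site region of the toy structure, reflecting the biological premise
of the analysis (specificity-determining residues cluster around the
catalytic site) and exercising the spatial filter.

The paired toy structures are ideal alpha-helix CA traces (rise 1.5 A, 100
degree turn, radius 2.3 A) related by a known proper rigid transform, with
an optional family-A-only inserted loop displaced off the helix axis - a
miniature of the Dop-loop.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .alignment_conservation import background_vector
from .sequence_families import AMINO_ACIDS, DivconsError, SequenceRecord
from .structure_mapping import Residue, StructureModel, Superposition
from .differential_analysis import ActiveSiteSpec

CONSTRAINT_CLASSES = ("shared_identical", "differently_conserved", "unique_A", "unique_B")

#: SSN bit-score separation point for bundles generated at the default
#: configuration: between-family Smith-Waterman scores stay below ~25 bits
#: while every sequence keeps within-family neighbours above ~45 bits, so a
#: threshold of 40 bits yields exactly the two planted clusters.
SEPARATION_THRESHOLD_BITS = 40.0

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TURN = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom
LOOP_DISPLACEMENT = 10.0  # radial displacement of inserted-loop residues, Angstrom


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteConstraint:
    """Planted constraint for one ancestral site (1-based)."""

    site: int
    constraint_class: str
    target_a: str | None
    target_b: str | None

    def __post_init__(self) -> None:
        if self.constraint_class not in CONSTRAINT_CLASSES + ("free",):
            raise DivconsError(f"unknown constraint class {self.constraint_class!r}")
        if self.constraint_class == "shared_identical" and self.target_a != self.target_b:
            raise DivconsError("shared sites must share their target")
        if self.constraint_class == "differently_conserved" and (
            self.target_a is None or self.target_a == self.target_b
        ):
            raise DivconsError("differently conserved sites need two distinct targets")
        if self.constraint_class == "unique_A" and (self.target_a is None or self.target_b is not None):
            raise DivconsError("unique_A sites have a target in family A only")
        if self.constraint_class == "unique_B" and (self.target_b is None or self.target_a is not None):
            raise DivconsError("unique_B sites have a target in family B only")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    ``tree_total_length`` is the summed branch length of each family's
    random tree in expected substitutions per site (it controls both
    within-family diversity and the rate exp(-rate * tree_total_length) at
    which a free column stays invariant by chance); ``duplication_depth``
    is the expected substitutions per site on each post-duplication stem
    branch, setting between-family divergence.  ``epsilon`` is the per-leaf
    constraint violation rate.
    """

    seed: int
    n_sequences: int = 50
    length: int = 200
    n_unique_a: int = 10
    n_unique_b: int = 10
    n_differently: int = 5
    n_shared: int = 5
    tree_total_length: float = 7.0
    duplication_depth: float = 1.0
    rate: float = 1.0
    epsilon: float = 0.02
    insertion: tuple[str, int, int] | None = None  # (family, start, length)
    active_site_residues: tuple[int, ...] = (95, 100, 105)
    placement_margin: float = 18.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DivconsError("a seed is mandatory")
        if not 0 <= self.epsilon < 0.5:
            raise DivconsError("epsilon must be in [0, 0.5)")
        if self.n_constrained > self.length:
            raise DivconsError(
                f"{self.n_constrained} constrained sites exceed protein length {self.length}"
            )
        if self.insertion is not None:
            family, start, ins_len = self.insertion
            if family != "A":
                raise DivconsError("only family-A insertions are supported")
            if not (1 <= start <= self.length and ins_len >= 1):
                raise DivconsError("insertion region out of bounds")
        bad_sites = [r for r in self.active_site_residues if not 1 <= r <= self.length]
        if bad_sites:
            raise DivconsError(
                f"active-site residues {bad_sites} outside the protein (length {self.length})"
            )

    @property
    def n_constrained(self) -> int:
        return self.n_unique_a + self.n_unique_b + self.n_differently + self.n_shared


@dataclass
class SyntheticBundle:
    """A generated two-family data set with full ground truth."""

    config: SimulationConfig
    records_a: list[SequenceRecord]
    records_b: list[SequenceRecord]
    constraints: list[SiteConstraint]
    structure_a: StructureModel
    structure_b: StructureModel
    true_pairs: list[tuple[int, int]]  # structure residue numbers A<->B
    true_transform: Superposition
    active_site: ActiveSiteSpec
    insertion_positions_a: list[int]  # family-A positions of inserted residues

    @property
    def reference_a(self) -> str:
        return self.records_a[0].id

    @property
    def reference_b(self) -> str:
        return self.records_b[0].id

    @property
    def labels(self) -> dict[str, str]:
        out = {r.id: "A" for r in self.records_a}
        out.update({r.id: "B" for r in self.records_b})
        return out

    def all_records(self) -> list[SequenceRecord]:
        """Both families interleaved (sorted by id) as one mixed input set."""
        return sorted(self.records_a + self.records_b, key=lambda r: r.id)

    def ancestral_position_a(self, position_a: int) -> int | None:
        """Map a family-A sequence position to ancestral coordinates
        (None for inserted residues)."""
        if self.config.insertion is None:
            return position_a
        _, start, ins_len = self.config.insertion
        if position_a <= start:
            return position_a
        if position_a <= start + ins_len:
            return None
        return position_a - ins_len

    def position_a_of_ancestral(self, site: int) -> int:
        if self.config.insertion is None:
            return site
        _, start, ins_len = self.config.insertion
        return site if site <= start else site + ins_len

    def true_candidate_sites(self) -> set[int]:
        return {
            c.site
            for c in self.constraints
            if c.constraint_class in ("unique_A", "unique_B", "differently_conserved")
        }

    def verify(self) -> None:
        """Internal consistency of the planted constraints.

        The mean target frequency over all constrained site/family pairs
        must reach 1 - 2*epsilon; each individual site additionally gets a
        six-standard-error binomial floor (per-site counts are
        Binomial(n_sequences, epsilon), so occasional 4-5 violation sites
        are expected and legitimate at n=50)."""
        eps = self.config.epsilon
        floor = 1.0 - 2.0 * eps - 6.0 * float(
            np.sqrt(eps * (1.0 - eps) / self.config.n_sequences)
        )
        freqs: list[float] = []
        for constraint in self.constraints:
            for records, target, pos_map in (
                (self.records_a, constraint.target_a, self.position_a_of_ancestral),
                (self.records_b, constraint.target_b, lambda s: s),
            ):
                if target is None:
                    continue
                pos = pos_map(constraint.site)
                hits = sum(1 for r in records if r.residues[pos - 1] == target)
                freq = hits / len(records)
                freqs.append(freq)
                if freq < floor - 1e-12:
                    raise DivconsError(
                        f"site {constraint.site}: target frequency {freq:.3f} "
                        f"below the binomial floor {floor:.3f}"
                    )
        if freqs and float(np.mean(freqs)) < 1.0 - 2.0 * eps - 1e-12:
            raise DivconsError(
                f"mean constrained-site target frequency {np.mean(freqs):.4f} "
                f"below 1 - 2*epsilon"
            )
        ident = identity_summary(self, max_pairs=60)
        if ident["within_identity"] <= ident["between_identity"]:
            raise DivconsError(
                "duplication structure violated: within-family identity "
                f"({ident['within_identity']:.3f}) does not exceed between-family "
                f"identity ({ident['between_identity']:.3f})"
            )


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------


def helix_coords(length: int) -> np.ndarray:
    """Ideal alpha-helix CA trace: rise 1.5 A, 100 degree turn, radius 2.3 A."""
    i = np.arange(length)
    theta = np.deg2rad(HELIX_TURN * i)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def make_toy_structures(
    length: int,
    insertion_region: tuple[int, int] | None = None,
    noise_sd: float = 0.0,
    transform: Superposition | None = None,
    seed: int = 0,
    sequence_a: str | None = None,
    sequence_b: str | None = None,
) -> tuple[StructureModel, StructureModel, list[tuple[int, int]], Superposition]:
    """Build a pair of toy CA-trace structures with known correspondence.

    Structure A is a helix of ``length`` residues; residues inside
    ``insertion_region`` (1-based, inclusive) form a displaced loop present
    only in A.  Structure B holds the remaining residues, Gaussian-perturbed
    (``noise_sd``) and moved by ``transform`` (identity if None).  Returns
    (A, B, true residue pairs, transform mapping B onto A).
    """
    if length < 10:
        raise DivconsError("length must be >= 10")
    coords_a = helix_coords(length)
    inserted: set[int] = set()
    if insertion_region is not None:
        start, end = insertion_region
        if not (1 <= start <= end <= length):
            raise DivconsError(f"insertion region {insertion_region} out of bounds")
        inserted = set(range(start, end + 1))
        center = coords_a[start - 1 : end].mean(axis=0)
        radial = center - np.array([0.0, 0.0, center[2]])
        norm = np.linalg.norm(radial)
        direction = radial / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        coords_a[start - 1 : end] += LOOP_DISPLACEMENT * direction
    if transform is None:
        transform = Superposition(
            rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0, pairs=[]
        )
    rng = np.random.default_rng(seed)
    keep = [i for i in range(length) if (i + 1) not in inserted]
    base_b = coords_a[keep] + rng.normal(scale=noise_sd, size=(len(keep), 3))
    # Store B so that transform.apply(B) reproduces the (noisy) A frame.
    coords_b = (base_b - transform.translation) @ transform.rotation
    seq_a = sequence_a or "A" * length
    seq_b = sequence_b or "".join(seq_a[i] for i in keep)
    if len(seq_a) != length or len(seq_b) != len(keep):
        raise DivconsError("sequence lengths do not match structure lengths")
    model_a = StructureModel(
        chain_id="A",
        residues=[
            Residue(residue_number=i + 1, amino_acid=seq_a[i], ca=tuple(coords_a[i]))
            for i in range(length)
        ],
    )
    model_b = StructureModel(
        chain_id="B",
        residues=[
            Residue(residue_number=j + 1, amino_acid=seq_b[j], ca=tuple(coords_b[j]))
            for j in range(len(keep))
        ],
    )
    true_pairs = [(keep[j] + 1, j + 1) for j in range(len(keep))]
    return model_a, model_b, true_pairs, transform


def random_rigid_transform(rng: np.random.Generator, translation_scale: float = 20.0) -> Superposition:
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.normal(scale=translation_scale, size=3)
    return Superposition(rotation=rotation, translation=translation, rmsd=0.0, pairs=[])


# ---------------------------------------------------------------------------
# Coalescent tree and sequence evolution
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    children: list
    length: float = 0.0
    leaf: int | None = None


def _yule_tree(n: int, total_length: float, rng: np.random.Generator) -> _Node:
    """Random ultrametric pure-birth (Yule) tree, rescaled so the summed
    branch length equals ``total_length``.

    Normalising by total length pins the expected fraction of sites
    untouched by any substitution to exp(-rate * total_length) - the
    quantity that controls how often a free column is invariant by chance.
    The ultrametric pure-birth shape additionally bounds every root-to-leaf
    path well below the total, so no single leaf drifts beyond
    recognisability (every sequence stays alignable to its family)."""
    root = _Node(children=[])
    birth: dict[int, float] = {}
    active: list[_Node] = []
    current = 0.0
    # root splits immediately into two lineages
    for _ in range(2):
        child = _Node(children=[])
        root.children.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n:
        k = len(active)
        current += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.length = current - birth[id(node)]
        for _ in range(2):
            child = _Node(children=[])
            node.children.append(child)
            birth[id(child)] = current
            active.append(child)
    height = current + rng.exponential(1.0 / n)
    for i, node in enumerate(active):
        node.length = height - birth[id(node)]
        node.leaf = None
    # assign leaf indices in a rng-determined order
    order = rng.permutation(len(active))
    for leaf_idx, node_idx in enumerate(order):
        active[node_idx].leaf = int(leaf_idx)
    total = 0.0
    stack = list(root.children)
    while stack:
        node = stack.pop()
        total += node.length
        stack.extend(node.children)
    scale = total_length / total if total > 0 else 0.0
    stack = list(root.children)
    while stack:
        node = stack.pop()
        node.length *= scale
        stack.extend(node.children)
    root.length = 0.0
    return root


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator, bg: np.ndarray) -> np.ndarray:
    """Per-site Poisson substitution; the end state of any substituted site is
    a single background draw (replacement proposals are memoryless)."""
    out = seq.copy()
    if t <= 0:
        return out
    hit = rng.poisson(t, size=len(seq)) > 0
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = rng.choice(20, size=n_hit, p=bg)
    return out


def _non_target_draw(rng: np.random.Generator, bg: np.ndarray, target_idx: int) -> int:
    p = bg.copy()
    p[target_idx] = 0.0
    p /= p.sum()
    return int(rng.choice(20, p=p))


def simulate_families(config: SimulationConfig) -> SyntheticBundle:
    """Generate one labelled two-family bundle (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    bg = background_vector("blosum62")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    # Plant constrained sites inside the active-site neighbourhood of the toy
    # helix: the spatial filter is part of the analysis being exercised.
    coords = helix_coords(config.length)
    site_coords = coords[[r - 1 for r in config.active_site_residues]]
    dists = np.sqrt(((coords[:, None, :] - site_coords[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    window = [i + 1 for i in range(config.length) if dists[i] <= config.placement_margin]
    if len(window) < config.n_constrained:
        raise DivconsError(
            f"active-site neighbourhood holds only {len(window)} sites; "
            f"{config.n_constrained} constrained sites requested"
        )
    chosen = sorted(rng.choice(window, size=config.n_constrained, replace=False).tolist())
    classes = (
        ["unique_A"] * config.n_unique_a
        + ["unique_B"] * config.n_unique_b
        + ["differently_conserved"] * config.n_differently
        + ["shared_identical"] * config.n_shared
    )
    rng.shuffle(classes)

    constraints: list[SiteConstraint] = []
    for site, cls in zip(chosen, classes):
        if cls == "shared_identical":
            t = int(rng.choice(20, p=bg))
            constraints.append(SiteConstraint(site, cls, aa[t], aa[t]))
        elif cls == "differently_conserved":
            ta = int(rng.choice(20, p=bg))
            tb = _non_target_draw(rng, bg, ta)
            constraints.append(SiteConstraint(site, cls, aa[ta], aa[tb]))
        elif cls == "unique_A":
            constraints.append(SiteConstraint(site, cls, aa[int(rng.choice(20, p=bg))], None))
        else:
            constraints.append(SiteConstraint(site, cls, None, aa[int(rng.choice(20, p=bg))]))

    ancestor = rng.choice(20, size=config.length, p=bg)
    aa_index = {ch: i for i, ch in enumerate(AMINO_ACIDS)}

    ins_start, ins_len = 0, 0
    insertion_positions: list[int] = []
    if config.insertion is not None:
        _, ins_start, ins_len = config.insertion
        insertion_positions = list(range(ins_start + 1, ins_start + ins_len + 1))

    def family_leaves(family: str) -> list[np.ndarray]:
        root_seq = _evolve(ancestor, config.rate * config.duplication_depth, rng, bg)
        if family == "A" and ins_len:
            inserted = rng.choice(20, size=ins_len, p=bg)
            root_seq = np.concatenate([root_seq[:ins_start], inserted, root_seq[ins_start:]])
        tree = _yule_tree(config.n_sequences, config.tree_total_length, rng)
        leaves: dict[int, np.ndarray] = {}

        def walk(node: _Node, seq: np.ndarray) -> None:
            seq = _evolve(seq, config.rate * node.length, rng, bg)
            if node.leaf is not None:
                leaves[node.leaf] = seq
            for child in node.children:
                walk(child, seq)

        walk(tree, root_seq)
        out = []
        for i in range(config.n_sequences):
            seq = leaves[i]
            for constraint in constraints:
                target = constraint.target_a if family == "A" else constraint.target_b
                if target is None:
                    continue
                pos = constraint.site
                if family == "A" and ins_len and pos > ins_start:
                    pos += ins_len
                t_idx = aa_index[target]
                if rng.random() < 1.0 - config.epsilon:
                    seq[pos - 1] = t_idx
                else:
                    seq[pos - 1] = _non_target_draw(rng, bg, t_idx)
            out.append(seq)
        return out

    leaves_a = family_leaves("A")
    leaves_b = family_leaves("B")
    width = len(str(config.n_sequences))
    records_a = [
        SequenceRecord(id=f"A_{i + 1:0{width}d}", residues="".join(aa[s]))
        for i, s in enumerate(leaves_a)
    ]
    records_b = [
        SequenceRecord(id=f"B_{i + 1:0{width}d}", residues="".join(aa[s]))
        for i, s in enumerate(leaves_b)
    ]

    transform = random_rigid_transform(rng)
    structure_seed = int(rng.integers(2**31 - 1))
    insertion_region = None
    if ins_len:
        insertion_region = (ins_start + 1, ins_start + ins_len)
    model_a, model_b, true_pairs, transform = make_toy_structures(
        length=config.length + ins_len,
        insertion_region=insertion_region,
        noise_sd=config.noise_sd,
        transform=transform,
        seed=structure_seed,
        sequence_a=records_a[0].residues,
        sequence_b=records_b[0].residues,
    )
    active_site_a = tuple(
        r if not ins_len or r <= ins_start else r + ins_len for r in config.active_site_residues
    )
    bundle = SyntheticBundle(
        config=config,
        records_a=records_a,
        records_b=records_b,
        constraints=constraints,
        structure_a=model_a,
        structure_b=model_b,
        true_pairs=true_pairs,
        true_transform=transform,
        active_site=ActiveSiteSpec(side="A", residue_numbers=active_site_a),
        insertion_positions_a=insertion_positions,
    )
    bundle.verify()
    return bundle


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    precision: float | None
    recall: float
    confusion: dict[str, dict[str, int]]
    n_selected: int
    n_true_candidates: int


def evaluate_recovery(
    predicted_sites: Iterable[int],
    constraints: Sequence[SiteConstraint],
    length: int | None = None,
) -> RecoveryResult:
    """Precision/recall of predicted candidate sites against the planted truth.

    Both inputs are in ancestral 1-based coordinates.  True candidates are
    the unique_A, unique_B and differently_conserved sites.  Precision is
    None (with a warning) when nothing was predicted.
    """
    predicted = set(int(p) for p in predicted_sites)
    if length is not None:
        bad = [p for p in predicted if not 1 <= p <= length]
        if bad:
            raise DivconsError(f"predicted sites outside ancestral coordinates: {sorted(bad)}")
    by_class: dict[str, set[int]] = {cls: set() for cls in CONSTRAINT_CLASSES}
    for c in constraints:
        by_class[c.constraint_class].add(c.site)
    candidate_sites = (
        by_class["unique_A"] | by_class["unique_B"] | by_class["differently_conserved"]
    )
    confusion: dict[str, dict[str, int]] = {}
    constrained_all: set[int] = set()
    for cls in CONSTRAINT_CLASSES:
        sites = by_class[cls]
        constrained_all |= sites
        confusion[cls] = {"n_sites": len(sites), "n_selected": len(sites & predicted)}
    confusion["free"] = {
        "n_sites": (length - len(constrained_all)) if length is not None else -1,
        "n_selected": len(predicted - constrained_all),
    }
    tp = len(predicted & candidate_sites)
    if predicted:
        precision = tp / len(predicted)
    else:
        warnings.warn("no sites predicted; precision undefined")
        precision = None
    recall = tp / len(candidate_sites) if candidate_sites else 1.0
    return RecoveryResult(
        precision=precision,
        recall=recall,
        confusion=confusion,
        n_selected=len(predicted),
        n_true_candidates=len(candidate_sites),
    )


def identity_summary(bundle: SyntheticBundle, max_pairs: int = 500) -> dict[str, float]:
    """Mean pairwise sequence identity within and between the two families
    (computed over ancestral-aligned positions; subsampled for large n)."""
    rng = np.random.default_rng(0)

    def to_ancestral(record: SequenceRecord, family: str) -> str:
        if family == "B" or bundle.config.insertion is None:
            return record.residues
        _, start, ins_len = bundle.config.insertion
        return record.residues[:start] + record.residues[start + ins_len :]

    seqs_a = [to_ancestral(r, "A") for r in bundle.records_a]
    seqs_b = [to_ancestral(r, "B") for r in bundle.records_b]

    def mean_identity(pairs: list[tuple[str, str]]) -> float:
        if len(pairs) > max_pairs:
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
        vals = [
            sum(x == y for x, y in zip(s, t)) / len(s)
            for s, t in pairs
        ]
        return float(np.mean(vals))

    within = [
        (s[i], s[j])
        for s in (seqs_a, seqs_b)
        for i in range(len(s))
        for j in range(i + 1, len(s))
    ]
    between = [(sa, sb) for sa in seqs_a for sb in seqs_b]
    return {
        "within_identity": mean_identity(within),
        "between_identity": mean_identity(between),
    }
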