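# Methods

This note records the models, parameter choices and numerical conventions
behind `divcons`, and what the synthetic benchmark does and does not show
about real data.

## Problem setting and assumptions

Two paralogous enzyme families descend from a duplicated ancestor and have
diverged in function.  The working hypothesis — the one the motivating
Pup-ligase/depupylase system validated experimentally — is that the
functional difference is carried by a modest set of positions that are
maximally conserved in one family but not the other (or maximally conserved
in both with different residues), concentrated near the active site, plus
occasional family-specific indels.  The pipeline assumes:

* the input homolog set contains both families and separates cleanly in
  pairwise-score space (no continuum of intermediates);
* one structure per family is representative enough that a rigid CA-level
  superposition gives the right residue correspondence outside indel
  regions;
* active-site residues are known a priori (no automatic detection).

## Family partitioning

All-vs-all Smith–Waterman with affine gaps; a gap of length *k* costs
`gap_open + (k − 1)·gap_extend` (defaults BLOSUM62, 11/1 — standard
protein-search parameters).  `X` scores 0 against everything.  Raw scores
become bits via the Karlin–Altschul constants (λ = 0.267, K = 0.041 for
gapped BLOSUM62 11/1; ungapped fallbacks for untabulated combinations).
The SSN keeps edges at or above a bit-score threshold; families are its
connected components, ordered by size then smallest member id.  The
threshold is a required, data-dependent knob: scoring scales differ between
score definitions, so a universal default would be false precision.  For
bundles from the synthetic generator at default conditions the documented
separation point is **40 bits** (between-family scores stay below ~25 bits,
within-family neighbours above ~45).  All-vs-all scoring is O(n²L²) and is
capped (default 500 000 pairs) with a clear error; the tool targets
desk-scale inputs.

## Alignment and conservation

Guide tree: fractional shared-k-mer distances (k = 3), neighbor joining
(scikit-bio), negative branch lengths clamped to zero.  The NJ root
trifurcation is resolved into a binary root by pairing the two
shortest-branch children (ties by smallest tip name) across a zero-length
edge — deterministic in the tree's content, not its input order.
Progressive alignment is profile–profile Needleman–Wunsch (Gotoh affine,
sum-of-pairs expected column score, "once a gap, always a gap").  It is
intentionally basic; large or gappy families should come pre-aligned via
`read_alignment`.

Sequence weights are Henikoff–Henikoff position-based weights with the gap
character as an extra symbol, normalised to sum to one.

The conservation score of a column is the sequence-weighted Jensen–Shannon
divergence (base-2) between the column's residue distribution and a
background, normalised by the largest divergence any distribution attains
against that background, then multiplied by (1 − gap fraction).  A
deliberate simplification replaces ConSurf's empirical-Bayes rate inference:
it is deterministic, oracle-checkable, and the downstream classification
consumes only rank-based grades.  **The default background is uniform.**
Under a uniform background every invariant gap-free column scores exactly 1
regardless of its residue, and the score is Schur-convex (more concentrated
columns never score lower) — both properties the maximal-grade
classification relies on.  The BLOSUM62 marginal background remains
available by flag for exploratory use; note that there an invariant column
of a common residue scores below one of a rare residue, which distorts the
maximal-grade ranking and is why it is not the default.

Grades 1–9 are assigned by equal-frequency binning of the score ranks over
columns with gap fraction ≤ 0.5 (grade 9 = most conserved bin; equal scores
always share the higher grade; gappier columns are pinned to grade 1 as
unreliable).  Equal-frequency binning guarantees a non-empty top bin for
any score distribution.  Absolute grades are not comparable to ConSurf's on
real data — only the classification logic transfers.

## Structural mapping

CA-only models; first MODEL of a PDB file, preferred altloc, residues
renumbered sequentially with the author label retained.  Superposition is
the Kabsch/SVD least-squares proper rotation; reflections are corrected by
flipping the smallest singular direction, and collinear point sets are
rejected as rank-deficient.  Starting from a global sequence alignment of
the two structures' residue strings, the algorithm alternates Kabsch on the
current pairs with a monotone (sequence-alignment-shaped) re-pairing that
maximises the number of residue pairs within a distance cutoff and, among
those, minimises total distance — dynamic programming, not greedy
nearest-neighbour, so the map stays colinear.  Defaults: cutoff 5.0 Å,
max 20 iterations (typical structure-alignment settings; both exposed in
config and echoed in output).  Residue pairs are lifted to alignment
columns through each family's reference row; columns without a partner are
reported unmatched and carry the family-specific insertions.

## Classification and spatial filter

With grade 9 as "maximally conserved": `shared_identical` (9/9, same
consensus), `differently_conserved` (9/9, different consensus),
`unique_A`/`unique_B` (9 on one side, the other side's grade strictly below
`low_cutoff`), `indel` (unmatched column at grade 9 on its own side),
`unconserved` otherwise.  **`low_cutoff` defaults to 9**, i.e. "not
maximally conserved" counts as not conserved.  Two considerations fix this
default: published reciprocal-mutagenesis sets for the Dop/PafA pair
include positions graded 7–8 on the non-conserved side, so the operative
published definition is "maximal in one, not maximal in the other"; and
under equal-frequency binning a genuinely unconstrained position's grade is
uniform over the rank bins, so any mid-scale cutoff would discard a large
fraction of true family-unique positions.  The knob remains configurable
for stricter use.

Candidates are filtered by minimum CA–CA distance from the position's
reference residue to any active-site residue, threshold 20 Å by default.
CA–CA (rather than all-atom) distance is the documented choice — the model
is CA-only.  A config list of forced positions can inject manual overrides
(e.g. secondary-structure-preserving picks) after the filter; they are
flagged in the summary.

## Mutant design

Anchors are 1-based on the wild-type sequence; insertions go after their
anchor, deletions and segment swaps cover inclusive ranges.  Units are
disjoint and applied in canonical descending-coordinate order (no
re-anchoring arithmetic; verified equivalent to an ascending-with-offsets
application).  Every unit carries the expected base content as a drift
guard.  Libraries enumerate all 2^k segment combinations in binary counting
order (backbone first, fully-on last; guard at 20 segments).  Reversion
series omit one unit *group* at a time, so multi-edit blocks marked as one
group revert together.  The package ships a transcription of the published
Dop→PafA reciprocal-mutagenesis position set and the 32-member library
memberships; the wild-type M. smegmatis Dop sequence itself is not
required for count/length/naming computations and is replaced by a clearly
labelled synthetic base sequence pinned to the published wild-type residues
at the anchored positions.

## Synthetic benchmark

`simulate_families` draws an ancestral sequence from the BLOSUM62 marginal
frequencies, duplicates it, and evolves each family along an independent
random ultrametric pure-birth (Yule) tree under per-site Poisson
substitution with background-proposal replacement.  Defaults (the study
conditions used throughout the tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| `n_sequences` | 50 per family | leaves per family |
| `length` | 200 | protein length (residues) |
| planted sites | 10 unique-A, 10 unique-B, 5 differently, 5 shared | candidate truth |
| `epsilon` | 0.02 | per-leaf constraint violation rate |
| `tree_total_length` | 7.0 | summed branch length (subs/site) per family tree |
| `duplication_depth` | 1.0 | stem branch (subs/site) per family |
| `active_site_residues` | 95, 100, 105 | active site on the toy helix |
| `placement_margin` | 18 Å | constrained sites planted within this CA distance of the active site |
| `noise_sd` | 0.3 Å | coordinate noise on structure B |

Two normalisations matter and were chosen on first principles.  The tree is
scaled by **total** branch length, because exp(−rate·total) is the chance a
free column is untouched by substitution — at 7.0 the expected number of
chance-invariant free columns is below one per family, so chance mimics of
constrained sites are rare.  The tree is **ultrametric pure-birth** rather
than coalescent-shaped because a coalescent's long basal branches routinely
carry single leaves beyond recognisability, which no aligner can place;
bounding the root-to-leaf height keeps every sequence alignable (default
conditions give ~54% mean within-family identity, ~12% between — comfortably
bracketing the 40-bit SSN separation point).  Constraints are enforced at
the leaves: with probability 1 − ε the leaf shows the family target,
otherwise an explicitly non-target background draw, so the per-site
violation frequency is exactly ε and binomially verifiable.  Constrained
sites are planted inside the active-site neighbourhood of the toy helix —
the biological premise of the spatial filter — which is also what makes the
filter informative in the benchmark: free columns that are conserved by
chance are mostly far from the active site and get filtered.

Toy structures are ideal α-helix CA traces (rise 1.5 Å, 100°/residue,
radius 2.3 Å); an optional family-A-only loop is displaced 10 Å radially
and deleted from structure B, which is noise-perturbed and moved by a known
random proper rigid transform.

What the benchmark does **not** emulate: realistic exchangeabilities or
rate heterogeneity (no Γ, no covarion), indel evolution within families,
compositional drift, structure flexibility, or uncertainty in the
active-site list.  Passing tests therefore demonstrate that the pipeline's
logic recovers planted signal under its own generative assumptions — not
that ConSurf-grade inferences on real alignments would yield the same
counts.  The published real-data counts for the motivating system (e.g.
377/285 cluster sizes from 2,689 sequences, 118/120 maximally conserved
positions, 22/34/10 unique/differently conserved) depend on the original
sequence harvest and scorer and are out of scope here.

## Numerical conventions and degenerate inputs

* Gap cost `open + (k−1)·extend`; `gap_open < gap_extend` is rejected.
* Consensus ties break alphabetically; cluster ordering by size then
  smallest id; library order is binary counting — all outputs byte-stable
  across reruns (timing lives only in `run.log`).
* All-gap columns: score 0, consensus `-`.  Fewer than nine gradable
  columns: rank grading with ties sharing the higher grade.
* Kabsch needs ≥ 3 pairs and non-collinear inputs; iterative mapping
  aborts if fewer than 3 pairs survive the cutoff.
* Two-taxon families bypass NJ via a direct join; single-sequence families
  align trivially.
* Random draws all flow from `numpy.random.default_rng(seed)`; the same
  seed reproduces a bundle byte-for-byte.

## Validation surfaces (computed by the test suite and acceptance script)

* Planted-candidate recovery, pooled over 20 seeded default-condition
  bundles through the full pipeline (SSN included): precision and recall
  are required to reach 0.9.
* Primitive-level oracle equivalences: Smith–Waterman vs an independent
  quadratic DP; connected components vs union-find; column scores vs
  direct JSD summation; active-site distances vs exhaustive scan.
* Kabsch recovery of 50 random proper transforms to < 1e-6 Å; mirror
  inputs never yield reflections.
* Exact exclusion of a planted 5-residue displaced loop from the
  structural pairing over 20 seeds.
* Mutant algebra: |library(k)| = 2^k for k ≤ 12; apply-then-invert
  identity on random unit sets; the published 32-member library and the
  20-position / 37-residue / 9+11-unit counts rebuilt from the shipped
  table transcription.

Problem sizes in the suite (bundle counts, sequence numbers, lengths) are
the study conditions above; smaller sizes appear only in unit tests of
single operations.

## Known limitations

* The progressive aligner degrades below roughly 35–40% within-family
  identity; supply an external MSA for such families.
* The SSN threshold is score-definition-specific and must be chosen per
  dataset (the EFI-EST-style "alignment score" does not map exactly onto
  bit scores).
* Rigid-body mapping cannot follow conformational rearrangements: a region
  that changes conformation between families (like the α-loop of the
  motivating system) maps only as well as the global superposition allows.
* Grades are relative within a family; comparing absolute grades across
  families with very different diversity is not meaningful.
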