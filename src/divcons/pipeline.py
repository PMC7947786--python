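"""End-to-end orchestration: cluster -> align/conserve -> map -> classify ->
design, as one reproducible run.

Two entry points:

* :func:`run_pipeline` - file-based run driven by a flat ``key = value``
  config (the CLI's ``divcons run``); writes every intermediate artifact,
  a run log and a machine-readable ``summary.json``.
* :func:`analyze_bundle` - the same stages applied to an in-memory
  :class:`~divcons.synthetic_data.SyntheticBundle`, returning the planted-
  position recovery metrics; this is the package's primary validation
  surface.

Outputs are deterministic for identical (config, inputs): timing and
timestamps go to the run log only, never into the data artifacts.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__ as _version
from .alignment_conservation import (
    align_family,
    conservation_profile,
    read_alignment,
    write_alignment,
    write_profile,
)
from .differential_analysis import (
    DEFAULT_DISTANCE_THRESHOLD,
    DEFAULT_LOW_CUTOFF,
    ActiveSiteSpec,
    annotate_distances,
    candidate_report,
    classify_positions,
    select_candidates,
)
from .mutant_design import MutantDefinition, reciprocal_units, write_mutants
from .sequence_families import (
    DivconsError,
    SequenceRecord,
    assign_reference,
    build_ssn,
    cluster_families,
    read_fasta,
    write_clusters,
    write_edge_list,
)
from .structure_mapping import (
    DEFAULT_CUTOFF,
    DEFAULT_MAX_ITER,
    iterative_structural_align,
    lift_to_columns,
    read_structure,
    write_map,
    write_superposition,
)
from .synthetic_data import (
    SEPARATION_THRESHOLD_BITS,
    RecoveryResult,
    SyntheticBundle,
    evaluate_recovery,
)

logger = logging.getLogger("divcons")

_DEFAULTS = {
    "ssn_threshold": 100.0,
    "matrix": "BLOSUM62",
    "gap_open": 11.0,
    "gap_extend": 1.0,
    "background": "uniform",
    "gap_grade_threshold": 0.5,
    "low_cutoff": float(DEFAULT_LOW_CUTOFF),
    "distance_threshold": DEFAULT_DISTANCE_THRESHOLD,
    "structural_cutoff": DEFAULT_CUTOFF,
    "max_iter": float(DEFAULT_MAX_ITER),
    "seed": 0.0,
    "chain_a": "A",
    "chain_b": "B",
    "forced_positions": "",
    "log_level": "INFO",
}

_RANGES = {
    "distance_threshold": (0.0, float("inf")),
    "structural_cutoff": (1e-9, float("inf")),
    "low_cutoff": (1.0, 9.0),
    "gap_grade_threshold": (0.0, 1.0),
    "max_iter": (1.0, 10_000.0),
}

_REQUIRED = ("structure_a", "structure_b", "reference_a", "reference_b", "active_site", "out_dir")
_KNOWN = set(_DEFAULTS) | set(_REQUIRED) | {"fasta", "alignment_a", "alignment_b"}


@dataclass
class RunConfig:
    structure_a: Path
    structure_b: Path
    reference_a: str
    reference_b: str
    active_site: tuple[int, ...]
    out_dir: Path
    fasta: Path | None = None
    alignment_a: Path | None = None
    alignment_b: Path | None = None
    chain_a: str = "A"
    chain_b: str = "B"
    ssn_threshold: float = 100.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    background: str = "uniform"
    gap_grade_threshold: float = 0.5
    low_cutoff: int = DEFAULT_LOW_CUTOFF
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD
    structural_cutoff: float = DEFAULT_CUTOFF
    max_iter: int = DEFAULT_MAX_ITER
    seed: int = 0
    forced_positions: tuple[int, ...] = ()
    log_level: str = "INFO"


@dataclass
class RunSummary:
    """Per-stage counts and the parameter echo for one pipeline run.

    ``stage_wall_times`` is informational only and is written to the run
    log, not to summary.json, so data artifacts stay byte-reproducible.
    """

    parameters: dict
    counts: dict
    software_version: str = _version
    stage_wall_times: dict = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        if c.get("selected", 0) > c.get("candidates", 0):
            raise DivconsError("summary inconsistency: selected > candidates")
        if c.get("candidates", 0) > c.get("matched_columns", 0) + c.get("indel_records", 0):
            raise DivconsError("summary inconsistency: candidates exceed classified positions")


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat ``key = value`` config file."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise DivconsError(f"{path}:{lineno}: expected 'key = value', got {stripped!r}")
        key, _, value = stripped.partition("=")
        raw[key.strip()] = value.strip()
    for key in raw:
        if key not in _KNOWN:
            warnings.warn(f"unknown config key {key!r} ignored")
    for key in _REQUIRED:
        if key not in raw:
            raise DivconsError(f"missing required config key {key!r}")
    if "fasta" not in raw and ("alignment_a" not in raw or "alignment_b" not in raw):
        raise DivconsError("config needs either 'fasta' or both 'alignment_a' and 'alignment_b'")

    def num(key: str) -> float:
        value = raw.get(key, _DEFAULTS.get(key))
        try:
            return float(value)
        except (TypeError, ValueError) as exc:
            raise DivconsError(f"config key {key!r}: not a number: {value!r}") from exc

    for key, (lo, hi) in _RANGES.items():
        v = num(key)
        if not lo <= v <= hi:
            raise DivconsError(f"config key {key!r}={v} outside allowed range [{lo}, {hi}]")

    def path_of(key: str) -> Path | None:
        if key not in raw:
            return None
        p = Path(raw[key])
        if not p.exists():
            raise DivconsError(f"config key {key!r}: path does not exist: {p}")
        return p

    def int_list(key: str) -> tuple[int, ...]:
        text = raw.get(key, _DEFAULTS.get(key, ""))
        if not text:
            return ()
        try:
            return tuple(int(x) for x in str(text).replace(",", " ").split())
        except ValueError as exc:
            raise DivconsError(f"config key {key!r}: expected integers, got {text!r}") from exc

    active_site = int_list("active_site")
    if not active_site:
        raise DivconsError("active_site must list at least one residue number")

    return RunConfig(
        structure_a=path_of("structure_a"),
        structure_b=path_of("structure_b"),
        reference_a=raw["reference_a"],
        reference_b=raw["reference_b"],
        active_site=active_site,
        out_dir=Path(raw["out_dir"]),
        fasta=path_of("fasta"),
        alignment_a=path_of("alignment_a"),
        alignment_b=path_of("alignment_b"),
        chain_a=raw.get("chain_a", "A"),
        chain_b=raw.get("chain_b", "B"),
        ssn_threshold=num("ssn_threshold"),
        matrix=raw.get("matrix", "BLOSUM62"),
        gap_open=num("gap_open"),
        gap_extend=num("gap_extend"),
        background=raw.get("background", "uniform"),
        gap_grade_threshold=num("gap_grade_threshold"),
        low_cutoff=int(num("low_cutoff")),
        distance_threshold=num("distance_threshold"),
        structural_cutoff=num("structural_cutoff"),
        max_iter=int(num("max_iter")),
        seed=int(num("seed")),
        forced_positions=int_list("forced_positions"),
        log_level=raw.get("log_level", "INFO"),
    )


def _partition_by_reference(
    records: Sequence[SequenceRecord],
    clusters: Sequence[set[str]],
    reference_a: str,
    reference_b: str,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    cluster_a = cluster_b = None
    for cluster in clusters:
        if reference_a in cluster:
            cluster_a = cluster
        if reference_b in cluster:
            cluster_b = cluster
    if cluster_a is None or cluster_b is None:
        missing = [r for r, c in ((reference_a, cluster_a), (reference_b, cluster_b)) if c is None]
        raise DivconsError(f"reference ids {missing} not found in any cluster")
    if cluster_a is cluster_b:
        raise DivconsError(
            "both references fall in one SSN cluster; raise the threshold to split the families"
        )
    family_a = [r for r in records if r.id in cluster_a]
    family_b = [r for r in records if r.id in cluster_b]
    return family_a, family_b


def analyze_bundle(
    bundle: SyntheticBundle,
    ssn_threshold: float = SEPARATION_THRESHOLD_BITS,
    low_cutoff: int = DEFAULT_LOW_CUTOFF,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    structural_cutoff: float = DEFAULT_CUTOFF,
    use_ssn: bool = True,
) -> dict:
    """Run the full analysis on a synthetic bundle and score the recovery of
    the planted candidate sites (ancestral coordinates)."""
    records = bundle.all_records()
    n_clusters = 2
    if use_ssn:
        network = build_ssn(records, threshold=ssn_threshold)
        clusters = cluster_families(network)
        n_clusters = len(clusters)
        family_a, family_b = _partition_by_reference(
            records, clusters, bundle.reference_a, bundle.reference_b
        )
    else:
        family_a = list(bundle.records_a)
        family_b = list(bundle.records_b)
    aln_a = align_family(family_a, reference_id=bundle.reference_a)
    aln_b = align_family(family_b, reference_id=bundle.reference_b)
    profile_a = conservation_profile(aln_a)
    profile_b = conservation_profile(aln_b)
    superposition, pairs = iterative_structural_align(
        bundle.structure_a, bundle.structure_b, cutoff=structural_cutoff
    )
    mapping = lift_to_columns(pairs, bundle.structure_a, bundle.structure_b, profile_a, profile_b)
    records_cls = classify_positions(profile_a, profile_b, mapping, low_cutoff=low_cutoff)
    annotate_distances(records_cls, bundle.structure_a, bundle.active_site)
    summary = select_candidates(records_cls, distance_threshold=distance_threshold)
    predicted = set()
    for rec in records_cls:
        if rec.selected and rec.ref_residue_a is not None:
            site = bundle.ancestral_position_a(rec.ref_residue_a[0])
            if site is not None:
                predicted.add(site)
    recovery = evaluate_recovery(predicted, bundle.constraints, length=bundle.config.length)
    return {
        "n_clusters": n_clusters,
        "alignment_a": aln_a,
        "alignment_b": aln_b,
        "profile_a": profile_a,
        "profile_b": profile_b,
        "superposition": superposition,
        "mapping": mapping,
        "records": records_cls,
        "selection_summary": summary,
        "predicted_sites": predicted,
        "recovery": recovery,
    }


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 1,
    config_kwargs: dict | None = None,
    **analysis_kwargs,
) -> dict:
    """Pooled planted-candidate precision/recall over independently seeded
    synthetic bundles (the package's central validation experiment)."""
    from .synthetic_data import SimulationConfig, simulate_families

    config_kwargs = config_kwargs or {}
    tp = n_pred = n_true = 0
    per_seed = []
    for i in range(n_seeds):
        seed = (base_seed * 100_003 + i) % (2**31 - 1)
        bundle = simulate_families(SimulationConfig(seed=seed, **config_kwargs))
        result = analyze_bundle(bundle, **analysis_kwargs)
        rec: RecoveryResult = result["recovery"]
        true_sites = bundle.true_candidate_sites()
        hits = len(result["predicted_sites"] & true_sites)
        tp += hits
        n_pred += rec.n_selected
        n_true += rec.n_true_candidates
        per_seed.append((rec.precision, rec.recall))
    return {
        "precision": tp / n_pred if n_pred else None,
        "recall": tp / n_true if n_true else None,
        "per_seed": per_seed,
        "n_seeds": n_seeds,
    }


def _setup_logging(out_dir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full file-based analysis run.

    Stages: cluster (unless pre-aligned MSAs are supplied) -> per-family
    alignment & conservation -> structural mapping -> classification &
    spatial filtering -> reciprocal mutant design.  All artifacts are
    written to ``config.out_dir``; any stage error aborts with the stage
    name while earlier artifacts are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    counts: dict[str, int] = {}
    wall: dict[str, float] = {}
    stage = "setup"

    def tick(name: str) -> float:
        nonlocal stage
        stage = name
        logger.info("[%s] started", name)
        return time.perf_counter()

    try:
        if config.alignment_a and config.alignment_b:
            t0 = tick("align")
            aln_a = read_alignment(config.alignment_a, reference_id=config.reference_a)
            aln_b = read_alignment(config.alignment_b, reference_id=config.reference_b)
            from .alignment_conservation import henikoff_weights

            aln_a.weights = henikoff_weights(aln_a)
            aln_b.weights = henikoff_weights(aln_b)
            counts["sequences"] = len(aln_a.rows) + len(aln_b.rows)
            counts["clusters"] = 2
            logger.info("[align] pre-aligned MSAs supplied; clustering and alignment skipped")
            wall["align"] = time.perf_counter() - t0
        else:
            t0 = tick("cluster")
            records = read_fasta(config.fasta)
            counts["sequences"] = len(records)
            network = build_ssn(
                records, config.ssn_threshold, config.matrix, config.gap_open, config.gap_extend
            )
            clusters = cluster_families(network)
            counts["clusters"] = len(clusters)
            family_a, family_b = _partition_by_reference(
                records, clusters, config.reference_a, config.reference_b
            )
            assign_reference(set(r.id for r in family_a), config.reference_a)
            assign_reference(set(r.id for r in family_b), config.reference_b)
            write_edge_list(network, out / "ssn_edges.tsv")
            ref_index = {}
            for i, cluster in enumerate(clusters):
                if config.reference_a in cluster:
                    ref_index[i] = config.reference_a
                if config.reference_b in cluster:
                    ref_index[i] = config.reference_b
            write_clusters(clusters, out / "clusters.tsv", ref_index)
            wall["cluster"] = time.perf_counter() - t0

            t0 = tick("align")
            aln_a = align_family(
                family_a, config.reference_a, config.matrix, config.gap_open, config.gap_extend
            )
            aln_b = align_family(
                family_b, config.reference_b, config.matrix, config.gap_open, config.gap_extend
            )
            wall["align"] = time.perf_counter() - t0
        write_alignment(aln_a, out / "alignment_a.fasta")
        write_alignment(aln_b, out / "alignment_b.fasta")

        t0 = tick("conserve")
        profile_a = conservation_profile(aln_a, config.background, config.gap_grade_threshold)
        profile_b = conservation_profile(aln_b, config.background, config.gap_grade_threshold)
        counts["columns_a"] = profile_a.n_columns
        counts["columns_b"] = profile_b.n_columns
        write_profile(profile_a, out / "profile_a.tsv")
        write_profile(profile_b, out / "profile_b.tsv")
        wall["conserve"] = time.perf_counter() - t0

        t0 = tick("map")
        model_a = read_structure(config.structure_a, config.chain_a)
        model_b = read_structure(config.structure_b, config.chain_b)
        superposition, pairs = iterative_structural_align(
            model_a,
            model_b,
            cutoff=config.structural_cutoff,
            max_iter=config.max_iter,
            matrix=config.matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        mapping = lift_to_columns(pairs, model_a, model_b, profile_a, profile_b)
        counts["matched_columns"] = len(mapping.matched)
        counts["unmatched_a"] = len(mapping.unmatched_a)
        counts["unmatched_b"] = len(mapping.unmatched_b)
        write_superposition(superposition, out / "superposition.tsv")
        write_map(mapping, profile_a, profile_b, out / "column_map.tsv")
        wall["map"] = time.perf_counter() - t0

        t0 = tick("classify")
        active_site = ActiveSiteSpec(side="A", residue_numbers=config.active_site)
        records_cls = classify_positions(profile_a, profile_b, mapping, config.low_cutoff)
        annotate_distances(records_cls, model_a, active_site)
        selection = select_candidates(records_cls, config.distance_threshold)
        forced = 0
        for rec in records_cls:
            if rec.ref_residue_a and rec.ref_residue_a[0] in config.forced_positions:
                if not rec.selected:
                    forced += 1
                rec.selected = True
        counts["indel_records"] = selection["counts_before_filter"].get("indel", 0)
        counts["candidates"] = selection["n_candidates"]
        counts["selected"] = selection["n_selected"] + forced
        counts["forced_positions"] = forced
        report = candidate_report(records_cls)
        report.to_csv(out / "candidates.tsv", sep="\t", index=False)
        wall["classify"] = time.perf_counter() - t0

        t0 = tick("design")
        base = None
        for rid, _ in aln_a.rows:
            if rid == config.reference_a:
                base = SequenceRecord(id=rid, residues=aln_a.ungapped(rid))
        selected = [r for r in records_cls if r.selected and r.ref_residue_a is not None]
        # The base carries the reference sequence, not the consensus: guard
        # against drift by re-anchoring unit expectations on the base itself.
        for rec in selected:
            pos = rec.ref_residue_a[0]
            rec.ref_residue_a = (pos, base.residues[pos - 1])
        usable = [
            r for r in selected
            if r.column_b is None or (r.consensus_b and r.consensus_b != r.ref_residue_a[1])
        ]
        units = reciprocal_units(usable, base)
        mutant = MutantDefinition(
            name="reciprocal_full", base_id=base.id, units=tuple(units)
        )
        write_mutants([mutant], base, out / "mutants.fasta")
        counts["mutation_units"] = len(units)
        counts["mutants_designed"] = 1
        wall["design"] = time.perf_counter() - t0

        summary = RunSummary(
            parameters={
                "ssn_threshold": config.ssn_threshold,
                "matrix": config.matrix,
                "gap_open": config.gap_open,
                "gap_extend": config.gap_extend,
                "background": config.background,
                "low_cutoff": config.low_cutoff,
                "distance_threshold": config.distance_threshold,
                "structural_cutoff": config.structural_cutoff,
                "max_iter": config.max_iter,
                "gap_grade_threshold": config.gap_grade_threshold,
                "forced_positions": list(config.forced_positions),
                "seed": config.seed,
            },
            counts=counts,
            stage_wall_times=wall,
        )
        summary.validate()
        payload = {
            "software_version": summary.software_version,
            "parameters": summary.parameters,
            "counts": summary.counts,
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        for name, seconds in wall.items():
            logger.info("[%s] finished in %.2f s", name, seconds)
        return summary
    except Exception as exc:
        logger.exception("pipeline aborted during stage %r", stage)
        raise DivconsError(f"pipeline failed during stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
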