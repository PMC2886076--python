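"""End-to-end orchestration: detect -> anchor -> leader -> cas -> atlas -> proto-spacer -> evolution.

A run is driven by a :class:`PipelineConfig` holding either a synthetic-world
configuration or paths to real inputs (exactly one of the two).  ``run_all``
executes every stage in order, logs one structured line per stage and returns
a :class:`~crispratlas.genome_io.ReportBundle` of deterministic tables; the
same config and seed always produce a byte-identical bundle.
"""
from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cas_annot import (
    ECOLI_CAS_GENES,
    YPEST_CAS_GENES,
    CasOperonCall,
    annotate_genome_cas,
    load_cas_refs,
)
from .crispr_detect import (
    CrisprArray,
    DetectorParams,
    detect_arrays,
    flag_terminal_degeneracy,
)
from .evo_stats import (
    DivergenceParams,
    distance_matrix,
    divergence_estimate,
    group_close_strains,
    repeat_correlation,
)
from .genome_io import (
    Genome,
    MobileElement,
    ReportBundle,
    load_elements,
    load_genome,
    write_elements,
    write_genome,
)
from .locus_map import GeneFamily, anchor_locus, core_genome, find_leader
from .spacer_protospacer import (
    ProtoQuery,
    atlas_stats,
    classify_hits,
    cluster_spacers,
    context_stats,
    detect_anti_crispr,
    detect_duplications,
    occurrences_from_arrays,
    polarity_profile,
    search_protospacers,
    self_targets,
)
from .synthetic_data import TruthSet, WorldConfig, generate_world

__all__ = ["PipelineConfig", "PipelineError", "run_all", "run_detect",
           "run_annotate", "load_inputs", "write_world"]

log = logging.getLogger("crispratlas")

_ALL_CAS_NAMES = frozenset(ECOLI_CAS_GENES) | frozenset(YPEST_CAS_GENES)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synth`` (generate a synthetic world) or ``genomes_dir``
    (load real FASTA/GFF3 inputs) must be set.  ``elements_fasta`` /
    ``elements_tsv`` supply the mobile-element pool for real inputs; the
    synthetic world carries its own pool.
    """

    synth: Optional[WorldConfig] = None
    genomes_dir: Optional[str] = None
    elements_fasta: Optional[str] = None
    elements_tsv: Optional[str] = None
    cas_refs_fasta: Optional[str] = None
    out_dir: Optional[str] = None
    seed: int = 0
    threads: int = 1
    detector: DetectorParams = field(default_factory=DetectorParams)
    divergence: DivergenceParams = field(default_factory=DivergenceParams)
    grouping_threshold: float = 0.0002
    min_proto_identity: float = 0.95
    n_perm: int = 10_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.genomes_dir is None):
            raise ValueError("exactly one of synth config or genomes_dir required")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if not 0 < self.min_proto_identity <= 1:
            raise ValueError("min_proto_identity must be in (0, 1]")


def load_inputs(config: PipelineConfig) -> tuple[list[Genome], list[MobileElement], Optional[TruthSet]]:
    """Produce the run's genomes and element pool from config (synth or disk)."""
    if config.synth is not None:
        genomes, elements, truth = generate_world(config.synth, seed=config.seed)
        return genomes, elements, truth
    if not os.path.isdir(config.genomes_dir):
        raise PipelineError("input", f"genome directory not found: {config.genomes_dir}")
    fastas = sorted(f for f in os.listdir(config.genomes_dir)
                    if f.endswith((".fasta", ".fa", ".fna")))
    if not fastas:
        raise PipelineError("input", f"no FASTA genomes in {config.genomes_dir}")
    genomes = []
    for f in fastas:
        stem = os.path.splitext(f)[0]
        gff = os.path.join(config.genomes_dir, stem + ".gff3")
        genomes.append(load_genome(os.path.join(config.genomes_dir, f),
                                   gff if os.path.exists(gff) else None))
    elements: list[MobileElement] = []
    if config.elements_fasta and config.elements_tsv:
        elements = load_elements(config.elements_fasta, config.elements_tsv)
    return genomes, elements, None


def write_world(genomes: Sequence[Genome], elements: Sequence[MobileElement],
                truth: Optional[TruthSet], out_dir: str) -> None:
    """Persist a (synthetic) world as the standard on-disk interfaces."""
    gdir = os.path.join(out_dir, "genomes")
    os.makedirs(gdir, exist_ok=True)
    for g in genomes:
        write_genome(g, os.path.join(gdir, f"{g.genome_id}.fasta"),
                     os.path.join(gdir, f"{g.genome_id}.gff3"))
    if elements:
        write_elements(elements, os.path.join(out_dir, "elements.fasta"),
                       os.path.join(out_dir, "elements.tsv"))
    if truth is not None:
        truth.save(os.path.join(out_dir, "truth.json"))


# ---------------------------------------------------------------------------
# Stages

def detect_stage(genomes: Sequence[Genome], params: DetectorParams,
                 threads: int = 1) -> dict[str, list[CrisprArray]]:
    """Run the repeat detector over every contig of every genome."""

    def one(genome: Genome) -> tuple[str, list[CrisprArray]]:
        arrays: list[CrisprArray] = []
        for contig_id, seq in genome.contigs:
            found = detect_arrays(seq, params, contig_id=contig_id)
            for arr in found:
                arr.genome_id = genome.genome_id
            arrays.extend(found)
        return genome.genome_id, arrays

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(one, genomes))
    else:
        results = [one(g) for g in genomes]
    return dict(sorted(results))


def anchor_stage(genomes: Sequence[Genome],
                 arrays_by_genome: dict[str, list[CrisprArray]],
                 core: Optional[Sequence[GeneFamily]]) -> None:
    """Assign each array its anchored locus name (in place)."""
    by_id = {g.genome_id: g for g in genomes}
    for gid, arrays in arrays_by_genome.items():
        for arr in arrays:
            arr.locus = anchor_locus(arr, by_id[gid], core=core)


def leader_stage(genomes: Sequence[Genome],
                 arrays_by_genome: dict[str, list[CrisprArray]]) -> list:
    """Call leaders per locus (orients arrays) and re-flag terminal decay."""
    by_id = {g.genome_id: g for g in genomes}
    by_locus: dict[str, list] = {}
    for gid, arrays in arrays_by_genome.items():
        for arr in arrays:
            by_locus.setdefault(arr.locus, []).append((by_id[gid], arr))
    leaders = []
    for locus in sorted(by_locus):
        if locus == "unanchored":
            continue
        leaders.extend(find_leader(by_locus[locus]))
    # orientation is now known, so 5'/3' degeneracy flags become meaningful
    for arrays in arrays_by_genome.values():
        for arr in arrays:
            deg5, deg3 = flag_terminal_degeneracy(arr)
            arr.flags["terminal_5_degenerate"] = deg5
            arr.flags["terminal_3_degenerate"] = deg3
    return leaders


def cas_stage(genomes: Sequence[Genome],
              arrays_by_genome: dict[str, list[CrisprArray]],
              refs) -> dict[str, dict[str, CasOperonCall]]:
    return {g.genome_id: annotate_genome_cas(g, arrays_by_genome[g.genome_id], refs)
            for g in genomes}


def core_alignment(genomes: Sequence[Genome],
                   core: Sequence[GeneFamily]) -> dict[str, str]:
    """Per-genome concatenation of core genes whose members share one length."""
    contig_seq = {g.genome_id: dict(g.contigs) for g in genomes}
    concat = {g.genome_id: [] for g in genomes}
    for fam in sorted(core, key=lambda f: f.family_id):
        if set(fam.members) != set(concat):
            continue
        seqs = {gid: gene.nucleotide_seq(contig_seq[gid][gene.contig_id])
                for gid, gene in fam.members.items()}
        if len({len(s) for s in seqs.values()}) != 1:
            continue  # indel-bearing family: unalignable without gaps
        for gid, s in seqs.items():
            concat[gid].append(s)
    out = {gid: "".join(parts) for gid, parts in concat.items()}
    if any(not s for s in out.values()):
        raise PipelineError("evolution", "no shared equal-length core families")
    return out


def _chromosomes_as_elements(genomes: Sequence[Genome]) -> list[MobileElement]:
    """Wrap each genome's chromosome as a searchable element (for self-targets)."""
    out = []
    for g in genomes:
        for contig_id, seq in g.contigs:
            out.append(MobileElement(
                element_id=g.genome_id, seq=seq, element_class="chromosome",
                genes=[gr for gr in g.genes if gr.contig_id == contig_id],
                spans=[(s, e, cls) for cid, s, e, cls in g.element_spans
                       if cid == contig_id],
            ))
    return out


def _cas_spans(operon_calls: dict[str, dict[str, CasOperonCall]],
               elements: Sequence[MobileElement]) -> dict[str, list[tuple[int, int]]]:
    """cas-gene coordinate spans per element id (called operons + annotated pool genes)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for gid, calls in operon_calls.items():
        for call in calls.values():
            for gc in list(call.gene_calls) + list(call.stray_calls):
                spans.setdefault(gid, []).append((gc.start, gc.end))
    for e in elements:
        for gr in e.genes:
            if gr.product in _ALL_CAS_NAMES:
                spans.setdefault(e.element_id, []).append((gr.start, gr.end))
    return spans


# ---------------------------------------------------------------------------
# Tables

def _arrays_table(arrays_by_genome: dict[str, list[CrisprArray]]) -> pd.DataFrame:
    rows = []
    for gid in sorted(arrays_by_genome):
        for arr in sorted(arrays_by_genome[gid], key=lambda a: (a.contig_id, a.start)):
            rows.append({
                "genome_id": gid, "contig_id": arr.contig_id, "array_id": arr.array_id,
                "locus": arr.locus, "start": arr.start, "end": arr.end,
                "n_repeats": arr.n_repeats, "n_spacers": len(arr.spacers),
                "orientation": arr.orientation,
                "consensus": arr.consensus.seq if arr.consensus else "",
                "disrupted": bool(arr.disrupted_segments),
                "terminal_5_degenerate": bool(arr.flags.get("terminal_5_degenerate")),
                "terminal_3_degenerate": bool(arr.flags.get("terminal_3_degenerate")),
            })
    return pd.DataFrame(rows, columns=[
        "genome_id", "contig_id", "array_id", "locus", "start", "end", "n_repeats",
        "n_spacers", "orientation", "consensus", "disrupted",
        "terminal_5_degenerate", "terminal_3_degenerate"])


def _leaders_table(leaders) -> pd.DataFrame:
    cols = ["genome_id", "array_id", "start", "end", "side", "at_fraction",
            "conservation", "significant"]
    rows = [{c: getattr(l, c) for c in cols} for l in leaders]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["genome_id", "array_id"], ignore_index=True) if len(df) else df


def _cas_table(operon_calls: dict[str, dict[str, CasOperonCall]]) -> pd.DataFrame:
    rows = []
    for gid in sorted(operon_calls):
        for subtype in sorted(operon_calls[gid]):
            call = operon_calls[gid][subtype]
            n_intact = sum(gc.status == "intact" for gc in call.gene_calls)
            n_pseudo = sum(gc.status == "pseudo" for gc in call.gene_calls)
            rows.append({
                "genome_id": gid, "subtype": subtype, "status": call.status,
                "n_intact": n_intact, "n_pseudo": n_pseudo,
                "co_oriented": call.co_oriented, "adjacent_locus": call.adjacent_locus,
            })
    return pd.DataFrame(rows, columns=["genome_id", "subtype", "status", "n_intact",
                                       "n_pseudo", "co_oriented", "adjacent_locus"])


def _hits_table(hits) -> pd.DataFrame:
    cols = ["spacer_id", "genome_id", "locus", "element_id", "start", "end",
            "strand", "mismatches", "identity", "target_class", "genic",
            "coding_strand"]
    rows = [{c: getattr(h, c) for c in cols} for h in hits]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["spacer_id", "element_id", "start"], ignore_index=True) if len(df) else df


def _kv_table(d: dict) -> pd.DataFrame:
    flat = {}

    def walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k in sorted(obj):
                walk(f"{prefix}{k}.", obj[k])
        else:
            flat[prefix.rstrip(".")] = obj

    walk("", d)
    return pd.DataFrame({"key": list(flat), "value": [str(v) for v in flat.values()]})


# ---------------------------------------------------------------------------
# Orchestration

def run_detect(config: PipelineConfig) -> ReportBundle:
    """Detection only: arrays table (loci unanchored, orientation unknown)."""
    genomes, _, _ = load_inputs(config)
    arrays_by_genome = detect_stage(genomes, config.detector, config.threads)
    bundle = ReportBundle()
    bundle.tables["arrays"] = _arrays_table(arrays_by_genome)
    return bundle


def run_annotate(config: PipelineConfig) -> ReportBundle:
    """Detection through cas annotation: arrays, leaders and operon tables."""
    genomes, _, _ = load_inputs(config)
    arrays_by_genome = detect_stage(genomes, config.detector, config.threads)
    core = core_genome(genomes)
    anchor_stage(genomes, arrays_by_genome, core)
    leaders = leader_stage(genomes, arrays_by_genome)
    refs = load_cas_refs(fasta_path=config.cas_refs_fasta)
    operon_calls = cas_stage(genomes, arrays_by_genome, refs)
    bundle = ReportBundle()
    bundle.tables["arrays"] = _arrays_table(arrays_by_genome)
    bundle.tables["leaders"] = _leaders_table(leaders)
    bundle.tables["cas_operons"] = _cas_table(operon_calls)
    return bundle


def run_all(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and return the full table bundle (written to
    ``config.out_dir`` by the CLI).  Deterministic for a fixed config."""
    logging.basicConfig(level=config.log_level)
    sub = np.random.default_rng(config.seed).integers(2**31, size=4)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    genomes, elements, truth = stage("input", load_inputs, config)
    log.info("stage=input genomes=%d elements=%d", len(genomes), len(elements))

    arrays_by_genome = stage("detect", detect_stage, genomes, config.detector,
                             config.threads)
    n_arrays = sum(len(a) for a in arrays_by_genome.values())
    log.info("stage=detect arrays=%d", n_arrays)

    core = stage("anchor", core_genome, genomes)
    stage("anchor", anchor_stage, genomes, arrays_by_genome, core)
    log.info("stage=anchor core_families=%d", len(core))

    leaders = stage("leader", leader_stage, genomes, arrays_by_genome)
    log.info("stage=leader leaders=%d", len(leaders))

    refs = stage("cas", load_cas_refs, fasta_path=config.cas_refs_fasta)
    operon_calls = stage("cas", cas_stage, genomes, arrays_by_genome, refs)
    n_present = sum(c.status != "absent" for calls in operon_calls.values()
                    for c in calls.values())
    log.info("stage=cas operons_present=%d", n_present)

    core_seqs = stage("evolution", core_alignment, genomes, core)
    D = stage("evolution", distance_matrix, core_seqs)
    groups = stage("evolution", group_close_strains, D, config.grouping_threshold)
    log.info("stage=evolution groups=%d", len(groups))

    occurrences = stage("atlas", occurrences_from_arrays, arrays_by_genome)
    clusters = stage("atlas", cluster_spacers, occurrences,
                     [g.members for g in groups])
    atlas = stage("atlas", atlas_stats, clusters)
    polarity = stage("atlas", polarity_profile, clusters, n_perm=config.n_perm,
                     seed=int(sub[0]))
    duplications = stage("atlas", detect_duplications, clusters)
    log.info("stage=atlas occurrences=%d clusters=%d", len(occurrences), len(clusters))

    queries = [ProtoQuery(spacer_id=f"{o.array_id}:{o.index_from_leader}",
                          seq=o.seq, genome_id=o.genome_id, locus=o.locus)
               for o in occurrences]
    chrom_elements = _chromosomes_as_elements(genomes)
    array_spans = {g.genome_id: [(arr.start - 100, arr.end + 100)
                                 for arr in arrays_by_genome[g.genome_id]]
                   for g in genomes}
    pool_hits = stage("protospacer", search_protospacers, queries, elements,
                      min_identity=config.min_proto_identity)
    chrom_hits = stage("protospacer", search_protospacers, queries, chrom_elements,
                       min_identity=config.min_proto_identity,
                       exclude_spans=array_spans)
    cas_spans = _cas_spans(operon_calls, elements)
    stage("protospacer", classify_hits, pool_hits, elements, cas_spans=cas_spans)
    stage("protospacer", classify_hits, chrom_hits, chrom_elements, cas_spans=cas_spans)
    context = stage("protospacer", context_stats, pool_hits, elements)
    ownership = {g.genome_id: {g.genome_id} for g in genomes}
    selfs = stage("protospacer", self_targets, chrom_hits, ownership)
    anti_flags, anti_conflicts = stage("protospacer", detect_anti_crispr,
                                       occurrences, operon_calls, refs,
                                       min_identity=config.min_proto_identity)
    log.info("stage=protospacer pool_hits=%d self_targets=%d anti_flags=%d",
             len(pool_hits), len(selfs), len(anti_flags))

    counts = {gid: {arr.locus: arr.n_repeats for arr in arrays}
              for gid, arrays in arrays_by_genome.items()}
    paired = sorted(gid for gid in counts
                    if "CRISPR1" in counts[gid] and "CRISPR2" in counts[gid])
    correlation = None
    if len(paired) >= 3:
        x = [counts[g]["CRISPR1"] for g in paired]
        y = [counts[g]["CRISPR2"] for g in paired]
        if len(set(x)) > 1 and len(set(y)) > 1:
            correlation = stage("evolution", repeat_correlation, x, y,
                                n_perm=config.n_perm, seed=int(sub[1]))

    est_rows = []
    for grp in groups:
        for i, a in enumerate(grp.members):
            for b in grp.members[i + 1:]:
                est = divergence_estimate(D.get(a, b), config.divergence)
                est_rows.append({"genome_a": a, "genome_b": b, "d": est.d,
                                 "years_clock": est.years_clock,
                                 "generations_neutral": est.generations_neutral,
                                 "years_neutral": est.years_neutral})

    bundle = ReportBundle()
    bundle.tables["arrays"] = _arrays_table(arrays_by_genome)
    bundle.tables["leaders"] = _leaders_table(leaders)
    bundle.tables["cas_operons"] = _cas_table(operon_calls)
    dist_df = pd.DataFrame(D.d, columns=D.labels)
    dist_df.insert(0, "genome_id", D.labels)
    bundle.tables["distances"] = dist_df
    bundle.tables["groups"] = pd.DataFrame(
        [{"group": g.representative, "members": ",".join(g.members)} for g in groups],
        columns=["group", "members"])
    bundle.tables["atlas_summary"] = _kv_table(atlas)
    bundle.tables["clusters"] = pd.DataFrame(
        [{"cluster_id": c.cluster_id, "spacer": c.key,
          "n_occurrences": len(c.occurrences),
          "n_genomes": len({o.genome_id for o in c.occurrences}),
          "loci": ",".join(sorted(c.loci)), "singleton": c.is_singleton}
         for c in clusters],
        columns=["cluster_id", "spacer", "n_occurrences", "n_genomes", "loci",
                 "singleton"])
    bundle.tables["polarity"] = pd.DataFrame([{
        "statistic": polarity.statistic, "null_low": polarity.null_low,
        "null_high": polarity.null_high, "p_perm": polarity.p_perm,
        "n_singleton": polarity.n_singleton, "n_shared": polarity.n_shared,
        "n_arrays": polarity.n_arrays, "reason": polarity.reason or ""}])
    bundle.tables["duplications"] = pd.DataFrame(
        duplications, columns=["cluster_id", "genome_id", "kind", "copies"])
    bundle.tables["protospacer_hits"] = _hits_table(pool_hits)
    bundle.tables["self_targets"] = _hits_table(selfs)
    bundle.tables["hit_context"] = _kv_table(context)
    bundle.tables["anti_crispr"] = pd.DataFrame(
        [{"genome_id": f.genome_id, "array_id": f.array_id, "subtype": f.subtype,
          "matched_cas_genes": ",".join(sorted(f.matched_cas_genes))}
         for f in anti_flags],
        columns=["genome_id", "array_id", "subtype", "matched_cas_genes"])
    bundle.tables["anti_crispr_conflicts"] = pd.DataFrame(
        [{"genome_id": c["genome_id"], "array_id": c["array_id"],
          "subtype": c["subtype"],
          "matched_cas_genes": ",".join(sorted(c["matched_cas_genes"]))}
         for c in anti_conflicts],
        columns=["genome_id", "array_id", "subtype", "matched_cas_genes"])
    bundle.tables["correlation"] = pd.DataFrame(
        [] if correlation is None else
        [{"locus_x": "CRISPR1", "locus_y": "CRISPR2",
          "r_squared": correlation.r_squared, "p_perm": correlation.p_perm,
          "n": correlation.n}],
        columns=["locus_x", "locus_y", "r_squared", "p_perm", "n"])
    bundle.tables["divergence_estimates"] = pd.DataFrame(
        est_rows, columns=["genome_a", "genome_b", "d", "years_clock",
                           "generations_neutral", "years_neutral"])
    bundle.tables["run_parameters"] = pd.DataFrame(
        [{"key": "seed", "value": str(config.seed)},
         {"key": "grouping_threshold", "value": str(config.grouping_threshold)},
         {"key": "min_proto_identity", "value": str(config.min_proto_identity)},
         {"key": "n_perm", "value": str(config.n_perm)},
         {"key": "mode", "value": "synthetic" if config.synth else "real"}])
    log.info("stage=report tables=%d checksum=%s", len(bundle.tables),
             bundle.checksum()[:12])
    return bundle
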