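"""Cas gene / pseudogene calling and operon subtype assignment.

Two CRISPR/cas subtypes are modelled: the Ecoli subtype of 8 successive
co-oriented genes (cas2, cas1, cse3, cas5, cse4, cse2, cse1, cas3), found
beside CRISPR1 arrays, and the Ypest subtype of 6 co-oriented genes (cas1,
cas3, csy1-csy4), found between CRISPR3 and CRISPR4.  Intact genes are
recognised by best-hit similarity of annotated CDS against bundled reference
proteins; decayed copies (frameshifts, internal stops, truncations) are
recovered by a six-frame translated scan of the raw sequence, which also
verifies the absence of cas copies elsewhere in the genome.

The bundled reference sets are synthetic stand-ins with realistic gene
lengths, generated deterministically; real reference proteins can be supplied
as FASTA instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from Bio import SeqIO

from .genome_io import Genome, GeneRecord, translate_cds, reverse_complement
from .locus_map import protein_similarity, _blosum

__all__ = [
    "ECOLI_CAS_GENES",
    "YPEST_CAS_GENES",
    "CasRef",
    "CasGeneCall",
    "CasOperonCall",
    "load_cas_refs",
    "call_cas",
    "find_pseudogenes",
    "operon_status",
    "annotate_genome_cas",
]

ECOLI_CAS_GENES = ["cas2", "cas1", "cse3", "cas5", "cse4", "cse2", "cse1", "cas3"]
YPEST_CAS_GENES = ["cas1", "cas3", "csy1", "csy2", "csy3", "csy4"]
_CANONICAL = {"Ecoli": ECOLI_CAS_GENES, "Ypest": YPEST_CAS_GENES}


@dataclass
class CasRef:
    subtype: str
    gene_name: str
    cds: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.gene_name not in _CANONICAL.get(self.subtype, []):
            raise ValueError(f"{self.gene_name} is not a {self.subtype}-subtype gene")
        if not self.protein:
            self.protein = translate_cds(self.cds)


@dataclass
class CasGeneCall:
    gene_name: str
    subtype: str
    contig_id: str
    start: int
    end: int
    strand: str
    status: str  # intact | pseudo
    similarity: float
    evidence: str  # cds_hit | translated_scan
    coverage: float = 1.0
    defects: list[str] = field(default_factory=list)  # frameshift, internal_stop, truncation


@dataclass
class CasOperonCall:
    subtype: str
    gene_calls: list[CasGeneCall]
    status: str  # complete | partial | absent
    co_oriented: bool
    adjacent_locus: str = "unanchored"
    stray_calls: list[CasGeneCall] = field(default_factory=list)


def load_cas_refs(subtype: Optional[str] = None,
                  fasta_path: Optional[str] = None) -> list[CasRef]:
    """Load reference Cas CDS sets (bundled synthetic files by default)."""
    refs: list[CasRef] = []
    if fasta_path is not None:
        for rec in SeqIO.parse(fasta_path, "fasta"):
            sub, name = rec.id.split("_", 1)
            refs.append(CasRef(sub, name, str(rec.seq).upper()))
        return refs
    files = {"Ecoli": "synthetic_cas_ecoli_cds.fasta", "Ypest": "synthetic_cas_ypest_cds.fasta"}
    wanted = [subtype] if subtype else ["Ecoli", "Ypest"]
    for sub in wanted:
        path = resources.files("crispratlas").joinpath("data", files[sub])
        with resources.as_file(path) as p:
            for rec in SeqIO.parse(str(p), "fasta"):
                _, name = rec.id.split("_", 1)
                refs.append(CasRef(sub, name, str(rec.seq).upper()))
    return refs


# ---------------------------------------------------------------------------
# CDS-based calling


def call_cas(
    genome: Genome,
    region: tuple[str, int, int],
    refs: Sequence[CasRef],
    min_similarity: float = 0.35,
) -> list[CasGeneCall]:
    """Call cas genes among the annotated CDS of a genomic region.

    Each CDS is assigned its best-scoring reference gene when the positives
    fraction reaches ``min_similarity``; a CDS with an internal stop or less
    than 80% of the reference length is a pseudogene call.
    """
    contig_id, lo, hi = region
    calls: list[CasGeneCall] = []
    for gene in genome.coding_genes():
        if gene.contig_id != contig_id or gene.end <= lo or gene.start >= hi:
            continue
        prot = genome.gene_protein(gene)
        best_ref, best_sim = None, -1.0
        for ref in refs:
            s = protein_similarity(prot, ref.protein)
            if s > best_sim:
                best_ref, best_sim = ref, s
        if best_ref is None or best_sim < min_similarity:
            continue
        defects = []
        if "*" in prot:
            defects.append("internal_stop")
        if len(prot) < 0.8 * len(best_ref.protein):
            defects.append("truncation")
        calls.append(
            CasGeneCall(
                gene_name=best_ref.gene_name, subtype=best_ref.subtype,
                contig_id=gene.contig_id, start=gene.start, end=gene.end,
                strand=gene.strand, status="pseudo" if defects else "intact",
                similarity=best_sim, evidence="cds_hit",
                coverage=len(prot) / len(best_ref.protein), defects=defects,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Six-frame translated scan (pseudogene discovery)

_SEED_K = 5
_XDROP = 20.0


def _translate_frames(seq: str):
    """Yield (strand, frame, protein-with-stops) for the six frames."""
    rc = reverse_complement(seq)
    from Bio.Seq import Seq

    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            yield strand, frame, str(Seq(sub).translate(table=11))


def _score(x: str, y: str) -> float:
    try:
        return float(_blosum[x, y])
    except KeyError:
        return -4.0


def _extend_seed(prot: str, ref: str, p: int, r: int) -> tuple[int, int, int, int, float, int]:
    """Ungapped X-drop extension of a seed; returns segment coords and stats."""
    # right
    score = best = 0.0
    i = j = 0
    best_i = 0
    while p + _SEED_K + i < len(prot) and r + _SEED_K + i < len(ref):
        a = prot[p + _SEED_K + i]
        if a == "*":
            break
        score += _score(a, ref[r + _SEED_K + i])
        i += 1
        if score > best:
            best, best_i = score, i
        elif best - score > _XDROP:
            break
    right = best_i
    score = best = 0.0
    best_j = 0
    while p - j - 1 >= 0 and r - j - 1 >= 0:
        a = prot[p - j - 1]
        if a == "*":
            break
        score += _score(a, ref[r - j - 1])
        j += 1
        if score > best:
            best, best_j = score, j
        elif best - score > _XDROP:
            break
    left = best_j
    ps, pe = p - left, p + _SEED_K + right
    rs, re = r - left, r + _SEED_K + right
    positives = sum(1 for a, b in zip(prot[ps:pe], ref[rs:re]) if _score(a, b) > 0)
    return ps, pe, rs, re, positives / (pe - ps), pe - ps


def _prot_to_genome(strand: str, frame: int, p_start: int, p_end: int, n: int) -> tuple[int, int]:
    if strand == "+":
        return frame + 3 * p_start, frame + 3 * p_end
    return n - (frame + 3 * p_end), n - (frame + 3 * p_start)


def find_pseudogenes(
    genome: Genome,
    refs: Sequence[CasRef],
    min_similarity: float = 0.35,
    min_coverage: float = 0.3,
    cluster_gap: int = 3000,
    min_relic_similarity: float = 0.7,
) -> list[CasGeneCall]:
    """Six-frame translated scan of the whole genome for cas gene remnants.

    Exact amino-acid seed words shared with a reference protein are extended
    without gaps (X-drop, hard stop at '*').  Segments matching the same
    reference within ``cluster_gap`` are clustered into one locus; a locus
    covering at least ``min_coverage`` of the reference at ``min_similarity``
    positives is called.  A locus needing multiple frames is a frameshift, one
    split by a stop codon an internal stop, and one covering less than 80% of
    the reference a truncation -- all pseudo; otherwise the call is intact.
    Because the scan is genome-wide it also reveals cas copies outside the
    CRISPR-associated regions.
    """
    seeds: dict[str, list[tuple[int, int]]] = {}
    for ridx, ref in enumerate(refs):
        prot = ref.protein
        for i in range(len(prot) - _SEED_K + 1):
            seeds.setdefault(prot[i : i + _SEED_K], []).append((ridx, i))

    calls: list[CasGeneCall] = []
    for contig_id, seq in genome.contigs:
        n = len(seq)
        # segments[ridx] -> list of (gstart, gend, rstart, rend, sim, strand, frame)
        segments: dict[int, list[tuple]] = {}
        for strand, frame, prot in _translate_frames(seq):
            done: set[tuple[int, int]] = set()  # (ridx, diagonal)
            for p in range(len(prot) - _SEED_K + 1):
                hits = seeds.get(prot[p : p + _SEED_K])
                if not hits:
                    continue
                for ridx, r in hits:
                    diag = p - r
                    if (ridx, diag) in done:
                        continue
                    done.add((ridx, diag))
                    ps, pe, rs, re, sim, length = _extend_seed(prot, refs[ridx].protein, p, r)
                    if length < 20 or sim < min_similarity:
                        continue
                    gs, ge = _prot_to_genome(strand, frame, ps, pe, n)
                    segments.setdefault(ridx, []).append((gs, ge, rs, re, sim, strand, frame))
        for ridx, segs in segments.items():
            ref = refs[ridx]
            segs.sort()
            # drop segments fully contained in a longer one on the same strand
            pruned = []
            for s in segs:
                if any(o is not s and o[0] <= s[0] and s[1] <= o[1] and o[5] == s[5]
                       and (o[1] - o[0]) > (s[1] - s[0]) for o in segs):
                    continue
                pruned.append(s)
            clusters: list[list[tuple]] = []
            for s in pruned:
                if clusters and s[0] - max(e for _, e, *_ in clusters[-1]) <= cluster_gap:
                    clusters[-1].append(s)
                else:
                    clusters.append([s])
            for cl in clusters:
                covered: set[int] = set()
                positives_w = 0.0
                for gs, ge, rs, re, sim, strand, frame in cl:
                    covered.update(range(rs, re))
                    positives_w += sim * (re - rs)
                coverage = len(covered) / len(ref.protein)
                total_len = sum(re - rs for _, _, rs, re, *_ in cl)
                sim = positives_w / total_len if total_len else 0.0
                if coverage < min_coverage or sim < min_similarity:
                    continue
                # short ungapped matches at ~0.4 similarity arise by chance in
                # megabase-scale scans; a real remnant retains either high
                # identity over its surviving segments or broad coverage
                if sim < min_relic_similarity and coverage < 0.6:
                    continue
                frames = {(s[5], s[6]) for s in cl}
                defects = []
                if len(frames) > 1:
                    defects.append("frameshift")
                elif len(cl) > 1:
                    defects.append("internal_stop")
                if coverage < 0.8:
                    defects.append("truncation")
                gstart = min(s[0] for s in cl)
                gend = max(s[1] for s in cl)
                strand = cl[0][5]
                calls.append(
                    CasGeneCall(
                        gene_name=ref.gene_name, subtype=ref.subtype,
                        contig_id=contig_id, start=gstart, end=gend,
                        strand=strand, status="pseudo" if defects else "intact",
                        similarity=sim, evidence="translated_scan",
                        coverage=coverage, defects=defects,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Operon assembly


def operon_status(calls: Sequence[CasGeneCall], subtype: str) -> CasOperonCall:
    """Completeness verdict for one genomic neighborhood's cas calls."""
    calls = list(calls)
    if any(c.subtype != subtype for c in calls):
        raise ValueError("operon_status received calls from mixed subtypes")
    if not calls:
        return CasOperonCall(subtype=subtype, gene_calls=[], status="absent", co_oriented=True)
    canonical = _CANONICAL[subtype]
    intact = {c.gene_name for c in calls if c.status == "intact"}
    co_oriented = len({c.strand for c in calls}) == 1
    complete = co_oriented and all(g in intact for g in canonical) and all(
        c.status == "intact" for c in calls
    )
    ordered = sorted(calls, key=lambda c: c.start)
    return CasOperonCall(
        subtype=subtype, gene_calls=ordered,
        status="complete" if complete else "partial", co_oriented=co_oriented,
    )


def annotate_genome_cas(
    genome: Genome,
    arrays: Sequence,
    refs: Sequence[CasRef],
    min_similarity: float = 0.35,
    region_pad: int = 10_000,
    adjacency: int = 5_000,
) -> dict[str, CasOperonCall]:
    """Per-subtype operon call for one genome.

    Annotated CDS in the CRISPR-associated regions are searched first; the
    whole genome is then scanned in six frames for decayed copies.  Scan hits
    overlapping a CDS call are discarded as redundant.  Each subtype's calls
    are grouped by proximity; the densest group becomes the operon and is
    assigned the locus of the nearest array within ``adjacency``.
    """
    regions = []
    for arr in arrays:
        regions.append((arr.contig_id, max(0, arr.start - region_pad), arr.end + region_pad))
    cds_calls: list[CasGeneCall] = []
    seen_regions: set[tuple] = set()
    for region in regions:
        if region in seen_regions:
            continue
        seen_regions.add(region)
        cds_calls.extend(call_cas(genome, region, refs, min_similarity))
    # deduplicate CDS picked up by overlapping regions
    uniq: dict[tuple, CasGeneCall] = {}
    for c in cds_calls:
        uniq[(c.contig_id, c.start, c.end, c.subtype)] = c
    cds_calls = list(uniq.values())

    scan_calls = find_pseudogenes(genome, refs, min_similarity)
    kept_scan = []
    for s in scan_calls:
        if any(c.contig_id == s.contig_id and s.start < c.end and c.start < s.end
               for c in cds_calls):
            continue
        kept_scan.append(s)

    out: dict[str, CasOperonCall] = {}
    for subtype in _CANONICAL:
        sub_calls = sorted(
            [c for c in cds_calls + kept_scan if c.subtype == subtype],
            key=lambda c: (c.contig_id, c.start),
        )
        if not sub_calls:
            out[subtype] = CasOperonCall(subtype=subtype, gene_calls=[], status="absent",
                                         co_oriented=True)
            continue
        groups: list[list[CasGeneCall]] = [[sub_calls[0]]]
        for c in sub_calls[1:]:
            prev = groups[-1][-1]
            if c.contig_id == prev.contig_id and c.start - prev.end <= adjacency:
                groups[-1].append(c)
            else:
                groups.append([c])
        main = max(groups, key=lambda g: (len(g), -g[0].start))
        call = operon_status(main, subtype)
        call.stray_calls = [c for g in groups if g is not main for c in g]
        lo = min(c.start for c in main)
        hi = max(c.end for c in main)
        best_locus, best_d = "unanchored", adjacency + 1
        for arr in arrays:
            if arr.contig_id != main[0].contig_id:
                continue
            d = max(0, max(arr.start - hi, lo - arr.end))
            if d <= adjacency and d < best_d:
                best_locus, best_d = arr.locus, d
        call.adjacent_locus = best_locus
        out[subtype] = call
    return out
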