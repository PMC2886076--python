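"""Orthology, core genome, locus anchoring and leader identification.

Orthologs are unique reciprocal best hits between protein sets (similarity =
fraction of positively-scoring aligned positions under BLOSUM62, global
alignment), refined by gene-order conservation.  CRISPR arrays are named by
the ordered pair of their nearest flanking core anchors:

    cysD-cysJ -> CRISPR1        cysJ-ygcF    -> CRISPR2
    clpS-tRNA-Ser -> CRISPR3    tRNA-Ser-infA -> CRISPR4

Leaders are found as the CRISPR flank that is conserved across genomes
sharing a locus, judged against the conservation of the opposite flank.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, GeneRecord
from .crispr_detect import CrisprArray

__all__ = [
    "LOCUS_ANCHORS",
    "ANCHOR_NAMES",
    "OrthologPair",
    "GeneFamily",
    "Leader",
    "protein_similarity",
    "rbh_orthologs",
    "synteny_refine",
    "core_genome",
    "anchor_locus",
    "find_leader",
]

LOCUS_ANCHORS = {
    ("cysD", "cysJ"): "CRISPR1",
    ("cysJ", "ygcF"): "CRISPR2",
    ("clpS", "tRNA-Ser"): "CRISPR3",
    ("tRNA-Ser", "infA"): "CRISPR4",
}
ANCHOR_NAMES = {name for pair in LOCUS_ANCHORS for name in pair} | {"aat"}

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11
_aligner.extend_gap_score = -1
_blosum = substitution_matrices.load("BLOSUM62")


def protein_similarity(a: str, b: str) -> float:
    """Positives fraction of a global BLOSUM62 alignment of two proteins.

    Counts aligned residue pairs with a positive substitution score and
    divides by the total alignment length (gap columns included), so the
    value is 1.0 only for identical sequences and decreases with both
    substitutions and indels.
    """
    if not a or not b:
        return 0.0
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    aln = _aligner.align(a, b)[0]
    positives = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            try:
                if _blosum[x, y] > 0:
                    positives += 1
            except KeyError:
                continue
    length = aln.shape[1]
    return positives / length if length else 0.0


@dataclass
class OrthologPair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    similarity: float
    length_diff: float


@dataclass
class GeneFamily:
    """One core-gene family: exactly one member per genome."""

    family_id: str
    members: dict[str, GeneRecord]  # genome_id -> gene


@dataclass
class Leader:
    genome_id: str
    array_id: str
    start: int
    end: int
    side: str  # left | right | unknown
    at_fraction: float
    conservation: float
    significant: bool


# ---------------------------------------------------------------------------
# Reciprocal best hits


def _kmer_set(prot: str, k: int = 4) -> set[str]:
    return {prot[i : i + k] for i in range(len(prot) - k + 1)}


class _SimilarityCache:
    def __init__(self) -> None:
        self._memo: dict[tuple[str, str], float] = {}

    def __call__(self, ga: GeneRecord, pa: str, gb: GeneRecord, pb: str) -> float:
        key = (ga.gene_id, gb.gene_id)
        if key not in self._memo:
            sim = protein_similarity(pa, pb)
            self._memo[key] = sim
            self._memo[(gb.gene_id, ga.gene_id)] = sim
        return self._memo[key]


def rbh_orthologs(
    genome_a: Genome,
    genome_b: Genome,
    min_similarity: float = 0.6,
    max_length_diff: float = 0.2,
    candidates: Optional[int] = None,
    _cache: Optional[_SimilarityCache] = None,
) -> list[OrthologPair]:
    """Unique pairwise reciprocal best hits between two genomes' proteins.

    A pair is reported iff each gene is the other's best hit under the
    similarity measure, the similarity is at least ``min_similarity`` and the
    protein length difference is below ``max_length_diff``.  ``candidates``
    optionally prescreens hits by shared amino-acid 4-mers (top-N aligned
    per query) to avoid the full all-vs-all alignment; with ``None`` every
    pair is aligned.
    """
    genes_a = genome_a.coding_genes()
    genes_b = genome_b.coding_genes()
    prots_a = {g.gene_id: genome_a.gene_protein(g) for g in genes_a}
    prots_b = {g.gene_id: genome_b.gene_protein(g) for g in genes_b}
    if not genes_a or not genes_b:
        return []
    sim = _cache or _SimilarityCache()

    kmers_b = {g.gene_id: _kmer_set(prots_b[g.gene_id]) for g in genes_b}
    kmers_a = {g.gene_id: _kmer_set(prots_a[g.gene_id]) for g in genes_a}

    def best_hit(g, prot, others, prots_o, kmers_o):
        pool = others
        if candidates is not None and len(others) > candidates:
            mine = _kmer_set(prot)
            scored = sorted(
                others,
                key=lambda o: (-len(mine & kmers_o[o.gene_id]), o.gene_id),
            )
            pool = scored[:candidates]
        best, best_sim = None, -1.0
        for o in sorted(pool, key=lambda o: o.gene_id):
            s = sim(g, prot, o, prots_o[o.gene_id])
            if s > best_sim:
                best, best_sim = o, s
        return best, best_sim

    best_a = {g.gene_id: best_hit(g, prots_a[g.gene_id], genes_b, prots_b, kmers_b)
              for g in genes_a}
    best_b = {g.gene_id: best_hit(g, prots_b[g.gene_id], genes_a, prots_a, kmers_a)
              for g in genes_b}

    pairs: list[OrthologPair] = []
    for g in genes_a:
        hit, s = best_a[g.gene_id]
        if hit is None:
            continue
        back, _ = best_b[hit.gene_id]
        if back is None or back.gene_id != g.gene_id:
            continue
        la, lb = len(prots_a[g.gene_id]), len(prots_b[hit.gene_id])
        ldiff = abs(la - lb) / max(la, lb)
        if s >= min_similarity and ldiff < max_length_diff:
            pairs.append(OrthologPair(g, hit, s, ldiff))
    return pairs


def synteny_refine(
    pairs: Sequence[OrthologPair], genome_a: Genome, genome_b: Genome,
    neighborhood: int = 2, percentile: float = 95.0,
) -> list[OrthologPair]:
    """Drop RBH pairs lying outside conserved gene neighborhoods.

    A pair survives if one of its up-to-``neighborhood`` flanking genes on
    either side maps (via another RBH pair) to a flanking gene of its
    partner, or if its similarity exceeds the given percentile of all pair
    similarities.  Output is always a subset of the input.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    order_a = {g.gene_id: i for i, g in enumerate(
        sorted(genome_a.coding_genes(), key=lambda g: (g.contig_id, g.start)))}
    order_b = {g.gene_id: i for i, g in enumerate(
        sorted(genome_b.coding_genes(), key=lambda g: (g.contig_id, g.start)))}
    partner = {p.gene_a.gene_id: p.gene_b.gene_id for p in pairs}
    sims = np.array([p.similarity for p in pairs])
    cutoff = float(np.percentile(sims, percentile))
    kept = []
    for p in pairs:
        ia, ib = order_a[p.gene_a.gene_id], order_b[p.gene_b.gene_id]
        conserved = False
        for other in pairs:
            if other is p:
                continue
            ja = order_a[other.gene_a.gene_id]
            jb = order_b[other.gene_b.gene_id]
            if 0 < abs(ja - ia) <= neighborhood and 0 < abs(jb - ib) <= neighborhood:
                conserved = True
                break
        if conserved or p.similarity > cutoff:
            kept.append(p)
    return kept


def core_genome(
    genomes: Sequence[Genome],
    min_similarity: float = 0.6,
    max_length_diff: float = 0.2,
    refine: bool = True,
    candidates: Optional[int] = None,
) -> list[GeneFamily]:
    """Gene families present exactly once in every genome.

    Built as the intersection of the pairwise RBH lists against the first
    genome (the reference), then verified for consistency: every within-family
    protein pair must itself pass the similarity/length thresholds, dropping
    families whose pairwise relations are not transitive.
    """
    if len(genomes) < 2:
        raise ValueError("core_genome requires at least two genomes")
    ref = genomes[0]
    cache = _SimilarityCache()
    maps: list[dict[str, GeneRecord]] = []
    for g in genomes[1:]:
        pairs = rbh_orthologs(ref, g, min_similarity, max_length_diff,
                              candidates=candidates, _cache=cache)
        if refine:
            pairs = synteny_refine(pairs, ref, g)
        maps.append({p.gene_a.gene_id: p.gene_b for p in pairs})

    prots = {gm.genome_id: {g.gene_id: gm.gene_protein(g) for g in gm.coding_genes()}
             for gm in genomes}
    families: list[GeneFamily] = []
    for gene in ref.coding_genes():
        if not all(gene.gene_id in m for m in maps):
            continue
        members = {ref.genome_id: gene}
        for gm, m in zip(genomes[1:], maps):
            members[gm.genome_id] = m[gene.gene_id]
        # all-pairs consistency check within the family
        ok = True
        ids = sorted(members)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ga, gb = members[ids[i]], members[ids[j]]
                pa, pb = prots[ids[i]][ga.gene_id], prots[ids[j]][gb.gene_id]
                ldiff = abs(len(pa) - len(pb)) / max(len(pa), len(pb))
                if ldiff >= max_length_diff or cache(ga, pa, gb, pb) < min_similarity:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            families.append(GeneFamily(family_id=gene.gene_id, members=members))
    return families


# ---------------------------------------------------------------------------
# Locus anchoring


def anchor_locus(
    array: CrisprArray,
    genome: Genome,
    core: Optional[Sequence[GeneFamily]] = None,
    search_radius: int = 30_000,
) -> str:
    """Locus label from the ordered pair of nearest flanking core anchors.

    Anchors are genes named after the canonical core markers; CDS anchors
    must additionally belong to a core family when one is supplied (tRNA
    anchors are matched by name).  Invariant under contig reverse
    complementation: both orders of the flanking pair are looked up.
    """
    core_ids: Optional[set[str]] = None
    if core is not None:
        core_ids = {m.gene_id for fam in core for m in fam.members.values()}
    anchors = []
    for g in genome.genes:
        if g.contig_id != array.contig_id or g.product not in ANCHOR_NAMES:
            continue
        if g.feature_type == "CDS" and core_ids is not None and g.gene_id not in core_ids:
            continue
        anchors.append(g)
    left = [g for g in anchors if g.end <= array.start and array.start - g.end <= search_radius]
    right = [g for g in anchors if g.start >= array.end and g.start - array.end <= search_radius]
    if not left or not right:
        return "unanchored"
    lg = max(left, key=lambda g: g.end)
    rg = min(right, key=lambda g: g.start)
    for pair in ((lg.product, rg.product), (rg.product, lg.product)):
        if pair in LOCUS_ANCHORS:
            return LOCUS_ANCHORS[pair]
    return "unanchored"


# ---------------------------------------------------------------------------
# Leader identification


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "AT") / len(seq)


def _mean_pairwise_identity(flanks: list[str], anchored: str) -> float:
    """Mean pairwise Hamming identity of flank sequences.

    ``anchored`` is 'right' for left flanks (compared from the array edge
    outwards, i.e. suffix-aligned) and 'left' for right flanks.
    """
    usable = [f for f in flanks if f]
    if len(usable) < 2:
        return 0.0
    vals = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            n = min(len(a), len(b))
            if n == 0:
                continue
            if anchored == "right":
                a, b = a[-n:], b[-n:]
            else:
                a, b = a[:n], b[:n]
            vals.append(sum(1 for x, y in zip(a, b) if x == y and x != "N") / n)
    return float(np.mean(vals)) if vals else 0.0


def find_leader(
    locus_arrays: Sequence[tuple[Genome, CrisprArray]],
    flank_len: int = 200,
    conservation_floor: float = 0.70,
    asymmetry_margin: float = 0.15,
) -> list[Leader]:
    """Identify the leader flank of a locus by cross-genome conservation.

    The flank (left or right of the array) with the higher cross-genome mean
    identity is called the leader iff it beats the opposite flank by
    ``asymmetry_margin`` and exceeds ``conservation_floor``.  On success the
    arrays' orientation is set so the newest-spacer (5') end abuts the
    leader.  With a single genome significance is undefined and the leader is
    returned with ``significant=False``.
    """
    lefts, rights = [], []
    for genome, arr in locus_arrays:
        contig = genome.contig_seq(arr.contig_id)
        lefts.append(contig[max(0, arr.start - flank_len) : arr.start])
        rights.append(contig[arr.end : arr.end + flank_len])
    cons_left = _mean_pairwise_identity(lefts, anchored="right")
    cons_right = _mean_pairwise_identity(rights, anchored="left")

    significant = False
    side = "unknown"
    if len(locus_arrays) >= 2:
        if cons_left >= cons_right:
            side, cons, other = "left", cons_left, cons_right
        else:
            side, cons, other = "right", cons_right, cons_left
        significant = cons >= conservation_floor and (cons - other) >= asymmetry_margin
        if not significant:
            side = "unknown"

    leaders = []
    for (genome, arr), lf, rf in zip(locus_arrays, lefts, rights):
        if side == "left":
            span = (max(0, arr.start - flank_len), arr.start)
            seq, cons = lf, cons_left
            arr.orientation = "leader_left"
        elif side == "right":
            span = (arr.end, min(len(genome.contig_seq(arr.contig_id)), arr.end + flank_len))
            seq, cons = rf, cons_right
            arr.orientation = "leader_right"
        else:
            span = (max(0, arr.start - flank_len), arr.start)
            seq, cons = lf, cons_left
        leaders.append(
            Leader(
                genome_id=genome.genome_id, array_id=arr.array_id,
                start=span[0], end=span[1], side=side,
                at_fraction=_at_fraction(seq), conservation=cons,
                significant=significant,
            )
        )
    return leaders
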