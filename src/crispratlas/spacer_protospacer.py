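"""Spacer atlas construction and proto-spacer matching.

Spacers are clustered by exact sequence identity after strand normalisation
(a spacer and its reverse complement are the same spacer).  Redundant
near-identical strains can be collapsed to one representative per group
before singleton/shared calls are made, so that clonal resampling does not
inflate "shared" counts.

Proto-spacer search is exact-Hamming: a spacer of length L matches a window
iff (L - mismatches) / L > min_identity, on either strand.  The search is
seeded (pigeonhole over m+1 disjoint exact chunks, where m is the largest
permitted mismatch count), so megabase chromosome targets stay fast while
results equal a full sliding-window scan.
"""
from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cas_annot import CasOperonCall, CasRef
from .genome_io import MobileElement, reverse_complement

__all__ = [
    "SpacerOccurrence",
    "SpacerCluster",
    "ProtoQuery",
    "ProtospacerHit",
    "PolarityResult",
    "AntiCrisprFlag",
    "round_half_up",
    "occurrences_from_arrays",
    "cluster_spacers",
    "atlas_stats",
    "polarity_profile",
    "detect_duplications",
    "search_protospacers",
    "classify_hits",
    "context_stats",
    "hit_span",
    "self_targets",
    "detect_anti_crispr",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (report style)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class SpacerOccurrence:
    """One spacer at one array position in one genome."""

    genome_id: str
    array_id: str
    locus: str                 # e.g. "CRISPR1"; "" if the array is unplaced
    index_from_leader: int     # 0 = leader-proximal when oriented
    seq: str
    oriented: bool = True      # False when the array orientation is unknown


@dataclass
class SpacerCluster:
    """All occurrences of one distinct spacer (strand-normalised exact match)."""

    cluster_id: str
    key: str                   # canonical sequence: min(seq, revcomp(seq))
    occurrences: list[SpacerOccurrence] = field(default_factory=list)
    is_singleton: bool = True  # present in exactly one strain group

    @property
    def loci(self) -> set[str]:
        return {o.locus for o in self.occurrences if o.locus}

    @property
    def genomes(self) -> set[str]:
        return {o.genome_id for o in self.occurrences}


@dataclass
class ProtoQuery:
    """A distinct spacer to search for, with its source bookkeeping."""

    spacer_id: str
    seq: str
    genome_id: str = ""
    locus: str = ""


@dataclass
class ProtospacerHit:
    spacer_id: str
    genome_id: str             # genome the query spacer came from
    locus: str
    element_id: str
    start: int                 # 0-based half-open span on the element
    end: int
    strand: str                # '+' if the spacer matches the element forward strand
    mismatches: int
    identity: float
    target_class: str = ""     # phage / plasmid / prophage / cas / chromosome
    genic: Optional[bool] = None
    coding_strand: Optional[bool] = None


@dataclass
class PolarityResult:
    """Leader-polarity test: are singletons nearer the leader than shared spacers?"""

    statistic: Optional[float]     # mean shared index - mean singleton index
    null_low: Optional[float]
    null_high: Optional[float]
    p_perm: Optional[float]
    n_singleton: int
    n_shared: int
    n_arrays: int
    reason: str = ""               # non-empty when the statistic is undefined


@dataclass
class AntiCrisprFlag:
    genome_id: str
    array_id: str
    subtype: str
    matched_cas_genes: list[str]
    cognate_subtype_present: bool

    def __post_init__(self) -> None:
        if self.cognate_subtype_present:
            raise ValueError("anti-CRISPR flag requires the cognate subtype to be absent")


# ---------------------------------------------------------------------------
# Atlas construction

def occurrences_from_arrays(
    arrays_by_genome: dict[str, list],
) -> list[SpacerOccurrence]:
    """Flatten detected arrays into spacer occurrences in leader order.

    ``arrays_by_genome`` maps genome_id -> list of CrisprArray.  Arrays with
    unknown orientation keep their left-to-right spacer order and are marked
    unoriented (they are excluded from polarity statistics).
    """
    out: list[SpacerOccurrence] = []
    for genome_id in sorted(arrays_by_genome):
        for arr in arrays_by_genome[genome_id]:
            oriented = arr.orientation != "unknown"
            for idx, sp in enumerate(arr.spacers_in_leader_order()):
                out.append(SpacerOccurrence(
                    genome_id=genome_id, array_id=arr.array_id,
                    locus=arr.locus or "", index_from_leader=idx,
                    seq=sp.seq.upper(), oriented=oriented,
                ))
    return out


def _canonical(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def cluster_spacers(
    occurrences: Iterable[SpacerOccurrence],
    strain_groups: Optional[Sequence[Iterable[str]]] = None,
) -> list[SpacerCluster]:
    """Group occurrences into distinct spacers; call singleton vs shared.

    Two occurrences are the same spacer iff their sequences are identical
    after strand normalisation.  ``strain_groups`` (a partition of genome
    ids, e.g. from near-identical strain grouping) collapses each group to
    one effective strain: a cluster is a singleton iff its occurrences all
    come from one group (or one genome when no grouping is given).
    """
    group_of: dict[str, int] = {}
    if strain_groups is not None:
        for gi, members in enumerate(strain_groups):
            for m in members:
                group_of[m] = gi

    buckets: dict[str, list[SpacerOccurrence]] = defaultdict(list)
    for occ in occurrences:
        buckets[_canonical(occ.seq)].append(occ)

    clusters = []
    for i, key in enumerate(sorted(buckets)):
        occs = sorted(buckets[key],
                      key=lambda o: (o.genome_id, o.array_id, o.index_from_leader))
        effective = {group_of.get(o.genome_id, o.genome_id) for o in occs}
        clusters.append(SpacerCluster(
            cluster_id=f"sp{i:04d}", key=key, occurrences=occs,
            is_singleton=len(effective) == 1,
        ))
    return clusters


def atlas_stats(clusters: Sequence[SpacerCluster]) -> dict:
    """Summary counts of the spacer atlas, overall and per locus.

    Percentages are integers rounded half-up, matching report conventions.
    A cluster observed at several loci counts once per locus but once only
    in the totals.
    """
    loci = sorted({loc for c in clusters for loc in c.loci})
    per_locus = {}
    for loc in loci:
        here = [c for c in clusters if loc in c.loci]
        n_sing = sum(c.is_singleton for c in here)
        per_locus[loc] = {
            "distinct": len(here),
            "singletons": n_sing,
            "pct_singletons": round_half_up(100 * n_sing / len(here)) if here else 0,
        }
    n_total = len(clusters)
    n_sing = sum(c.is_singleton for c in clusters)
    n_occ = sum(len(c.occurrences) for c in clusters)
    return {
        "total_occurrences": n_occ,
        "distinct": n_total,
        "singletons": n_sing,
        "pct_singletons": round_half_up(100 * n_sing / n_total) if n_total else 0,
        "per_locus": per_locus,
    }


def polarity_profile(
    clusters: Sequence[SpacerCluster],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PolarityResult:
    """Test whether singleton spacers sit closer to the leader than shared ones.

    Statistic: mean leader index of singleton occurrences minus mean leader
    index of shared occurrences (negative = singletons leader-proximal).
    The null permutes singleton/shared labels within each array; ``p_perm``
    is the one-sided add-one-smoothed lower-tail probability, and
    ``null_low``/``null_high`` are the central 95% band of the null.
    Only occurrences from oriented arrays are used.
    """
    per_array: dict[tuple[str, str], list[tuple[int, bool]]] = defaultdict(list)
    skipped_unoriented = 0
    for c in clusters:
        for o in c.occurrences:
            if not o.oriented:
                skipped_unoriented += 1
                continue
            per_array[(o.genome_id, o.array_id)].append((o.index_from_leader, c.is_singleton))
    if skipped_unoriented:
        warnings.warn(f"polarity_profile: {skipped_unoriented} occurrences from "
                      "unoriented arrays excluded")

    idx_all: list[int] = []
    lab_all: list[bool] = []
    array_slices = []
    pos = 0
    for key in sorted(per_array):
        items = per_array[key]
        idx_all.extend(i for i, _ in items)
        lab_all.extend(s for _, s in items)
        array_slices.append((pos, pos + len(items)))
        pos += len(items)
    idx = np.asarray(idx_all, dtype=float)
    lab = np.asarray(lab_all, dtype=bool)
    n_sing, n_shared = int(lab.sum()), int((~lab).sum())
    if n_sing == 0 or n_shared == 0:
        return PolarityResult(None, None, None, None, n_sing, n_shared,
                              len(per_array),
                              reason="needs both singleton and shared spacers")

    def stat(labels: np.ndarray) -> float:
        return float(idx[labels].mean() - idx[~labels].mean())

    obs = stat(lab)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = lab.copy()
        for a, b in array_slices:
            perm[a:b] = rng.permutation(perm[a:b])
        # degenerate permutations (all one label) can only arise if the whole
        # dataset is one label, excluded above
        null[k] = stat(perm)
    lo, hi = np.percentile(null, [2.5, 97.5])
    p = (int((null <= obs).sum()) + 1) / (n_perm + 1)
    return PolarityResult(obs, float(lo), float(hi), p, n_sing, n_shared,
                          len(per_array))


def detect_duplications(clusters: Sequence[SpacerCluster]) -> list[dict]:
    """Spacers occurring more than once in one genome.

    ``kind`` is "within_array" when one array holds >=2 copies, else
    "between_arrays" when >=2 arrays of the same genome share the spacer.
    """
    out = []
    for c in clusters:
        per_genome: dict[str, Counter] = defaultdict(Counter)
        for o in c.occurrences:
            per_genome[o.genome_id][o.array_id] += 1
        for genome_id in sorted(per_genome):
            arrays = per_genome[genome_id]
            if max(arrays.values()) >= 2:
                out.append({"cluster_id": c.cluster_id, "genome_id": genome_id,
                            "kind": "within_array", "copies": sum(arrays.values())})
            elif len(arrays) >= 2:
                out.append({"cluster_id": c.cluster_id, "genome_id": genome_id,
                            "kind": "between_arrays", "copies": sum(arrays.values())})
    return out


# ---------------------------------------------------------------------------
# Proto-spacer search

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; windows containing N get code -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    run = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    vals = np.where(valid, codes, 0)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + vals[j : j + n]
    out[~run] = -1
    return out


def _max_mismatches(length: int, min_identity: float) -> int:
    """Largest m with (length - m) / length strictly > min_identity."""
    m = int(np.floor(length * (1.0 - min_identity)))
    while m >= 0 and (length - m) / length <= min_identity:
        m -= 1
    return m


def search_protospacers(
    queries: Sequence[ProtoQuery],
    elements: Sequence[MobileElement],
    min_identity: float = 0.95,
    exclude_spans: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> list[ProtospacerHit]:
    """Find all Hamming matches of each spacer on both strands of each element.

    A window matches iff its identity to the spacer is strictly greater than
    ``min_identity`` (no gaps; N never matches).  ``exclude_spans`` masks
    regions per element id (e.g. the query genome's own arrays) — hits
    overlapping a masked span are dropped.
    """
    exclude_spans = exclude_spans or {}
    hits: list[ProtospacerHit] = []
    # group query patterns by chunk length so each element is indexed once per k
    by_k: dict[int, list[tuple[ProtoQuery, str, str, int]]] = defaultdict(list)
    for q in queries:
        seq = q.seq.upper()
        m = _max_mismatches(len(seq), min_identity)
        if m < 0:
            continue
        k = len(seq) // (m + 1)
        if k < 4:
            raise ValueError(f"spacer {q.spacer_id}: too short/divergent for seeded search")
        by_k[k].append((q, seq, reverse_complement(seq), m))

    for elem in sorted(elements, key=lambda e: e.element_id):
        eseq = elem.seq.upper()
        ecodes = _encode(eseq)
        masked = exclude_spans.get(elem.element_id, [])
        for k in sorted(by_k):
            kcodes = _kmer_codes(ecodes, k)
            if kcodes.size == 0:
                continue
            order = np.argsort(kcodes, kind="stable")
            sorted_codes = kcodes[order]
            for q, fwd, rev, m in by_k[k]:
                L = len(fwd)
                cand: set[tuple[int, str]] = set()
                for strand, pat in (("+", fwd), ("-", rev)):
                    pcodes = _encode(pat)
                    for c in range(m + 1):
                        off = c * k
                        chunk = pcodes[off : off + k]
                        if (chunk >= 4).any():
                            continue
                        code = 0
                        for v in chunk:
                            code = code * 4 + int(v)
                        lo = np.searchsorted(sorted_codes, code, side="left")
                        hi = np.searchsorted(sorted_codes, code, side="right")
                        for pos in order[lo:hi]:
                            start = int(pos) - off
                            if 0 <= start <= len(eseq) - L:
                                cand.add((start, strand))
                for start, strand in sorted(cand):
                    pat = fwd if strand == "+" else rev
                    window = ecodes[start : start + L]
                    pc = _encode(pat)
                    mm = int(((window != pc) | (window >= 4)).sum())
                    identity = (L - mm) / L
                    if identity <= min_identity:
                        continue
                    end = start + L
                    if any(s < end and start < e for s, e in masked):
                        continue
                    hits.append(ProtospacerHit(
                        spacer_id=q.spacer_id, genome_id=q.genome_id,
                        locus=q.locus, element_id=elem.element_id,
                        start=start, end=end, strand=strand,
                        mismatches=mm, identity=identity,
                    ))
    hits.sort(key=lambda h: (h.spacer_id, h.element_id, h.start, h.strand))
    return hits


def classify_hits(
    hits: Sequence[ProtospacerHit],
    elements: Sequence[MobileElement],
    cas_spans: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> None:
    """Assign each hit a target class, in place.

    Phage and plasmid elements give their class directly.  Hits on a
    chromosome element are sub-classified as "prophage" when inside a
    prophage span, "cas" when inside a supplied cas-gene span, else
    "chromosome".
    """
    by_id = {e.element_id: e for e in elements}
    cas_spans = cas_spans or {}
    for h in hits:
        elem = by_id[h.element_id]
        if elem.element_class in ("phage", "plasmid"):
            h.target_class = elem.element_class
            continue
        cls = "chromosome"
        for s, e, span_cls in elem.spans:
            if s < h.end and h.start < e and span_cls == "prophage":
                cls = "prophage"
                break
        if cls == "chromosome":
            for s, e in cas_spans.get(h.element_id, []):
                if s < h.end and h.start < e:
                    cls = "cas"
                    break
        h.target_class = cls


def context_stats(
    hits: Sequence[ProtospacerHit],
    elements: Sequence[MobileElement],
) -> dict:
    """Annotate hits with gene context and summarise genic / coding-strand rates.

    A hit is genic iff it overlaps an annotated gene by >=1 bp; among genic
    hits, coding_strand is True when the hit strand equals the strand of the
    maximally-overlapping gene (i.e. the spacer matches the mRNA-like
    strand).  Percentages are rounded half-up.
    """
    by_id = {e.element_id: e for e in elements}
    n_genic = n_coding = 0
    for h in hits:
        best = None
        best_ov = 0
        for g in by_id[h.element_id].genes:
            ov = min(h.end, g.end) - max(h.start, g.start)
            if ov > best_ov:
                best, best_ov = g, ov
        if best is None:
            h.genic = False
            h.coding_strand = None
            continue
        h.genic = True
        h.coding_strand = h.strand == best.strand
        n_genic += 1
        n_coding += h.coding_strand
    n = len(hits)
    return {
        "n_hits": n,
        "n_genic": n_genic,
        "pct_genic": round_half_up(100 * n_genic / n) if n else 0,
        "n_coding_strand": n_coding,
        "pct_coding_strand": round_half_up(100 * n_coding / n_genic) if n_genic else 0,
    }


def hit_span(hits: Sequence[ProtospacerHit]) -> int:
    """Extent (bp) covered by hits on one element: max(end) - min(start)."""
    if not hits:
        return 0
    ids = {h.element_id for h in hits}
    if len(ids) > 1:
        raise ValueError("hit_span expects hits on a single element")
    return max(h.end for h in hits) - min(h.start for h in hits)


def self_targets(
    hits: Sequence[ProtospacerHit],
    ownership: dict[str, set[str]],
) -> list[ProtospacerHit]:
    """Hits where a genome's spacer matches an element of that same genome.

    ``ownership`` maps genome_id -> element ids representing that genome's
    own replicons (chromosome, resident plasmids, integrated prophages).
    """
    return [h for h in hits if h.element_id in ownership.get(h.genome_id, set())]


# ---------------------------------------------------------------------------
# Anti-CRISPR

def detect_anti_crispr(
    occurrences: Sequence[SpacerOccurrence],
    operon_calls: dict[str, dict[str, CasOperonCall]],
    refs: Sequence[CasRef],
    min_identity: float = 0.95,
    accept_partial_relic: bool = False,
) -> tuple[list[AntiCrisprFlag], list[dict]]:
    """Flag arrays carrying spacers against cas genes of a missing subtype.

    Each genome's spacers are searched against the cas reference CDS set.
    An array is flagged anti-CRISPR only when the matched subtype's operon
    is not functionally present in that genome: by default "present" means
    any non-absent call; with ``accept_partial_relic`` a partial operon
    consisting solely of pseudogenes (a relic) still counts as absent.
    Matches against a subtype whose operon IS present are returned
    separately as self-targeting conflicts, never as anti-CRISPR.
    """
    cas_elements = [
        MobileElement(element_id=f"{r.subtype}_{r.gene_name}", seq=r.cds,
                      element_class="chromosome")
        for r in refs
    ]
    queries = []
    occ_by_qid: dict[str, SpacerOccurrence] = {}
    for i, occ in enumerate(occurrences):
        qid = f"acr_q{i:05d}"
        queries.append(ProtoQuery(spacer_id=qid, seq=occ.seq,
                                  genome_id=occ.genome_id, locus=occ.locus))
        occ_by_qid[qid] = occ
    hits = search_protospacers(queries, cas_elements, min_identity=min_identity)

    # (genome, array) -> subtype -> matched gene names
    matched: dict[tuple[str, str], dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for h in hits:
        occ = occ_by_qid[h.spacer_id]
        subtype, gene = h.element_id.split("_", 1)
        matched[(occ.genome_id, occ.array_id)][subtype].add(gene)

    flags: list[AntiCrisprFlag] = []
    conflicts: list[dict] = []
    for (genome_id, array_id) in sorted(matched):
        for subtype in sorted(matched[(genome_id, array_id)]):
            genes = sorted(matched[(genome_id, array_id)][subtype])
            call = operon_calls.get(genome_id, {}).get(subtype)
            if call is None or call.status == "absent":
                present = False
            elif call.status == "partial" and accept_partial_relic:
                present = any(c.status == "intact" for c in call.gene_calls)
            else:
                present = True
            if present:
                conflicts.append({"genome_id": genome_id, "array_id": array_id,
                                  "subtype": subtype, "matched_cas_genes": genes})
            else:
                flags.append(AntiCrisprFlag(
                    genome_id=genome_id, array_id=array_id, subtype=subtype,
                    matched_cas_genes=genes, cognate_subtype_present=False))
    return flags, conflicts
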