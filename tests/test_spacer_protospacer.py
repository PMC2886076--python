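"""Spacer atlas, proto-spacer search (vs exhaustive oracle), anti-CRISPR."""
from __future__ import annotations

import numpy as np
import pytest

from crispratlas.genome_io import GeneRecord, MobileElement, reverse_complement
from crispratlas.spacer_protospacer import (
    ProtoQuery,
    SpacerOccurrence,
    atlas_stats,
    cluster_spacers,
    context_stats,
    classify_hits,
    detect_duplications,
    polarity_profile,
    round_half_up,
    search_protospacers,
    self_targets,
)


def occ(gid, seq, idx=0, array="a0", locus="CRISPR1", oriented=True):
    return SpacerOccurrence(genome_id=gid, array_id=array, locus=locus,
                            index_from_leader=idx, seq=seq, oriented=oriented)


S1 = "ACTTAGGACTATTACCGGATAACCTAGGAAGT"
S2 = "TTGACCTAGGCATTACGGATCCTTAAGGACAT"
S3 = "CAGGATTTACCGTTAACCGGTTAAGCATACCA"


def test_round_half_up():
    assert round_half_up(0.5) == 1
    assert round_half_up(1.5) == 2
    assert round_half_up(2.4) == 2
    assert round_half_up(85.0) == 85


def test_clustering_is_strand_blind():
    clusters = cluster_spacers([occ("g1", S1), occ("g2", reverse_complement(S1))])
    assert len(clusters) == 1
    assert not clusters[0].is_singleton


def test_singleton_counts_strain_groups_once():
    occs = [occ("g2", S1), occ("g2b", S1)]
    # two different strains -> shared
    assert not cluster_spacers(occs)[0].is_singleton
    # same strain group -> effectively one observation -> singleton
    clusters = cluster_spacers(occs, strain_groups=[["g2", "g2b"], ["g1"]])
    assert clusters[0].is_singleton


def test_atlas_stats_arithmetic():
    occs = [occ("g1", S1), occ("g2", S1), occ("g1", S2, idx=1), occ("g3", S3)]
    stats = atlas_stats(cluster_spacers(occs))
    assert stats["total_occurrences"] == 4
    assert stats["distinct"] == 3
    assert stats["singletons"] == 2
    assert stats["pct_singletons"] == round_half_up(100 * 2 / 3)


def test_duplications_within_and_between_arrays():
    occs = [occ("g1", S1, idx=0, array="a0"), occ("g1", S1, idx=3, array="a0"),
            occ("g1", S2, idx=1, array="a0"), occ("g1", S2, idx=0, array="a1")]
    dups = {d["kind"] for d in detect_duplications(cluster_spacers(occs))}
    assert dups == {"within_array", "between_arrays"}


def test_polarity_negative_when_singletons_lead():
    rng = np.random.default_rng(0)

    def rand_seq():
        return "".join(rng.choice(list("ACGT"), size=32))

    occs = []
    for a in range(8):
        shared = rand_seq()
        for gid in ("g1", "g2"):
            # singleton unique to each genome at the leader, shared spacer distal
            occs.append(occ(gid, rand_seq(), idx=0, array=f"arr{a}"))
            occs.append(occ(gid, shared, idx=5, array=f"arr{a}"))
    res = polarity_profile(cluster_spacers(occs), n_perm=2000, seed=1)
    assert res.statistic < 0
    assert res.statistic < res.null_low
    assert res.p_perm < 0.05


def test_polarity_needs_both_labels():
    occs = [occ("g1", S1), occ("g2", S1)]
    res = polarity_profile(cluster_spacers(occs), n_perm=10, seed=0)
    assert res.statistic is None
    assert res.reason


# ---------------------------------------------------------------------------
# Search vs exhaustive oracle

def _oracle(query: str, element: MobileElement, min_identity: float):
    L = len(query)
    hits = []
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        for i in range(len(element.seq) - L + 1):
            w = element.seq[i : i + L]
            ident = sum(a == b and a != "N" for a, b in zip(q, w)) / L
            if ident > min_identity:
                hits.append((element.element_id, i, i + L, strand))
    return sorted(hits)


def _rand_element(rng, eid, n=4000, cls="phage"):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return MobileElement(eid, seq, cls)


def test_search_matches_oracle_with_planted_mismatches():
    rng = np.random.default_rng(42)
    elements = [_rand_element(rng, f"ph{i:02d}") for i in range(6)]
    queries = []
    expected = []
    for mm in (0, 1, 2):
        for rep in range(4):
            e = elements[rng.integers(0, len(elements))]
            pos = int(rng.integers(0, len(e.seq) - 32))
            spacer = list(e.seq[pos : pos + 32])
            for p in rng.choice(32, size=mm, replace=False):
                spacer[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[p]]
            q = ProtoQuery(spacer_id=f"q{mm}_{rep}", seq="".join(spacer),
                           genome_id="g1", locus="CRISPR1")
            queries.append(q)
            expected.append((q, mm))
    hits = search_protospacers(queries, elements, min_identity=0.95)
    by_query = {}
    for h in hits:
        by_query.setdefault(h.spacer_id, []).append(h)
    for q, mm in expected:
        got = sorted((h.element_id, h.start, h.end, h.strand)
                     for h in by_query.get(q.spacer_id, []))
        want = sorted(set().union(*[_oracle(q.seq, e, 0.95) for e in elements]))
        assert got == want, q.spacer_id
        if mm <= 1:
            assert got, f"{q.spacer_id}: <=1 mismatch must be found"
        else:
            assert all(h.mismatches >= 2 for h in by_query.get(q.spacer_id, []))


def test_search_finds_reverse_strand():
    rng = np.random.default_rng(5)
    e = _rand_element(rng, "ph00")
    q = ProtoQuery("q0", reverse_complement(e.seq[100:132]), "g1", "CRISPR1")
    hits = search_protospacers([q], [e], min_identity=0.95)
    assert [(h.start, h.end, h.strand, h.mismatches) for h in hits] == \
        [(100, 132, "-", 0)]


def test_search_respects_exclusion_spans():
    rng = np.random.default_rng(6)
    e = _rand_element(rng, "chr0", cls="chromosome")
    q = ProtoQuery("q0", e.seq[200:232], "g1", "CRISPR1")
    assert search_protospacers([q], [e], min_identity=0.95)
    masked = search_protospacers([q], [e], min_identity=0.95,
                                 exclude_spans={"chr0": [(150, 300)]})
    assert masked == []


def test_classify_and_context_and_self_targets():
    rng = np.random.default_rng(7)
    e = _rand_element(rng, "g1", n=3000, cls="chromosome")
    e.genes = [GeneRecord("g1_gene0", "g1", 500, 1700, "+")]
    e.spans = [(2000, 2600, "prophage")]
    queries = [
        ProtoQuery("genic", e.seq[600:632], "g1", "CRISPR1"),
        ProtoQuery("inter", e.seq[1800:1832], "g1", "CRISPR1"),
        ProtoQuery("proph", e.seq[2100:2132], "g2", "CRISPR1"),
    ]
    hits = search_protospacers(queries, [e], min_identity=0.95)
    classify_hits(hits, [e])
    stats = context_stats(hits, [e])
    by_id = {h.spacer_id: h for h in hits}
    assert by_id["genic"].genic and by_id["genic"].coding_strand
    assert not by_id["inter"].genic
    assert by_id["proph"].target_class == "prophage"
    assert stats["n_hits"] == 3 and stats["n_genic"] == 1
    own = self_targets(hits, {"g1": {"g1"}})
    assert {h.spacer_id for h in own} == {"genic", "inter"}
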