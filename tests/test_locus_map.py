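"""Orthology, locus anchoring and leader calling."""
from __future__ import annotations

import pytest

from crispratlas.crispr_detect import detect_arrays
from crispratlas.locus_map import (
    LOCUS_ANCHORS,
    anchor_locus,
    core_genome,
    find_leader,
    protein_similarity,
    rbh_orthologs,
)


@pytest.fixture(scope="module")
def detected(small_world):
    genomes, _, _ = small_world
    out = {}
    for g in genomes:
        arrays = []
        for cid, seq in g.contigs:
            found = detect_arrays(seq, contig_id=cid)
            for a in found:
                a.genome_id = g.genome_id
            arrays.extend(found)
        out[g.genome_id] = arrays
    return out


@pytest.fixture(scope="module")
def core(small_world):
    genomes, _, _ = small_world
    return core_genome(genomes)


def test_protein_similarity_bounds():
    assert protein_similarity("MKV", "MKV") == 1.0
    assert protein_similarity("MKV", "WWW") < 0.5
    a, b = "MKVLAAGHQRST", "MKVLAVGHQRST"
    assert 0.0 <= protein_similarity(a, b) <= 1.0
    assert protein_similarity(a, b) == protein_similarity(b, a)


def test_rbh_is_symmetric_and_one_to_one(small_world):
    genomes, _, _ = small_world
    a = next(g for g in genomes if g.genome_id == "g1")
    b = next(g for g in genomes if g.genome_id == "g3")
    pairs = rbh_orthologs(a, b)
    assert pairs
    assert len({p.gene_a.gene_id for p in pairs}) == len(pairs)
    assert len({p.gene_b.gene_id for p in pairs}) == len(pairs)
    flipped = rbh_orthologs(b, a)
    assert {(p.gene_a.gene_id, p.gene_b.gene_id) for p in pairs} == \
        {(p.gene_b.gene_id, p.gene_a.gene_id) for p in flipped}


def test_core_families_have_one_member_per_genome(small_world, core):
    genomes, _, _ = small_world
    ids = {g.genome_id for g in genomes}
    assert core
    for fam in core:
        assert set(fam.members) == ids


def test_anchoring_matches_truth(small_world, genomes_by_id, detected, core):
    _, _, truth = small_world
    truth_spans = {(r["genome_id"], r["start"], r["end"]): r["locus"]
                   for r in truth.arrays}
    n = 0
    for gid, arrays in detected.items():
        for arr in arrays:
            locus = anchor_locus(arr, genomes_by_id[gid], core=core)
            assert locus == truth_spans[(gid, arr.start, arr.end)]
            n += 1
    assert n == len(truth.arrays)


def test_anchor_names_cover_four_loci():
    assert sorted(LOCUS_ANCHORS.values()) == \
        ["CRISPR1", "CRISPR2", "CRISPR3", "CRISPR4"]


def test_leader_sides_match_truth(small_world, genomes_by_id, detected, core):
    _, _, truth = small_world
    for gid, arrays in detected.items():
        for arr in arrays:
            arr.locus = anchor_locus(arr, genomes_by_id[gid], core=core)
    truth_side = {r["locus"]: r["side"] for r in truth.leaders}
    by_locus = {}
    for gid, arrays in detected.items():
        for arr in arrays:
            by_locus.setdefault(arr.locus, []).append((genomes_by_id[gid], arr))
    for locus, pairs in by_locus.items():
        leaders = find_leader(pairs)
        assert leaders
        for leader in leaders:
            assert leader.side == truth_side[locus]
            assert leader.significant
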