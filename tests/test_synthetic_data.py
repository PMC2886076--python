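"""Generator: determinism, truth consistency, and config validation."""
from __future__ import annotations

import json

import pytest

from crispratlas.genome_io import reverse_complement
from crispratlas.synthetic_data import TruthSet, WorldConfig, generate_world


def test_config_validation():
    with pytest.raises(ValueError):
        WorldConfig(n_strains=1)
    with pytest.raises(ValueError):
        WorldConfig(mismatch_probs=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        WorldConfig(spacer_len_range=(10, 35))
    with pytest.raises(ValueError):
        WorldConfig(is_len=5000)


def test_same_seed_reproduces_world(small_config):
    g1, e1, t1 = generate_world(small_config, seed=3)
    g2, e2, t2 = generate_world(small_config, seed=3)
    assert [g.contigs for g in g1] == [g.contigs for g in g2]
    assert [e.seq for e in e1] == [e.seq for e in e2]
    assert json.dumps(t1.to_json(), sort_keys=True) == \
        json.dumps(t2.to_json(), sort_keys=True)


def test_different_seed_changes_world(small_config):
    g1, _, _ = generate_world(small_config, seed=3)
    g2, _, _ = generate_world(small_config, seed=4)
    assert g1[0].contigs != g2[0].contigs


def test_truth_spans_match_sequence(small_world):
    genomes, _, truth = small_world
    by_id = {g.genome_id: dict(g.contigs) for g in genomes}
    for rec in truth.arrays:
        contig = by_id[rec["genome_id"]][rec["contig_id"]]
        for (s, e) in rec["repeats"]:
            assert 0 <= s < e <= len(contig)
        for sp in rec["spacers"]:
            assert contig[sp["start"]:sp["end"]] == sp["seq"]
        # every spacer sits exactly between two consecutive repeats
        # (spacers are listed in leader order; IS slots have no spacer entry)
        repeat_ends = {e for _, e in rec["repeats"]}
        repeat_starts = {s for s, _ in rec["repeats"]}
        for sp in rec["spacers"]:
            assert sp["start"] in repeat_ends
            assert sp["end"] in repeat_starts


def test_no_consensus_words_leak_into_spacers(small_world):
    genomes, _, truth = small_world
    k = 8
    words = set()
    for rec in truth.arrays:
        cons = rec["consensus"]
        for s in (cons, reverse_complement(cons)):
            words.update(s[i:i + k] for i in range(len(s) - k + 1))
    for rec in truth.arrays:
        for sp in rec["spacers"]:
            seq = sp["seq"]
            assert not any(seq[i:i + k] in words for i in range(len(seq) - k + 1))


def test_truth_roundtrip(tmp_path, small_world):
    _, _, truth = small_world
    path = tmp_path / "truth.json"
    truth.save(str(path))
    back = TruthSet.load(str(path))
    assert json.dumps(back.to_json(), sort_keys=True) == \
        json.dumps(truth.to_json(), sort_keys=True)


def test_close_pair_present_and_close(small_world):
    genomes, _, truth = small_world
    ids = {g.genome_id for g in genomes}
    assert "g2b" in ids
    g2 = dict(next(g for g in genomes if g.genome_id == "g2").contigs)
    g2b = dict(next(g for g in genomes if g.genome_id == "g2b").contigs)
    (seq_a,), (seq_b,) = g2.values(), g2b.values()
    diffs = sum(a != b for a, b in zip(seq_a, seq_b))
    assert len(seq_a) == len(seq_b)
    assert 0 < diffs < 1e-4 * len(seq_a)


def test_every_genome_has_crispr1(small_world):
    _, _, truth = small_world
    for gid in {r["genome_id"] for r in truth.arrays}:
        loci = {r["locus"] for r in truth.arrays if r["genome_id"] == gid}
        assert "CRISPR1" in loci


def test_anti_crispr_genome_lacks_cognate_operon(small_world):
    _, _, truth = small_world
    assert truth.anti_crispr, "world must plant an anti-CRISPR array"
    for rec in truth.anti_crispr:
        assert truth.cas[rec["genome_id"]][rec["subtype"]]["status"] == "absent"


def test_is_disruption_recorded(small_world):
    _, _, truth = small_world
    disrupted = [r for r in truth.arrays if r["disrupted"]]
    assert disrupted
    for rec in disrupted:
        # an IS insertion shows as two consecutive repeats much further apart
        gaps = [nxt[0] - cur[1] for cur, nxt in
                zip(rec["repeats"], rec["repeats"][1:])]
        assert max(gaps) > 500
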