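"""cas operon annotation: reference loading, status logic, world agreement."""
from __future__ import annotations

import pytest

from crispratlas.cas_annot import (
    ECOLI_CAS_GENES,
    YPEST_CAS_GENES,
    CasGeneCall,
    annotate_genome_cas,
    load_cas_refs,
    operon_status,
)
from crispratlas.crispr_detect import detect_arrays
from crispratlas.genome_io import translate_cds


def test_reference_sets():
    assert len(ECOLI_CAS_GENES) == 8
    assert len(YPEST_CAS_GENES) == 6
    refs = load_cas_refs()
    assert {r.subtype for r in refs} == {"Ecoli", "Ypest"}
    assert {r.gene_name for r in refs if r.subtype == "Ecoli"} == set(ECOLI_CAS_GENES)
    assert {r.gene_name for r in refs if r.subtype == "Ypest"} == set(YPEST_CAS_GENES)
    for r in refs:
        assert "*" not in r.protein
        assert r.protein == translate_cds(r.cds)


def _call(name, status, strand="+", start=0):
    return CasGeneCall(gene_name=name, subtype="Ecoli", contig_id="c",
                       start=start, end=start + 90, strand=strand,
                       status=status, similarity=1.0, evidence="cds",
                       coverage=1.0, defects=[] if status == "intact" else ["x"])


def test_operon_status_complete_partial_absent():
    intact = [_call(g, "intact", start=i * 100)
              for i, g in enumerate(ECOLI_CAS_GENES)]
    assert operon_status(intact, "Ecoli").status == "complete"
    assert operon_status([], "Ecoli").status == "absent"
    one_pseudo = intact[:-1] + [_call(ECOLI_CAS_GENES[-1], "pseudo", start=700)]
    assert operon_status(one_pseudo, "Ecoli").status == "partial"
    missing = intact[:-1]
    assert operon_status(missing, "Ecoli").status == "partial"


def test_operon_status_requires_co_orientation():
    calls = [_call(g, "intact", strand="+" if i else "-", start=i * 100)
             for i, g in enumerate(ECOLI_CAS_GENES)]
    res = operon_status(calls, "Ecoli")
    assert not res.co_oriented
    assert res.status == "partial"


def test_operon_status_rejects_mixed_subtypes():
    bad = _call("cas1", "intact")
    bad.subtype = "Ypest"
    with pytest.raises(ValueError):
        operon_status([_call("cas1", "intact"), bad], "Ecoli")


def test_world_statuses_match_truth(small_world, genomes_by_id):
    genomes, _, truth = small_world
    refs = load_cas_refs()
    for g in genomes:
        arrays = []
        for cid, seq in g.contigs:
            arrays.extend(detect_arrays(seq, contig_id=cid))
        calls = annotate_genome_cas(g, arrays, refs)
        for subtype, call in calls.items():
            assert call.status == truth.cas[g.genome_id][subtype]["status"], \
                (g.genome_id, subtype)


def test_partial_operon_reports_pseudogene_defects(small_world):
    genomes, _, truth = small_world
    refs = load_cas_refs()
    decayed = next(gid for gid, entry in truth.cas.items()
                   if entry["Ecoli"]["status"] == "partial")
    g = next(x for x in genomes if x.genome_id == decayed)
    arrays = []
    for cid, seq in g.contigs:
        arrays.extend(detect_arrays(seq, contig_id=cid))
    call = annotate_genome_cas(g, arrays, refs)["Ecoli"]
    assert call.status == "partial"
    pseudo = [c for c in call.gene_calls if c.status == "pseudo"]
    assert pseudo
    assert all(c.defects for c in pseudo)
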