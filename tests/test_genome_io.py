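"""I/O round trips, translation and deterministic table writing."""
from __future__ import annotations

import pandas as pd
import pytest

from crispratlas.genome_io import (
    GeneRecord,
    Genome,
    MobileElement,
    ReportBundle,
    load_elements,
    load_genome,
    reverse_complement,
    translate_cds,
    write_elements,
    write_genome,
    write_tables,
)


def test_reverse_complement_involution():
    seq = "ACGTTGCANNRY"
    assert reverse_complement(reverse_complement(seq)) == seq
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAAC") == "GTTT"


def test_translate_cds_bacterial_table():
    assert translate_cds("ATGGCATAA") == "MA"          # trailing stop stripped
    assert translate_cds("ATGTAAGCA") == "M*A"         # internal stop kept
    assert translate_cds("GTGAAA") == "VK"             # table 11 keeps GTG as V mid-gene


def test_gene_record_validation():
    with pytest.raises(ValueError):
        GeneRecord("g", "c", 10, 5, "+")
    with pytest.raises(ValueError):
        GeneRecord("g", "c", 0, 5, "?")


def test_gene_record_strand_extraction():
    rec = GeneRecord("g", "c", 2, 8, "-")
    assert rec.nucleotide_seq("TTATGGCATT") == "CCATA"[0:0] + reverse_complement("ATGGCA")


def test_genome_roundtrip(tmp_path):
    genome = Genome(
        genome_id="gX",
        contigs=[("gX_chr", "ATGGCATAACCCGGGTTT")],
        genes=[GeneRecord("gX_g1", "gX_chr", 0, 9, "+", product="demo")],
        element_spans=[("gX_chr", 9, 15, "prophage")],
    )
    fasta = tmp_path / "gX.fasta"
    gff = tmp_path / "gX.gff3"
    write_genome(genome, str(fasta), str(gff))
    back = load_genome(str(fasta), str(gff))
    assert back.genome_id == "gX"
    assert back.contigs == genome.contigs
    assert len(back.genes) == 1
    g = back.genes[0]
    assert (g.gene_id, g.start, g.end, g.strand) == ("gX_g1", 0, 9, "+")
    assert back.element_spans == genome.element_spans


def test_elements_roundtrip(tmp_path):
    elems = [
        MobileElement("phage00", "ACGT" * 10, "phage",
                      genes=[GeneRecord("phage00_g0", "phage00", 0, 12, "+")]),
        MobileElement("plasmid00", "TTGGCCAA" * 5, "plasmid"),
    ]
    write_elements(elems, str(tmp_path / "e.fasta"), str(tmp_path / "e.tsv"))
    back = load_elements(str(tmp_path / "e.fasta"), str(tmp_path / "e.tsv"))
    assert [(e.element_id, e.element_class, e.seq) for e in back] == \
        [(e.element_id, e.element_class, e.seq) for e in elems]


def test_element_class_validated():
    with pytest.raises(ValueError):
        MobileElement("x", "ACGT", "starship")


def test_write_tables_deterministic(tmp_path):
    bundle = ReportBundle(tables={
        "b": pd.DataFrame({"x": [1, 2]}),
        "a": pd.DataFrame({"y": ["u", "v"]}),
    })
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    p1 = write_tables(bundle, str(d1))
    p2 = write_tables(bundle, str(d2))
    assert [p.rsplit("/", 1)[1] for p in p1] == ["a.tsv", "b.tsv"]
    for a, b in zip(p1, p2):
        assert open(a, "rb").read() == open(b, "rb").read()
    assert bundle.checksum() == bundle.checksum()
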