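"""Genome/annotation data model and the standard-format I/O used by the pipeline.

Coordinates are 0-based half-open internally; GFF3 files at the package
boundary use the format's 1-based closed convention.  Proteins are derived
with the bacterial translation table (11) when not supplied.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "Genome",
    "MobileElement",
    "ReportBundle",
    "load_genome",
    "write_genome",
    "load_elements",
    "write_elements",
    "write_tables",
    "translate_cds",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtn", "TGCANYRSWMKtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a nucleotide CDS with the bacterial table; trailing stop stripped.

    Internal stops are kept as '*' so callers can spot pseudogenes.
    """
    trimmed = seq[: len(seq) - len(seq) % 3]
    prot = str(Seq(trimmed).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class GeneRecord:
    """One annotated feature (CDS or tRNA) on a contig; 0-based half-open span."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: Optional[str] = None
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    def nucleotide_seq(self, contig_seq: str) -> str:
        sub = contig_seq[self.start : self.end]
        return sub if self.strand == "+" else reverse_complement(sub)


@dataclass
class Genome:
    """A genome: contigs, gene annotations and optional mobile-element spans."""

    genome_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    # (contig_id, start, end, element_class) with class in {"prophage", "IS"}
    element_spans: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        for g in self.genes:
            if g.contig_id not in lengths:
                raise ValueError(f"{self.genome_id}: gene {g.gene_id} on unknown contig {g.contig_id}")
            if g.end > lengths[g.contig_id]:
                raise ValueError(f"{self.genome_id}: gene {g.gene_id} exceeds contig bounds")
        for cid, s, e, cls in self.element_spans:
            if cid not in lengths or not (0 <= s < e <= lengths[cid]):
                raise ValueError(f"{self.genome_id}: element span out of bounds on {cid}")
            if cls not in ("prophage", "IS"):
                raise ValueError(f"{self.genome_id}: unknown element class {cls!r}")

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(f"{self.genome_id}: no contig {contig_id}")

    def gene_protein(self, gene: GeneRecord) -> str:
        """Protein sequence: stored translation if present, else derived (table 11)."""
        if gene.protein is not None:
            return gene.protein
        return translate_cds(gene.nucleotide_seq(self.contig_seq(gene.contig_id)))

    def coding_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.feature_type == "CDS"]


@dataclass
class MobileElement:
    """A phage / plasmid / chromosome element from the target pool."""

    element_id: str
    seq: str
    element_class: str
    genes: list[GeneRecord] = field(default_factory=list)
    # optional sub-spans on chromosome elements: (start, end, class) e.g. prophage
    spans: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.element_class not in ("phage", "plasmid", "chromosome"):
            raise ValueError(f"{self.element_id}: unknown element class {self.element_class!r}")


# ---------------------------------------------------------------------------
# FASTA / GFF3

def load_genome(fasta_path: str, gff_path: Optional[str] = None) -> Genome:
    """Read a genome FASTA (plus optional GFF3 annotation) into the data model.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Raises if the GFF references a contig id absent from the FASTA.
    """
    genome_id = os.path.splitext(os.path.basename(fasta_path))[0]
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fasta_path, "fasta")]
    genome = Genome(genome_id=genome_id, contigs=contigs)
    if gff_path is None:
        return genome

    import gffutils

    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    contig_ids = {cid for cid, _ in genome.contigs}
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "tRNA", "gene"):
            continue
        if feat.featuretype == "gene":
            # gene parents are redundant with their CDS/tRNA children here
            continue
        if feat.seqid not in contig_ids:
            raise ValueError(f"GFF contig {feat.seqid!r} not present in {fasta_path}")
        attrs = feat.attributes
        gid = (attrs.get("ID") or attrs.get("gene_id") or [f"{feat.seqid}_{feat.start}"])[0]
        product = (attrs.get("product") or [""])[0]
        protein = (attrs.get("translation") or [None])[0]
        genes.append(
            GeneRecord(
                gene_id=gid, contig_id=feat.seqid,
                start=feat.start - 1, end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                product=product, protein=protein, feature_type=feat.featuretype,
            )
        )
    genome.genes = genes
    # element spans travel as a dedicated feature type
    for feat in db.all_features():
        if feat.featuretype == "mobile_element":
            cls = (feat.attributes.get("element_class") or ["IS"])[0]
            genome.element_spans.append((feat.seqid, feat.start - 1, feat.end, cls))
    return Genome(genome.genome_id, genome.contigs, genome.genes, genome.element_spans)


def _gff_attr(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_genome(genome: Genome, fasta_path: str, gff_path: Optional[str] = None) -> None:
    """Write a Genome back to FASTA (+GFF3); inverse of :func:`load_genome`."""
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs]
    SeqIO.write(records, fasta_path, "fasta")
    if gff_path is None:
        return
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs:
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={_gff_attr(g.gene_id)}"
            if g.product:
                attrs += f";product={_gff_attr(g.product)}"
            if g.protein is not None:
                attrs += f";translation={_gff_attr(g.protein)}"
            fh.write(
                f"{g.contig_id}\tcrispratlas\t{g.feature_type}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t"
                f"{'0' if g.feature_type == 'CDS' else '.'}\t{attrs}\n"
            )
        for cid, s, e, cls in genome.element_spans:
            fh.write(
                f"{cid}\tcrispratlas\tmobile_element\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={cid}_{s}_{cls};element_class={cls}\n"
            )


def write_elements(elements: Iterable[MobileElement], fasta_path: str, tsv_path: str) -> None:
    """Element pool to FASTA plus a class/annotation TSV."""
    elements = list(elements)
    records = [SeqRecord(Seq(e.seq), id=e.element_id, description=e.element_class) for e in elements]
    SeqIO.write(records, fasta_path, "fasta")
    rows = []
    for e in elements:
        rows.append({"element_id": e.element_id, "element_class": e.element_class,
                     "length": len(e.seq),
                     "genes": json.dumps([[g.gene_id, g.start, g.end, g.strand] for g in e.genes]),
                     "spans": json.dumps(e.spans)})
    pd.DataFrame(rows, columns=["element_id", "element_class", "length", "genes", "spans"]).to_csv(
        tsv_path, sep="\t", index=False, lineterminator="\n")


def load_elements(fasta_path: str, tsv_path: str) -> list[MobileElement]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    meta = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    out = []
    for _, row in meta.iterrows():
        eid = row["element_id"]
        genes = [GeneRecord(gid, eid, s, e, strand) for gid, s, e, strand in json.loads(row["genes"])]
        spans = [tuple(x) for x in json.loads(row["spans"])]
        out.append(MobileElement(eid, seqs[eid], row["element_class"], genes, spans))
    return out


# ---------------------------------------------------------------------------
# Report tables

@dataclass
class ReportBundle:
    """All result tables of one pipeline run, keyed by table name."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(sep="\t", index=False, lineterminator="\n").encode())
        return h.hexdigest()


def write_tables(results: ReportBundle, out_dir: str) -> list[str]:
    """Write every table of the bundle as a deterministic TSV; returns the paths.

    Identical bundles produce byte-identical files (stable column order,
    '\\n' line endings, no index column).  An empty table yields a
    header-only file.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in sorted(results.tables):
        path = os.path.join(out_dir, f"{name}.tsv")
        results.tables[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths.append(path)
    return paths
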