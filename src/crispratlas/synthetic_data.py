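"""Synthetic enterobacterial worlds with planted, fully-known CRISPR ground truth.

A world is a small panel of related strains (single-contig genomes) plus a
pool of mobile elements (phages, plasmids, chromosome fragments).  Each strain
carries CRISPR arrays at up to four canonical loci between conserved anchor
genes, a conserved AT-rich leader on one side of each array, a degenerate
3'-terminal repeat, optional cas operons (intact or pseudogenised), an
IS-disrupted array, an anti-CRISPR array whose spacers target cas genes of a
subtype the strain lacks, and spacers copied from the element pool with a
configurable mismatch mix.  Strains diverge from common ancestral parts by
point substitution; one optional close pair sits at a much smaller distance.

Detectability guarantee: the sequence columns immediately flanking every
planted repeat (the first/last characters of spacers, leaders and flanks) are
assigned so that no single base is shared by more than (number of repeats - 2)
of them.  A column-consensus extension that tolerates one deviant row
therefore stops exactly at the true repeat boundaries, which makes exact
recovery of planted arrays a property of the data rather than luck.

All randomness flows from a single integer seed through per-concern
``numpy.random.Generator`` streams.
"""
from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .cas_annot import CasRef, ECOLI_CAS_GENES, YPEST_CAS_GENES, load_cas_refs
from .crispr_detect import REPEAT1_DEFAULT, REPEAT2_CONSENSUS
from .genome_io import GeneRecord, Genome, MobileElement, reverse_complement

__all__ = [
    "WorldConfig",
    "TruthSet",
    "generate_world",
    "evolve_strain",
    "plant_anti_crispr",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
           if a + b + c not in _STOPS]
# cyclic alphabets for the first/last characters of ancestral pool spacers
_POOL_FIRST = "ACGT"
_POOL_LAST = "GTAC"

_IUPAC_EXPAND = {"W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
                 "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


# ---------------------------------------------------------------------------
# Configuration and truth containers


@dataclass
class WorldConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_strains: int = 6
    close_pair: bool = True              # add a near-identical twin of strain 2
    genome_length: int = 1_000_000
    repeat1: str = REPEAT1_DEFAULT       # CRISPR1/CRISPR2 repeat (29 bp)
    repeat2: str = REPEAT2_CONSENSUS     # CRISPR3/CRISPR4 repeat (28 bp)
    spacer_len_mean: float = 32.0
    spacer_len_sd: float = 1.5
    spacer_len_range: tuple[int, int] = (29, 35)
    leader_len: int = 120
    leader_at: float = 0.7
    n_phage: int = 25
    n_plasmid: int = 15
    n_chromosome: int = 5
    element_len: int = 9000
    n_core_genes: int = 40
    core_gene_len: int = 1200            # bp, multiple of 3
    provenance_fraction: float = 0.5     # spacers copied from the element pool
    provenance_class_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    mismatch_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # 0/1/2 mismatches
    genic_fraction: float = 0.87         # planted proto-spacers inside genes
    coding_strand_fraction: float = 0.51
    strain_divergence: float = 5e-4      # per-strain substitutions/site from ancestor
    close_pair_divergence: float = 5e-5
    acquisition_mode: str = "leader"     # leader | uniform
    terminal_degeneracy: int = 5         # mutated bases at the 3' repeat end
    is_disruption: bool = True           # IS element inside one CRISPR2 array
    is_len: int = 1200
    anti_crispr: bool = True             # one strain with cas-targeting spacers
    n_anti_spacers: int = 2

    def __post_init__(self) -> None:
        if not (2 <= self.n_strains <= 6):
            raise ValueError("n_strains must be between 2 and 6")
        if self.acquisition_mode not in ("leader", "uniform"):
            raise ValueError("acquisition_mode must be 'leader' or 'uniform'")
        if self.core_gene_len % 3:
            raise ValueError("core_gene_len must be a multiple of 3")
        lo, hi = self.spacer_len_range
        if not (19 <= lo <= hi <= 48):
            raise ValueError("spacer_len_range must lie within the detectable 19..48")
        if not (0 <= self.provenance_fraction <= 1):
            raise ValueError("provenance_fraction must be in [0, 1]")
        for probs in (self.provenance_class_probs, self.mismatch_probs):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("probability triples must sum to 1")
        if self.is_len <= 48 or self.is_len > 1900:
            raise ValueError("is_len must exceed the spacer maximum and stay below 1900")


@dataclass
class TruthSet:
    """Complete ground truth of one generated world (JSON round-trippable)."""

    config: dict
    genomes: list[str]
    groups: list[list[str]]              # near-identical strain groups
    arrays: list[dict] = field(default_factory=list)
    leaders: list[dict] = field(default_factory=list)
    cas: dict = field(default_factory=dict)       # genome -> subtype -> call
    elements: dict = field(default_factory=dict)  # element_id -> class
    ownership: dict = field(default_factory=dict)
    anti_crispr: list[dict] = field(default_factory=list)
    self_targets: list[dict] = field(default_factory=list)

    def arrays_for(self, genome_id: str) -> list[dict]:
        return [a for a in self.arrays if a["genome_id"] == genome_id]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        return cls(**json.loads(text))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Low-level sequence helpers


def _rand_dna(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()


def _forbidden_kmers(cfg: WorldConfig, k: int = 8) -> frozenset[str]:
    """All k-mers of the repeat consensi (IUPAC expanded) and reverse complements."""
    variants: set[str] = set()
    for rep in (cfg.repeat1, cfg.repeat2):
        seqs = [""]
        for c in rep:
            opts = _IUPAC_EXPAND.get(c, c)
            seqs = [s + o for s in seqs for o in opts]
        variants.update(seqs)
    variants |= {reverse_complement(s) for s in variants}
    out: set[str] = set()
    for s in variants:
        out.update(s[i : i + k] for i in range(len(s) - k + 1))
    return frozenset(out)


def _has_forbidden(seq: str, forbidden: frozenset[str], k: int = 8) -> bool:
    return any(seq[i : i + k] in forbidden for i in range(len(seq) - k + 1))


def _scrub(rng: np.random.Generator, seq: str, forbidden: frozenset[str],
           at: float = 0.5, k: int = 8) -> str:
    """Resample any window containing a repeat-derived k-mer until clean."""
    s = seq
    for _ in range(1000):
        hit = next((i for i in range(len(s) - k + 1) if s[i : i + k] in forbidden), None)
        if hit is None:
            return s
        s = s[:hit] + _rand_dna(rng, k, at) + s[hit + k :]
    raise RuntimeError("could not scrub repeat k-mers from sequence")


def _fresh_nc(rng: np.random.Generator, n: int, forbidden: frozenset[str],
              at: float = 0.5) -> str:
    return _scrub(rng, _rand_dna(rng, n, at), forbidden, at)


def _rand_cds(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence: ATG, non-stop codons, one trailing TAA."""
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    n_codons = length // 3 - 2
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "ATG" + "".join(_CODONS[i] for i in idx) + "TAA"


def _mutate_noncoding(rng: np.random.Generator, seq: str, rate: float) -> str:
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(n, size=k, replace=False):
        cur = s[pos]
        alts = [b for b in _BASES if b != cur]
        s[pos] = alts[rng.integers(0, 3)]
    return "".join(s)


def _mutate_cds(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point substitutions that never introduce an in-frame stop codon."""
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(n, size=k, replace=False):
        cur = s[pos]
        alts = [b for b in _BASES if b != cur]
        new = alts[rng.integers(0, 3)]
        c0 = pos - pos % 3
        codon = s[c0] + s[c0 + 1] + s[c0 + 2]
        mutated = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
        if mutated in _STOPS or c0 + 3 >= n:  # keep the terminal stop intact too
            continue
        s[pos] = new
    return "".join(s)


# ---------------------------------------------------------------------------
# Strain evolution (public)


def evolve_strain(
    genome: Genome,
    new_genome_id: str,
    rate: float,
    seed: int,
    protected_spans: Optional[Sequence[tuple[str, int, int]]] = None,
) -> Genome:
    """Derive a descendant strain by uniform point substitution.

    CDS substitutions are stop-safe (a substitution that would create an
    in-frame stop on the coding strand is skipped), ``protected_spans``
    ((contig_id, start, end), 0-based half-open) are left untouched, and all
    annotations carry over with identifiers re-prefixed to the new genome id.
    """
    rng = np.random.default_rng(seed)

    def rename(ident: str) -> str:
        prefix = genome.genome_id
        if ident.startswith(prefix):
            return new_genome_id + ident[len(prefix):]
        return ident

    new_contigs: list[tuple[str, str]] = []
    for cid, seq in genome.contigs:
        n = len(seq)
        protected = np.zeros(n, dtype=bool)
        for pcid, s, e in protected_spans or []:
            if pcid == cid:
                protected[max(0, s) : min(n, e)] = True
        # map position -> index of covering CDS (genes do not overlap here)
        gene_at = np.full(n, -1, dtype=np.int32)
        cds = [g for g in genome.genes if g.contig_id == cid and g.feature_type == "CDS"]
        for gi, g in enumerate(cds):
            gene_at[g.start : g.end] = gi
        k = rng.binomial(n, rate)
        s_list = list(seq)
        for pos in (rng.choice(n, size=k, replace=False) if k else []):
            if protected[pos]:
                continue
            cur = s_list[pos]
            if cur not in _BASES:
                continue
            alts = [b for b in _BASES if b != cur]
            new = alts[rng.integers(0, 3)]
            gi = gene_at[pos]
            if gi >= 0:
                g = cds[gi]
                if g.strand == "+":
                    off = (pos - g.start) % 3
                    c0 = pos - off
                    codon = "".join(s_list[c0 : c0 + 3])
                    mutated = codon[:off] + new + codon[off + 1 :]
                else:
                    off = (g.end - 1 - pos) % 3
                    c_hi = pos + off + 1
                    codon = "".join(s_list[c_hi - 3 : c_hi])
                    mutated = codon[: 2 - off] + new + codon[3 - off :]
                    mutated = reverse_complement(mutated)
                if mutated in _STOPS:
                    continue
            s_list[pos] = new
        new_contigs.append((rename(cid), "".join(s_list)))

    new_genes = [
        GeneRecord(
            gene_id=rename(g.gene_id), contig_id=rename(g.contig_id),
            start=g.start, end=g.end, strand=g.strand, product=g.product,
            protein=None, feature_type=g.feature_type,
        )
        for g in genome.genes
    ]
    new_spans = [(rename(cid), s, e, cls) for cid, s, e, cls in genome.element_spans]
    return Genome(new_genome_id, new_contigs, new_genes, new_spans)


# ---------------------------------------------------------------------------
# Element pool


def _make_elements(
    rng: np.random.Generator, cfg: WorldConfig, ecoli_refs: Sequence[CasRef],
    forbidden: frozenset[str],
) -> tuple[list[MobileElement], dict[str, list[tuple[int, int]]]]:
    """Phage / plasmid / chromosome target pool.

    The first chromosome element carries an exact copy of the Ecoli-subtype
    cas operon (annotated with cas product names); every chromosome element
    also has a marked prophage span.  Returns the elements plus a registry of
    pre-reserved windows (the embedded cas operon must not be sampled as
    ordinary proto-spacer provenance).
    """
    elements: list[MobileElement] = []
    reserved: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def add_genes(eid: str, length: int, skip: Sequence[tuple[int, int]] = ()) -> list[GeneRecord]:
        genes: list[GeneRecord] = []
        pos = int(rng.integers(80, 150))
        gi = 0
        while True:
            glen = 3 * int(rng.integers(200, 400))
            if pos + glen + 100 > length:
                break
            span = (pos, pos + glen)
            if any(span[0] < e and s < span[1] for s, e in skip):
                pos += 200
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"{eid}_g{gi}", eid, span[0], span[1], strand))
            gi += 1
            pos = span[1] + int(rng.integers(80, 200))
        return genes

    for cls, count in (("phage", cfg.n_phage), ("plasmid", cfg.n_plasmid),
                       ("chromosome", cfg.n_chromosome)):
        for i in range(count):
            eid = f"{cls}{i:02d}"
            if cls == "chromosome" and i == 0:
                # cas-operon-bearing chromosome fragment
                operon_parts: list[str] = []
                cursor = 200
                genes: list[GeneRecord] = []
                for r in ecoli_refs:
                    genes.append(GeneRecord(f"{eid}_{r.gene_name}", eid, cursor,
                                            cursor + len(r.cds), "+", r.gene_name))
                    operon_parts.append(r.cds)
                    cursor += len(r.cds)
                    operon_parts.append(_rand_dna(rng, 50))
                    cursor += 50
                operon_end = cursor
                length = operon_end + 3200
                tail = _rand_dna(rng, length - operon_end)
                seq = _rand_dna(rng, 200) + "".join(operon_parts) + tail
                spans = [(operon_end + 300, operon_end + 2800, "prophage")]
                reserved[eid].append((0, operon_end))
                genes += add_genes(eid, length, skip=[(0, operon_end)])
            else:
                length = cfg.element_len
                seq = _rand_dna(rng, length)
                spans = []
                if cls == "chromosome":
                    s = int(rng.integers(200, length - 2700))
                    spans = [(s, s + 2500, "prophage")]
                genes = add_genes(eid, length)
            genes.sort(key=lambda g: g.start)
            elements.append(MobileElement(eid, seq, cls, genes, spans))
    return elements, reserved


# ---------------------------------------------------------------------------
# Spacer construction


def _spacer_len(rng: np.random.Generator, cfg: WorldConfig) -> int:
    lo, hi = cfg.spacer_len_range
    return int(np.clip(round(rng.normal(cfg.spacer_len_mean, cfg.spacer_len_sd)), lo, hi))


def _random_spacer(rng: np.random.Generator, length: int, first: str, last: str,
                   forbidden: frozenset[str]) -> str:
    for _ in range(1000):
        s = first + _rand_dna(rng, length - 2) + last
        if not _has_forbidden(s, forbidden):
            return s
    raise RuntimeError("could not build a clean random spacer")


def _provenance_spacer(
    rng: np.random.Generator,
    cfg: WorldConfig,
    elements: Sequence[MobileElement],
    length: int,
    first: str,
    last: str,
    used: dict[str, list[tuple[int, int]]],
    forbidden: frozenset[str],
    force_element: Optional[str] = None,
    force_window: Optional[tuple[int, int]] = None,
    force_mismatches: Optional[int] = None,
) -> tuple[str, dict]:
    """A spacer copied from an element window, with the planned mismatch count.

    The window is chosen so the stored spacer's first/last characters equal
    the required boundary characters; mismatches are applied to interior
    positions only, so the planned mismatch count is exact.
    """
    by_class: dict[str, list[MobileElement]] = defaultdict(list)
    for e in elements:
        by_class[e.element_class].append(e)
    if force_mismatches is not None:
        n_mm = force_mismatches
    else:
        n_mm = int(rng.choice(3, p=list(cfg.mismatch_probs)))

    for _ in range(5000):
        if force_element is not None:
            elem = next(e for e in elements if e.element_id == force_element)
        else:
            cls = ("phage", "plasmid", "chromosome")[
                int(rng.choice(3, p=list(cfg.provenance_class_probs)))]
            pool = by_class[cls]
            if not pool:
                continue
            elem = pool[int(rng.integers(0, len(pool)))]
        lo, hi = force_window if force_window else (0, len(elem.seq))
        if hi - lo < length:
            continue
        want_genic = rng.random() < cfg.genic_fraction and bool(elem.genes)
        if want_genic and force_window is None:
            genes = [g for g in elem.genes if g.end - g.start >= length]
            if not genes:
                continue
            g = genes[int(rng.integers(0, len(genes)))]
            start = int(rng.integers(g.start, g.end - length + 1))
            want_coding = rng.random() < cfg.coding_strand_fraction
            hit_strand = g.strand if want_coding else ("-" if g.strand == "+" else "+")
        else:
            start = int(rng.integers(lo, hi - length + 1))
            if force_window is None and any(
                g.start < start + length and start < g.end for g in elem.genes
            ):
                continue
            hit_strand = "+" if rng.random() < 0.5 else "-"
        end = start + length
        if any(s < end and start < e for s, e in used.get(elem.element_id, [])):
            continue
        window = elem.seq[start:end]
        stored = window if hit_strand == "+" else reverse_complement(window)
        if stored[0] != first or stored[-1] != last:
            continue
        if _has_forbidden(stored, forbidden):
            continue
        if n_mm:
            pos = rng.choice(np.arange(1, length - 1), size=n_mm, replace=False)
            s_list = list(stored)
            for p in pos:
                alts = [b for b in _BASES if b != s_list[p]]
                s_list[p] = alts[rng.integers(0, 3)]
            mutated = "".join(s_list)
            if _has_forbidden(mutated, forbidden):
                continue
            stored = mutated
        used.setdefault(elem.element_id, []).append((start, end))
        prov = {
            "element_id": elem.element_id, "start": start, "end": end,
            "strand": hit_strand, "mismatches": n_mm,
            "recoverable": (length - n_mm) / length > 0.95,
        }
        return stored, prov
    raise RuntimeError("could not sample a provenance spacer window")


def _make_pools(
    rng: np.random.Generator,
    cfg: WorldConfig,
    plan: dict,
    elements: Sequence[MobileElement],
    used: dict[str, list[tuple[int, int]]],
    forbidden: frozenset[str],
) -> dict[str, list[dict]]:
    """Ancestral (shared) spacer pool per locus, oldest spacer = highest index.

    Pool spacer q carries fixed first/last characters from the cyclic
    alphabets, so any contiguous run of pool spacers yields boundary columns
    with near-uniform base usage.
    """
    pools: dict[str, list[dict]] = {}
    for locus in sorted(plan):
        pool: list[dict] = []
        for q in range(plan[locus]["pool"]):
            length = _spacer_len(rng, cfg)
            first = _POOL_FIRST[q % 4]
            last = _POOL_LAST[(q + 1) % 4]
            if rng.random() < cfg.provenance_fraction:
                seq, prov = _provenance_spacer(rng, cfg, elements, length, first,
                                               last, used, forbidden)
            else:
                seq, prov = _random_spacer(rng, length, first, last, forbidden), None
            pool.append({"seq": seq, "provenance": prov, "q": q})
        pools[locus] = pool
    return pools


# ---------------------------------------------------------------------------
# Boundary-column assignment


def _assign_column(fixed: Sequence[Optional[str]]) -> list[str]:
    """Fill the free entries of a boundary column, balancing base counts.

    Raises if the column cannot satisfy modal count <= len(fixed) - 2, the
    condition that stops a one-deviant column-consensus extension exactly at
    the repeat boundary.
    """
    m = len(fixed)
    counts = {b: 0 for b in _BASES}
    for c in fixed:
        if c is not None:
            counts[c] += 1
    out = list(fixed)
    for i in range(m):
        if out[i] is None:
            pick = min(_BASES, key=lambda b: (counts[b], b))
            out[i] = pick
            counts[pick] += 1
    if max(counts.values()) > m - 2:
        raise ValueError("boundary column cannot be made diverse enough")
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# World plan
#
# Per-locus membership: strain index -> (pool suffix start p, new singletons).
# A strain's array holds its new spacers (leader end) plus pool spacers p..end
# (leader-distal end), so old spacers are shared and new ones are unique.

_LOCUS_PLAN: dict = {
    "CRISPR1": {"repeat": "repeat1", "side": "left", "pool": 10,
                "members": {0: (0, 4), 1: (1, 3), 2: (2, 3), 3: (1, 2),
                            4: (0, 5), 5: (3, 4)}},
    "CRISPR2": {"repeat": "repeat1", "side": "left", "pool": 6,
                "members": {0: (0, 2), 1: (1, 2), 3: (2, 2), 5: (1, 2)}},
    "CRISPR3": {"repeat": "repeat2", "side": "right", "pool": 5,
                "members": {2: (0, 3), 4: (1, 2)}},
    "CRISPR4": {"repeat": "repeat2", "side": "right", "pool": 4,
                "members": {2: (0, 2), 4: (0, 3)}},
}
_ECOLI_INTACT = (0, 1, 5)
_ECOLI_PSEUDO = (3,)
_YPEST_INTACT = (2,)
_ANTI_INDEX = 4          # strain with cas-targeting spacers, no cognate operon
_IS_TARGET = (3, "CRISPR2")
_IS_SLOT = 3             # contig-order slot replaced by the IS element
_SELF_TARGET_INDEX = 0   # strain with a resident prophage its own spacer targets
_PROPHAGE_SRC = ("phage00", 500, 3500)


def _compose_array(
    rng: np.random.Generator,
    cfg: WorldConfig,
    side: str,
    repeat: str,
    pool: list[dict],
    p: int,
    n_new: int,
    forbidden: frozenset[str],
    elements: Sequence[MobileElement],
    used: dict[str, list[tuple[int, int]]],
    is_slot: Optional[int] = None,
    forced_prov: Optional[dict[int, tuple[str, tuple[int, int], int]]] = None,
) -> dict:
    """Build one array's sequence with boundary columns guaranteed diverse.

    Returns the array sequence with repeat/spacer coordinates relative to the
    array start, the required single flanking characters on each side, and
    the truth records for every spacer slot.
    """
    leader_order = [("new", i) for i in range(n_new)] + \
                   [("pool", q) for q in range(p, len(pool))]
    n_slots = len(leader_order)
    m = n_slots + 1
    if m < 3:
        raise ValueError("arrays need at least 3 repeats")

    for _attempt in range(200):
        if cfg.acquisition_mode == "uniform":
            order = [leader_order[i] for i in rng.permutation(n_slots)]
        else:
            order = list(leader_order)
        contig_order = order if side == "left" else order[::-1]
        fixed_first: list[Optional[str]] = []
        fixed_last: list[Optional[str]] = []
        for kind, v in contig_order:
            if kind == "pool":
                fixed_first.append(pool[v]["seq"][0])
                fixed_last.append(pool[v]["seq"][-1])
            else:
                fixed_first.append(None)
                fixed_last.append(None)
        try:
            chars_r = _assign_column(fixed_first + [None])
            chars_l = _assign_column([None] + fixed_last)
            break
        except ValueError:
            if cfg.acquisition_mode != "uniform":
                raise
    else:
        raise RuntimeError("could not find a boundary-safe slot order")

    # slot contents in contig order
    slots: list[dict] = []
    for j, (kind, v) in enumerate(contig_order):
        leader_index = j if side == "left" else n_slots - 1 - j
        first, last = chars_r[j], chars_l[j + 1]
        if is_slot is not None and j == is_slot:
            seq = first + _fresh_nc(rng, cfg.is_len - 2, forbidden) + last
            slots.append({"kind": "is", "seq": seq, "leader_index": leader_index,
                          "provenance": None})
            continue
        if kind == "pool":
            spec = pool[v]
            slots.append({"kind": "pool", "seq": spec["seq"], "q": v,
                          "leader_index": leader_index,
                          "provenance": spec["provenance"]})
            continue
        length = _spacer_len(rng, cfg)
        forced = (forced_prov or {}).get(leader_index)
        if forced is not None:
            eid, window, n_mm = forced
            seq, prov = _provenance_spacer(
                rng, cfg, elements, length, first, last, used, forbidden,
                force_element=eid, force_window=window, force_mismatches=n_mm)
        elif rng.random() < cfg.provenance_fraction:
            seq, prov = _provenance_spacer(rng, cfg, elements, length, first,
                                           last, used, forbidden)
        else:
            seq, prov = _random_spacer(rng, length, first, last, forbidden), None
        slots.append({"kind": "new", "seq": seq, "leader_index": leader_index,
                      "provenance": prov})

    # repeats, with a degenerate 3'-distal terminal
    repeats = [repeat] * m
    deg = cfg.terminal_degeneracy
    if deg > 0:
        if side == "left":      # 3' end of transcription = rightmost repeat
            t = list(repeats[-1])
            for i in range(len(t) - deg, len(t)):
                alts = [b for b in _BASES if b != t[i]]
                t[i] = alts[rng.integers(0, 3)]
            repeats[-1] = "".join(t)
        else:                   # leader on the right: 3' distal = leftmost repeat
            t = list(repeats[0])
            for i in range(deg):
                alts = [b for b in _BASES if b != t[i]]
                t[i] = alts[rng.integers(0, 3)]
            repeats[0] = "".join(t)

    parts: list[str] = []
    cursor = 0
    repeat_spans: list[tuple[int, int]] = []
    spacer_truth: list[dict] = []
    disrupted: list[tuple[int, int]] = []
    for j in range(m):
        parts.append(repeats[j])
        repeat_spans.append((cursor, cursor + len(repeats[j])))
        cursor += len(repeats[j])
        if j < n_slots:
            slot = slots[j]
            span = (cursor, cursor + len(slot["seq"]))
            parts.append(slot["seq"])
            cursor += len(slot["seq"])
            if slot["kind"] == "is":
                disrupted.append(span)
            else:
                spacer_truth.append({
                    "start": span[0], "end": span[1], "seq": slot["seq"],
                    "leader_index": slot["leader_index"],
                    "kind": slot["kind"], "provenance": slot["provenance"],
                    "singleton": None,
                })
    spacer_truth.sort(key=lambda s: s["leader_index"])
    return {
        "seq": "".join(parts),
        "repeat_spans": repeat_spans,
        "spacers": spacer_truth,
        "disrupted": disrupted,
        "left_char": chars_l[0],
        "right_char": chars_r[m - 1],
        "consensus": repeat,
        "side": side,
        "n_repeats": m,
    }


def _pseudogenize(rng: np.random.Generator, cds: str, frameshift: bool) -> tuple[str, list[str]]:
    """Degrade a CDS: one internal stop, optionally a single-base deletion."""
    n_codons = len(cds) // 3
    stop_at = max(2, int(n_codons * 0.35))
    seq = cds[: 3 * stop_at] + "TAA" + cds[3 * stop_at + 3 :]
    defects = ["internal_stop"]
    if frameshift:
        cut = 3 * max(stop_at + 5, int(n_codons * 0.65)) + 1
        if cut < len(seq) - 10:
            seq = seq[:cut] + seq[cut + 1 :]
            defects.append("frameshift")
    return seq, defects


def _make_ancestral(
    rng: np.random.Generator, cfg: WorldConfig,
    refs_by_subtype: dict[str, list[CasRef]], forbidden: frozenset[str],
) -> dict[str, tuple[str, str]]:
    """Shared ancestral parts: name -> (kind, seq); kind in cds | nc | trna."""
    anc: dict[str, tuple[str, str]] = {}
    for i in range(cfg.n_core_genes):
        anc[f"core_{i:02d}"] = ("cds", _rand_cds(rng, cfg.core_gene_len))
    for name, length in (("cysD", 900), ("cysJ", 900), ("ygcF", 900),
                         ("clpS", 600), ("infA", 300),
                         ("post_0", 900), ("post_1", 900)):
        anc[name] = ("cds", _rand_cds(rng, length))
    anc["tRNA-Ser"] = ("trna", _fresh_nc(rng, 90, forbidden))
    for locus in _LOCUS_PLAN:
        anc[f"leader_{locus}"] = ("nc", _fresh_nc(rng, cfg.leader_len, forbidden,
                                                  at=cfg.leader_at))
    for i in range(cfg.n_core_genes):
        anc[f"gapc_{i:02d}"] = ("nc", _fresh_nc(rng, 120, forbidden))
    for name, length in (("gap_c1a", 100), ("gap_c1b", 150), ("pad_c2", 2500),
                         ("gap_c2b", 150), ("gap_B", 300), ("gap_c3a", 100),
                         ("gap_y1", 100), ("gap_y2", 100), ("pad_c4", 2500),
                         ("gap_c4b", 120), ("gap_end", 200),
                         ("gap_p0", 120), ("gap_p1", 120)):
        anc[name] = ("nc", _fresh_nc(rng, length, forbidden))
    for subtype, refs in refs_by_subtype.items():
        for i, r in enumerate(refs):
            anc[f"{subtype}_{r.gene_name}"] = ("cds", r.cds)
            anc[f"gap_{subtype}_{i}"] = ("nc", _fresh_nc(rng, 50, forbidden))
    return anc


# ---------------------------------------------------------------------------
# Strain assembly


def _build_strain(
    idx: int,
    gid: str,
    cfg: WorldConfig,
    seed: int,
    anc: dict[str, tuple[str, str]],
    pools: dict[str, list[dict]],
    refs_by_subtype: dict[str, list[CasRef]],
    elements: Sequence[MobileElement],
    used: dict[str, list[tuple[int, int]]],
    forbidden: frozenset[str],
) -> tuple[Genome, dict]:
    rng = np.random.default_rng(seed)
    contig_id = f"{gid}_chr"
    chunks: list[str] = []
    genes: list[GeneRecord] = []
    espans: list[tuple[str, int, int, str]] = []
    truth: dict = {"arrays": [], "leaders": [], "cas": {}, "prophage": None}
    pos = 0

    def put(seq: str) -> int:
        nonlocal pos
        chunks.append(seq)
        start = pos
        pos += len(seq)
        return start

    def put_anc(name: str) -> int:
        kind, seq = anc[name]
        rate = cfg.strain_divergence
        mseq = _mutate_cds(rng, seq, rate) if kind == "cds" else _mutate_noncoding(rng, seq, rate)
        return put(mseq)

    def put_gene(name: str, product: str = "", ftype: str = "CDS") -> GeneRecord:
        kind, seq = anc[name]
        rate = cfg.strain_divergence
        mseq = _mutate_cds(rng, seq, rate) if kind == "cds" else _mutate_noncoding(rng, seq, rate)
        start = put(mseq)
        g = GeneRecord(f"{gid}_{name}", contig_id, start, start + len(mseq), "+",
                       product, None, ftype)
        genes.append(g)
        return g

    def put_array(locus: str) -> None:
        plan = _LOCUS_PLAN[locus]
        p, n_new = plan["members"][idx]
        repeat = cfg.repeat1 if plan["repeat"] == "repeat1" else cfg.repeat2
        is_slot = _IS_SLOT if (cfg.is_disruption and (idx, locus) == _IS_TARGET) else None
        forced = None
        if idx == _SELF_TARGET_INDEX and locus == "CRISPR1":
            eid, lo, hi = _PROPHAGE_SRC
            forced = {0: (eid, (lo, hi), 0)}
        comp = _compose_array(rng, cfg, plan["side"], repeat, pools[locus], p,
                              n_new, forbidden, elements, used,
                              is_slot=is_slot, forced_prov=forced)
        _, lseq = anc[f"leader_{locus}"]
        leader = _mutate_noncoding(rng, lseq, cfg.strain_divergence)
        flank = _fresh_nc(rng, 250, forbidden)
        if plan["side"] == "left":
            block = (leader[:-1] + comp["left_char"] + comp["seq"]
                     + comp["right_char"] + flank[1:])
            bstart = put(block)
            a_start = bstart + len(leader)
        else:
            block = (flank[:-1] + comp["left_char"] + comp["seq"]
                     + comp["right_char"] + leader[1:])
            bstart = put(block)
            a_start = bstart + len(flank)
        a_end = a_start + len(comp["seq"])
        leader_span = ((a_start - cfg.leader_len, a_start) if plan["side"] == "left"
                       else (a_end, a_end + cfg.leader_len))
        spacers = []
        for sp in comp["spacers"]:
            rec = dict(sp)
            rec["start"] += a_start
            rec["end"] += a_start
            spacers.append(rec)
        disrupted = [[s + a_start, e + a_start] for s, e in comp["disrupted"]]
        for s, e in disrupted:
            espans.append((contig_id, s, e, "IS"))
        truth["arrays"].append({
            "genome_id": gid, "contig_id": contig_id, "locus": locus,
            "orientation": "leader_left" if plan["side"] == "left" else "leader_right",
            "start": a_start, "end": a_end,
            "consensus": comp["consensus"], "n_repeats": comp["n_repeats"],
            "terminal_degenerate": cfg.terminal_degeneracy > 0,
            "repeats": [[s + a_start, e + a_start] for s, e in comp["repeat_spans"]],
            "spacers": spacers, "disrupted": disrupted,
        })
        truth["leaders"].append({
            "genome_id": gid, "locus": locus, "side": plan["side"],
            "start": leader_span[0], "end": leader_span[1],
        })

    def put_operon(subtype: str, mode: str) -> None:
        gene_truth = []
        for i, r in enumerate(refs_by_subtype[subtype]):
            if mode == "intact":
                g = put_gene(f"{subtype}_{r.gene_name}", product=r.gene_name)
                gene_truth.append({"gene": r.gene_name, "start": g.start,
                                   "end": g.end, "strand": "+",
                                   "status": "intact", "defects": []})
            else:
                seq, defects = _pseudogenize(rng, r.cds, frameshift=(i % 2 == 0))
                s = put(seq)
                gene_truth.append({"gene": r.gene_name, "start": s,
                                   "end": s + len(seq), "strand": "+",
                                   "status": "pseudo", "defects": defects})
            put_anc(f"gap_{subtype}_{i}")
        truth["cas"][subtype] = {
            "status": "complete" if mode == "intact" else "partial",
            "annotated": mode == "intact", "genes": gene_truth,
        }

    half = cfg.n_core_genes // 2
    for i in range(half):
        put_gene(f"core_{i:02d}")
        put_anc(f"gapc_{i:02d}")
    put_gene("cysD", product="cysD")
    put_anc("gap_c1a")
    put_array("CRISPR1")
    if idx in _ECOLI_INTACT:
        put_operon("Ecoli", "intact")
    elif idx in _ECOLI_PSEUDO:
        put_operon("Ecoli", "pseudo")
    else:
        truth["cas"]["Ecoli"] = {"status": "absent", "annotated": False, "genes": []}
    put_anc("gap_c1b")
    put_gene("cysJ", product="cysJ")
    put_anc("pad_c2")
    if idx in _LOCUS_PLAN["CRISPR2"]["members"]:
        put_array("CRISPR2")
    put_anc("gap_c2b")
    put_gene("ygcF", product="ygcF")
    put_anc("gap_B")
    for i in range(half, cfg.n_core_genes):
        put_gene(f"core_{i:02d}")
        put_anc(f"gapc_{i:02d}")
    put_gene("clpS", product="clpS")
    put_anc("gap_c3a")
    if idx in _LOCUS_PLAN["CRISPR3"]["members"]:
        put_array("CRISPR3")
    put_anc("gap_y1")
    if idx in _YPEST_INTACT:
        put_operon("Ypest", "intact")
    else:
        truth["cas"]["Ypest"] = {"status": "absent", "annotated": False, "genes": []}
    put_anc("gap_y2")
    put_gene("tRNA-Ser", product="tRNA-Ser", ftype="tRNA")
    put_anc("pad_c4")
    if idx in _LOCUS_PLAN["CRISPR4"]["members"]:
        put_array("CRISPR4")
    put_anc("gap_c4b")
    put_gene("infA", product="infA")
    put_anc("gap_end")
    # conserved downstream companions so infA sits in a stable gene neighborhood
    put_gene("post_0")
    put_anc("gap_p0")
    put_gene("post_1")
    put_anc("gap_p1")
    if idx == _SELF_TARGET_INDEX:
        eid, lo, hi = _PROPHAGE_SRC
        elem = next(e for e in elements if e.element_id == eid)
        s = put(elem.seq[lo:hi])
        espans.append((contig_id, s, s + (hi - lo), "prophage"))
        truth["prophage"] = {"element_id": eid, "src_start": lo, "src_end": hi,
                             "start": s, "end": s + (hi - lo)}

    tail = cfg.genome_length - pos
    if tail < 0:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small; layout needs {pos} bp")
    put(_rand_dna(rng, tail))
    genome = Genome(gid, [(contig_id, "".join(chunks))], genes, espans)
    return genome, truth


# ---------------------------------------------------------------------------
# Anti-CRISPR planting (public)


def plant_anti_crispr(
    genome: Genome,
    array_truth: dict,
    refs: Sequence[CasRef],
    n_spacers: int = 2,
    seed: int = 0,
    forbidden: frozenset[str] = frozenset(),
) -> list[dict]:
    """Overwrite the leader-most unique spacers of an array with cas-gene windows.

    Spacer spans and their boundary characters are preserved (the replacement
    window is chosen to start/end with the same characters), so detectability
    is unaffected.  The genome is modified in place; the updated truth
    records of the planted spacers are returned.
    """
    rng = np.random.default_rng(seed)
    candidates = sorted((s for s in array_truth["spacers"] if s["kind"] == "new"),
                        key=lambda s: s["leader_index"])[:n_spacers]
    if len(candidates) < n_spacers:
        raise ValueError("array has too few unique spacers to plant anti-CRISPR")
    cid = array_truth["contig_id"]
    i_contig = next(i for i, (c, _) in enumerate(genome.contigs) if c == cid)
    seq = genome.contigs[i_contig][1]
    planted = []
    for sp in candidates:
        length = sp["end"] - sp["start"]
        first, last = sp["seq"][0], sp["seq"][-1]
        window = None
        for _ in range(20_000):
            r = refs[int(rng.integers(0, len(refs)))]
            if len(r.cds) < length:
                continue
            st = int(rng.integers(0, len(r.cds) - length + 1))
            w = r.cds[st : st + length]
            if w[0] == first and w[-1] == last and not _has_forbidden(w, forbidden):
                window = (r, st, w)
                break
        if window is None:
            raise RuntimeError("could not find a cas-gene window with matching edges")
        r, st, w = window
        seq = seq[: sp["start"]] + w + seq[sp["end"] :]
        sp["seq"] = w
        sp["provenance"] = {"cas_ref": r.gene_name, "subtype": r.subtype,
                            "ref_start": st, "mismatches": 0, "recoverable": True}
        sp["anti"] = True
        planted.append(dict(sp))
    genome.contigs[i_contig] = (cid, seq)
    return planted


# ---------------------------------------------------------------------------
# World generation


def _ordered_refs(refs: Sequence[CasRef]) -> dict[str, list[CasRef]]:
    by_subtype: dict[str, list[CasRef]] = {}
    for subtype, canonical in (("Ecoli", ECOLI_CAS_GENES), ("Ypest", YPEST_CAS_GENES)):
        members = {r.gene_name: r for r in refs if r.subtype == subtype}
        by_subtype[subtype] = [members[g] for g in canonical if g in members]
    return by_subtype


def generate_world(
    config: Optional[WorldConfig] = None, seed: int = 0
) -> tuple[list[Genome], list[MobileElement], TruthSet]:
    """Generate a strain panel, an element pool and the full ground truth."""
    cfg = config or WorldConfig()
    forbidden = _forbidden_kmers(cfg)
    rng_master = np.random.default_rng(seed)
    sub = [int(s) for s in rng_master.integers(0, 2**31 - 1, size=16)]
    refs_by_subtype = _ordered_refs(load_cas_refs())

    elements, used = _make_elements(np.random.default_rng(sub[0]), cfg,
                                    refs_by_subtype["Ecoli"], forbidden)
    used = defaultdict(list, used)
    pools = _make_pools(np.random.default_rng(sub[1]), cfg, _LOCUS_PLAN,
                        elements, used, forbidden)
    anc = _make_ancestral(np.random.default_rng(sub[2]), cfg, refs_by_subtype,
                          forbidden)

    strain_ids = [f"g{i + 1}" for i in range(cfg.n_strains)]
    genomes: list[Genome] = []
    truth = TruthSet(config=asdict(cfg), genomes=list(strain_ids),
                     groups=[[gid] for gid in strain_ids])
    prophage_info = None
    for idx, gid in enumerate(strain_ids):
        genome, st = _build_strain(idx, gid, cfg, sub[3 + idx], anc, pools,
                                   refs_by_subtype, elements, used, forbidden)
        genomes.append(genome)
        truth.arrays.extend(st["arrays"])
        truth.leaders.extend(st["leaders"])
        truth.cas[gid] = st["cas"]
        if st["prophage"] is not None:
            prophage_info = (gid, st["prophage"])

    if cfg.anti_crispr and cfg.n_strains > _ANTI_INDEX:
        gid = strain_ids[_ANTI_INDEX]
        arr = next(a for a in truth.arrays_for(gid) if a["locus"] == "CRISPR1")
        planted = plant_anti_crispr(genomes[_ANTI_INDEX], arr,
                                    refs_by_subtype["Ecoli"],
                                    cfg.n_anti_spacers, sub[9], forbidden)
        truth.anti_crispr.append({
            "genome_id": gid, "locus": "CRISPR1", "subtype": "Ecoli",
            "spacers": [p["seq"] for p in planted],
        })

    if cfg.close_pair:
        src = genomes[1]
        twin_id = f"{src.genome_id}b"
        protect = [(a["contig_id"], a["start"] - 1, a["end"] + 1)
                   for a in truth.arrays_for(src.genome_id)]
        twin = evolve_strain(src, twin_id, cfg.close_pair_divergence, sub[10],
                             protect)
        genomes.append(twin)
        truth.genomes.append(twin_id)
        truth.groups[1].append(twin_id)
        renamed = json.loads(json.dumps(
            {"arrays": truth.arrays_for(src.genome_id),
             "leaders": [l for l in truth.leaders
                         if l["genome_id"] == src.genome_id]}
        ).replace(f'"{src.genome_id}_chr"', f'"{twin_id}_chr"')
         .replace(f'"{src.genome_id}"', f'"{twin_id}"'))
        truth.arrays.extend(renamed["arrays"])
        truth.leaders.extend(renamed["leaders"])
        truth.cas[twin_id] = json.loads(json.dumps(truth.cas[src.genome_id]))

    truth.elements = {e.element_id: e.element_class for e in elements}
    truth.ownership = {g.genome_id: [g.genome_id] for g in genomes}
    _finalize_singletons(truth)
    if prophage_info is not None:
        _finalize_self_targets(truth, prophage_info)
    return genomes, elements, truth


def _finalize_singletons(truth: TruthSet) -> None:
    """Singleton = spacer present in exactly one strain group (strand-normalised)."""
    group_of = {gid: gi for gi, members in enumerate(truth.groups) for gid in members}
    seen: dict[str, set[int]] = defaultdict(set)
    for arr in truth.arrays:
        for sp in arr["spacers"]:
            key = min(sp["seq"], reverse_complement(sp["seq"]))
            seen[key].add(group_of[arr["genome_id"]])
    for arr in truth.arrays:
        for sp in arr["spacers"]:
            key = min(sp["seq"], reverse_complement(sp["seq"]))
            sp["singleton"] = len(seen[key]) == 1


def _finalize_self_targets(truth: TruthSet, prophage_info: tuple[str, dict]) -> None:
    """Record spacers of the prophage-carrying strain that hit its own prophage."""
    gid, ph = prophage_info
    for arr in truth.arrays_for(gid):
        for sp in arr["spacers"]:
            prov = sp["provenance"]
            if (prov and prov.get("element_id") == ph["element_id"]
                    and prov["start"] < ph["src_end"]
                    and ph["src_start"] < prov["end"]
                    and prov.get("recoverable")):
                truth.self_targets.append({
                    "genome_id": gid, "spacer_seq": sp["seq"],
                    "element_id": ph["element_id"],
                    "chromosome_start": ph["start"] + prov["start"] - ph["src_start"],
                    "chromosome_end": ph["start"] + prov["end"] - ph["src_start"],
                })
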