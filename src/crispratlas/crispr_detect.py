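"""De novo CRISPR array detection, consensus building and spacer extraction.

The detector follows the classic seed-and-extend strategy for tandem direct
repeats: exact seed words recurring at array-like spacing are chained,
extended column-wise into full repeats, and the resulting candidate arrays
are re-anchored with a fuzzy (Hamming) search against their own consensus so
that degenerate repeats -- notably the 3'-degenerate terminal repeat -- and
repeats separated by an insertion-sequence gap are recovered.  Identity is
always Hamming matches over equal-length windows; no indels are considered
during rescue.  Windows containing N never count as matches.

Two repeat consensus sequences recur throughout enterobacterial genomes and
are used as configurable defaults elsewhere in the package: a 29 bp repeat
shared by the CRISPR1/CRISPR2 loci (with an A/T-ambiguous position, IUPAC W)
and a 28 bp repeat shared by CRISPR3/CRISPR4.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "REPEAT1_CONSENSUS",
    "REPEAT1_DEFAULT",
    "REPEAT2_CONSENSUS",
    "DetectorParams",
    "RepeatUnit",
    "Spacer",
    "ConsensusRepeat",
    "PositionFrequencyMatrix",
    "CrisprArray",
    "detect_arrays",
    "consensus_of",
    "fuzzy_find",
    "extract_spacers",
    "flag_terminal_degeneracy",
    "pfm_of",
    "palindromicity",
    "hamming_identity",
]

# CRISPR1/2 consensus (29 bp; position 28 is A or T) and CRISPR3/4 consensus (28 bp)
REPEAT1_CONSENSUS = "CGGTTTATCCCCGCTGGCGCGGGGAACWC"
REPEAT1_DEFAULT = "CGGTTTATCCCCGCTGGCGCGGGGAACAC"
REPEAT2_CONSENSUS = "GTTCACTGCCGTACAGGCAGCTTAGAAA"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# IUPAC nucleotide codes as 4-bit sets over (A, C, G, T)
_IUPAC_MASK = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111,
}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code of every k-window plus a validity mask (no N inside)."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        window = codes[j : j + m]
        out = out * 4 + np.where(window < 4, window, 0)
        bad |= window >= 4
    return out, ~bad


def hamming_identity(a: str, b: str) -> float:
    """Fraction of matching positions over equal-length strings (N never matches)."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return matches / len(a)


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class DetectorParams:
    """Detector configuration; defaults mirror the published CRT defaults."""

    seed_word: int = 8
    min_repeats: int = 3
    repeat_len: tuple[int, int] = (19, 38)
    spacer_len: tuple[int, int] = (19, 48)
    rescue_min_identity: float = 0.6
    max_gap_spacers: int = 1
    # boundary-extension rescue is held to a stricter identity than interior
    # gap-filling, so arrays are not spuriously extended into random flanks
    edge_rescue_identity: float = 0.75
    min_repeat_identity: float = 0.8
    rescue_pad: int = 1500
    max_disrupt_gap: int = 2000

    def __post_init__(self) -> None:
        if self.repeat_len[0] > self.repeat_len[1] or self.spacer_len[0] > self.spacer_len[1]:
            raise ValueError("min must not exceed max for repeat/spacer length ranges")
        if not (0 < self.rescue_min_identity <= 1):
            raise ValueError("rescue_min_identity must be in (0, 1]")

    @property
    def period_min(self) -> int:
        return self.repeat_len[0] + self.spacer_len[0]

    @property
    def period_max(self) -> int:
        return self.repeat_len[1] + self.spacer_len[1]


@dataclass
class RepeatUnit:
    start: int
    end: int
    seq: str
    identity_to_consensus: float = 1.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("repeat seq length must equal span length")


@dataclass
class Spacer:
    spacer_id: str
    array_id: str
    index_from_leader: int
    seq: str
    start: int
    end: int


@dataclass
class ConsensusRepeat:
    seq: str
    support: int
    exact_fraction: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PositionFrequencyMatrix:
    """Per-position relative base frequencies over (A, C, G, T); rows sum to 1."""

    freqs: np.ndarray  # shape (L, 4)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.freqs, axis=1))


@dataclass
class CrisprArray:
    array_id: str
    contig_id: str
    repeats: list[RepeatUnit]
    spacers: list[Spacer] = field(default_factory=list)
    orientation: str = "unknown"  # leader_left | leader_right | unknown
    consensus: Optional[ConsensusRepeat] = None
    flags: dict = field(default_factory=dict)
    # oversized inter-repeat segments (IS insertions / missing spacers): (start, end)
    disrupted_segments: list[tuple[int, int]] = field(default_factory=list)
    genome_id: str = ""
    locus: str = "unanchored"

    @property
    def start(self) -> int:
        return self.repeats[0].start

    @property
    def end(self) -> int:
        return self.repeats[-1].end

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def spacers_in_leader_order(self) -> list[Spacer]:
        """Spacers ordered from the leader end (index 0 = newest)."""
        if self.orientation == "leader_right":
            return list(reversed(self.spacers))
        return list(self.spacers)


# ---------------------------------------------------------------------------
# Consensus / frequency matrix / palindromicity


def consensus_of(repeat_seqs: Sequence[str], exclude_terminal: bool = False) -> ConsensusRepeat:
    """Modal full-length repeat sequence; ties broken lexicographically.

    ``exclude_terminal`` drops the first and last sequence from the
    exact-fraction bookkeeping (terminal repeats are typically degenerate),
    while the mode itself is still computed over all sequences.
    """
    seqs = list(repeat_seqs)
    if not seqs:
        raise ValueError("consensus_of requires at least one repeat")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("consensus_of requires equal-length repeats")
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    top = max(counts.values())
    modal = min(s for s, c in counts.items() if c == top)
    internal = seqs[1:-1] if exclude_terminal and len(seqs) > 2 else seqs
    support = len(internal)
    exact = sum(1 for s in internal if s == modal) / support if support else 0.0
    return ConsensusRepeat(seq=modal, support=support, exact_fraction=exact)


def pfm_of(repeat_seqs: Sequence[str]) -> PositionFrequencyMatrix:
    """Column-wise relative base frequencies; N is excluded from the counts."""
    seqs = list(repeat_seqs)
    if not seqs:
        raise ValueError("pfm_of requires at least one sequence")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("pfm_of requires equal-length sequences")
    L = len(seqs[0])
    counts = np.zeros((L, 4), dtype=float)
    for s in seqs:
        for i, c in enumerate(s):
            if c in _BASE_CODE:
                counts[i, _BASE_CODE[c]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return PositionFrequencyMatrix(freqs=counts / totals)


_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}


def palindromicity(seq: str, include_gu: bool = False, min_loop: int = 3) -> float:
    """Self-complementarity score in [0, 1] as a stand-in for fold stability.

    Maximum number of nested base pairs (Nussinov recursion, minimum hairpin
    loop of ``min_loop`` unpaired bases) divided by floor(len/2).  The default
    pairing alphabet is Watson-Crick only, which makes the score invariant
    under reverse complementation; GU wobble pairs can be enabled but break
    that symmetry.
    """
    n = len(seq)
    if n < 8:
        raise ValueError("palindromicity requires length >= 8")
    pairs = _WC_PAIRS | (_GU_PAIRS if include_gu else set())
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if (seq[i], seq[j]) in pairs:
                best = max(best, dp[i + 1, j - 1] + 1)
            for k in range(i + 1, j):
                if (seq[i], seq[k]) in pairs and k - i > min_loop:
                    cand = dp[i + 1, k - 1] + 1 + (dp[k + 1, j] if k + 1 <= j else 0)
                    best = max(best, cand)
            dp[i, j] = best
    return float(dp[0, n - 1]) / (n // 2)


# ---------------------------------------------------------------------------
# Fuzzy (Hamming) consensus search


def _consensus_masks(consensus: str) -> tuple[np.ndarray, np.ndarray]:
    fwd = np.array([_IUPAC_MASK.get(c, 0) for c in consensus], dtype=np.uint8)
    comp = np.zeros_like(fwd)
    # complement each 4-bit set: A<->T (bits 0,3), C<->G (bits 1,2)
    comp |= ((fwd >> 0) & 1) << 3
    comp |= ((fwd >> 3) & 1) << 0
    comp |= ((fwd >> 1) & 1) << 2
    comp |= ((fwd >> 2) & 1) << 1
    return fwd, comp[::-1].copy()


def fuzzy_find(
    contig: str,
    consensus: ConsensusRepeat | str,
    region: tuple[int, int],
    min_identity: float,
    both_strands: bool = True,
) -> list[RepeatUnit]:
    """All non-overlapping consensus-like windows in a region, best first.

    Every window of consensus length on either strand with Hamming identity
    >= ``min_identity`` is a candidate; IUPAC codes in the consensus match any
    of their bases.  Candidates are made non-overlapping greedily in order of
    decreasing identity (ties: leftmost, then forward strand).
    """
    cons = consensus.seq if isinstance(consensus, ConsensusRepeat) else consensus
    L = len(cons)
    lo, hi = region
    if not (0 <= lo <= hi <= len(contig)):
        raise ValueError(f"region {region} out of contig bounds")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    if hi - lo < L:
        return []
    sub = contig[lo:hi]
    codes = _encode(sub)
    bits = np.where(codes < 4, np.left_shift(1, codes, dtype=np.uint8), 0).astype(np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(bits, L)
    fwd_mask, rc_mask = _consensus_masks(cons)
    candidates: list[tuple[float, int, str]] = []
    strands = [("+", fwd_mask)] + ([("-", rc_mask)] if both_strands else [])
    for strand, mask in strands:
        matches = ((windows & mask[None, :]) != 0).sum(axis=1)
        ident = matches / L
        for idx in np.flatnonzero(ident >= min_identity):
            candidates.append((float(ident[idx]), int(idx), strand))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: list[RepeatUnit] = []
    occupied: list[tuple[int, int]] = []
    for ident, idx, strand in candidates:
        s, e = lo + idx, lo + idx + L
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        chosen.append(RepeatUnit(start=s, end=e, seq=contig[s:e],
                                 identity_to_consensus=ident, strand=strand))
    chosen.sort(key=lambda u: u.start)
    return chosen


# ---------------------------------------------------------------------------
# Seed chaining and extension


def _seed_chains(codes: np.ndarray, params: DetectorParams) -> list[np.ndarray]:
    k = params.seed_word
    kcodes, valid = _kmer_codes(codes, k)
    pos_all = np.flatnonzero(valid)
    if pos_all.size < 2:
        return []
    kv = kcodes[pos_all]
    order = np.argsort(kv, kind="stable")
    kv, pv = kv[order], pos_all[order]
    same = kv[1:] == kv[:-1]
    gap = pv[1:] - pv[:-1]
    link = same & (gap >= params.period_min) & (gap <= 2 * params.period_max)
    chains: list[np.ndarray] = []
    idx = np.flatnonzero(link)
    if idx.size == 0:
        return []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            chains.append(pv[start : prev + 2])
            start = i
        prev = i
    chains.append(pv[start : prev + 2])
    return chains


def _column_agreement(codes: np.ndarray, qs: np.ndarray, offset: int, allow: int) -> bool:
    pos = qs + offset
    if pos[0] < 0 or pos[-1] >= codes.shape[0]:
        return False
    cols = codes[pos]
    good = cols[cols < 4]
    if good.size == 0:
        return False
    modal = int(np.bincount(good, minlength=4).max())
    return (qs.shape[0] - modal) <= allow


def _extend_chain(
    codes: np.ndarray, qs: np.ndarray, params: DetectorParams
) -> Optional[tuple[np.ndarray, int]]:
    """Grow the seed windows into full equal-length repeats.

    Columns are added while at most one occurrence deviates from the modal
    base (unanimity for two occurrences), bounded by the repeat-length range
    and by the requirement that no spacer shrinks below its minimum.
    """
    k = params.seed_word
    m = qs.shape[0]
    allow = 1 if m >= 3 else 0
    gaps = np.diff(qs)
    normal = gaps[gaps <= params.period_max]
    cap = params.repeat_len[1]
    if normal.size:
        cap = min(cap, int(normal.min()) - params.spacer_len[0])
    if cap < params.repeat_len[0]:
        return None
    left, right = 0, k
    while left + right < cap and _column_agreement(codes, qs, right, allow):
        right += 1
    while left + right < cap and _column_agreement(codes, qs, -left - 1, allow):
        left += 1
    L = left + right
    if L < params.repeat_len[0]:
        return None
    return qs - left, L


def _chain_consensus(contig: str, starts: np.ndarray, L: int) -> ConsensusRepeat:
    return consensus_of([contig[s : s + L] for s in starts])


def _split_on_bad_gaps(
    starts: np.ndarray, L: int, params: DetectorParams
) -> list[np.ndarray]:
    """Split a repeat chain wherever adjacent spacing is invalid and not rescuable."""
    runs: list[list[int]] = [[int(starts[0])]]
    for prev, cur in zip(starts[:-1], starts[1:]):
        spacer = int(cur) - (int(prev) + L)
        if params.spacer_len[0] <= spacer <= params.spacer_len[1]:
            runs[-1].append(int(cur))
        elif spacer > params.spacer_len[1]:
            runs[-1].append(int(cur))  # oversized gap resolved during rescue
        else:
            runs.append([int(cur)])
    return [np.array(r) for r in runs]


def _assemble(
    contig: str,
    units: list[RepeatUnit],
    anchor_span: tuple[int, int],
    params: DetectorParams,
) -> tuple[list[RepeatUnit], list[tuple[int, int]]]:
    """Chain fuzzy-rescued units into one array around an anchor span.

    Interior gaps may exceed the spacer maximum up to ``max_disrupt_gap``
    (IS insertion / missing spacer); such segments are recorded rather than
    emitted as spacers.  Units that extend the array beyond the anchor are
    held to the stricter edge identity.
    """
    units = [u for u in units if u.strand == "+"]
    if not units:
        return [], []
    # anchor = highest-identity unit overlapping the anchor span
    overlapping = [u for u in units if u.start < anchor_span[1] and anchor_span[0] < u.end]
    pool = overlapping if overlapping else units
    anchor = max(pool, key=lambda u: (u.identity_to_consensus, -u.start))
    by_start = sorted(units, key=lambda u: u.start)
    i = by_start.index(anchor)
    chain = [anchor]
    disrupted: list[tuple[int, int]] = []

    def edge_ok(u: RepeatUnit) -> bool:
        if anchor_span[0] <= u.start and u.end <= anchor_span[1]:
            return u.identity_to_consensus >= params.rescue_min_identity
        return u.identity_to_consensus >= params.edge_rescue_identity

    j = i
    while j + 1 < len(by_start):
        cur = chain[-1]
        nxt = None
        for cand in by_start[j + 1 :]:
            gap = cand.start - cur.end
            if gap < params.spacer_len[0]:
                continue
            if gap <= params.spacer_len[1] and edge_ok(cand):
                nxt = cand
                break
            if gap <= params.max_disrupt_gap and edge_ok(cand):
                nxt = cand
                disrupted.append((cur.end, cand.start))
                break
            break
        if nxt is None:
            break
        chain.append(nxt)
        j = by_start.index(nxt)
    j = i
    while j > 0:
        cur = chain[0]
        prv = None
        for cand in reversed(by_start[:j]):
            gap = cur.start - cand.end
            if gap < params.spacer_len[0]:
                continue
            if gap <= params.spacer_len[1] and edge_ok(cand):
                prv = cand
                break
            if gap <= params.max_disrupt_gap and edge_ok(cand):
                prv = cand
                disrupted.append((cand.end, cur.start))
                break
            break
        if prv is None:
            break
        chain.insert(0, prv)
        j = by_start.index(prv)
    disrupted.sort()
    return chain, disrupted


def _build_array(
    contig: str,
    contig_id: str,
    repeats: list[RepeatUnit],
    disrupted: list[tuple[int, int]],
    consensus: ConsensusRepeat,
    array_id: str,
) -> CrisprArray:
    arr = CrisprArray(
        array_id=array_id,
        contig_id=contig_id,
        repeats=sorted(repeats, key=lambda u: u.start),
        consensus=consensus,
        disrupted_segments=disrupted,
        flags={
            "is_disrupted": bool(disrupted),
            "single_repeat": len(repeats) == 1,
            "terminal_3prime_degenerate": False,
        },
    )
    arr.spacers = extract_spacers(arr, contig)
    five, three = flag_terminal_degeneracy(arr)
    arr.flags["terminal_3prime_degenerate"] = three
    return arr


def detect_arrays(
    contig: str, params: Optional[DetectorParams] = None, contig_id: str = "contig"
) -> list[CrisprArray]:
    """Detect CRISPR arrays de novo on one contig.

    Returns maximal, non-overlapping arrays of >= ``min_repeats`` equal-length
    repeats within the configured repeat/spacer length ranges, with degenerate
    and IS-separated repeats recovered by consensus-guided rescue.
    """
    params = params or DetectorParams()
    if len(contig) < params.repeat_len[0] * params.min_repeats + params.spacer_len[0] * (
        params.min_repeats - 1
    ):
        return []
    codes = _encode(contig)
    chains = _seed_chains(codes, params)

    candidates: list[tuple[np.ndarray, int]] = []  # (repeat starts, L)
    loose_units: list[RepeatUnit] = []
    for qs in chains:
        ext = _extend_chain(codes, qs, params)
        if ext is None:
            continue
        starts, L = ext
        for run in _split_on_bad_gaps(starts, L, params):
            if run.shape[0] >= params.min_repeats:
                candidates.append((run, L))
            else:
                for s in run:
                    loose_units.append(
                        RepeatUnit(int(s), int(s) + L, contig[s : s + L])
                    )

    # stitch fragmented evidence (mutated repeats break exact seed chains)
    candidates.extend(_stitch_loose_units(loose_units, params))

    arrays: list[CrisprArray] = []
    seen_spans: set[tuple[int, int, int]] = set()
    for idx, (starts, L) in enumerate(candidates):
        key = (int(starts[0]), int(starts[-1]), L)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        consensus = _chain_consensus(contig, starts, L)
        span = (int(starts[0]), int(starts[-1]) + L)
        region = (max(0, span[0] - params.rescue_pad), min(len(contig), span[1] + params.rescue_pad))
        units = fuzzy_find(contig, consensus, region, params.rescue_min_identity,
                           both_strands=False)
        repeats, disrupted = _assemble(contig, units, span, params)
        if len(repeats) < params.min_repeats:
            continue
        good = [r for r in repeats if r.identity_to_consensus >= params.min_repeat_identity]
        if len(good) < params.min_repeats:
            continue
        consensus = consensus_of([r.seq for r in repeats], exclude_terminal=True)
        arrays.append(
            _build_array(contig, contig_id, repeats, disrupted, consensus, f"array_{idx}")
        )

    # global non-overlap, best first (repeat count, then summed identity, then position)
    arrays.sort(
        key=lambda a: (-a.n_repeats, -sum(r.identity_to_consensus for r in a.repeats), a.start)
    )
    final: list[CrisprArray] = []
    for arr in arrays:
        if any(arr.start < f.end and f.start < arr.end for f in final):
            continue
        final.append(arr)
    final.sort(key=lambda a: a.start)
    for i, arr in enumerate(final):
        arr.array_id = f"{contig_id}_arr{i}"
        for sp in arr.spacers:
            sp.array_id = arr.array_id
    return final


def _stitch_loose_units(
    units: list[RepeatUnit], params: DetectorParams
) -> list[tuple[np.ndarray, int]]:
    """Group isolated repeat-pair evidence into array candidates.

    Units whose spans overlap are merged (one merged locus per repeat); runs of
    loci at valid array spacing with at least ``min_repeats`` members become
    candidates for consensus rescue.
    """
    if not units:
        return []
    units = sorted(units, key=lambda u: (u.start, -u.end))
    merged: list[list[int]] = []  # [start, end]
    for u in units:
        if merged and u.start < merged[-1][1]:
            merged[-1][0] = min(merged[-1][0], u.start)
            merged[-1][1] = max(merged[-1][1], u.end)
        else:
            merged.append([u.start, u.end])
    out: list[tuple[np.ndarray, int]] = []
    run: list[list[int]] = [merged[0]]
    for loc in merged[1:]:
        gap = loc[0] - run[-1][0]
        if params.period_min <= gap <= 2 * params.period_max:
            run.append(loc)
        else:
            if len(run) >= params.min_repeats:
                out.append(_run_to_candidate(run, params))
            run = [loc]
    if len(run) >= params.min_repeats:
        out.append(_run_to_candidate(run, params))
    return [c for c in out if c is not None]


def _run_to_candidate(run: list[list[int]], params: DetectorParams):
    lengths = [e - s for s, e in run]
    L = int(np.median(lengths))
    L = max(params.repeat_len[0], min(params.repeat_len[1], L))
    starts = np.array([s for s, _ in run])
    return starts, L


# ---------------------------------------------------------------------------
# Spacers and terminal degeneracy


def extract_spacers(array: CrisprArray, contig: str) -> list[Spacer]:
    """Inter-repeat segments in contig order; oversized segments are withheld.

    Concatenating repeats and spacers (and any withheld disrupted segments) in
    order reproduces the contig substring of the array span exactly.
    """
    reps = array.repeats
    for a, b in zip(reps[:-1], reps[1:]):
        if a.end > b.start:
            raise ValueError(f"{array.array_id}: overlapping repeats")
    disrupted = set((s, e) for s, e in array.disrupted_segments)
    spacers: list[Spacer] = []
    for i, (a, b) in enumerate(zip(reps[:-1], reps[1:])):
        seg = (a.end, b.start)
        if seg in disrupted:
            continue
        spacers.append(
            Spacer(
                spacer_id=f"{array.array_id}_sp{i}",
                array_id=array.array_id,
                index_from_leader=len(spacers),
                seq=contig[a.end : b.start],
                start=a.end,
                end=b.start,
            )
        )
    return spacers


def flag_terminal_degeneracy(
    array: CrisprArray, internal_identity_floor: float = 0.9
) -> tuple[bool, bool]:
    """Whether the 5' / 3' terminal repeats are degenerate in their distal third.

    Terminals are interpreted in transcription orientation (leader side = 5');
    with unknown orientation the contig-forward order is used.  A terminal is
    degenerate when it differs from the consensus within its distal third
    while internal repeats stay near-exact on average.
    """
    reps = array.repeats
    if array.consensus is None or len(reps) < 2:
        return False, False
    cons = array.consensus.seq
    L = len(cons)
    third = max(1, L // 3)
    internal = reps[1:-1] or reps
    mean_internal = float(np.mean([hamming_identity(r.seq, cons) for r in internal
                                   if len(r.seq) == L] or [0.0]))
    if mean_internal < internal_identity_floor:
        return False, False

    def mismatch_in(rep: RepeatUnit, sl: slice) -> bool:
        if len(rep.seq) != L:
            return True
        return any(a != b for a, b in zip(rep.seq[sl], cons[sl]))

    left_rep, right_rep = reps[0], reps[-1]
    # distal ends point away from the array interior
    left_distal = mismatch_in(left_rep, slice(0, third))
    right_distal = mismatch_in(right_rep, slice(L - third, L))
    if array.orientation == "leader_right":
        five_prime, three_prime = right_distal, left_distal
    else:
        five_prime, three_prime = left_distal, right_distal
    return five_prime, three_prime
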