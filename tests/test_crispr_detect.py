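"""Detector unit tests plus a brute-force repeat-chain oracle on small contigs."""
from __future__ import annotations

import numpy as np
import pytest

from crispratlas.crispr_detect import (
    REPEAT1_CONSENSUS,
    REPEAT1_DEFAULT,
    REPEAT2_CONSENSUS,
    consensus_of,
    detect_arrays,
    extract_spacers,
    flag_terminal_degeneracy,
    fuzzy_find,
    hamming_identity,
    palindromicity,
    pfm_of,
)
from crispratlas.genome_io import reverse_complement


def _compose(repeat: str, spacers: list[str], flank: int = 250, seed: int = 0) -> tuple[str, list[int]]:
    """Random-flanked array of exact repeats; returns (contig, repeat starts)."""
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    # fixed flank edge chars keep the boundary columns diverse, so one-deviant
    # column extension cannot walk past the true repeat edges at any seed
    left = rand(flank - 1) + "C"
    parts, starts, pos = [left], [], len(left)
    for sp in spacers + [None]:
        starts.append(pos)
        parts.append(repeat)
        pos += len(repeat)
        if sp is not None:
            parts.append(sp)
            pos += len(sp)
    parts.append("T" + rand(flank - 1))
    return "".join(parts), starts


SPACERS = ["ACTTAGGACTATTACCGGATAACCTAGGAAGG",
           "CTGACCTAGGCATTACGGATCCTTAAGGACAT",
           "GAGGATTTACCGTTAACCGGTTAAGCATACCA"]


def test_hamming_identity():
    assert hamming_identity("ACGT", "ACGT") == 1.0
    assert hamming_identity("ACGT", "ACGA") == 0.75
    with pytest.raises(ValueError):
        hamming_identity("ACGT", "ACG")


def test_detects_simple_array_exact_boundaries():
    contig, starts = _compose(REPEAT1_DEFAULT, SPACERS)
    arrays = detect_arrays(contig, contig_id="c")
    assert len(arrays) == 1
    arr = arrays[0]
    assert [r.start for r in arr.repeats] == starts
    assert all(r.end - r.start == len(REPEAT1_DEFAULT) for r in arr.repeats)
    assert [s.seq for s in arr.spacers] == SPACERS


def test_detects_reverse_complement_array():
    contig, starts = _compose(REPEAT1_DEFAULT, SPACERS, seed=5)
    rc = reverse_complement(contig)
    arrays = detect_arrays(rc, contig_id="c")
    assert len(arrays) == 1
    spaced = {reverse_complement(s.seq) for s in arrays[0].spacers}
    assert spaced == set(SPACERS)


def test_no_array_in_random_sequence():
    rng = np.random.default_rng(11)
    contig = "".join(rng.choice(list("ACGT"), size=20_000))
    assert detect_arrays(contig, contig_id="c") == []


def test_two_repeats_not_reported_by_default():
    contig, _ = _compose(REPEAT1_DEFAULT, SPACERS[:1])  # 2 repeats, 1 spacer
    arrays = detect_arrays(contig, contig_id="c")
    assert arrays == []


def test_consensus_majority_and_exact_fraction():
    reps = [REPEAT1_DEFAULT, REPEAT1_DEFAULT,
            REPEAT1_DEFAULT[:-1] + ("G" if REPEAT1_DEFAULT[-1] != "G" else "T")]
    cons = consensus_of(reps)
    assert cons.seq == REPEAT1_DEFAULT
    assert cons.support == 3
    assert cons.exact_fraction == pytest.approx(2 / 3)


def test_fuzzy_find_recovers_planted_degenerate_copy():
    contig, starts = _compose(REPEAT1_DEFAULT, SPACERS, seed=2)
    mutated = list(contig)
    mutated[starts[0] + 3] = "A" if contig[starts[0] + 3] != "A" else "C"
    units = fuzzy_find("".join(mutated), REPEAT1_DEFAULT,
                       (0, len(contig)), min_identity=0.9)
    assert starts == sorted(u.start for u in units if u.strand == "+")


def test_terminal_degeneracy_flag():
    reps = [REPEAT1_DEFAULT] * 5
    contig, starts = _compose(REPEAT1_DEFAULT, SPACERS + [SPACERS[0][::-1]], seed=3)
    # damage the distal third of the last repeat at 5 positions
    L = len(REPEAT1_DEFAULT)
    mut = list(contig)
    for off in range(L - 5, L):
        pos = starts[-1] + off
        mut[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[pos]]
    arrays = detect_arrays("".join(mut), contig_id="c")
    assert len(arrays) == 1
    deg5, deg3 = flag_terminal_degeneracy(arrays[0])
    assert deg3 and not deg5


def test_pfm_columns_sum_to_one():
    pfm = pfm_of([REPEAT1_DEFAULT, REPEAT1_DEFAULT[::-1]])
    assert pfm.freqs.shape == (len(REPEAT1_DEFAULT), 4)
    assert np.allclose(pfm.freqs.sum(axis=1), 1.0)
    assert pfm_of([REPEAT1_DEFAULT]).consensus() == REPEAT1_DEFAULT


def test_palindromicity_bounds_and_ordering():
    hairpin = "GGGCCCAAATTTGGGCCC"      # strong stem
    random_ish = "ACT" * 6
    ph = palindromicity(hairpin)
    pr = palindromicity(random_ish)
    assert 0.0 <= pr <= ph <= 1.0
    assert palindromicity(hairpin, include_gu=True) >= ph


# ---------------------------------------------------------------------------
# Brute-force oracle: fuzzy occurrences of the true consensus, chained by
# plausible spacing, must coincide with both the planted truth and the
# detector output on every small test contig.

def _oracle_chains(contig: str, consensus: str, min_identity: float = 0.8,
                   spacer_range: tuple[int, int] = (19, 48),
                   disrupt_gap: int = 2000) -> list[list[int]]:
    L = len(consensus)
    rc = reverse_complement(consensus)
    occs = []
    for i in range(len(contig) - L + 1):
        w = contig[i : i + L]
        if hamming_identity(w, consensus) >= min_identity or \
           hamming_identity(w, rc) >= min_identity:
            occs.append(i)
    # keep local-best occurrences: drop any overlapping a better-scoring one
    def score(i: int) -> float:
        w = contig[i : i + L]
        return max(hamming_identity(w, consensus), hamming_identity(w, rc))

    keep = [i for i in occs
            if not any(j != i and abs(j - i) < L and
                       (score(j), -j) > (score(i), -i) for j in occs)]
    chains: list[list[int]] = []
    lo, hi = L + spacer_range[0], L + spacer_range[1]
    for i in keep:
        if chains and (lo <= i - chains[-1][-1] <= hi
                       or i - chains[-1][-1] <= disrupt_gap + L):
            chains[-1].append(i)
        else:
            chains.append([i])
    return [c for c in chains if len(c) >= 3]


def test_detector_matches_oracle_and_truth_on_world_slices(small_world, genomes_by_id):
    _, _, truth = small_world
    pad = 300
    checked = 0
    for rec in truth.arrays:
        genome = genomes_by_id[rec["genome_id"]]
        contig = dict(genome.contigs)[rec["contig_id"]]
        a, b = max(0, rec["start"] - pad), min(len(contig), rec["end"] + pad)
        if b - a > 10_000:
            continue
        piece = contig[a:b]
        truth_starts = [s - a for s, _ in rec["repeats"]]
        chains = _oracle_chains(piece, rec["consensus"])
        assert chains == [truth_starts], rec["genome_id"] + ":" + rec["locus"]
        arrays = detect_arrays(piece, contig_id="slice")
        assert len(arrays) == 1
        assert [r.start for r in arrays[0].repeats] == truth_starts
        checked += 1
    assert checked >= 10


def test_extract_spacers_round_trip():
    contig, _ = _compose(REPEAT1_DEFAULT, SPACERS, seed=9)
    arr = detect_arrays(contig, contig_id="c")[0]
    spacers = extract_spacers(arr, contig)
    assert [s.seq for s in spacers] == SPACERS
    for s in spacers:
        assert contig[s.start : s.end] == s.seq
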